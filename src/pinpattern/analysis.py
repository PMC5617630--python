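"""Pattern statistics for simulation outcomes.

Turns the qualitative outcome "auxin peaks form, and with the KAN/REV
prepattern they sit in the boundary annulus" into numbers: graph-local
peak detection, the boundary-restriction score (fraction of peaks in
the annulus), circular peak-spacing statistics and a mass-conservation
diagnostic for closed (production-free) runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ModelParams, SystemState, Trajectory
from .tissue import TissueGraph

__all__ = [
    "PeakSet",
    "PeakSpacing",
    "ConservationReport",
    "UndefinedStatisticError",
    "detect_peaks",
    "boundary_restriction_score",
    "peak_spacing",
    "peak_radii",
    "conservation_report",
    "plot_tissue",
]


class UndefinedStatisticError(ValueError):
    """A statistic was requested on input where it is undefined."""


@dataclass
class PeakSet:
    """Auxin maxima: cells strictly exceeding all wall-neighbors.

    A cell is a peak iff its A strictly exceeds every neighbor's A and
    exceeds ``threshold_used`` (a fraction of the global maximum); ties
    disqualify both cells, so a homogeneous field has no peaks and no
    two peaks are ever wall-adjacent.
    """

    peak_cells: list[int]
    peak_values: np.ndarray
    threshold_used: float
    peak_indices: list[int] | None = None   # positions in tissue cell order

    def __len__(self) -> int:
        return len(self.peak_cells)


def detect_peaks(
    state: SystemState, tissue: TissueGraph, rel_threshold: float = 0.5
) -> PeakSet:
    """Strict graph-local auxin maxima above ``rel_threshold * max(A)``."""
    if tissue.n_cells == 0:
        raise ValueError("empty tissue")
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must lie in (0, 1]")
    A = np.asarray(state.A, dtype=float)
    if len(A) != tissue.n_cells:
        raise ValueError("state/tissue size mismatch")
    wi, wj = tissue.wall_index_arrays()
    is_max = np.ones(tissue.n_cells, dtype=bool)
    # each wall disqualifies the lower side; a tie disqualifies both
    np.logical_and.at(is_max, wi, A[wi] > A[wj])
    np.logical_and.at(is_max, wj, A[wj] > A[wi])
    threshold = rel_threshold * float(A.max())
    is_max &= A > threshold
    idx = np.flatnonzero(is_max)
    return PeakSet(
        peak_cells=[tissue.cell_ids[k] for k in idx],
        peak_values=A[idx],
        threshold_used=threshold,
        peak_indices=[int(k) for k in idx],
    )


def boundary_restriction_score(peaks: PeakSet, mask: np.ndarray) -> float:
    """Fraction of peak cells lying inside the boundary mask.

    Undefined (raises) for an empty peak set — distinct from a score of
    0.0, which means peaks exist but none is in the mask.
    """
    if len(peaks) == 0:
        raise UndefinedStatisticError("no peaks: boundary score undefined")
    mask = np.asarray(mask, dtype=bool)
    # mask is positional (tissue cell order), as are peak_indices
    idx = peaks.peak_indices
    if idx is None:
        idx = peaks.peak_cells
    inside = int(np.count_nonzero(mask[np.asarray(idx, dtype=int)]))
    return inside / len(peaks)


@dataclass
class PeakSpacing:
    """Sorted polar angles of peaks about the tissue center, and gaps."""

    angles_deg: np.ndarray
    gaps_deg: np.ndarray
    gap_cv: float


def peak_spacing(peaks: PeakSet, tissue: TissueGraph) -> PeakSpacing:
    """Circular spacing of peaks: angles, gaps (sum 360°), gap CV."""
    if len(peaks) < 2:
        raise UndefinedStatisticError("need >= 2 peaks for spacing")
    center = tissue.center()
    pos = np.array(
        [tissue.centroids[tissue.index_of(c)] - center for c in peaks.peak_cells]
    )
    angles = np.degrees(np.arctan2(pos[:, 1], pos[:, 0])) % 360.0
    angles = np.sort(angles)
    gaps = np.diff(np.concatenate([angles, [angles[0] + 360.0]]))
    cv = float(np.std(gaps) / np.mean(gaps))
    return PeakSpacing(angles_deg=angles, gaps_deg=gaps, gap_cv=cv)


def peak_radii(peaks: PeakSet, tissue: TissueGraph) -> np.ndarray:
    """Radial distance of each peak cell from the tissue center."""
    center = tissue.center()
    return np.array(
        [
            float(np.linalg.norm(tissue.centroids[tissue.index_of(c)] - center))
            for c in peaks.peak_cells
        ]
    )


@dataclass
class ConservationReport:
    """Relative drift of total auxin mass M(t) = sum_i V_i A_i."""

    max_relative_drift: float
    informational: bool   # True when production/degradation were active


def conservation_report(
    trajectory: Trajectory, tissue: TissueGraph, params: ModelParams
) -> ConservationReport:
    """Max relative drift of V-weighted auxin mass along a trajectory.

    Transport (passive and active) is antisymmetric in V-weighted form,
    so with c_A = d_A = 0 the mass is an exact invariant and any drift
    is solver error.  With production or degradation on, the report is
    flagged informational.
    """
    V = tissue.volumes
    M = np.array([float(np.sum(V * st.A)) for st in trajectory.states])
    if M[0] == 0.0:
        raise UndefinedStatisticError("initial auxin mass is zero")
    drift = float(np.max(np.abs(M - M[0])) / M[0])
    informational = not (params.c_A == 0.0 and params.d_A == 0.0)
    return ConservationReport(max_relative_drift=drift, informational=informational)


def plot_tissue(
    tissue: TissueGraph,
    values: np.ndarray,
    path,
    peaks: PeakSet | None = None,
    mask: np.ndarray | None = None,
    title: str | None = None,
) -> None:
    """Render the tissue colored by a per-cell field (PNG/SVG by suffix).

    Uses cell polygons when the tissue carries them, otherwise a scatter
    of centroids.  Peaks are circled; the boundary annulus is hatched.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    fig, ax = plt.subplots(figsize=(6, 6))
    values = np.asarray(values, dtype=float)
    if tissue.polygons:
        verts = [tissue.polygons[c] for c in tissue.cell_ids]
        pc = PolyCollection(verts, array=values, edgecolor="0.4", linewidth=0.3)
        ax.add_collection(pc)
        fig.colorbar(pc, ax=ax, shrink=0.8)
        if mask is not None:
            hatch = [tissue.polygons[c] for c, m in zip(tissue.cell_ids, mask) if m]
            ax.add_collection(
                PolyCollection(
                    hatch, facecolor="none", edgecolor="k", hatch="///", linewidth=0.0
                )
            )
        ax.autoscale_view()
    else:
        sc = ax.scatter(
            tissue.centroids[:, 0], tissue.centroids[:, 1], c=values, s=30
        )
        fig.colorbar(sc, ax=ax, shrink=0.8)
    if peaks is not None and len(peaks) > 0:
        pts = np.array([tissue.centroids[tissue.index_of(c)] for c in peaks.peak_cells])
        ax.scatter(
            pts[:, 0], pts[:, 1], facecolor="none", edgecolor="red", s=120, linewidth=1.5
        )
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
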
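"""Radial KANADI / REVOLUTA expression prepattern.

KAN and REV levels are set by Hill kinetics in the radial coordinate
``r_i`` (distance of cell i from the template center) and run to
equilibrium before the transport dynamics start:

    dK_i/dt = V_K * r^n_K / (K_K^n_K + r^n_K) - d_K * K_i
    dR_i/dt = V_R * h(r)                      - d_R * R_i

With the default steep exponents (n = 20) and half-max radii
K_K = 30 > K_R = 25 this produces a peripheral KAN domain, a central
REV domain and a low-expression boundary annulus in between — the
dorsoventral boundary where the transport model concentrates auxin
maxima.  KAN is sharpened to a binary field by thresholding the
equilibrium at 0.5 (K_i <= 0.5 -> 0, > 0.5 -> 1); REV stays graded.

``rev_orientation`` selects whether REV decreases with r ("central",
h = K_R^n/(K_R^n + r^n), the default) or increases ("peripheral",
h = r^n/(K_R^n + r^n)).  Both are provided because the two conventions
appear in the literature for this kind of radial Hill prepattern; only
the central orientation yields disjoint KAN/REV domains with a boundary
annulus when K_K > K_R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .tissue import TissueGraph

__all__ = [
    "PrepatternParams",
    "PrepatternField",
    "radial_coordinate",
    "prepattern_equilibrium",
    "integrate_prepattern",
    "boundary_mask",
    "null_prepattern",
]

KAN_THRESHOLD = 0.5


@dataclass(frozen=True)
class PrepatternParams:
    """Hill-kinetics parameters of the KAN/REV prepattern."""

    V_K: float = 1.0
    V_R: float = 1.0
    d_K: float = 1.0
    d_R: float = 1.0
    K_K: float = 30.0
    K_R: float = 25.0
    n_K: float = 20.0
    n_R: float = 20.0
    rev_orientation: str = "central"

    def __post_init__(self) -> None:
        for name in ("V_K", "V_R", "d_K", "d_R", "K_K", "K_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_K < 1 or self.n_R < 1:
            raise ValueError("Hill exponents must be >= 1")
        if self.rev_orientation not in ("central", "peripheral"):
            raise ValueError("rev_orientation must be 'central' or 'peripheral'")


@dataclass
class PrepatternField:
    """Per-cell prepattern values.

    ``K`` is the thresholded (binary) KAN level used by the dynamics;
    ``K_raw`` the pre-threshold equilibrium; ``R`` the graded REV level;
    ``r`` the radial coordinate.
    """

    r: np.ndarray
    K_raw: np.ndarray
    K: np.ndarray
    R: np.ndarray
    converged: bool = True


def radial_coordinate(tissue: TissueGraph, central_radius: float | None = None) -> np.ndarray:
    """Distance of every cell centroid from the template center.

    The center is the volume-weighted centroid of the tissue.  If
    ``central_radius`` is given and no cell lies within it, a warning is
    issued (the prepattern would then lack a genuine central domain).
    """
    center = tissue.center()
    r = np.linalg.norm(tissue.centroids - center, axis=1)
    if central_radius is not None and not np.any(r < central_radius):
        warnings.warn(
            f"no cell lies within r < {central_radius}: the template has no "
            "central expression zone",
            stacklevel=2,
        )
    return r


def _hill_up(x: np.ndarray, K: float, n: float) -> np.ndarray:
    # x^n / (K^n + x^n), computed via (x/K)^n for overflow safety
    z = np.power(np.asarray(x, dtype=float) / K, n)
    return z / (1.0 + z)


def prepattern_equilibrium(r: np.ndarray, params: PrepatternParams) -> PrepatternField:
    """Closed-form equilibrium of the prepattern ODEs.

    Production is constant in time for fixed r, so each cell relaxes
    linearly to production/degradation; the equilibrium is exact.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial coordinates must be non-negative")
    K_raw = (params.V_K / params.d_K) * _hill_up(r, params.K_K, params.n_K)
    if params.rev_orientation == "central":
        R = (params.V_R / params.d_R) * (1.0 - _hill_up(r, params.K_R, params.n_R))
    else:
        R = (params.V_R / params.d_R) * _hill_up(r, params.K_R, params.n_R)
    K = np.where(K_raw > KAN_THRESHOLD, 1.0, 0.0)
    return PrepatternField(r=r, K_raw=K_raw, K=K, R=R)


def integrate_prepattern(
    tissue: TissueGraph,
    params: PrepatternParams,
    t_end: float = 20.0,
    tol: float = 1e-6,
) -> PrepatternField:
    """Numerically integrate the prepattern ODEs from zero to t_end.

    Exists as a fidelity check on :func:`prepattern_equilibrium`; flags
    non-convergence when the residual production-decay imbalance at
    t_end exceeds ``tol`` times the decay rate.
    """
    r = radial_coordinate(tissue, central_radius=params.K_R)
    prod_K = params.V_K * _hill_up(r, params.K_K, params.n_K)
    if params.rev_orientation == "central":
        prod_R = params.V_R * (1.0 - _hill_up(r, params.K_R, params.n_R))
    else:
        prod_R = params.V_R * _hill_up(r, params.K_R, params.n_R)

    n = tissue.n_cells

    def rhs(_t, y):
        K, R = y[:n], y[n:]
        return np.concatenate([prod_K - params.d_K * K, prod_R - params.d_R * R])

    converged = True
    if t_end <= 0:
        K_num = np.zeros(n)
        R_num = np.zeros(n)
        converged = False
    else:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            np.zeros(2 * n),
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        K_num, R_num = sol.y[:n, -1], sol.y[n:, -1]
    dK_final = prod_K - params.d_K * K_num
    if np.max(np.abs(dK_final), initial=0.0) > tol * params.d_K:
        converged = False
    if not converged:
        warnings.warn(
            f"prepattern not converged at t_end={t_end}", stacklevel=2
        )
    K = np.where(K_num > KAN_THRESHOLD, 1.0, 0.0)
    return PrepatternField(r=r, K_raw=K_num, K=K, R=R_num, converged=converged)


def boundary_mask(field: PrepatternField, rev_threshold: float = 0.5) -> np.ndarray:
    """Cells in the boundary annulus: KAN absent and REV below threshold."""
    if rev_threshold <= 0:
        raise ValueError("rev_threshold must be positive")
    return (field.K == 0) & (field.R < rev_threshold)


def null_prepattern(n_cells: int) -> PrepatternField:
    """K = R = 0 everywhere: the unrepressed transport model."""
    z = np.zeros(n_cells)
    return PrepatternField(r=z.copy(), K_raw=z.copy(), K=z.copy(), R=z.copy())
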
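"""Cell-network tissue templates.

The dynamics run on a static cell graph: cells with volumes ``V_i``,
walls between neighboring cells with contact areas ``a_ij = a_ji``, and
cell centroids (used only for the radial coordinate and plotting).  Two
generators are provided: an irregular polygonal disc tissue (seeded
Voronoi tessellation with optional Lloyd relaxation, clipped to a disc)
and a regular 1D periodic ring used for oracle and stability tests.

Geometry is two-dimensional: "volume" is polygon area and "wall area"
is shared-edge length; the model symbols are used regardless of
dimension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

__all__ = [
    "TissueGraph",
    "TissueFormatError",
    "generate_disc_tissue",
    "generate_ring_tissue",
    "read_tissue",
    "write_tissue",
]


class TissueFormatError(ValueError):
    """Raised when a tissue file violates the tissue JSON schema."""


@dataclass
class TissueGraph:
    """Static cell-network geometry.

    Attributes
    ----------
    cell_ids
        Integer identifiers, one per cell.
    volumes
        Per-cell positive volume ``V_i`` (polygon area; arbitrary units).
    centroids
        Per-cell 2D coordinates, shape ``(n, 2)``.
    walls
        Unordered cell-id pairs ``(i, j)`` with ``i < j``, one per wall.
    wall_areas
        Per-wall positive contact area ``a_ij`` (edge length), aligned
        with ``walls``.
    boundary_flags
        Per-cell indicator of tissue-edge cells.
    polygons
        Optional vertex rings per cell id, for plotting only.
    meta
        Provenance (generator name, seed, ...).
    """

    cell_ids: list[int]
    volumes: np.ndarray
    centroids: np.ndarray
    walls: list[tuple[int, int]]
    wall_areas: np.ndarray
    boundary_flags: np.ndarray
    polygons: dict[int, list[list[float]]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.wall_areas = np.asarray(self.wall_areas, dtype=float)
        self.boundary_flags = np.asarray(self.boundary_flags, dtype=bool)
        self._index = {c: k for k, c in enumerate(self.cell_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_walls(self) -> int:
        return len(self.walls)

    def index_of(self, cell_id: int) -> int:
        return self._index[cell_id]

    def neighbors(self, cell_id: int) -> list[int]:
        out = []
        for i, j in self.walls:
            if i == cell_id:
                out.append(j)
            elif j == cell_id:
                out.append(i)
        return out

    def wall_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional index arrays (wi, wj) of the two cells of each wall."""
        wi = np.array([self._index[i] for i, _ in self.walls], dtype=np.intp)
        wj = np.array([self._index[j] for _, j in self.walls], dtype=np.intp)
        return wi, wj

    def center(self) -> np.ndarray:
        """Volume-weighted centroid of the tissue (the template center)."""
        return (self.volumes[:, None] * self.centroids).sum(axis=0) / self.volumes.sum()

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cell_ids)
        g.add_edges_from(self.walls)
        return g

    def validate(self) -> None:
        """Check structural invariants; raise :class:`TissueFormatError`."""
        if len(set(self.cell_ids)) != self.n_cells:
            raise TissueFormatError("duplicate cell ids")
        if np.any(self.volumes <= 0):
            bad = self.cell_ids[int(np.argmin(self.volumes))]
            raise TissueFormatError(f"non-positive volume for cell {bad}")
        if np.any(self.wall_areas <= 0):
            bad = self.walls[int(np.argmin(self.wall_areas))]
            raise TissueFormatError(f"non-positive area for wall {bad}")
        seen = set()
        for (i, j), _a in zip(self.walls, self.wall_areas):
            if i == j:
                raise TissueFormatError(f"wall {(i, j)} joins a cell to itself")
            if i not in self._index or j not in self._index:
                raise TissueFormatError(f"wall {(i, j)} references an absent cell")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise TissueFormatError(f"duplicate wall record for pair {key}")
            seen.add(key)
        if self.n_cells > 1 and not nx.is_connected(self.graph()):
            raise TissueFormatError("neighbor graph is not connected")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TissueGraph):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and np.array_equal(self.volumes, other.volumes)
            and np.array_equal(self.centroids, other.centroids)
            and [tuple(sorted(w)) for w in self.walls]
            == [tuple(sorted(w)) for w in other.walls]
            and np.array_equal(self.wall_areas, other.wall_areas)
            and np.array_equal(self.boundary_flags, other.boundary_flags)
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _mirror_points(points: np.ndarray, radius: float) -> np.ndarray:
    """Reflect interior points radially across the disc boundary.

    Augmenting the Voronoi input with these mirrors bounds every interior
    cell and makes the tessellation approximately conform to the disc.
    """
    d = np.linalg.norm(points, axis=1)
    d = np.where(d < 1e-12, 1e-12, d)
    return points * ((2.0 * radius - d) / d)[:, None]


def _clipped_voronoi_polygons(
    points: np.ndarray, radius: float
) -> list[Polygon]:
    """Voronoi cells of `points`, clipped to the disc of given radius."""
    disc = Point(0.0, 0.0).buffer(radius, quad_segs=128)
    aug = np.vstack([points, _mirror_points(points, radius)])
    vor = Voronoi(aug)
    polys: list[Polygon] = []
    for k in range(len(points)):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) < 3:
            # mirror trick failed for this point; fall back to a tiny disc
            # around the point so downstream code degrades gracefully
            poly = Point(*points[k]).buffer(radius / 100.0, quad_segs=16)
        else:
            poly = Polygon(vor.vertices[region])
        poly = poly.intersection(disc)
        if poly.geom_type != "Polygon" or poly.is_empty:
            poly = Point(*points[k]).buffer(radius / 100.0, quad_segs=16)
        polys.append(poly)
    return polys


def generate_disc_tissue(
    n_cells: int,
    radius: float,
    seed: int,
    relaxation_steps: int = 50,
) -> TissueGraph:
    """Generate an irregular polygonal tissue tiling a disc.

    Seeded random points in the disc are optionally Lloyd-relaxed
    (each step moves every point to the centroid of its disc-clipped
    Voronoi cell), then tessellated; volumes are polygon areas and wall
    areas are shared-edge lengths.  Deterministic for fixed arguments.

    Parameters
    ----------
    n_cells
        Number of cells (>= 7).
    radius
        Disc radius (> 0), in the model's length units.
    seed
        RNG seed for the point sample.
    relaxation_steps
        Lloyd iterations; 0 gives a fully irregular tessellation, large
        values approach a centroidal (honeycomb-like) one.
    """
    if n_cells < 7:
        raise ValueError(f"n_cells must be >= 7, got {n_cells}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if relaxation_steps < 0:
        raise ValueError("relaxation_steps must be non-negative")

    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n_cells))
    th = 2.0 * np.pi * rng.random(n_cells)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])

    for _ in range(relaxation_steps):
        polys = _clipped_voronoi_polygons(pts, radius)
        pts = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    polys = _clipped_voronoi_polygons(pts, radius)
    volumes = np.array([p.area for p in polys])
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    # adjacency candidates from Voronoi ridges between original points
    aug = np.vstack([pts, _mirror_points(pts, radius)])
    vor = Voronoi(aug)
    walls: list[tuple[int, int]] = []
    wall_areas: list[float] = []
    boundary = np.zeros(n_cells, dtype=bool)
    for (p, q) in vor.ridge_points:
        if p < n_cells and q < n_cells:
            shared = polys[p].intersection(polys[q])
            length = shared.length
            if length > 1e-9 * radius:
                i, j = (p, q) if p < q else (q, p)
                walls.append((int(i), int(j)))
                wall_areas.append(float(length))
        elif p < n_cells or q < n_cells:
            boundary[min(p, q)] = True

    order = np.lexsort(([j for _, j in walls], [i for i, _ in walls]))
    walls = [walls[k] for k in order]
    wall_areas_arr = np.array(wall_areas)[order]

    tissue = TissueGraph(
        cell_ids=list(range(n_cells)),
        volumes=volumes,
        centroids=centroids,
        walls=walls,
        wall_areas=wall_areas_arr,
        boundary_flags=boundary,
        polygons={
            k: [[float(x), float(y)] for x, y in p.exterior.coords]
            for k, p in enumerate(polys)
        },
        meta={
            "generator": "disc",
            "n_cells": n_cells,
            "radius": radius,
            "seed": seed,
            "relaxation_steps": relaxation_steps,
        },
    )
    tissue.validate()
    return tissue


def generate_ring_tissue(
    n_cells: int, cell_volume: float = 1.0, wall_area: float = 1.0
) -> TissueGraph:
    """Periodic 1D chain of identical cells (cycle graph, degree 2).

    Centroids are placed on a circle with unit cell spacing so radial
    and angular diagnostics remain meaningful.
    """
    if n_cells < 3:
        raise ValueError(f"n_cells must be >= 3, got {n_cells}")
    if cell_volume <= 0 or wall_area <= 0:
        raise ValueError("cell_volume and wall_area must be positive")
    ring_radius = n_cells / (2.0 * np.pi)
    th = 2.0 * np.pi * np.arange(n_cells) / n_cells
    centroids = ring_radius * np.column_stack([np.cos(th), np.sin(th)])
    walls = [(i, (i + 1) % n_cells) for i in range(n_cells)]
    walls = [tuple(sorted(w)) for w in walls]
    walls.sort()
    tissue = TissueGraph(
        cell_ids=list(range(n_cells)),
        volumes=np.full(n_cells, float(cell_volume)),
        centroids=centroids,
        walls=walls,
        wall_areas=np.full(n_cells, float(wall_area)),
        boundary_flags=np.zeros(n_cells, dtype=bool),
        meta={
            "generator": "ring",
            "n_cells": n_cells,
            "cell_volume": cell_volume,
            "wall_area": wall_area,
        },
    )
    tissue.validate()
    return tissue


# ---------------------------------------------------------------------------
# serialization (tissue JSON schema)
# ---------------------------------------------------------------------------


def write_tissue(tissue: TissueGraph, path) -> None:
    """Serialize a tissue to the JSON schema (one record per wall pair)."""
    obj = {
        "cells": [
            {
                "id": int(c),
                "volume": float(v),
                "centroid": [float(x), float(y)],
            }
            for c, v, (x, y) in zip(tissue.cell_ids, tissue.volumes, tissue.centroids)
        ],
        "walls": [
            {"i": int(i), "j": int(j), "area": float(a)}
            for (i, j), a in zip(tissue.walls, tissue.wall_areas)
        ],
        "boundary_cells": [int(c) for c, b in zip(tissue.cell_ids, tissue.boundary_flags) if b],
        "meta": tissue.meta,
    }
    if tissue.polygons is not None:
        obj["polygons"] = {str(k): v for k, v in tissue.polygons.items()}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tissue(path) -> TissueGraph:
    """Read a tissue JSON file; raise :class:`TissueFormatError` on bad input."""
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TissueFormatError(f"not valid JSON: {exc}") from exc
    for key in ("cells", "walls"):
        if key not in obj:
            raise TissueFormatError(f"missing top-level key {key!r}")
    cell_ids, volumes, centroids = [], [], []
    for rec in obj["cells"]:
        try:
            cell_ids.append(int(rec["id"]))
            volumes.append(float(rec["volume"]))
            centroids.append([float(rec["centroid"][0]), float(rec["centroid"][1])])
        except (KeyError, TypeError, IndexError) as exc:
            raise TissueFormatError(f"malformed cell record {rec!r}") from exc
    walls, wall_areas = [], []
    for rec in obj["walls"]:
        try:
            walls.append((int(rec["i"]), int(rec["j"])))
            wall_areas.append(float(rec["area"]))
        except (KeyError, TypeError) as exc:
            raise TissueFormatError(f"malformed wall record {rec!r}") from exc
    boundary_set = set(obj.get("boundary_cells", []))
    polygons = None
    if "polygons" in obj:
        polygons = {int(k): v for k, v in obj["polygons"].items()}
    tissue = TissueGraph(
        cell_ids=cell_ids,
        volumes=np.array(volumes),
        centroids=np.array(centroids).reshape(len(cell_ids), 2),
        walls=walls,
        wall_areas=np.array(wall_areas),
        boundary_flags=np.array([c in boundary_set for c in cell_ids]),
        polygons=polygons,
        meta=obj.get("meta", {}),
    )
    tissue.validate()
    return tissue
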
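"""Adaptive local-convex-hull (a-LoCoH) hypervolumes in d dimensions.

For every focal point of an individual's niche cloud, neighbours are added
in order of increasing Euclidean distance until the *cumulative* distance
from the focal point would exceed the threshold ``a``; the convex hull of
the focal point and its neighbours forms one local polytope.  Hulls are
therefore small where points are dense and large where they are sparse.
The individual's hypervolume is the union of its valid polytopes,
discretised on a shared regular grid: a grid cell belongs to the
hypervolume iff its centroid lies in at least one polytope, and the volume
is the occupied-cell count times grain**d.  The population (total niche)
volume is the same union taken over every individual's polytopes, on the
same grid, which is what makes the within-individual and population volumes
directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "LocohParams",
    "GridSpec",
    "Polytope",
    "Hypervolume",
    "GridError",
    "neighbor_set",
    "build_polytope",
    "occupancy",
    "union_volume",
    "individual_hypervolume",
]

#: Half-space tolerance: a centroid exactly on a facet counts as inside.
BOUNDARY_TOL = 1e-9

#: Supported dimensionalities.
SUPPORTED_DIMS = (2, 3, 4)


class GridError(ValueError):
    """Grid contract violation (mismatched grids, polytope outside grid)."""


@dataclass(frozen=True)
class LocohParams:
    """Adaptive-LoCoH parameters.

    ``a`` is the cumulative-distance threshold: metres in geographic space
    (default 400 km there), unitless in standardised environmental space
    (default 3).  The same ``a`` is used for every individual so their
    hypervolumes are comparable.
    """

    a: float
    d: int

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.d not in SUPPORTED_DIMS:
            raise ValueError(f"dimension must be one of {SUPPORTED_DIMS}")


#: Field defaults: chosen by the stabilisation/visual-fit diagnostics on the
#: albatross analysis; override per study.
DEFAULT_A_GEOGRAPHIC = 400_000.0  # metres
DEFAULT_A_ENVIRONMENTAL = 3.0  # standardised units
DEFAULT_GRAIN_GEOGRAPHIC = 25_000.0  # metres
DEFAULT_GRAIN_ENVIRONMENTAL = 0.125


@dataclass(frozen=True)
class GridSpec:
    """Regular d-dimensional occupancy grid.

    ``origin`` is the lower corner of cell (0, …, 0); cell *centroids* sit at
    ``origin + (index + 0.5) * grain``.  All individuals of one analysis
    share a single grid (origin snapped down to a multiple of the grain,
    one-cell margin) so cell sets can be unioned and compared.
    """

    origin: tuple
    grain: float
    shape: tuple

    def __post_init__(self):
        if self.grain <= 0:
            raise ValueError("grain must be positive")
        if len(self.origin) != len(self.shape):
            raise ValueError("origin and shape must have equal dimension")

    @property
    def d(self) -> int:
        return len(self.shape)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(self.shape) * self.grain

    @classmethod
    def from_points(cls, points: np.ndarray, grain: float, margin: int = 1) -> "GridSpec":
        """Grid covering a point cloud with ``margin`` whole cells to spare,
        origin snapped down to a multiple of the grain (alignment is then a
        pure function of the grain, not of the data ordering)."""
        points = np.asarray(points, dtype=float)
        lo = np.floor(points.min(axis=0) / grain - margin) * grain
        hi = points.max(axis=0)
        shape = np.floor((hi - lo) / grain).astype(int) + 1 + margin
        return cls(tuple(lo.tolist()), float(grain), tuple(int(s) for s in shape))

    def covers(self, points: np.ndarray) -> bool:
        points = np.asarray(points, dtype=float)
        lo = np.asarray(self.origin)
        return bool((points >= lo).all() and (points <= self.upper).all())

    def centroid(self, index: int) -> np.ndarray:
        multi = np.unravel_index(index, self.shape)
        return np.asarray(self.origin) + (np.asarray(multi) + 0.5) * self.grain

    def centroids(self, indices) -> np.ndarray:
        multi = np.stack(np.unravel_index(np.asarray(list(indices), dtype=int), self.shape), axis=1)
        return np.asarray(self.origin) + (multi + 0.5) * self.grain


@dataclass
class Polytope:
    """Convex hull of one focal point and its a-LoCoH neighbours."""

    vertices: np.ndarray  # (m, d) input points (focal first)
    focal_index: int
    equations: np.ndarray  # Qhull facet half-spaces A·x + b <= 0 inside
    measure: float  # exact d-volume of the hull

    @property
    def d(self) -> int:
        return self.vertices.shape[1]

    def contains(self, points: np.ndarray, tol: float = BOUNDARY_TOL) -> np.ndarray:
        """Half-space membership test (boundary counts as inside)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        vals = points @ self.equations[:, :-1].T + self.equations[:, -1]
        return (vals <= tol).all(axis=1)


@dataclass
class Hypervolume:
    """A set of occupied grid cells and its volume."""

    grid: GridSpec
    cells: frozenset
    n_points_used: int = 0
    n_points_ignored: int = 0
    n_ignored_strict: int = 0  # count under the stricter d+1-neighbour rule

    @property
    def volume(self) -> float:
        return len(self.cells) * self.grid.grain ** self.grid.d

    def __len__(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# Neighbour selection and polytope construction
# ---------------------------------------------------------------------------


def neighbor_set(cloud: np.ndarray, focal_index: int, a: float) -> np.ndarray:
    """Indices of the a-LoCoH neighbours of ``cloud[focal_index]``.

    Neighbours are taken in order of increasing Euclidean distance (ties
    broken by ascending point index, so runs are reproducible); the returned
    prefix is the longest whose distances *sum* to at most ``a``.  May be
    empty.
    """
    cloud = np.asarray(cloud, dtype=float)
    d = np.linalg.norm(cloud - cloud[focal_index], axis=1)
    order = np.argsort(d, kind="stable")  # stable → ties by ascending index
    order = order[order != focal_index]
    csum = np.cumsum(d[order])
    k = int(np.searchsorted(csum, a, side="right"))
    return order[:k]


def build_polytope(
    cloud: np.ndarray, focal_index: int, neighbours: np.ndarray
) -> Polytope | None:
    """Convex hull of the focal point and its neighbours, or None.

    Building a full-dimensional polytope in d dimensions needs at least
    d + 1 affinely independent points; focal points that fail this (too few
    neighbours, or a degenerate — e.g. collinear — point set) are ignored,
    which doubles as an outlier filter.
    """
    cloud = np.asarray(cloud, dtype=float)
    d = cloud.shape[1]
    idx = np.concatenate([[focal_index], np.asarray(neighbours, dtype=int)])
    pts = cloud[idx]
    if len(pts) < d + 1:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # affinely dependent (flat) set
    return Polytope(pts, int(focal_index), hull.equations.copy(), float(hull.volume))


# ---------------------------------------------------------------------------
# Grid occupancy
# ---------------------------------------------------------------------------


def _occupied_flat_indices(poly: Polytope, grid: GridSpec, tol: float) -> np.ndarray:
    """Flat indices of grid cells whose centroid lies inside ``poly``."""
    origin = np.asarray(grid.origin)
    lo_v = poly.vertices.min(axis=0)
    hi_v = poly.vertices.max(axis=0)
    if not grid.covers(poly.vertices):
        raise GridError("polytope vertex outside the occupancy grid")
    # candidate cell ranges from the polytope bounding box (±1 cell slack)
    i_lo = np.maximum(np.floor((lo_v - origin) / grid.grain).astype(int) - 1, 0)
    i_hi = np.minimum(
        np.floor((hi_v - origin) / grid.grain).astype(int) + 1,
        np.asarray(grid.shape) - 1,
    )
    axes = [np.arange(a, b + 1) for a, b in zip(i_lo, i_hi)]
    if any(ax.size == 0 for ax in axes):
        return np.empty(0, dtype=np.int64)
    mesh = np.meshgrid(*axes, indexing="ij")
    multi = np.stack([m.ravel() for m in mesh], axis=1)
    cent = origin + (multi + 0.5) * grid.grain
    inside = (cent @ poly.equations[:, :-1].T + poly.equations[:, -1] <= tol).all(axis=1)
    if not inside.any():
        return np.empty(0, dtype=np.int64)
    return np.ravel_multi_index(tuple(multi[inside].T), grid.shape)


def occupancy(
    polytopes: list[Polytope], grid: GridSpec, tol: float = BOUNDARY_TOL
) -> Hypervolume:
    """Union the grid cells whose centroids fall in at least one polytope."""
    chunks = [_occupied_flat_indices(p, grid, tol) for p in polytopes]
    if chunks:
        cells = frozenset(np.unique(np.concatenate(chunks)).tolist())
    else:
        cells = frozenset()
    return Hypervolume(grid, cells)


def union_volume(hypervolumes: list[Hypervolume]) -> Hypervolume:
    """Union of cell sets on one shared grid."""
    if not hypervolumes:
        raise ValueError("need at least one hypervolume")
    grid = hypervolumes[0].grid
    if any(hv.grid != grid for hv in hypervolumes):
        raise GridError("hypervolumes must share one GridSpec")
    cells = frozenset().union(*(hv.cells for hv in hypervolumes))
    return Hypervolume(
        grid,
        cells,
        n_points_used=sum(hv.n_points_used for hv in hypervolumes),
        n_points_ignored=sum(hv.n_points_ignored for hv in hypervolumes),
        n_ignored_strict=sum(hv.n_ignored_strict for hv in hypervolumes),
    )


# ---------------------------------------------------------------------------
# Per-individual hypervolume
# ---------------------------------------------------------------------------


def local_polytopes(
    cloud: np.ndarray, params: LocohParams, strict: bool = False
) -> tuple[list[Polytope], int, int]:
    """All valid local polytopes of a cloud.

    Returns ``(polytopes, n_ignored, n_ignored_strict)``.  The default rule
    requires at least d + 1 points *including* the focal (the mathematical
    minimum for a full-dimensional simplex); ``strict=True`` instead demands
    d + 1 neighbours in addition to the focal point.
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != params.d:
        raise ValueError(f"cloud must be (n, {params.d})")
    polys: list[Polytope] = []
    n_ignored = 0
    n_ignored_strict = 0
    d = params.d
    for i in range(len(cloud)):
        nbrs = neighbor_set(cloud, i, params.a)
        if len(nbrs) < d + 1:
            n_ignored_strict += 1
            if strict:
                n_ignored += 1
                continue
        poly = build_polytope(cloud, i, nbrs)
        if poly is None:
            n_ignored += 1
        else:
            polys.append(poly)
    return polys, n_ignored, n_ignored_strict


def individual_hypervolume(
    cloud: np.ndarray,
    params: LocohParams,
    grid: GridSpec,
    strict: bool = False,
    tol: float = BOUNDARY_TOL,
) -> Hypervolume:
    """a-LoCoH hypervolume of one individual's niche cloud on a shared grid.

    Focal points without enough neighbours within the cumulative-distance
    budget contribute no polytope and are counted as ignored; if no focal
    point yields a valid polytope the hypervolume is empty (with a warning).
    """
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    polys, n_ignored, n_ignored_strict = local_polytopes(cloud, params, strict=strict)
    if not polys:
        warnings.warn("no valid polytope — empty hypervolume", stacklevel=2)
    hv = occupancy(polys, grid, tol=tol)
    return Hypervolume(
        hv.grid,
        hv.cells,
        n_points_used=len(cloud) - n_ignored,
        n_points_ignored=n_ignored,
        n_ignored_strict=n_ignored_strict,
    )
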
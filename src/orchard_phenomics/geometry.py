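"""Architectural descriptors of tree crowns from terrestrial-LiDAR point clouds.

Four descriptors are computed from a crown point cloud (coordinates in metres):

* ``c_volume`` — volume of the 3D convex hull, the maximal space occupation;
* ``a_volume`` — volume of the 3D alpha shape, a concave envelope tracking the
  space actually occupied by foliage;
* ``c_i``     — convexity index, the ratio ``a_volume / c_volume``, a proxy for
  foliage density inside the crown envelope;
* ``STAR``    — silhouette to total leaf area ratio, the mean projected
  (silhouette) area of the foliage over a set of viewing directions divided by
  the total one-sided leaf area; a proxy for light interception efficiency.

Alpha-shape convention
----------------------
The alpha shape is the union of Delaunay tetrahedra whose circumscribing-sphere
radius is strictly below ``alpha`` (the "alpha = radius bound" convention, the
one used by the R ``alphashape3d`` family of tools).  Under this convention
``a_volume`` is non-decreasing in ``alpha`` and converges to ``c_volume`` for
large ``alpha``.  Volumes of disconnected components are summed, since crowns
may fragment at small ``alpha``.  The convention is recorded in all metadata
emitted by the CLI because a published ``alpha`` value is meaningless without
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial import QhullError
from scipy.stats import pearsonr

__all__ = [
    "ALPHA_CONVENTION",
    "DEFAULT_ALPHA",
    "PointCloud",
    "DegenerateCloudError",
    "HullResult",
    "StarResult",
    "AlphaSelection",
    "convex_hull_volume",
    "alpha_hull_volume",
    "convexity_index",
    "hull_descriptors",
    "select_alpha",
    "upper_hemisphere_directions",
    "silhouette_area",
    "compute_star",
]

#: Default shape parameter for the alpha hull (metres; radius-bound convention).
DEFAULT_ALPHA = 0.15

ALPHA_CONVENTION = "tetrahedron kept iff circumsphere radius < alpha (radius bound)"


class DegenerateCloudError(ValueError):
    """Point cloud is too small or degenerate (coplanar/collinear) for 3D hulls."""


@dataclass
class PointCloud:
    """One tree crown as an (n, 3) array of points in metres, with an optional
    per-point one-sided leaf-area weight (m^2/point) for STAR denominators."""

    points: np.ndarray
    tree_id: str = ""
    leaf_area_weight: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {self.points.shape}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class HullResult:
    """Convex and alpha hull volumes of one crown, with the convexity index."""

    c_volume: float
    a_volume: float
    alpha: float
    c_i: float


@dataclass(frozen=True)
class StarResult:
    """STAR and its ingredients: per-direction silhouette areas (m^2) and the
    total one-sided leaf area (m^2) used as denominator."""

    star: float
    silhouette_areas: np.ndarray
    total_leaf_area: float
    directions: np.ndarray = field(repr=False, default=None)


def _as_points(cloud) -> np.ndarray:
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


def convex_hull_volume(cloud) -> float:
    """Volume (m^3) of the 3D convex hull of the cloud.

    Raises
    ------
    DegenerateCloudError
        If fewer than 4 points, or all points coplanar/collinear.
    """
    pts = _as_points(cloud)
    if len(pts) < 4:
        raise DegenerateCloudError(f"need >= 4 points for a 3D hull, got {len(pts)}")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as exc:
        raise DegenerateCloudError(f"degenerate point cloud: {exc}") from exc


def _tetra_volumes_and_circumradii(pts: np.ndarray, simplices: np.ndarray):
    """Volumes and circumsphere radii of Delaunay tetrahedra, vectorized.

    Degenerate (near-flat) tetrahedra get an infinite radius so that no finite
    alpha retains them.
    """
    a = pts[simplices[:, 0]]
    edges = pts[simplices[:, 1:]] - a[:, None, :]  # (m, 3, 3)
    det = np.linalg.det(edges)
    vol = np.abs(det) / 6.0

    # Circumcenter c solves 2 E (c - a) = |e_i|^2 for the three edge vectors.
    rhs = np.einsum("mij,mij->mi", edges, edges)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-14
    if ok.any():
        sol = np.linalg.solve(2.0 * edges[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(sol, axis=1)
    return vol, radii


def alpha_hull_volume(cloud, alpha: float) -> float:
    """Volume (m^3) of the 3D alpha shape at shape parameter ``alpha``.

    The alpha shape is the union of Delaunay tetrahedra with circumsphere
    radius < ``alpha``; volumes of disconnected components are summed.
    Returns 0.0 (with a warning) when no tetrahedron survives.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    pts = _as_points(cloud)
    if len(pts) < 4:
        raise DegenerateCloudError(f"need >= 4 points for a 3D hull, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateCloudError(f"degenerate point cloud: {exc}") from exc
    vol, radii = _tetra_volumes_and_circumradii(pts, tri.simplices)
    keep = radii < alpha
    if not keep.any():
        warnings.warn(
            f"alpha={alpha} retains no tetrahedron; alpha-hull volume is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(vol[keep].sum())


def alpha_volume_profile(cloud, alphas) -> np.ndarray:
    """Alpha-hull volumes over a grid of alpha values (one Delaunay pass)."""
    pts = _as_points(cloud)
    tri = Delaunay(pts)
    vol, radii = _tetra_volumes_and_circumradii(pts, tri.simplices)
    return np.array([vol[radii < a].sum() for a in np.asarray(alphas, dtype=float)])


def convexity_index(a_volume: float, c_volume: float) -> float:
    """Convexity index c_i = a_volume / c_volume, in (0, 1]."""
    if c_volume <= 0:
        raise ValueError(f"c_volume must be > 0, got {c_volume}")
    if a_volume > c_volume * (1 + 1e-9):
        raise ValueError(
            f"a_volume ({a_volume}) exceeds c_volume ({c_volume}); "
            "an alpha shape cannot exceed its convex hull"
        )
    return float(a_volume / c_volume)


def hull_descriptors(cloud, alpha: float = DEFAULT_ALPHA) -> HullResult:
    """Convex-hull volume, alpha-hull volume and convexity index of one crown."""
    c_vol = convex_hull_volume(cloud)
    a_vol = alpha_hull_volume(cloud, alpha)
    # Clip the (tiny) numerical excess that can arise from independent hull passes.
    a_vol = min(a_vol, c_vol)
    c_i = convexity_index(a_vol, c_vol) if a_vol > 0 else 0.0
    return HullResult(c_volume=c_vol, a_volume=a_vol, alpha=float(alpha), c_i=c_i)


@dataclass(frozen=True)
class AlphaSelection:
    """Outcome of calibrating alpha against reference total leaf areas."""

    alpha: float
    profile: np.ndarray  # (n_alpha, 2): alpha, Pearson r between a_volume and TLA
    calibrated: bool


def select_alpha(clouds=None, tla=None, alpha_grid=None) -> AlphaSelection:
    """Choose alpha as the grid value maximizing the Pearson correlation between
    alpha-hull volume and measured total leaf area (TLA) on a calibration subset.

    With no calibration data (``clouds`` or ``tla`` omitted) the published
    default ``DEFAULT_ALPHA`` = 0.15 is returned uncalibrated.
    """
    if clouds is None or tla is None:
        return AlphaSelection(alpha=DEFAULT_ALPHA, profile=np.empty((0, 2)), calibrated=False)
    tla = np.asarray(tla, dtype=float)
    if len(clouds) != len(tla):
        raise ValueError("clouds and tla must be paired")
    if len(clouds) < 3:
        raise ValueError(f"need >= 3 calibration crowns, got {len(clouds)}")
    if np.ptp(tla) == 0:
        raise ValueError("constant TLA across the calibration subset: correlation undefined")
    if alpha_grid is None or len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be non-empty")
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    volumes = np.stack([alpha_volume_profile(c, alpha_grid) for c in clouds])  # (n_tree, n_alpha)
    corr = np.full(len(alpha_grid), -np.inf)
    for j in range(len(alpha_grid)):
        col = volumes[:, j]
        if np.ptp(col) > 0:
            corr[j] = pearsonr(col, tla)[0]
    if not np.isfinite(corr).any():
        raise ValueError("no alpha on the grid yields a non-constant a_volume")
    best = int(np.argmax(corr))
    return AlphaSelection(
        alpha=float(alpha_grid[best]),
        profile=np.column_stack([alpha_grid, corr]),
        calibrated=True,
    )


def upper_hemisphere_directions(n: int = 46) -> np.ndarray:
    """``n`` roughly equal-area viewing directions over the upper hemisphere
    (Fibonacci lattice), returned as unit vectors pointing upward."""
    if n < 1:
        raise ValueError("need at least one direction")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = (i + 0.5) / n  # cos(zenith) uniform in (0, 1): equal-area on the hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _plane_basis(direction: np.ndarray):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def silhouette_area(
    points: np.ndarray, direction, leaf_radius: float, grid_resolution: float
) -> float:
    """Projected (silhouette) area, m^2, of opaque disks of radius
    ``leaf_radius`` centred on the points and facing ``direction``.

    The projection plane orthogonal to ``direction`` is rasterized at
    ``grid_resolution`` (m/cell); a cell is covered when its centre falls
    within ``leaf_radius`` of a projected disk centre.
    """
    u, v = _plane_basis(direction)
    px = points @ u
    py = points @ v
    r = leaf_radius
    res = grid_resolution
    w = int(np.ceil(r / res)) + 1  # stamp half-width in cells
    margin = (w + 2) * res
    x0, y0 = px.min() - margin, py.min() - margin
    nx = int(np.ceil((px.max() + margin - x0) / res)) + w + 2
    ny = int(np.ceil((py.max() + margin - y0) / res)) + w + 2
    covered = np.zeros((nx, ny), dtype=bool)
    # Cell centres: x0 + (i + 0.5) * res. Stamp a local window per disk.
    ci = np.floor((px - x0) / res).astype(int)
    cj = np.floor((py - y0) / res).astype(int)
    off = np.arange(-w, w + 1)
    oi, oj = np.meshgrid(off, off, indexing="ij")
    for x, y, i, j in zip(px, py, ci, cj):
        xi = x0 + (i + oi + 0.5) * res
        yj = y0 + (j + oj + 0.5) * res
        mask = (xi - x) ** 2 + (yj - y) ** 2 <= r * r
        covered[i - w : i + w + 1, j - w : j + w + 1] |= mask
    return float(covered.sum()) * res * res


def compute_star(
    cloud,
    directions=None,
    leaf_radius: float | None = None,
    grid_resolution: float | None = None,
    total_leaf_area: float | None = None,
) -> StarResult:
    """STAR = mean over viewing directions of silhouette area / total one-sided
    leaf area.

    Each point is rendered as an opaque disk of radius ``leaf_radius`` facing
    the viewing direction.  Defaults: 46 upper-hemisphere directions;
    ``leaf_radius`` = half the median nearest-neighbour distance (scale-free);
    ``grid_resolution`` = ``leaf_radius / 10``; ``total_leaf_area`` =
    n_points * pi * leaf_radius^2 (known TLA should be passed for synthetic
    crowns).
    """
    pts = _as_points(cloud)
    if len(pts) == 0:
        raise ValueError("empty point cloud")
    if directions is None:
        directions = upper_hemisphere_directions(46)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(directions) < 1:
        raise ValueError("need at least one viewing direction")
    if leaf_radius is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        leaf_radius = float(np.median(d[:, 1])) / 2.0
        if leaf_radius <= 0:
            raise ValueError("cannot infer a leaf radius from coincident points")
    if grid_resolution is None:
        grid_resolution = leaf_radius / 10.0
    if grid_resolution >= leaf_radius:
        raise ValueError(
            f"grid_resolution ({grid_resolution}) must be finer than "
            f"leaf_radius ({leaf_radius})"
        )
    if total_leaf_area is None:
        total_leaf_area = len(pts) * np.pi * leaf_radius**2
    if total_leaf_area <= 0:
        raise ValueError("total leaf area must be > 0")
    areas = np.array(
        [silhouette_area(pts, d, leaf_radius, grid_resolution) for d in directions]
    )
    star = float(np.mean(areas) / total_leaf_area)
    return StarResult(
        star=star,
        silhouette_areas=areas,
        total_leaf_area=float(total_leaf_area),
        directions=directions,
    )
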
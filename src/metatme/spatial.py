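"""Spatial interaction and proximity metrics on single-core point patterns.

Three complementary scales:

* **G-Cross** — empirical CDF of nearest-neighbor distances from a reference
  phenotype to a target phenotype, summarized by its trapezoidal AUC on
  [0, 150] µm normalized by the maximum radius, so AUC is 1 for coincident
  point sets and (r_max - d)/r_max for a single pair at distance d.  No edge
  correction; the radius is kept below the core radius instead.
* **JSD** — Jensen-Shannon distance (base 2, square root of the divergence)
  between the normalized 2D Gaussian-kernel intensity estimates of two
  phenotypes on a shared grid: 0 for complete overlap, 1 for complete
  separation.
* **Interaction z-score** — mean count of target cells within 100 µm of each
  reference cell, standardized against a permutation null that shuffles
  phenotype labels within the compartment.

Edge cells of a neighborhood region are the points on the boundary of its
alpha shape (Delaunay triangles filtered by circumradius), falling back to
the convex hull when the region is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from scipy.spatial.distance import jensenshannon

from .core import ValidationError, logger

R_MAX = 150.0
N_GRID = 151
INTERACTION_RADIUS = 100.0
KDE_BW_FLOOR = 10.0
KDE_GRID = 128


# --------------------------------------------------------------------------
# G-Cross
# --------------------------------------------------------------------------

@dataclass
class GCrossResult:
    reference: str
    target: str
    compartment: str | None
    radii: np.ndarray
    cdf: np.ndarray | None
    auc: float | None
    n_reference: int
    n_target: int


def gcross_auc(
    reference: np.ndarray,
    target: np.ndarray,
    r_max: float = R_MAX,
    n_grid: int = N_GRID,
    exclude_self: bool = False,
    reference_name: str = "ref",
    target_name: str = "target",
    compartment: str | None = None,
) -> GCrossResult:
    """Nearest-neighbor CDF from each reference point to the target set.

    ``exclude_self`` must be set when both sets are the same phenotype so a
    point is not its own nearest neighbor.  Empty reference or target sets
    yield a null (not zero) AUC.
    """
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    target = np.asarray(target, dtype=float).reshape(-1, 2)
    radii = np.linspace(0.0, r_max, n_grid)
    n_ref, n_tgt = len(reference), len(target)
    if n_ref == 0 or n_tgt == 0 or (exclude_self and n_tgt < 2):
        return GCrossResult(
            reference_name, target_name, compartment, radii, None, None, n_ref, n_tgt
        )
    tree = cKDTree(target)
    if exclude_self:
        d, _ = tree.query(reference, k=2)
        nnd = d[:, 1]
    else:
        nnd, _ = tree.query(reference, k=1)
    cdf = (nnd[None, :] <= radii[:, None]).mean(axis=1)
    # exact integral of the empirical step CDF on [0, r_max]:
    # integral 1{nnd <= r} dr = r_max - min(nnd, r_max), averaged over refs
    auc = float(np.mean(r_max - np.minimum(nnd, r_max)) / r_max)
    return GCrossResult(
        reference_name, target_name, compartment, radii, cdf, auc, n_ref, n_tgt
    )


# --------------------------------------------------------------------------
# Alpha-shape edge cells
# --------------------------------------------------------------------------

def _alpha_boundary(points: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of points on the alpha-shape boundary.

    Triangles of the Delaunay triangulation with circumradius <= alpha are
    kept; boundary edges are those used by exactly one kept triangle.  Points
    in no kept triangle are isolated and flagged as boundary themselves.
    """
    tri = Delaunay(points)
    simplices = tri.simplices
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la, lb, lc = (
        np.linalg.norm(b - c, axis=1),
        np.linalg.norm(a - c, axis=1),
        np.linalg.norm(a - b, axis=1),
    )
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = la * lb * lc / np.maximum(2.0 * area2, 1e-300)
    keep = simplices[circumradius <= alpha]
    if len(keep) == 0:
        return np.arange(len(points))
    edge_count: dict[tuple[int, int], int] = {}
    for s in keep:
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = (min(s[i], s[j]), max(s[i], s[j]))
            edge_count[e] = edge_count.get(e, 0) + 1
    boundary = {v for e, cnt in edge_count.items() if cnt == 1 for v in e}
    used = set(keep.ravel().tolist())
    isolated = set(range(len(points))) - used
    return np.array(sorted(boundary | isolated), dtype=int)


def _hull_boundary(points: np.ndarray) -> np.ndarray:
    try:
        hull = ConvexHull(points)
        return np.asarray(hull.vertices, dtype=int)
    except QhullError:
        return np.arange(len(points))  # collinear: every point is boundary


def edge_cells(
    cells: pd.DataFrame, view: str = "cn2_label", alpha: float | None = None
) -> pd.Series:
    """Flag cells on the concave-hull boundary of their neighborhood region.

    The alpha-shape filter length defaults to twice the median
    nearest-neighbor spacing of the region's points; degenerate regions
    (collinear or Delaunay failure) fall back to the convex hull with a
    warning.  Regions with fewer than 4 cells are skipped.
    """
    flags = pd.Series(False, index=cells.index)
    for (core_id, region), sub in cells.groupby(["core_id", view], sort=True):
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) < 4:
            continue
        if alpha is None:
            tree = cKDTree(pts)
            d, _ = tree.query(pts, k=2)
            a = 2.0 * float(np.median(d[:, 1]))
        else:
            a = alpha
        try:
            idx = _alpha_boundary(pts, a)
        except QhullError:
            logger.warning(
                "core %r region %r: degenerate geometry, convex-hull fallback",
                core_id, region,
            )
            idx = _hull_boundary(pts)
        flags.loc[sub.index[idx]] = True
    return flags


# --------------------------------------------------------------------------
# Jensen-Shannon distance between KDE intensities
# --------------------------------------------------------------------------

@dataclass
class JsdResult:
    phenotype_a: str
    phenotype_b: str
    compartment: str | None
    bandwidth_a: float | None
    bandwidth_b: float | None
    grid_shape: tuple[int, int]
    distance: float | None


def _scott_bandwidth(points: np.ndarray, floor: float) -> float:
    n = len(points)
    sd = float(np.sqrt(points.var(axis=0).mean()))
    return max(sd * n ** (-1.0 / 6.0), floor)


def kde_pmf(
    points: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Isotropic Gaussian KDE evaluated on a grid, normalized to a pmf."""
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    density = np.zeros(len(flat))
    for start in range(0, len(points), 512):
        chunk = points[start : start + 512]
        d2 = ((flat[:, None, :] - chunk[None, :, :]) ** 2).sum(axis=2)
        density += np.exp(-d2 * inv2h2).sum(axis=1)
    total = density.sum()
    if total <= 0:
        raise ValidationError("degenerate KDE: zero mass on evaluation grid")
    return density / total


def jsd(
    points_a: np.ndarray,
    points_b: np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
    bandwidth: float | None = None,
    grid_size: int = KDE_GRID,
    bw_floor: float = KDE_BW_FLOOR,
    name_a: str = "A",
    name_b: str = "B",
    compartment: str | None = None,
) -> JsdResult:
    """Jensen-Shannon distance between the two phenotypes' KDE intensities.

    Bandwidths follow Scott's rule per point set with a floor of 10 µm
    (override with ``bandwidth``); the shared evaluation grid covers the
    union bounding box (or explicit ``bounds`` = (xmin, xmax, ymin, ymax))
    padded by 3 bandwidths.  Either set with fewer than 2 points yields a
    null distance, imputed downstream.
    """
    A = np.asarray(points_a, dtype=float).reshape(-1, 2)
    B = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(A) < 2 or len(B) < 2:
        return JsdResult(name_a, name_b, compartment, None, None,
                         (grid_size, grid_size), None)
    h_a = bandwidth if bandwidth is not None else _scott_bandwidth(A, bw_floor)
    h_b = bandwidth if bandwidth is not None else _scott_bandwidth(B, bw_floor)
    pad = 3.0 * max(h_a, h_b)
    if bounds is None:
        allpts = np.vstack([A, B])
        bounds = (
            allpts[:, 0].min(), allpts[:, 0].max(),
            allpts[:, 1].min(), allpts[:, 1].max(),
        )
    grid_x = np.linspace(bounds[0] - pad, bounds[1] + pad, grid_size)
    grid_y = np.linspace(bounds[2] - pad, bounds[3] + pad, grid_size)
    p = kde_pmf(A, grid_x, grid_y, h_a)
    q = kde_pmf(B, grid_x, grid_y, h_b)
    dist = float(jensenshannon(p, q, base=2))
    if not np.isfinite(dist):
        dist = 1.0
    return JsdResult(
        name_a, name_b, compartment, h_a, h_b, (grid_size, grid_size), min(dist, 1.0)
    )


# --------------------------------------------------------------------------
# Permutation interaction z-score
# --------------------------------------------------------------------------

def interaction_zscore(
    xy: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    radius: float = INTERACTION_RADIUS,
    n_perm: int = 200,
    seed: int = 0,
) -> float | None:
    """Permutation z-score of target counts near reference cells.

    Observed statistic: mean number of ``pair[1]`` cells within ``radius`` of
    each ``pair[0]`` cell (self excluded).  The null shuffles all labels in
    the compartment ``n_perm`` times, holding positions fixed.
    """
    if n_perm <= 0:
        raise ValidationError("n_perm must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    a, b = pair
    if (labels == a).sum() == 0 or (labels == b).sum() == 0:
        return None
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=radius)
    flat, offsets = [], [0]
    for i, lst in enumerate(neighbor_lists):
        flat.extend(j for j in lst if j != i)
        offsets.append(len(flat))
    flat = np.asarray(flat, dtype=int)
    offsets = np.asarray(offsets[:-1], dtype=int)

    def stat(lab: np.ndarray) -> float:
        is_b = (lab == b).astype(float)
        counts = np.add.reduceat(is_b[flat], offsets) if len(flat) else np.zeros(len(xy))
        # reduceat quirk: empty segments copy the next element
        seg_len = np.diff(np.append(offsets, len(flat)))
        counts[seg_len == 0] = 0.0
        return float(counts[lab == a].mean())

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = stat(rng.permutation(labels))
    sd = null.std(ddof=1)
    if sd == 0:
        return None
    return float((obs - null.mean()) / sd)
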
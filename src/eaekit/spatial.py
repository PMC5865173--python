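"""Standardized-disk spatial analysis of spinal-cord slices.

A slice is reduced to a boundary polygon plus a list of labeled cell
points.  Each cell at angle ``theta`` from the section center is mapped to
normalized radius ``r = d / R(theta)`` where ``R(theta)`` is the distance
from the center to the boundary along the same ray — every slice becomes a
unit disk of normalized area and shape.  On that disk the module computes
equal-area annular band profiles, averaged density maps, two-channel
overlap maps, and plaque (dense cluster) detection with dorsal versus
ventro-lateral sector counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon
from shapely.ops import polylabel
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import radius_neighbors_graph

from .datatypes import (
    BandProfile,
    DensityMap,
    PlaqueSet,
    SliceRecord,
    StandardizedSlice,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default sector partition (degrees, counterclockwise from +x, +y dorsal).
DEFAULT_SECTORS: dict[str, list[tuple[float, float]]] = {
    "dorsal": [(45.0, 135.0)],
    "ventro_lateral": [(0.0, 45.0), (135.0, 360.0)],
}


def ray_boundary_distance(
    center: tuple[float, float], angles: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Distance from ``center`` to the nearest boundary crossing along each ray.

    Exact polygon-ray intersection (no angular binning): for each angle the
    ray ``center + t * (cos, sin)`` is intersected with every polygon edge
    and the smallest positive ``t`` is returned (``inf`` when the ray never
    crosses, which cannot happen for an interior center).
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    v = np.asarray(vertices, dtype=float)
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    p, q = v[:-1], v[1:]                        # (M, 2) edge endpoints
    e = q - p                                   # (M, 2)
    c = np.asarray(center, dtype=float)
    w = p - c                                   # (M, 2)

    d = np.stack([np.cos(angles), np.sin(angles)], axis=1)   # (N, 2)
    # cross products, broadcast to (N, M)
    denom = d[:, 0:1] * e[None, :, 1] - d[:, 1:2] * e[None, :, 0]
    wxe = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]              # (M,)
    wxd = w[None, :, 0] * d[:, 1:2] - w[None, :, 1] * d[:, 0:1]

    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxe[None, :] / denom
        s = wxd / denom
    valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def find_center(rec: SliceRecord | np.ndarray) -> tuple[float, float]:
    """Area centroid of the slice boundary polygon."""
    boundary = rec.boundary if isinstance(rec, SliceRecord) else np.asarray(rec)
    poly = Polygon(boundary)
    if poly.area <= 0:
        raise ValidationError("degenerate boundary polygon (zero area)")
    c = poly.centroid
    return (c.x, c.y)


class DiskStandardizer(BaseEstimator, TransformerMixin):
    """Boundary-relative polar normalization of a slice onto the unit disk.

    Parameters
    ----------
    center_mode : {'centroid', 'chebyshev'}
        Reference point.  'centroid' uses the polygon area centroid and
        falls back to the pole of inaccessibility (Chebyshev-like center)
        when the centroid leaves more than ``max_flagged_frac`` of the
        cells outside the first boundary crossing of their ray
        (non-star-shaped configuration).
    max_flagged_frac : float
        Tolerated fraction of unplaceable cells before the fallback.
    """

    def __init__(self, center_mode: str = "centroid", max_flagged_frac: float = 0.01):
        self.center_mode = center_mode
        self.max_flagged_frac = max_flagged_frac

    def fit(self, rec: SliceRecord, y=None) -> "DiskStandardizer":
        poly = Polygon(np.asarray(rec.boundary, dtype=float))
        if poly.area <= 0:
            raise ValidationError("degenerate boundary polygon (zero area)")
        if not poly.is_simple:
            raise ValidationError("boundary polygon is self-intersecting")
        if self.center_mode == "chebyshev":
            c = polylabel(poly, tolerance=poly.length / 1e4)
            self.center_ = (c.x, c.y)
        else:
            self.center_ = (poly.centroid.x, poly.centroid.y)
        self.boundary_ = np.asarray(rec.boundary, dtype=float)
        return self

    def transform(self, rec: SliceRecord) -> StandardizedSlice:
        cells = rec.cells
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        std = self._standardize_points(xy, self.center_)
        flagged = np.flatnonzero(std[:, 0] > 1.0 + 1e-9)
        if len(flagged) > self.max_flagged_frac * max(len(xy), 1) and self.center_mode == "centroid":
            # centroid not a star center for this boundary: fall back
            poly = Polygon(self.boundary_)
            c = polylabel(poly, tolerance=poly.length / 1e4)
            logger.warning(
                "centroid leaves %d/%d cells unplaceable; falling back to "
                "pole of inaccessibility", len(flagged), len(xy),
            )
            self.center_ = (c.x, c.y)
            std = self._standardize_points(xy, self.center_)
            flagged = np.flatnonzero(std[:, 0] > 1.0 + 1e-9)
        out = cells.copy()
        out["r"] = np.minimum(std[:, 0], 1.0)
        out["theta"] = std[:, 1]
        out = out.drop(columns=["x", "y"])
        return StandardizedSlice(
            cells=out,
            center=self.center_,
            metadata=dict(rec.metadata),
            flagged=flagged if len(flagged) else None,
        )

    def _standardize_points(self, xy: np.ndarray, center) -> np.ndarray:
        if len(xy) == 0:
            return np.empty((0, 2))
        dx = xy[:, 0] - center[0]
        dy = xy[:, 1] - center[1]
        dist = np.hypot(dx, dy)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        R = ray_boundary_distance(center, theta, self.boundary_)
        if not np.all(np.isfinite(R)):
            raise ValidationError("a cell ray failed to intersect the boundary")
        r = np.where(dist == 0, 0.0, dist / R)
        return np.stack([r, theta], axis=1)


def standardize(rec: SliceRecord, **kwargs) -> StandardizedSlice:
    """Map a slice onto the standardized unit disk (see DiskStandardizer)."""
    return DiskStandardizer(**kwargs).fit(rec).transform(rec)


def band_profile(
    std: StandardizedSlice | list[StandardizedSlice], K: int = 20
) -> BandProfile:
    """Cell counts and densities in K equal-area concentric bands.

    Band k spans sqrt((k-1)/K) <= r < sqrt(k/K); every band has normalized
    area pi/K.  For several slices, counts are per-slice means.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    slices = std if isinstance(std, list) else [std]
    if not slices:
        raise ValidationError("empty slice list")
    counts = np.zeros(K, dtype=float)
    for s in slices:
        r2 = np.clip(s.cells["r"].to_numpy(dtype=float) ** 2, 0.0, None)
        idx = np.minimum((r2 * K).astype(int), K - 1)
        counts += np.bincount(idx, minlength=K)
    counts /= len(slices)
    edges = np.sqrt(np.arange(K + 1) / K)
    return BandProfile(
        edges=edges, counts=counts, densities=counts / (np.pi / K),
        n_slices=len(slices),
    )


def density_map(
    slices: list[StandardizedSlice],
    grid_n: int = 64,
    bandwidth: float = 0.0,
    channel: str | None = None,
) -> DensityMap:
    """Average cell density over the standardized disk on an N x N grid.

    Per slice, cells are binned on the [-1, 1]^2 grid, optionally smoothed
    with a Gaussian kernel of ``bandwidth`` (normalized units), masked to
    the unit disk and rescaled so the per-slice integral equals the slice's
    cell count; maps are then averaged across slices.  Values are cells per
    unit normalized area; grid cells outside the disk are NaN.
    """
    if not slices:
        raise ValidationError("empty slice list")
    px = 2.0 / grid_n
    centers = -1.0 + px * (np.arange(grid_n) + 0.5)
    yy, xx = np.meshgrid(centers, centers, indexing="ij")
    inside = xx**2 + yy**2 <= 1.0
    acc = np.zeros((grid_n, grid_n))
    edges = np.linspace(-1.0, 1.0, grid_n + 1)
    for s in slices:
        cells = s.cells
        if channel is not None:
            cells = cells[cells["channel"] == channel]
        r = cells["r"].to_numpy(dtype=float)
        th = cells["theta"].to_numpy(dtype=float)
        h, _, _ = np.histogram2d(r * np.sin(th), r * np.cos(th), bins=(edges, edges))
        n = h.sum()
        if bandwidth > 0:
            h = gaussian_filter(h, sigma=bandwidth / px, mode="constant")
        h[~inside] = 0.0
        tot = h.sum()
        if tot > 0:
            h *= n / tot          # conserve per-slice mass on the disk
        acc += h / (px * px)      # counts -> density
    grid = acc / len(slices)
    grid[~inside] = np.nan
    return DensityMap(grid=grid, n_slices=len(slices), channel=channel)


def overlap_map(a: DensityMap, b: DensityMap, q: float = 0.5) -> np.ndarray:
    """Tri-state occupancy map of two density maps.

    Each map is binarized at the q-th quantile of its positive values;
    returns an int grid with 0 = empty, 1 = A only, 2 = B only,
    3 = overlap, -1 = outside the disk.
    """
    if a.grid.shape != b.grid.shape:
        raise ValidationError("density map grids differ in shape")
    out = np.zeros(a.grid.shape, dtype=int)
    masks = []
    for m in (a, b):
        g = m.grid
        vals = g[np.isfinite(g) & (g > 0)]
        if vals.size == 0:
            masks.append(np.zeros_like(out, dtype=bool))
            continue
        thr = np.quantile(vals, q)
        masks.append(np.isfinite(g) & (g >= thr) & (g > 0))
    out[masks[0]] += 1
    out[masks[1]] += 2
    out[~np.isfinite(a.grid)] = -1
    return out


class PlaqueDetector(BaseEstimator):
    """Density-linkage plaque detection on standardized disk coordinates.

    Two cells are linked when their Euclidean distance (in normalized disk
    coordinates) is at most ``eps``; plaques are connected components with
    at least ``min_cells`` members.  Cells outside any such component get
    label -1 (diffuse / noise).
    """

    def __init__(self, eps: float = 0.03, min_cells: int = 10):
        self.eps = eps
        self.min_cells = min_cells

    def fit(self, X: np.ndarray, y=None) -> "PlaqueDetector":
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.min_cells < 3:
            raise ValidationError("min_cells must be >= 3")
        X = np.asarray(X, dtype=float)
        labels = np.full(len(X), -1, dtype=int)
        if len(X):
            graph = radius_neighbors_graph(X, radius=self.eps, mode="connectivity")
            _, comp = connected_components(graph, directed=False)
            keep = 0
            for cid, size in zip(*np.unique(comp, return_counts=True)):
                if size >= self.min_cells:
                    labels[comp == cid] = keep
                    keep += 1
        self.labels_ = labels
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def detect_plaques(
    std: StandardizedSlice,
    channel: str | None = None,
    eps: float = 0.03,
    min_cells: int = 10,
    sectors: dict[str, list[tuple[float, float]]] | None = None,
) -> PlaqueSet:
    """Detect plaques of one channel (or all channels) in a standardized slice."""
    sectors = _validate_sectors(sectors)
    cells = std.cells
    sel = np.ones(len(cells), dtype=bool) if channel is None \
        else (cells["channel"] == channel).to_numpy()
    r = cells["r"].to_numpy(dtype=float)[sel]
    th = cells["theta"].to_numpy(dtype=float)[sel]
    X = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    labels = PlaqueDetector(eps=eps, min_cells=min_cells).fit_predict(X)
    pos = np.flatnonzero(sel)
    members, cents, secs = [], [], []
    for pid in range(labels.max() + 1 if len(labels) else 0):
        idx = labels == pid
        members.append(pos[idx])
        cx, cy = X[idx, 0].mean(), X[idx, 1].mean()
        rc = float(np.hypot(cx, cy))
        tc = float(np.mod(np.arctan2(cy, cx), 2 * np.pi))
        cents.append((rc, tc))
        secs.append(sector_of(tc, sectors))
    return PlaqueSet(
        members=members,
        centroids=np.asarray(cents).reshape(-1, 2),
        sectors=secs,
    )


def sector_of(theta: float, sectors: dict[str, list[tuple[float, float]]]) -> str:
    """Sector containing angle ``theta`` (radians)."""
    deg = np.degrees(theta) % 360.0
    for name, spans in sectors.items():
        for lo, hi in spans:
            if lo <= deg < hi:
                return name
    raise ValidationError(f"angle {deg:.2f} deg not covered by sector config")


def _validate_sectors(sectors):
    sectors = sectors if sectors is not None else DEFAULT_SECTORS
    spans = sorted((lo, hi) for v in sectors.values() for lo, hi in v)
    total = sum(hi - lo for lo, hi in spans)
    cover = abs(total - 360.0) < 1e-9 and spans[0][0] == 0.0
    disjoint = all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
    if not (cover and disjoint):
        raise ValidationError("sectors must partition [0, 360) degrees")
    return sectors


def sector_counts(
    plaques: PlaqueSet | list[PlaqueSet],
    sectors: dict[str, list[tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Plaque counts per sector, one row per slice."""
    sectors = _validate_sectors(sectors)
    sets = plaques if isinstance(plaques, list) else [plaques]
    rows = []
    for ps in sets:
        row = {name: 0 for name in sectors}
        for theta_sec in ps.sectors:
            row[theta_sec] += 1
        rows.append(row)
    return pd.DataFrame(rows)
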
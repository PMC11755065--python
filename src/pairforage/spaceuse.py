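"""Kernel utilization distributions, volume contours, and overlap.

UDs are estimated on a metric grid in the colony-centred azimuthal-
equidistant plane with an isotropic bivariate Gaussian kernel (default grid
200 m, study bandwidth 2720 m — the ad-hoc reference bandwidth averaged over
birds).  Grids are always aligned to integer multiples of the cell size in
colony coordinates so any two UDs can be pasted onto a common (union) grid
without resampling error.

Overlap is Bhattacharyya's Affinity, Σ√(p₁·p₂) over cells: 0 for disjoint
distributions, 1 for identical ones.  By default each UD is first masked to
its own 50% volume contour (core foraging area) and renormalized, so the
"identical UDs → 1" endpoint holds at any contour level; the unrenormalized
variant is available for cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geo import ColonyProjection


def href_bandwidth(points_xy: np.ndarray) -> float:
    """Ad-hoc reference bandwidth for a bivariate Gaussian kernel (metres):
    h = 0.5 · (sd_x + sd_y) · n^(−1/6), sample SDs (ddof=1)."""
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need >= 5 two-dimensional points")
    sd = pts.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("degenerate points: zero variance in x or y")
    return float(0.5 * sd.sum() * len(pts) ** (-1.0 / 6.0))


@dataclass
class UDGrid:
    """Gridded utilization distribution; mass per cell sums to one.

    ``origin`` is the (x, y) of the lower-left cell *centre*, an integer
    multiple of ``cell_size`` in the colony plane; ``masses[i, j]`` is the
    cell at y = origin[1] + i·cell, x = origin[0] + j·cell.
    """

    origin: tuple
    cell_size: float
    bandwidth: float
    masses: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if (self.masses < 0).any():
            raise ValueError("masses must be >= 0")
        s = self.masses.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"masses must sum to 1, got {s}")

    @property
    def shape(self):
        return self.masses.shape

    def cell_centers(self):
        ny, nx = self.masses.shape
        x = self.origin[0] + np.arange(nx) * self.cell_size
        y = self.origin[1] + np.arange(ny) * self.cell_size
        return x, y


def kernel_ud(points_xy, h: float, cell_size: float = 200.0, pad_factor: float = 4.0) -> UDGrid:
    """Gaussian-kernel UD of a point set (metres in the colony plane).

    Points are binned to the grid and smoothed with an isotropic Gaussian of
    SD ``h`` (exact up to the sub-cell binning offset, which is below
    cell_size/2 ≤ h/27 at the study configuration).  Grid extent is the data
    bounding box padded by ``pad_factor``·h, snapped to cell multiples.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("need >= 1 two-dimensional point")
    if not h > 0:
        raise ValueError("bandwidth must be > 0")
    pad = pad_factor * h
    x0 = np.floor((pts[:, 0].min() - pad) / cell_size) * cell_size
    y0 = np.floor((pts[:, 1].min() - pad) / cell_size) * cell_size
    x1 = np.ceil((pts[:, 0].max() + pad) / cell_size) * cell_size
    y1 = np.ceil((pts[:, 1].max() + pad) / cell_size) * cell_size
    nx = int(round((x1 - x0) / cell_size)) + 1
    ny = int(round((y1 - y0) / cell_size)) + 1
    ix = np.clip(np.round((pts[:, 0] - x0) / cell_size).astype(int), 0, nx - 1)
    iy = np.clip(np.round((pts[:, 1] - y0) / cell_size).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)
    dens = gaussian_filter(counts, sigma=h / cell_size, mode="constant", truncate=8.0)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum()
    return UDGrid(origin=(float(x0), float(y0)), cell_size=float(cell_size), bandwidth=float(h), masses=dens)


def volume_contour(grid: UDGrid, q: float) -> np.ndarray:
    """Boolean mask of the minimal-mass-area q-contour: cells sorted by mass
    descending, smallest prefix with cumulative mass >= q; ties at the
    cut-off density are all retained."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    flat = grid.masses.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, q - 1e-12)) + 1
    k = min(k, len(flat))
    thresh = flat[order[k - 1]]
    mask = (grid.masses >= thresh) & (grid.masses > 0)
    return mask


def _union_paste(a: UDGrid, b: UDGrid):
    """Place two aligned UDs on their union grid; returns (A, B, origin)."""
    if abs(a.cell_size - b.cell_size) > 1e-9:
        raise ValueError("UDs must share a cell size")
    cs = a.cell_size
    for g in (a, b):
        if abs(g.origin[0] / cs - round(g.origin[0] / cs)) > 1e-6 or abs(
            g.origin[1] / cs - round(g.origin[1] / cs)
        ) > 1e-6:
            raise ValueError("UD origins must be aligned to cell multiples")
    x0 = min(a.origin[0], b.origin[0])
    y0 = min(a.origin[1], b.origin[1])
    x1 = max(a.origin[0] + (a.shape[1] - 1) * cs, b.origin[0] + (b.shape[1] - 1) * cs)
    y1 = max(a.origin[1] + (a.shape[0] - 1) * cs, b.origin[1] + (b.shape[0] - 1) * cs)
    nx = int(round((x1 - x0) / cs)) + 1
    ny = int(round((y1 - y0) / cs)) + 1
    out = []
    for g in (a, b):
        M = np.zeros((ny, nx))
        oy = int(round((g.origin[1] - y0) / cs))
        ox = int(round((g.origin[0] - x0) / cs))
        M[oy : oy + g.shape[0], ox : ox + g.shape[1]] = g.masses
        out.append(M)
    return out[0], out[1], (x0, y0)


def bhattacharyya_overlap(ud_f: UDGrid, ud_m: UDGrid, level: float = 0.5,
                          renormalize: bool = True) -> float:
    """Bhattacharyya's Affinity between two UDs on their union grid.

    Each UD is masked to its own ``level`` volume contour (level=1 keeps the
    full distribution); with ``renormalize`` each masked UD is rescaled to
    sum 1 before Σ√(p_f·p_m) is taken, so BA(ud, ud) = 1 at any level.
    """
    A, B, _ = _union_paste(ud_f, ud_m)
    if level < 1.0:
        ga = UDGrid(origin=(0.0, 0.0), cell_size=ud_f.cell_size, bandwidth=ud_f.bandwidth, masses=A / A.sum())
        gb = UDGrid(origin=(0.0, 0.0), cell_size=ud_m.cell_size, bandwidth=ud_m.bandwidth, masses=B / B.sum())
        A = np.where(volume_contour(ga, level), A, 0.0)
        B = np.where(volume_contour(gb, level), B, 0.0)
    if A.sum() == 0 or B.sum() == 0:
        import warnings

        warnings.warn("empty UD after masking; BA = 0")
        return 0.0
    if renormalize:
        A = A / A.sum()
        B = B / B.sum()
    return float(np.clip(np.sqrt(A * B).sum(), 0.0, 1.0))


def contour_geojson(grid: UDGrid, levels, proj: ColonyProjection) -> str:
    """GeoJSON FeatureCollection of contour polygons in WGS84 lon/lat."""
    from shapely.geometry import box, mapping
    from shapely.ops import transform, unary_union

    feats = []
    cs = grid.cell_size
    for q in levels:
        mask = volume_contour(grid, q)
        iy, ix = np.nonzero(mask)
        boxes = [
            box(
                grid.origin[0] + j * cs - cs / 2, grid.origin[1] + i * cs - cs / 2,
                grid.origin[0] + j * cs + cs / 2, grid.origin[1] + i * cs + cs / 2,
            )
            for i, j in zip(iy, ix)
        ]
        poly = unary_union(boxes)

        def to_ll(x, y):
            lon, lat = proj.to_lonlat(np.asarray(x), np.asarray(y))
            return lon, lat

        poly_ll = transform(to_ll, poly)
        feats.append(
            {"type": "Feature", "properties": {"level": q}, "geometry": mapping(poly_ll)}
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})


def ud_to_text(grid: UDGrid) -> str:
    """Plain-text raster: one header line (origin, cell size, bandwidth) then
    rows of cell masses, bottom row first."""
    header = f"# origin_x={grid.origin[0]} origin_y={grid.origin[1]} cell_size={grid.cell_size} bandwidth={grid.bandwidth}"
    body = "\n".join(" ".join(f"{v:.6e}" for v in row) for row in grid.masses)
    return header + "\n" + body + "\n"
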
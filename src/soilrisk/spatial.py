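"""Scattered-data interpolation to hazard rasters and area accounting.

Site-level index values are interpolated to a regular metric grid with
multilevel B-spline approximation: a hierarchy of uniform cubic B-spline
control lattices, coarse to fine (lattice resolution doubling per level), each
fitted to the residuals of the previous level, so the final surface is the sum
of progressively finer smooth corrections.  The scheme is deterministic,
independent of point order, and drives the residual at the data points to zero
as levels are added.

The interpolated surface is then classified with the right-closed hazard
scales from :mod:`soilrisk.indices`, per-class areas are counted from grid
cells (optionally inside a study polygon), and contours are traced by marching
squares.  Rasters travel as ESRI ASCII grids, contours and masks as GeoJSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

from .indices import ClassificationScale

__all__ = [
    "RasterGrid",
    "MBSSurface",
    "make_grid_spec",
    "fit_mbs",
    "fit_mbs_surface",
    "classify_raster",
    "area_shares",
    "extract_contours",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_contours_geojson",
    "read_mask_geojson",
]

NODATA = -9999.0

DEFAULT_CELL_SIZE = 100.0  # m
DEFAULT_PADDING = 0.05  # fraction of bbox extent added per side
DEFAULT_LEVELS = 8
DEFAULT_INITIAL_LATTICE = 4


@dataclass
class RasterGrid:
    """Regular grid in projected meters; row 0 is the northernmost row."""

    x_origin: float  # lower-left corner
    y_origin: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), row-major, north to south
    nodata: float = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-style (X, Y) arrays of cell-center coordinates."""
        x = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def mask_valid(self) -> np.ndarray:
        return ~np.isclose(self.values.astype(float), self.nodata) & np.isfinite(
            self.values.astype(float)
        )


def make_grid_spec(
    bbox: tuple[float, float, float, float],
    cell_size: float = DEFAULT_CELL_SIZE,
    padding: float = DEFAULT_PADDING,
) -> tuple[tuple[float, float, float, float], float]:
    """Pad a sample bbox and snap it to whole grid cells."""
    xmin, ymin, xmax, ymax = bbox
    dx, dy = xmax - xmin, ymax - ymin
    xmin, xmax = xmin - padding * dx, xmax + padding * dx
    ymin, ymax = ymin - padding * dy, ymax + padding * dy
    n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    return (xmin, ymin, xmin + n_cols * cell_size, ymin + n_rows * cell_size), cell_size


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B_0..B_3 at local parameter t."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


def _lattice_coords(x, y, bbox, m, n):
    """Map points into lattice units and split into cell index + fraction."""
    xmin, ymin, xmax, ymax = bbox
    u = (np.asarray(x, dtype=float) - xmin) / (xmax - xmin) * m
    v = (np.asarray(y, dtype=float) - ymin) / (ymax - ymin) * n
    i = np.clip(np.floor(u).astype(int), 0, m - 1)
    j = np.clip(np.floor(v).astype(int), 0, n - 1)
    return i, j, u - i, v - j


def _ba_fit(x, y, z, bbox, m, n) -> np.ndarray:
    """One-level B-spline approximation: least-effort control lattice for z.

    Each data point distributes its value to the 4×4 surrounding control
    points in proportion to the squared basis weights; overlapping claims are
    resolved by the weighted average (the standard BA update).
    """
    i, j, s, t = _lattice_coords(x, y, bbox, m, n)
    ws, wt = _bspline_weights(s), _bspline_weights(t)
    delta = np.zeros((m + 3, n + 3))
    omega = np.zeros((m + 3, n + 3))
    w_sq_sum = np.zeros(len(z))
    for k in range(4):
        for l in range(4):
            w_sq_sum += (ws[k] * wt[l]) ** 2
    for k in range(4):
        for l in range(4):
            w = ws[k] * wt[l]
            phi = w * z / w_sq_sum
            np.add.at(delta, (i + k, j + l), w * w * phi)
            np.add.at(omega, (i + k, j + l), w * w)
    control = np.zeros_like(delta)
    nz = omega > 0
    control[nz] = delta[nz] / omega[nz]
    return control


def _ba_eval(x, y, control, bbox, m, n) -> np.ndarray:
    i, j, s, t = _lattice_coords(x, y, bbox, m, n)
    ws, wt = _bspline_weights(s), _bspline_weights(t)
    out = np.zeros(np.shape(s))
    for k in range(4):
        for l in range(4):
            out += ws[k] * wt[l] * control[i + k, j + l]
    return out


@dataclass
class MBSSurface:
    """Fitted multilevel B-spline surface over a rectangular domain.

    ``level_residuals[l]`` is the maximum absolute data-point residual after
    the first ``l+1`` levels; it is non-increasing by construction of the
    residual hierarchy.
    """

    bbox: tuple[float, float, float, float]
    offset: float = 0.0  # data mean; lattices fit residuals about it
    lattices: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    level_residuals: list[float] = field(default_factory=list)

    def __call__(self, x, y) -> np.ndarray:
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        out = np.full(x.shape, self.offset)
        for m, n, control in self.lattices:
            out += _ba_eval(x, y, control, self.bbox, m, n)
        return out


def _merge_coincident(x, y, z):
    """Average values at coincident points (conflicts trigger a warning)."""
    key = pd.DataFrame({"x": x, "y": y, "z": z})
    grouped = key.groupby(["x", "y"], sort=False)["z"]
    if grouped.size().max() > 1:
        if (grouped.nunique() > 1).any():
            warnings.warn("coincident points with conflicting values were averaged")
        merged = grouped.mean().reset_index()
        return merged["x"].to_numpy(), merged["y"].to_numpy(), merged["z"].to_numpy()
    return np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)


def fit_mbs(
    points: np.ndarray,
    values: np.ndarray,
    bbox: tuple[float, float, float, float],
    levels: int = DEFAULT_LEVELS,
    initial_lattice: int = DEFAULT_INITIAL_LATTICE,
    tolerance: float = 1e-6,
) -> MBSSurface:
    """Fit the multilevel B-spline surface to scattered (x, y, value) data.

    ``initial_lattice`` is the cell count of the coarsest control lattice per
    axis; each level doubles it.  Fitting stops early once the maximum
    data-point residual falls below ``tolerance`` of the value range.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("interpolation needs at least one point")
    values = np.asarray(values, dtype=float)
    x, y, z = _merge_coincident(points[:, 0], points[:, 1], values)
    xmin, ymin, xmax, ymax = bbox
    if (x < xmin).any() or (x > xmax).any() or (y < ymin).any() or (y > ymax).any():
        raise ValueError("all points must lie inside or on the interpolation bbox")
    # Fit residuals about the data mean: constant fields are reproduced
    # exactly and the surface relaxes toward the mean away from data support.
    surface = MBSSurface(bbox=bbox, offset=float(z.mean()))
    value_range = float(z.max() - z.min())
    tol_abs = tolerance * (value_range if value_range > 0 else max(abs(z.max()), 1.0))
    residual = z - surface.offset
    m = n = initial_lattice
    for _ in range(levels):
        control = _ba_fit(x, y, residual, bbox, m, n)
        surface.lattices.append((m, n, control))
        residual = residual - _ba_eval(x, y, control, bbox, m, n)
        surface.level_residuals.append(float(np.max(np.abs(residual))))
        if surface.level_residuals[-1] < tol_abs:
            break
        m, n = m * 2, n * 2
    return surface


def fit_mbs_surface(
    points: np.ndarray,
    values: np.ndarray,
    grid_spec: tuple[tuple[float, float, float, float], float],
    levels: int = DEFAULT_LEVELS,
    initial_lattice: int = DEFAULT_INITIAL_LATTICE,
) -> RasterGrid:
    """Interpolate scattered data onto the grid described by ``grid_spec``.

    ``grid_spec`` is ``(bbox, cell_size)`` as produced by
    :func:`make_grid_spec`; the surface is evaluated at cell centers.
    """
    bbox, cell_size = grid_spec
    surface = fit_mbs(points, values, bbox, levels=levels, initial_lattice=initial_lattice)
    grid = RasterGrid(
        x_origin=bbox[0],
        y_origin=bbox[1],
        cell_size=cell_size,
        values=np.zeros(
            (
                int(round((bbox[3] - bbox[1]) / cell_size)),
                int(round((bbox[2] - bbox[0]) / cell_size)),
            )
        ),
    )
    gx, gy = grid.cell_centers()
    grid.values = surface(gx, gy)
    return grid


def idw_surface(points, values, grid_spec, power: float = 2.0) -> RasterGrid:
    """Inverse-distance-weighted surface; a simple cross-check interpolator."""
    bbox, cell_size = grid_spec
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n_cols = int(round((bbox[2] - bbox[0]) / cell_size))
    n_rows = int(round((bbox[3] - bbox[1]) / cell_size))
    grid = RasterGrid(bbox[0], bbox[1], cell_size, np.zeros((n_rows, n_cols)))
    gx, gy = grid.cell_centers()
    d2 = (gx[..., None] - points[:, 0]) ** 2 + (gy[..., None] - points[:, 1]) ** 2
    with np.errstate(divide="ignore"):
        w = d2 ** (-power / 2.0)
    exact = d2.min(axis=-1) == 0
    w = np.where(np.isinf(w), 0.0, w)
    grid.values = (w * values).sum(axis=-1) / w.sum(axis=-1)
    if exact.any():
        nearest = d2.argmin(axis=-1)
        grid.values[exact] = values[nearest[exact]]
    return grid


def classify_raster(
    grid: RasterGrid, scale: ClassificationScale, clamp_min: float | None = 0.0
) -> RasterGrid:
    """Per-cell hazard classification; returns an integer class grid.

    Slight spline overshoot below ``clamp_min`` (indices are non-negative by
    construction) is clamped before classification; nodata is preserved as
    class -1.
    """
    valid = grid.mask_valid()
    values = grid.values.astype(float)
    if clamp_min is not None:
        values = np.maximum(values, clamp_min)
    classes = np.full(grid.values.shape, -1, dtype=int)
    classes[valid] = scale.class_index(values[valid])
    out = RasterGrid(grid.x_origin, grid.y_origin, grid.cell_size, classes, nodata=-1)
    return out


def area_shares(
    class_grid: RasterGrid,
    scale: ClassificationScale | None = None,
    mask: shapely.Geometry | None = None,
) -> pd.DataFrame:
    """Per-class area (m²) and percentage share of the mapped area.

    Cells are attributed by their center; with ``mask`` only cells whose
    center falls inside the polygon are counted.  With a ``scale`` every label
    appears in the result (zero for absent classes) and rows follow scale
    order.
    """
    classes = class_grid.values.astype(int)
    counted = class_grid.mask_valid()
    if mask is not None:
        gx, gy = class_grid.cell_centers()
        counted &= shapely.contains_xy(mask, gx, gy)
        if not counted.any():
            raise ValueError("mask polygon does not intersect any grid cell")
    total = int(counted.sum())
    cell_area = class_grid.cell_size**2
    labels = range(classes[counted].min(), classes[counted].max() + 1) if scale is None else range(len(scale.labels))
    rows = []
    for cls in labels:
        count = int(((classes == cls) & counted).sum())
        rows.append(
            {
                "class_index": cls,
                "label": scale.labels[cls] if scale is not None else str(cls),
                "area_m2": count * cell_area,
                "share_percent": 100.0 * count / total,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def extract_contours(grid: RasterGrid, levels: list[float]) -> list[dict]:
    """Marching-squares isolines in projected coordinates.

    Returns one ``{"level": v, "coords": (n, 2) array}`` per polyline; levels
    outside the grid's value range yield nothing (with a warning).
    """
    from skimage import measure

    vmin, vmax = float(np.nanmin(grid.values)), float(np.nanmax(grid.values))
    out = []
    for level in levels:
        if not (vmin < level < vmax):
            warnings.warn(f"contour level {level} outside grid range [{vmin}, {vmax}]")
            continue
        for line in measure.find_contours(grid.values.astype(float), level):
            rows, cols = line[:, 0], line[:, 1]
            x = grid.x_origin + (cols + 0.5) * grid.cell_size
            y = grid.y_origin + (grid.n_rows - rows - 0.5) * grid.cell_size
            out.append({"level": float(level), "coords": np.column_stack([x, y])})
    return out


# ---------------------------------------------------------------------------
# text I/O: ESRI ASCII grids, GeoJSON contours and masks


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid body does not match declared shape")
    return RasterGrid(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", NODATA),
    )


def write_contours_geojson(contours: list[dict], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": c["coords"].tolist()},
            "properties": {"level": c["level"]},
        }
        for c in contours
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_mask_geojson(path: str | Path) -> shapely.Geometry:
    """Read the study polygon (first Polygon/MultiPolygon feature)."""
    with open(path) as fh:
        data = json.load(fh)
    geoms = data["features"] if data.get("type") == "FeatureCollection" else [data]
    for feat in geoms:
        geom = feat.get("geometry", feat)
        if geom.get("type") in ("Polygon", "MultiPolygon"):
            return _geojson_shape(geom)
    raise ValueError(f"{path}: no polygon feature found")
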
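"""Spatial interpolation of environmental fields over irregular sample layouts.

Scattered samples are Delaunay-triangulated and each covariate is
interpolated piecewise-linearly (barycentric weights within each triangle) —
the triangulation-based linear mode used for irregularly spaced geochemical
data. Grid nodes outside the convex hull of the samples are missing (NaN):
no extrapolation. At a node coinciding with a sample point the field
reproduces that sample's value exactly, and every interpolated value lies
within the vertex-value range of its triangle.

Exports are text rasters in ESRI ASCII grid layout plus node/point CSVs, so
any GIS front-end can render them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .catalog import GeneCatalog


def triangulate(points: np.ndarray) -> Delaunay:
    """Delaunay triangulation of sample coordinates.

    Parameters
    ----------
    points:
        (n, 2) array of planar coordinates; needs >= 3 non-collinear,
        pairwise-distinct points.

    Raises
    ------
    ValueError
        Naming the offending points on duplicates or a degenerate
        (collinear) configuration. Cocircular degeneracies are broken
        deterministically by processing points in lexicographic order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("triangulation needs at least 3 points")
    _, idx, counts = np.unique(pts, axis=0, return_index=True, return_counts=True)
    if (counts > 1).any():
        dup = pts[idx[counts > 1][0]]
        raise ValueError(f"duplicate coordinates at {tuple(dup)}")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    try:
        tri = Delaunay(pts[order])
    except QhullError as exc:
        raise ValueError(f"degenerate (collinear?) point set: {exc}") from exc
    # re-index simplices back to the caller's point order
    simplices = order[tri.simplices]
    v1 = pts[simplices[:, 1]] - pts[simplices[:, 0]]
    v2 = pts[simplices[:, 2]] - pts[simplices[:, 0]]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    if np.any(area2 == 0):
        raise ValueError("degenerate triangle in triangulation")
    wrapped = Delaunay(pts)  # scipy object for downstream interpolation
    wrapped._ncycle_simplices = simplices  # deterministic simplex listing
    return wrapped


def triangles(tri: Delaunay) -> np.ndarray:
    """Simplex vertex indices from :func:`triangulate` (deterministic order)."""
    return getattr(tri, "_ncycle_simplices", tri.simplices)


@dataclass
class SpatialField:
    """A covariate interpolated onto a regular grid.

    ``values[i, j]`` is the field at ``(x[j], y[i])`` — row-major with y
    varying along rows, NaN outside the convex hull of the samples.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    cellsize: float

    @property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)


def make_grid(
    points: np.ndarray, resolution: int = 200, margin: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Regular grid axes over the samples' bounding box with a fractional margin."""
    pts = np.asarray(points, dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    dx = (xmax - xmin) * margin
    dy = (ymax - ymin) * margin
    return (
        np.linspace(xmin - dx, xmax + dx, resolution),
        np.linspace(ymin - dy, ymax + dy, resolution),
    )


def interpolate_linear(
    tri: Delaunay,
    values: np.ndarray,
    grid_x: np.ndarray | None = None,
    grid_y: np.ndarray | None = None,
    resolution: int = 200,
) -> SpatialField:
    """Piecewise-planar interpolation of per-sample values onto a grid.

    Inside each triangle the value is the barycentric combination of the
    three vertex values; outside the hull nodes are NaN. A missing vertex
    value (NaN) propagates to every node of its incident triangles.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != tri.points.shape[0]:
        raise ValueError("need exactly one value per triangulation vertex")
    if grid_x is None or grid_y is None:
        grid_x, grid_y = make_grid(tri.points, resolution=resolution)
    interp = LinearNDInterpolator(tri, values)
    gx, gy = np.meshgrid(grid_x, grid_y)
    field = interp(gx, gy)
    cell = float(grid_x[1] - grid_x[0]) if len(grid_x) > 1 else 0.0
    return SpatialField(np.asarray(grid_x), np.asarray(grid_y), field, cell)


def interpolate_at(tri: Delaunay, values: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Interpolate at arbitrary query points (NaN outside the hull)."""
    interp = LinearNDInterpolator(tri, np.asarray(values, dtype=float))
    return interp(np.asarray(xy, dtype=float))


def write_esri_ascii(field: SpatialField, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid text raster (ncols/nrows/xllcorner/... header).

    Rows are written north-up (first data row = largest y), per the format.
    """
    vals = np.where(np.isnan(field.values), nodata, field.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {len(field.x)}\n")
        fh.write(f"nrows {len(field.y)}\n")
        fh.write(f"xllcorner {field.x[0] - field.cellsize / 2:.6f}\n")
        fh.write(f"yllcorner {field.y[0] - field.cellsize / 2:.6f}\n")
        fh.write(f"cellsize {field.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def field_to_frame(field: SpatialField) -> pd.DataFrame:
    """Long CSV-ready table of grid nodes: x, y, value (NaN outside hull)."""
    gx, gy = field.grid
    return pd.DataFrame(
        {"x": gx.ravel(), "y": gy.ravel(), "value": field.values.ravel()}
    )


def export_point_layers(
    metrics: pd.DataFrame,
    env: pd.DataFrame,
    catalog: GeneCatalog,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-KO point layers: coordinates + abundance/richness/variance.

    One layer per catalog KO, each a sample-per-row table with ``sample_id,
    x, y, abundance, richness, variance`` in the metadata's sample order
    (undefined variance stays as an empty/NaN field). With ``outdir`` given,
    each layer is written to ``<outdir>/points_<ko>.csv``.
    """
    coords = env[["x", "y"]]
    layers: dict[str, pd.DataFrame] = {}
    for ko in catalog.kos:
        sub = metrics[metrics["ko"] == ko].set_index("sample_id")
        layer = coords.join(sub[["abundance", "richness", "variance"]], how="inner")
        layer = layer.reset_index().rename(columns={"index": "sample_id"})
        layers[ko] = layer
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            layer.to_csv(Path(outdir) / f"points_{ko}.csv", index=False, na_rep="")
    return layers
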
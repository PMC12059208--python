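"""Environmental raster layers and point extraction.

Grids are single-band geographic rasters in WGS84 decimal degrees. Extraction
is containing-cell (no interpolation) with a half-open cell convention: a
point on a shared edge belongs to the cell to the east/south of the edge.
Curvature layers (pcurv/tcurv) are in radians per meter; positive values are
convex surfaces, negative concave.

A pre-extracted environment table can be supplied instead of rasters, in
which case this module is bypassed entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridError

logger = logging.getLogger(__name__)

#: Canonical names of the 48 environmental predictors, grouped as
#: 19 climatic + 13 soil + 16 topographic variables.
CLIMATE_VARIABLES = tuple(f"bio{i}" for i in range(1, 20))
SOIL_VARIABLES = (
    "bdod", "cec", "cfvo", "clay", "nitrogen", "ocd", "ocs",
    "sand", "silt", "soc", "wv0010", "wv0033", "wv1500",
)
TOPO_VARIABLES = (
    "aspectcosine", "aspectsine", "dx", "dxx", "dy", "dyy", "eastness",
    "elevation", "northness", "pcurv", "roughness", "slope", "tcurv",
    "tpi", "tri", "vrm",
)
ENV_VARIABLES: tuple[str, ...] = CLIMATE_VARIABLES + SOIL_VARIABLES + TOPO_VARIABLES
assert len(ENV_VARIABLES) == 48


@dataclass
class RasterGrid:
    """Single-band geographic grid, row 0 = northernmost row."""

    name: str
    x_origin: float  # west (lower-left) corner longitude
    y_origin: float  # south (lower-left) corner latitude
    cell_size: float  # degrees
    nodata: float
    values: np.ndarray  # shape (n_rows, n_cols), row-major, top row first

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridError("grid values must be 2-D (single band)")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside.

        Half-open convention: a point on a vertical shared edge belongs to
        the cell east of it, on a horizontal edge to the cell south of it.
        """
        col = int(np.floor((lon - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_max - lat) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def value_at(self, lon: float, lat: float) -> float:
        """Cell value at the point; NaN for outside-extent or nodata cells."""
        idx = self.cell_index(lon, lat)
        if idx is None:
            return float("nan")
        v = self.values[idx]
        return float("nan") if v == self.nodata else float(v)


def read_ascii_grid(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "xllcenter", "yllcenter", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(tok) for tok in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridError(f"{path.name}: missing required header {req!r}")
    cs = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cs / 2
    else:
        raise GridError(f"{path.name}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y0 = header["yllcorner"]
    elif "yllcenter" in header:
        y0 = header["yllcenter"] - cs / 2
    else:
        raise GridError(f"{path.name}: missing yllcorner/yllcenter")
    values = np.array([v for r in rows for v in r], dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise GridError(
            f"{path.name}: expected {nrows * ncols} values, found {values.size}"
        )
    return RasterGrid(
        name=name or path.stem,
        x_origin=x0,
        y_origin=y0,
        cell_size=cs,
        nodata=header.get("nodata_value", -9999.0),
        values=values.reshape(nrows, ncols),
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {grid.nodata!r}\n")
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_geotiff(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF using its geo-referencing tags."""
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=float)
        if data.ndim != 2:
            raise GridError(f"{path.name}: multi-band rasters not supported")
        tags = {t.name: t.value for t in page.tags.values()}
        scale = tags.get("ModelPixelScaleTag")
        tie = tags.get("ModelTiepointTag")
        if scale is None or tie is None:
            raise GridError(f"{path.name}: not a geo-referenced TIFF")
        sx, sy = float(scale[0]), float(scale[1])
        if abs(sx - sy) > 1e-9:
            raise GridError(f"{path.name}: anisotropic cells not supported")
        # tiepoint maps raster (i, j) -> world (x, y); standard is (0, 0) at
        # the upper-left corner
        x_ul, y_ul = float(tie[3]), float(tie[4])
        nodata = tags.get("GDAL_NODATA")
        nodata = float(nodata) if nodata is not None else -9999.0
    return RasterGrid(
        name=name or path.stem,
        x_origin=x_ul,
        y_origin=y_ul - data.shape[0] * sy,
        cell_size=sx,
        nodata=nodata,
        values=data,
    )


def read_grid(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read a grid, dispatching on extension (.asc/.txt or .tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt", ".grd"}:
        return read_ascii_grid(path, name)
    if suffix in {".tif", ".tiff"}:
        return read_geotiff(path, name)
    raise GridError(f"unrecognised grid format: {path.name}")


def _check_aligned(stack: Sequence[RasterGrid]) -> None:
    ref = stack[0]
    for g in stack[1:]:
        same = (
            np.isclose(g.x_origin, ref.x_origin)
            and np.isclose(g.y_origin, ref.y_origin)
            and np.isclose(g.cell_size, ref.cell_size)
            and g.values.shape == ref.values.shape
        )
        if not same:
            raise GridError(
                f"grid {g.name!r} not aligned with {ref.name!r} "
                "(extent/resolution mismatch)"
            )


def extract_at_points(
    stack: Sequence[RasterGrid],
    points: Iterable[tuple[float, float]],
    point_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Containing-cell values of every grid at every (lon, lat) point.

    Points outside the common extent, or falling on nodata cells, yield NaN
    with a warning; extraction never fails on individual points.
    """
    stack = list(stack)
    if not stack:
        raise GridError("empty grid stack")
    _check_aligned(stack)
    pts = [(float(lon), float(lat)) for lon, lat in points]
    for lon, lat in pts:
        if not (np.isfinite(lon) and np.isfinite(lat)):
            raise ValueError("non-finite point coordinates")
    out = {}
    for g in stack:
        col = []
        for lon, lat in pts:
            v = g.value_at(lon, lat)
            if np.isnan(v):
                logger.warning(
                    "point (%g, %g) outside extent or nodata in layer %r",
                    lon, lat, g.name,
                )
            col.append(v)
        out[g.name] = col
    index = list(point_ids) if point_ids is not None else None
    return pd.DataFrame(out, index=index)


def crop_stack(
    stack: Sequence[RasterGrid],
    extent: tuple[float, float, float, float],
) -> list[RasterGrid]:
    """Crop every grid to the minimal cell-aligned window covering ``extent``.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max). Extraction results
    for in-extent points are unchanged. Empty intersection raises GridError.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_min > lon_max or lat_min > lat_max:
        raise GridError("malformed extent")
    stack = list(stack)
    _check_aligned(stack)
    ref = stack[0]
    cs = ref.cell_size
    c0 = int(np.floor((lon_min - ref.x_origin) / cs))
    c1 = int(np.ceil((lon_max - ref.x_origin) / cs))
    r0 = int(np.floor((ref.y_max - lat_max) / cs))
    r1 = int(np.ceil((ref.y_max - lat_min) / cs))
    c0, c1 = max(c0, 0), min(c1, ref.n_cols)
    r0, r1 = max(r0, 0), min(r1, ref.n_rows)
    if c0 >= c1 or r0 >= r1:
        raise GridError("extent does not intersect the grid stack")
    out = []
    for g in stack:
        out.append(
            replace(
                g,
                values=g.values[r0:r1, c0:c1].copy(),
                x_origin=g.x_origin + c0 * cs,
                y_origin=g.y_max - r1 * cs,
            )
        )
    return out


def read_env_table(path: str | Path, *, delimiter: str | None = None) -> pd.DataFrame:
    """Read a pre-extracted environment table keyed by population_id.

    Expected columns: species, population_id, lon, lat plus predictors.
    """
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    df = pd.read_csv(path, sep=sep)
    if "population_id" not in df.columns:
        raise GridError(f"{path.name}: missing 'population_id' column")
    return df
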
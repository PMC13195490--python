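"""Single-band float32 GeoTIFF readers/writers and monthly raster stacks.

All gridded data in the pipeline travels as north-up, square-cell,
single-band float32 GeoTIFFs, one file per variable per month with the
month (``YYYY-MM``) carried in the filename.  Nodata cells are stored as an
explicit sentinel and surface in memory as numpy masked arrays; every
arithmetic stage propagates the mask (any nodata input -> nodata output).

Georeferencing is written/read through the standard GeoTIFF tags
(ModelPixelScale 33550, ModelTiepoint 33922, GeoKeyDirectory 34735) plus
the GDAL nodata tag 42113.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridMeta:
    """Georeferencing shared by every raster in a run.

    ``origin_x``/``origin_y`` are the projected coordinates of the outer
    corner of the upper-left cell; rows increase southward.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    crs_id: str = "EPSG:32649"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def same_grid(self, other: "GridMeta") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.crs_id == other.crs_id
        )


_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


def parse_month(label: str) -> tuple[int, int]:
    m = _MONTH_RE.match(label)
    if not m:
        raise ValueError(f"month label {label!r} is not YYYY-MM")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month label {label!r} has month outside 1..12")
    return year, month


def month_range(start: str, end: str) -> list[str]:
    """Inclusive, contiguous list of YYYY-MM labels."""
    y0, m0 = parse_month(start)
    y1, m1 = parse_month(end)
    if (y1, m1) < (y0, m0):
        raise ValueError(f"month range {start}..{end} is empty")
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return out


@dataclass
class MonthlyRasterStack:
    """Co-registered per-month grids of one variable.

    ``data`` is a (n_months, n_rows, n_cols) masked float array; ``months``
    holds the YYYY-MM labels, in order.
    """

    data: np.ma.MaskedArray
    months: list[str]
    meta: GridMeta

    def __post_init__(self) -> None:
        self.data = np.ma.masked_invalid(np.ma.asarray(self.data, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (month, row, col)")
        if self.data.shape[0] != len(self.months):
            raise ValueError("number of layers does not match number of months")
        if self.data.shape[1:] != self.meta.shape:
            raise ValueError("layer shape does not match GridMeta")

    def layer(self, month: str) -> np.ma.MaskedArray:
        try:
            i = self.months.index(month)
        except ValueError:
            raise KeyError(f"month {month} not in stack") from None
        return self.data[i]

    def annual_max(self) -> dict[int, np.ma.MaskedArray]:
        """Per-year maximum composite (e.g. annual-max NDVI)."""
        out: dict[int, np.ma.MaskedArray] = {}
        years = sorted({parse_month(m)[0] for m in self.months})
        for y in years:
            idx = [i for i, m in enumerate(self.months) if parse_month(m)[0] == y]
            out[y] = self.data[idx].max(axis=0)
        return out

    def subset(self, months: list[str]) -> "MonthlyRasterStack":
        idx = [self.months.index(m) for m in months]
        return MonthlyRasterStack(self.data[idx], list(months), self.meta)


def _geokey_directory(crs_id: str) -> tuple[int, ...]:
    code = 32649
    m = re.match(r"EPSG:(\d+)$", crs_id)
    if m:
        code = int(m.group(1))
    # header (version, rev, minor, nkeys) then GTModelType, GTRasterType,
    # ProjectedCSType
    return (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, code)


def write_raster(grid, meta: GridMeta, path: str) -> None:
    """Write a 2-D grid as a single-band float32 GeoTIFF.

    Masked (or NaN) cells are stored as ``meta.nodata``.
    """
    arr = np.ma.masked_invalid(np.ma.asarray(grid, dtype=float))
    if arr.shape != meta.shape:
        raise ValueError(
            f"grid shape {arr.shape} does not match GridMeta shape {meta.shape}"
        )
    filled = arr.filled(meta.nodata).astype(np.float32)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(meta.cell_size), float(meta.cell_size), 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(meta.origin_x), float(meta.origin_y), 0.0),
        ),
        (_TAG_GEOKEYS, "H", 16, _geokey_directory(meta.crs_id)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(meta.nodata))),
    ]
    try:
        tifffile.imwrite(path, filled, photometric="minisblack", extratags=extratags)
    except OSError as exc:
        raise OSError(f"cannot write raster to {path!r}: {exc}") from exc


def read_raster(path: str) -> tuple[np.ma.MaskedArray, GridMeta]:
    """Read a single-band float GeoTIFF written by :func:`write_raster`."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            arr = page.asarray().astype(float)
            tags = page.tags
            nodata = DEFAULT_NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            cell = 1.0
            if _TAG_PIXEL_SCALE in tags:
                cell = float(tags[_TAG_PIXEL_SCALE].value[0])
            ox = oy = 0.0
            if _TAG_TIEPOINT in tags:
                tp = tags[_TAG_TIEPOINT].value
                ox, oy = float(tp[3]), float(tp[4])
            crs = "EPSG:32649"
            if _TAG_GEOKEYS in tags:
                kd = tags[_TAG_GEOKEYS].value
                for i in range(4, len(kd), 4):
                    if kd[i] == 3072:
                        crs = f"EPSG:{kd[i + 3]}"
    except OSError as exc:
        raise OSError(f"cannot read raster from {path!r}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path!r} is not a single-band raster")
    meta = GridMeta(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        cell_size=cell,
        origin_x=ox,
        origin_y=oy,
        crs_id=crs,
        nodata=nodata,
    )
    masked = np.ma.masked_invalid(np.ma.masked_values(arr, nodata, rtol=0, atol=0))
    return masked, meta


def read_raster_stack(path_pattern: str, months: list[str]) -> MonthlyRasterStack:
    """Assemble a monthly stack from one GeoTIFF per month.

    ``path_pattern`` must contain a ``{month}`` placeholder which is filled
    with each YYYY-MM label.  All files must share bit-identical
    georeferencing; the first file's meta is adopted.
    """
    if "{month}" not in path_pattern:
        raise ValueError("path_pattern must contain a {month} placeholder")
    layers, meta, first_path = [], None, None
    for label in months:
        parse_month(label)
        path = path_pattern.format(month=label)
        if not os.path.exists(path):
            candidates = _glob.glob(path_pattern.format(month="*"))
            raise FileNotFoundError(
                f"missing month {label}: no file at {path!r} "
                f"({len(candidates)} sibling files present)"
            )
        arr, m = read_raster(path)
        if meta is None:
            meta, first_path = m, path
        elif not meta.same_grid(m):
            raise ValueError(
                f"grid mismatch between {first_path!r} and {path!r}: "
                f"{meta.shape}@{meta.cell_size} vs {m.shape}@{m.cell_size}"
            )
        layers.append(arr)
    assert meta is not None
    stack = MonthlyRasterStack(np.ma.stack(layers), list(months), meta)
    n_nodata = int(stack.data.mask.sum()) if stack.data.mask is not np.ma.nomask else 0
    log.info(
        "read stack %s: %d months, grid %dx%d, %d nodata cells",
        path_pattern, len(months), meta.n_rows, meta.n_cols, n_nodata,
    )
    return stack


def write_raster_stack(stack: MonthlyRasterStack, path_pattern: str) -> list[str]:
    if "{month}" not in path_pattern:
        raise ValueError("path_pattern must contain a {month} placeholder")
    paths = []
    for i, label in enumerate(stack.months):
        path = path_pattern.format(month=label)
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        write_raster(stack.data[i], stack.meta, path)
        paths.append(path)
    return paths


def aligned(*grids) -> None:
    """Raise unless all grids share one shape (mask-aware arithmetic helper)."""
    shapes = {np.ma.asarray(g).shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"grid mismatch: shapes {sorted(shapes)}")
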
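"""Raster file I/O and radiometric pre-processing.

Two on-disk formats are supported:

* **GeoTIFF** (primary), read and written through :mod:`tifffile`. The
  nodata sentinel is stored in the ``GDAL_NODATA`` tag, the geotransform
  in ``ModelTransformationTag`` (written) / ``ModelPixelScale`` +
  ``ModelTiepoint`` (also understood on read), and the CRS string in a
  small JSON payload inside ``ImageDescription``. Multi-band grids are
  written one band per page.
* **ESRI ASCII grid** (``.asc``), a plain-text single-band fallback that
  is convenient for fixtures; it can only represent north-up grids with
  square cells.

The pre-processing operations implement NDVI from a red/NIR band pair
and linear rescaling to 8-bit radiometric resolution (256 integer
classes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .exceptions import (
    BandOutOfRangeError,
    ParameterError,
    RasterIOError,
    ShapeMismatchError,
)
from .grid import GeoTransform, RasterGrid, _invalid

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GDAL_NODATA = 42113

#: nodata sentinel used for 8-bit rescaled outputs (int16 data).
EIGHT_BIT_NODATA = -1


@dataclass(frozen=True)
class BandPair:
    """Aligned red and near-infrared reflectance grids."""

    red: RasterGrid
    nir: RasterGrid

    def __post_init__(self) -> None:
        if self.red.shape != self.nir.shape:
            raise ShapeMismatchError(
                f"red {self.red.shape} and nir {self.nir.shape} differ in shape"
            )


# ---------------------------------------------------------------------------
# reading / writing


def read_raster(path: Union[str, Path], band: Optional[int] = None) -> RasterGrid:
    """Read a GeoTIFF or ESRI ASCII grid.

    ``band`` selects a single band (1-based); ``None`` returns all bands
    (a stack if the file has more than one).
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such file: {path}")
    if path.suffix.lower() == ".asc":
        grid = _read_ascii_grid(path)
        if band is not None and band != 1:
            raise BandOutOfRangeError(
                f"band {band} requested but ASCII grid has 1 band"
            )
        return grid
    return _read_tiff(path, band)


def write_raster(
    raster: RasterGrid,
    path: Union[str, Path],
    nodata: Optional[float] = None,
) -> None:
    """Write a grid (or heterogeneity map) to GeoTIFF or ``.asc``.

    ``nodata`` overrides the grid's own sentinel in the file's nodata
    tag. A warning is emitted if the declared sentinel also occurs as a
    valid data value.
    """
    path = Path(path)
    sentinel = raster.nodata if nodata is None else nodata
    _warn_on_nodata_collision(raster, sentinel)
    try:
        if path.suffix.lower() == ".asc":
            _write_ascii_grid(raster, path, sentinel)
        else:
            _write_tiff(raster, path, sentinel)
    except OSError as exc:
        raise RasterIOError(f"cannot write {path}: {exc}") from exc


def _warn_on_nodata_collision(raster: RasterGrid, sentinel: Optional[float]) -> None:
    if sentinel is None or (isinstance(sentinel, float) and np.isnan(sentinel)):
        return
    valid = raster.data[~_invalid(raster.data, raster.nodata)]
    if valid.size and np.any(valid == sentinel):
        warnings.warn(
            f"nodata sentinel {sentinel!r} also occurs as a valid data value",
            UserWarning,
            stacklevel=3,
        )


def _read_tiff(path: Path, band: Optional[int]) -> RasterGrid:
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            page = tif.pages[0]
            nodata = _parse_gdal_nodata(page)
            transform = _parse_geotransform(page)
            crs = _parse_crs(page)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise RasterIOError(f"unreadable raster {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    elif data.ndim != 3:
        raise RasterIOError(f"unsupported TIFF layout with shape {data.shape}")
    n_bands = data.shape[0]
    if band is not None:
        if not (1 <= band <= n_bands):
            raise BandOutOfRangeError(
                f"band {band} requested but file has {n_bands} band(s)"
            )
        data = data[band - 1]
    elif n_bands == 1:
        data = data[0]
    return RasterGrid(data=data, nodata=nodata, transform=transform, crs=crs)


def _write_tiff(raster: RasterGrid, path: Path, sentinel: Optional[float]) -> None:
    extratags = []
    if sentinel is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(sentinel), True))
    if raster.transform is not None:
        x0, pw, rr, y0, cr, ph = raster.transform
        matrix = (
            pw, rr, 0.0, x0,
            cr, ph, 0.0, y0,
            0.0, 0.0, 0.0, 0.0,
            0.0, 0.0, 0.0, 1.0,
        )
        extratags.append((_TAG_MODEL_TRANSFORMATION, "d", 16, matrix, True))
    description = json.dumps({"crs": raster.crs}) if raster.crs else None
    data = raster.data if raster.is_stack else raster.data[None, :, :]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=description,
        extratags=extratags,
        metadata=None,
    )


def _parse_gdal_nodata(page) -> Optional[float]:
    tag = page.tags.get(_TAG_GDAL_NODATA)
    if tag is None:
        return None
    try:
        value = float(str(tag.value).strip().split()[0])
    except (ValueError, IndexError):
        return None
    if np.issubdtype(page.dtype, np.integer):
        return int(value)
    return value


def _parse_geotransform(page) -> Optional[GeoTransform]:
    tag = page.tags.get(_TAG_MODEL_TRANSFORMATION)
    if tag is not None:
        m = np.asarray(tag.value, dtype=float).reshape(4, 4)
        return (m[0, 3], m[0, 0], m[0, 1], m[1, 3], m[1, 0], m[1, 1])
    scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie = page.tags.get(_TAG_MODEL_TIEPOINT)
    if scale is not None and tie is not None:
        sx, sy = float(scale.value[0]), float(scale.value[1])
        i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
        return (x - i * sx, sx, 0.0, y + j * sy, 0.0, -sy)
    return None


def _parse_crs(page) -> Optional[str]:
    desc = page.tags.get(270)  # ImageDescription
    if desc is None:
        return None
    try:
        payload = json.loads(desc.value)
    except (json.JSONDecodeError, TypeError):
        return None
    if isinstance(payload, dict):
        crs = payload.get("crs")
        return str(crs) if crs is not None else None
    return None


def _read_ascii_grid(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cellsize = header["cellsize"]
    except KeyError as exc:
        raise RasterIOError(f"{path}: missing ASCII grid header field {exc}") from exc
    data = np.asarray([v for row in rows for v in row], dtype=np.float64)
    if data.size != nrows * ncols:
        raise RasterIOError(
            f"{path}: expected {nrows * ncols} cells, found {data.size}"
        )
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    transform = (xll, cellsize, 0.0, yll + nrows * cellsize, 0.0, -cellsize)
    return RasterGrid(data=data, nodata=nodata, transform=transform, crs=None)


def _write_ascii_grid(raster: RasterGrid, path: Path, sentinel: Optional[float]) -> None:
    if raster.is_stack:
        raise RasterIOError("ASCII grid cannot hold a multi-layer stack")
    nrows, ncols = raster.shape
    if raster.transform is not None:
        x0, pw, rr, y0, cr, ph = raster.transform
        if rr or cr or abs(pw + ph) > 1e-12:
            raise RasterIOError(
                "ASCII grid supports only north-up grids with square cells"
            )
        cellsize, xll, yll = pw, x0, y0 + nrows * ph
    else:
        cellsize, xll, yll = 1.0, 0.0, 0.0
    if sentinel is None or (isinstance(sentinel, float) and np.isnan(sentinel)):
        sentinel = -9999.0
    data = np.asarray(raster.data, dtype=np.float64).copy()
    data[_invalid(raster.data, raster.nodata)] = sentinel
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(sentinel)!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# pre-processing


def compute_ndvi(bands: BandPair) -> RasterGrid:
    """Normalized difference vegetation index (nir - red) / (nir + red).

    Cells where either band is nodata, or where nir + red == 0 (no
    reflectance information), come out as nodata (NaN).
    """
    red = np.asarray(bands.red.data, dtype=np.float64)
    nir = np.asarray(bands.nir.data, dtype=np.float64)
    bad = _invalid(bands.red.data, bands.red.nodata)
    bad |= _invalid(bands.nir.data, bands.nir.nodata)
    denom = nir + red
    bad |= denom == 0
    out = np.full(red.shape, np.nan, dtype=np.float64)
    good = ~bad
    out[good] = (nir[good] - red[good]) / denom[good]
    return bands.red.with_data(out, nodata=np.nan)


def rescale_to_8bit(
    raster: RasterGrid,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
) -> RasterGrid:
    """Linearly rescale a grid to 8-bit radiometric resolution (0..255).

    With ``lo``/``hi`` both ``None`` the observed min/max of the valid
    cells are used; otherwise the fixed range [lo, hi) is mapped onto
    [0, 255]. Values are rounded half-away-from-zero and clipped. The
    degenerate constant-input case under observed min/max maps to 0.

    Returns an int16 grid with nodata :data:`EIGHT_BIT_NODATA` (-1).
    """
    if (lo is None) != (hi is None):
        raise ParameterError("lo and hi must be given together")
    data = np.asarray(raster.data, dtype=np.float64)
    bad = _invalid(raster.data, raster.nodata)
    valid = data[~bad]
    if valid.size == 0:
        raise ParameterError("cannot rescale an all-nodata raster")
    if lo is None:
        lo, hi = float(valid.min()), float(valid.max())
        if lo == hi:  # degenerate constant input
            out = np.zeros(data.shape, dtype=np.int16)
            out[bad] = EIGHT_BIT_NODATA
            return raster.with_data(out, nodata=EIGHT_BIT_NODATA)
    lo, hi = float(lo), float(hi)
    if lo >= hi:
        raise ParameterError(f"need lo < hi, got lo={lo}, hi={hi}")
    scaled = (data - lo) / (hi - lo) * 255.0
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)  # half away from zero
    clipped = np.clip(rounded, 0, 255)
    clipped[bad] = 0.0  # placeholder; overwritten with the sentinel below
    out = clipped.astype(np.int16)
    out[bad] = EIGHT_BIT_NODATA
    return raster.with_data(out, nodata=EIGHT_BIT_NODATA)
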
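"""Raster grid container shared by all modules.

A :class:`RasterGrid` is a thin wrapper around a 2-D numpy array (single
layer) or a 3-D ``(layers, rows, cols)`` stack, together with a nodata
sentinel and optional georeferencing (a GDAL-style 6-element geotransform
plus a CRS string) that is carried through computations unchanged.

NaN cells are always treated as nodata, in addition to the explicit
sentinel if one is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ShapeMismatchError

#: GDAL-style geotransform: (x0, px_w, row_rot, y0, col_rot, px_h).
GeoTransform = tuple[float, float, float, float, float, float]


@dataclass(frozen=True)
class RasterGrid:
    """A numeric grid with a nodata sentinel and optional geo metadata.

    Parameters
    ----------
    data
        ``(rows, cols)`` array for a single layer, or ``(layers, rows,
        cols)`` for an aligned stack. Stored as given (no copy).
    nodata
        Sentinel value marking invalid cells, or ``None``. NaNs are
        treated as invalid regardless.
    transform
        Optional GDAL-style geotransform, passed through untouched.
    crs
        Optional CRS identifier string (e.g. ``"EPSG:32632"``).
    """

    data: np.ndarray
    nodata: Optional[float] = None
    transform: Optional[GeoTransform] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim not in (2, 3):
            raise ShapeMismatchError(
                f"raster data must be 2-D or 3-D, got {arr.ndim}-D"
            )
        if arr.shape[-1] < 1 or arr.shape[-2] < 1:
            raise ShapeMismatchError(f"empty raster shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        if self.transform is not None:
            t = tuple(float(v) for v in self.transform)
            if len(t) != 6:
                raise ValueError("geotransform must have 6 elements")
            object.__setattr__(self, "transform", t)

    # -- geometry ---------------------------------------------------------

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 3

    @property
    def n_layers(self) -> int:
        return self.data.shape[0] if self.is_stack else 1

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols), regardless of layer count."""
        return self.data.shape[-2:]

    # -- validity ---------------------------------------------------------

    def valid_mask(self) -> np.ndarray:
        """Boolean (rows, cols) mask; for stacks, a cell is valid only if
        valid in every layer."""
        arr = self.data
        mask = ~_invalid(arr, self.nodata)
        if self.is_stack:
            mask = mask.all(axis=0)
        return mask

    def layers(self) -> list["RasterGrid"]:
        """Split a stack into single-layer grids (shares memory)."""
        if not self.is_stack:
            return [self]
        return [replace(self, data=self.data[i]) for i in range(self.n_layers)]

    def with_data(self, data: np.ndarray, nodata: Optional[float] = None) -> "RasterGrid":
        """New grid with the same geo metadata but different data/nodata."""
        return RasterGrid(data=data, nodata=nodata, transform=self.transform, crs=self.crs)


def _invalid(arr: np.ndarray, nodata: Optional[float]) -> np.ndarray:
    bad = np.zeros(arr.shape, dtype=bool)
    if np.issubdtype(arr.dtype, np.floating):
        bad |= np.isnan(arr)
    if nodata is not None and not (isinstance(nodata, float) and np.isnan(nodata)):
        bad |= arr == nodata
    return bad


def stack(layers: Sequence[RasterGrid]) -> RasterGrid:
    """Stack aligned single-layer grids into one multi-layer grid.

    All layers must share shape; geo metadata is taken from the first.
    Data is promoted to float64 and each layer's nodata is rewritten to
    NaN so the stack has uniform nodata semantics.
    """
    if not layers:
        raise ValueError("need at least one layer")
    shp = layers[0].shape
    for g in layers:
        if g.is_stack:
            raise ShapeMismatchError("stack() expects single-layer grids")
        if g.shape != shp:
            raise ShapeMismatchError(
                f"layer shapes differ: {g.shape} vs {shp}"
            )
    data = np.empty((len(layers),) + shp, dtype=np.float64)
    for i, g in enumerate(layers):
        layer = np.asarray(g.data, dtype=np.float64).copy()
        layer[_invalid(g.data, g.nodata)] = np.nan
        data[i] = layer
    first = layers[0]
    return RasterGrid(data=data, nodata=np.nan, transform=first.transform, crs=first.crs)
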
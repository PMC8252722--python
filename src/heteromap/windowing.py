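"""Moving-window (focal) engine.

Slides an odd-sided square window over a raster, evaluates an index on
the valid values under each placement and writes the result at the focal
position. Edge windows are clipped: out-of-bounds positions simply do
not contribute, so the output has the full input extent. A focal cell
that is itself nodata yields nodata in the output.

The traversal order has no effect on the result (the engine is purely
sequential and each cell is independent); ``traversal`` exists so the
determinism contract can be exercised in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from . import indices as _ix
from .exceptions import ParameterError
from .grid import RasterGrid, _invalid

#: Output nodata sentinel for heterogeneity maps.
MAP_NODATA = np.nan

INDEX_NAMES = ("shannon", "renyi", "hill", "simpson", "rao")


@dataclass(frozen=True)
class WindowSpec:
    """Square moving window of odd edge length ``side`` (pixels)."""

    side: int

    def __post_init__(self) -> None:
        if self.side < 1 or self.side % 2 == 0:
            raise ParameterError(
                f"window side must be an odd integer >= 1, got {self.side}"
            )

    @property
    def center_offset(self) -> int:
        """1-based offset of the central entry: (side + 1) / 2."""
        return (self.side + 1) // 2

    @property
    def radius(self) -> int:
        return self.side // 2


def extract_window(
    raster: RasterGrid, spec: WindowSpec, row: int, col: int
) -> np.ndarray:
    """Valid values in the ``side x side`` neighborhood centered at
    (row, col), 0-based.

    Returns a 1-D array for a single layer, or an ``(n_valid, n_layers)``
    array for a stack (a pixel counts only if valid in every layer).
    Out-of-bounds positions are absent, nodata cells excluded.
    """
    rows, cols = raster.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"focal position ({row}, {col}) outside {rows}x{cols} raster")
    r = spec.radius
    r0, r1 = max(0, row - r), min(rows, row + r + 1)
    c0, c1 = max(0, col - r), min(cols, col + r + 1)
    if raster.is_stack:
        block = raster.data[:, r0:r1, c0:c1]
        valid = ~_invalid(block, raster.nodata).any(axis=0)
        return block[:, valid].T  # (n_valid, n_layers)
    block = raster.data[r0:r1, c0:c1]
    valid = ~_invalid(block, raster.nodata)
    return block[valid]


def _resolve_index(
    name: str,
    *,
    alpha: Optional[float] = None,
    q: Optional[float] = None,
    metric: Optional[str] = None,
    is_stack: bool = False,
) -> Callable[[np.ndarray], float]:
    """Map an index name + parameters to a per-sample callable."""
    if name == "shannon":
        return lambda s: _ix.shannon(_ix.relative_abundances(s))
    if name == "renyi":
        a = 1.0 if alpha is None else float(alpha)
        if a < 0:
            raise ParameterError(f"alpha must be >= 0, got {a}")
        return lambda s: _ix.renyi(_ix.relative_abundances(s), a)
    if name == "hill":
        qq = 0.0 if q is None else float(q)
        if qq < 0:
            raise ParameterError(f"q must be >= 0, got {qq}")
        return lambda s: _ix.hill(_ix.relative_abundances(s), qq)
    if name == "simpson":
        return lambda s: _ix.simpson_dominance(_ix.relative_abundances(s))
    if name == "rao":
        m = metric or ("euclidean" if is_stack else "absolute-difference")
        if is_stack:
            return lambda s: _ix.rao_q_multilayer(list(s.T), m)
        return lambda s: _ix.rao_q_from_sample(s, m)
    raise ParameterError(
        f"unknown index {name!r}; choose from {INDEX_NAMES}"
    )


def apply_moving_window(
    raster: RasterGrid,
    spec: WindowSpec,
    index: str,
    *,
    alpha: Optional[float] = None,
    q: Optional[float] = None,
    metric: Optional[str] = None,
    traversal: str = "row-major",
) -> RasterGrid:
    """Evaluate ``index`` under every window placement.

    Returns a float64 map of the input's full extent with
    :data:`MAP_NODATA` (NaN) where the focal cell is nodata. Geo
    metadata is passed through unchanged.
    """
    fn = _resolve_index(
        index, alpha=alpha, q=q, metric=metric, is_stack=raster.is_stack
    )
    rows, cols = raster.shape
    out = np.full((rows, cols), MAP_NODATA, dtype=np.float64)
    focal_valid = raster.valid_mask()
    for row, col in _traverse(rows, cols, traversal):
        if not focal_valid[row, col]:
            continue
        sample = extract_window(raster, spec, row, col)
        out[row, col] = fn(sample)
    return raster.with_data(out, nodata=MAP_NODATA)


def renyi_profile(
    raster: RasterGrid,
    spec: WindowSpec,
    alphas: Sequence[float],
    *,
    traversal: str = "row-major",
) -> list[RasterGrid]:
    """One Renyi map per alpha, extracting each window only once.

    Each returned map is identical to ``apply_moving_window(...,
    "renyi", alpha=a)``; sharing window extraction across alphas is a
    performance contract, not a semantic one.
    """
    alphas = [float(a) for a in alphas]
    if not alphas:
        raise ParameterError("alphas must be non-empty")
    for a in alphas:
        if a < 0:
            raise ParameterError(f"alpha must be >= 0, got {a}")
    rows, cols = raster.shape
    outs = [np.full((rows, cols), MAP_NODATA, dtype=np.float64) for _ in alphas]
    focal_valid = raster.valid_mask()
    for row, col in _traverse(rows, cols, traversal):
        if not focal_valid[row, col]:
            continue
        dist = _ix.relative_abundances(extract_window(raster, spec, row, col))
        for k, a in enumerate(alphas):
            outs[k][row, col] = _ix.renyi(dist, a)
    return [raster.with_data(o, nodata=MAP_NODATA) for o in outs]


def _traverse(rows: int, cols: int, traversal: str) -> Iterable[tuple[int, int]]:
    if traversal == "row-major":
        return ((r, c) for r in range(rows) for c in range(cols))
    if traversal == "col-major":
        return ((r, c) for c in range(cols) for r in range(rows))
    raise ParameterError(f"unknown traversal {traversal!r}")
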
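"""Deterministic synthetic raster fixtures.

Seeded generators emulating 8-bit landscape imagery, so every index and
the full NDVI pipeline can be exercised without external downloads.
Generation is a pure function of the :class:`FixtureSpec`: the same spec
always yields a bit-identical grid. Random kinds use
``numpy.random.default_rng`` (PCG64) seeded from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .exceptions import ParameterError
from .grid import RasterGrid
from .raster_io import BandPair

KINDS = (
    "constant",
    "checkerboard",
    "gradient",
    "random-categorical",
    "fractal-surface",
)

#: sentinel used for masked cells in generated integer-valued fixtures
FIXTURE_NODATA = -9999.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic raster.

    ``params`` are kind-specific:

    - ``constant``: ``value``
    - ``checkerboard``: ``low``, ``high``, ``tile``
    - ``gradient``: ``start``, ``stop``, ``axis`` (0 = down rows, 1 = across cols)
    - ``random-categorical``: ``n_classes``
    - ``fractal-surface``: ``roughness`` in (0, 1]

    ``nodata_fraction`` masks that fraction of cells (seeded, so
    deterministic too).
    """

    kind: str
    rows: int
    cols: int
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    nodata_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.rows < 1 or self.cols < 1:
            raise ParameterError(f"invalid fixture size {self.rows}x{self.cols}")
        if not (0.0 <= self.nodata_fraction < 1.0):
            raise ParameterError("nodata_fraction must be in [0, 1)")


def generate(spec: FixtureSpec) -> RasterGrid:
    """Materialize a fixture spec into a grid (deterministic)."""
    builder = {
        "constant": _constant,
        "checkerboard": _checkerboard,
        "gradient": _gradient,
        "random-categorical": _random_categorical,
        "fractal-surface": _fractal_surface,
    }[spec.kind]
    data = builder(spec)
    nodata: Optional[float] = None
    if spec.nodata_fraction > 0:
        data = data.astype(np.float64)
        # separate stream from the value generator so masking a fixture
        # does not change the values of the unmasked cells
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xDA7A]))
        mask = rng.random(data.shape) < spec.nodata_fraction
        data[mask] = FIXTURE_NODATA
        nodata = FIXTURE_NODATA
    return RasterGrid(data=data, nodata=nodata)


def _constant(spec: FixtureSpec) -> np.ndarray:
    value = spec.params.get("value", 0)
    return np.full((spec.rows, spec.cols), value, dtype=np.float64)


def _checkerboard(spec: FixtureSpec) -> np.ndarray:
    low = spec.params.get("low", 0)
    high = spec.params.get("high", 255)
    tile = int(spec.params.get("tile", 1))
    if tile < 1:
        raise ParameterError(f"tile size must be >= 1, got {tile}")
    r = np.arange(spec.rows)[:, None] // tile
    c = np.arange(spec.cols)[None, :] // tile
    board = (r + c) % 2
    return np.where(board == 0, low, high).astype(np.float64)


def _gradient(spec: FixtureSpec) -> np.ndarray:
    start = float(spec.params.get("start", 0.0))
    stop = float(spec.params.get("stop", 255.0))
    axis = int(spec.params.get("axis", 1))
    if axis not in (0, 1):
        raise ParameterError("gradient axis must be 0 (rows) or 1 (cols)")
    n = spec.rows if axis == 0 else spec.cols
    ramp = np.linspace(start, stop, n) if n > 1 else np.array([start])
    if axis == 0:
        return np.repeat(ramp[:, None], spec.cols, axis=1)
    return np.repeat(ramp[None, :], spec.rows, axis=0)


def _random_categorical(spec: FixtureSpec) -> np.ndarray:
    k = int(spec.params.get("n_classes", 8))
    if k < 1:
        raise ParameterError(f"n_classes must be >= 1, got {k}")
    rng = np.random.default_rng(spec.seed)
    return rng.integers(0, k, size=(spec.rows, spec.cols)).astype(np.float64)


def _fractal_surface(spec: FixtureSpec) -> np.ndarray:
    """Midpoint-displacement (diamond-square) surface, rescaled to 0..255.

    Chosen only as a heterogeneity-rich fixture; no claim of ecological
    realism.
    """
    roughness = float(spec.params.get("roughness", 0.6))
    if not (0.0 < roughness <= 1.0):
        raise ParameterError(f"roughness must be in (0, 1], got {roughness}")
    n = 1
    while 2**n + 1 < max(spec.rows, spec.cols):
        n += 1
    size = 2**n + 1
    rng = np.random.default_rng(spec.seed)
    grid = np.zeros((size, size), dtype=np.float64)
    grid[0, 0], grid[0, -1], grid[-1, 0], grid[-1, -1] = rng.random(4)
    step, amp = size - 1, 1.0
    while step > 1:
        half = step // 2
        # diamond step
        for r in range(half, size, step):
            for c in range(half, size, step):
                avg = (
                    grid[r - half, c - half] + grid[r - half, c + half]
                    + grid[r + half, c - half] + grid[r + half, c + half]
                ) / 4.0
                grid[r, c] = avg + amp * (rng.random() - 0.5)
        # square step
        for r in range(0, size, half):
            start = half if (r // half) % 2 == 0 else 0
            for c in range(start, size, step):
                acc, cnt = 0.0, 0
                for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < size and 0 <= cc < size:
                        acc += grid[rr, cc]
                        cnt += 1
                grid[r, c] = acc / cnt + amp * (rng.random() - 0.5)
        step = half
        amp *= roughness
    crop = grid[: spec.rows, : spec.cols]
    lo, hi = crop.min(), crop.max()
    if hi > lo:
        crop = (crop - lo) / (hi - lo) * 255.0
    return np.floor(crop + 0.5)


# ---------------------------------------------------------------------------
# red/NIR band pairs for the NDVI pipeline


BAND_PATTERNS = ("vegetation", "bare", "split")


def generate_band_pair(
    rows: int,
    cols: int,
    pattern: str = "split",
    seed: int = 0,
    noise: float = 0.02,
) -> BandPair:
    """Aligned red/NIR reflectance grids with known structure.

    - ``vegetation``: NIR well above red everywhere (NDVI > 0).
    - ``bare``: NIR identically equal to red (NDVI == 0).
    - ``split``: vegetation in the left half of the grid, bare soil in
      the right half, so the NDVI map has two modes separated along the
      middle column (an artificial ecotone).

    ``noise`` adds seeded within-patch reflectance variation.
    """
    if pattern not in BAND_PATTERNS:
        raise ParameterError(
            f"unknown band-pair pattern {pattern!r}; choose from {BAND_PATTERNS}"
        )
    if rows < 1 or cols < 1:
        raise ParameterError(f"invalid size {rows}x{cols}")
    rng = np.random.default_rng(seed)
    shape = (rows, cols)
    if pattern == "bare":
        base = 0.25 + noise * rng.standard_normal(shape)
        red = np.clip(base, 0.01, 1.0)
        nir = red.copy()
    else:
        veg = np.ones(shape, dtype=bool)
        if pattern == "split":
            veg[:, cols // 2 :] = False
        red = np.where(veg, 0.06, 0.24) + noise * rng.standard_normal(shape)
        nir = np.where(veg, 0.52, 0.27) + noise * rng.standard_normal(shape)
        red = np.clip(red, 0.01, 1.0)
        nir = np.clip(nir, 0.01, 1.0)
        nir = np.where(veg, np.maximum(nir, red + 0.05), nir)
    return BandPair(red=RasterGrid(data=red), nir=RasterGrid(data=nir))
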
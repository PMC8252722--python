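# heteromap

Information-theoretic heterogeneity maps on raster grids: Shannon
entropy, the Rényi generalized-entropy profile, Hill numbers, Simpson
dominance and Rao's quadratic entropy (single- or multi-layer),
evaluated over a moving-window (focal) engine, plus the NDVI / 8-bit
pre-processing pipeline commonly used to prepare satellite imagery for
these indices.

All entropies use the natural logarithm (nats). Windows are odd-sided
squares; edge windows are clipped (out-of-bounds and nodata cells simply
do not contribute), so output maps keep the full input extent. A focal
cell that is itself nodata maps to nodata.

## Library use

```python
import numpy as np
import heteromap as hm

# indices on a sample of values
d = hm.relative_abundances(np.array([1, 2, 3, 4, 5, 6, 7, 8, 9]))
hm.shannon(d)            # ln 9 = 2.197225
hm.renyi(d, alpha=0)     # log-richness
hm.hill(d, q=2)          # effective number of classes
hm.rao_q(d, hm.build_distance_matrix(d))  # expected pairwise distance

# moving-window maps
grid = hm.RasterGrid(data=np.random.default_rng(0).integers(0, 256, (100, 100)))
shannon_map = hm.apply_moving_window(grid, hm.WindowSpec(9), "shannon")
profile = hm.renyi_profile(grid, hm.WindowSpec(9), alphas=[0, 1, 2])

# NDVI pipeline on a synthetic red/NIR pair
pair = hm.generate_band_pair(60, 80, pattern="split", seed=1)
ndvi = hm.compute_ndvi(pair)                   # values in [-1, 1]
eight = hm.rescale_to_8bit(ndvi, lo=-1, hi=1)  # integers 0..255
```

Raster files are read and written as GeoTIFF (via `tifffile`, carrying
nodata, geotransform and a CRS tag) or as plain-text ESRI ASCII grids
(`.asc`).

## Command line

```sh
# synthetic fixture -> GeoTIFF
heteromap fixture --kind random-categorical --rows 100 --cols 100 \
    --classes 16 --seed 42 --output scene.tif

# heterogeneity maps, one output per alpha (alpha=1 is Shannon)
heteromap index --input scene.tif --index renyi \
    --alpha 0 --alpha 1 --alpha 2 --window 9 --output renyi.tif

# Rao's Q, optionally over several aligned layers
heteromap index --input scene.tif --index rao --window 9 --output rao.tif

# NDVI + 8-bit rescale from a red/NIR pair
heteromap ndvi --red red.tif --nir nir.tif --output ndvi.tif \
    --rescale-8bit ndvi8.tif --range -1 1
```

Every subcommand validates its configuration before computing, writes
outputs atomically, and exits nonzero with an `error: {json}` line on
stderr on failure. Same configuration + same inputs gives bit-identical
outputs.

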
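# monkeyhab

Village-development-aware habitat-quality modelling for the Yunnan
snub-nosed monkey, runnable end-to-end on synthetic landscapes.

The package implements four analysis stages plus a synthetic-data
generator and a pipeline driver:

- **`synthetic_data`** — patchy multi-class land-cover rasters, villages
  whose 30 socio-economic indicators are driven by a latent development
  factor, nearest-neighbour road links, a regular grid of 4 km² survey
  plots, and monkey-group range polygons grown in high-suitability
  forest. Deterministic for a fixed seed.
- **`village_development`** — correlation-matrix PCA of the 30
  indicators with Kaiser (eigenvalue > 1) retention, a
  variance-weighted composite development score `Z`, grades I–VII, and
  a quartic kernel-density surface of village agglomeration.
- **`plot_ecology`** — type-scores the seven plot indices (I/II/III →
  1/2/3) against the shipped classification criteria, computes the
  composite `Y = Σ Wᵢ Xᵢ` (lower is better), grades plots 1–4, and
  estimates threat distance thresholds from score–distance
  correlations.
- **`habitat_quality`** — twelve threat factors (villages by grade,
  roads, and four land-cover-derived sources) radiate influence that
  decays with distance from the nearest source (exponential
  `exp(−2.99·d/d_max)` or linear, hard-clamped at the maximum effective
  distance). Degradation combines influence with per-class sensitivity
  under normalized threat weights; quality is suitability discounted by
  a half-saturation response `Q = H·(1 − Dᶻ/(Dᶻ + kᶻ))` (defaults
  `k = 0.5`, `z = 2.5`), then graded into five classes with an area
  table.
- **`spatial_stats`** — block aggregation with queen contiguity, global
  Moran's I (permutation + analytic inference), Getis-Ord Gi* hot-spot
  z-scores with a five-class labelling, and zonal mean quality over
  group polygons.
- **`params` / `pipeline` / `cli`** — shipped default coefficient
  tables with validated YAML overrides, an end-to-end driver whose
  reruns are bit-identical for a fixed config and seed, and a `click`
  CLI.

Rasters are exchanged as ESRI ASCII grids (`.asc`, plain text with full
grid geometry); vector layers as GeoJSON; tables as CSV; configs as
YAML. All coordinates are planar metres, north-up, pixel-center
registered.

## CLI

```sh
# generate a synthetic landscape
monkeyhab simulate --config scene.yaml --out scene/

# score village development (PCA composite Z, grades I-VII)
monkeyhab villages --indicators scene/villages.csv --out scores.csv

# plot ecological quality (Y and grades 1-4)
monkeyhab plots --plots scene/plots.csv --out plot_scores.csv

# habitat degradation/quality/grades + area table
monkeyhab hq --lulc scene/lulc.asc --villages scores.csv \
             --roads scene/roads.geojson --out hq/

# Moran's I, Gi* hot spots, zonal group quality
monkeyhab stats --quality hq/quality.asc --groups scene/groups.geojson --out stats/

# full pipeline from one YAML config (see below); --dry-run validates only
monkeyhab run --config pipeline.yaml
```

Example pipeline config:

```yaml
seed: 1
out_dir: out
scene:                    # or an `inputs:` block with file paths
  grid_shape: [200, 200]
  pixel_size: 100.0
  n_villages: 250
  n_groups: 3
analysis:
  unit_size: 5
  permutations: 199
# params_file: overrides.yaml   # optional parameter-table overrides
```

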
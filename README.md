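# microquant

Seed-guided fluorescence micrograph quantification, with synthetic ground
truth for every stage. The toolkit covers:

- **synth** — synthetic cell fields, tubular branched networks, decay
  histograms and 4-phase respiration traces, all with exact ground truth
  (label masks, per-object statistics, generating skeleton graphs).
- **preprocess** — Gaussian despeckling and background-illumination
  correction (large-kernel field estimation with foreground exclusion or
  user-supplied cell-free ROIs; division by the unit-mean field).
- **segment** — mean adaptive thresholding (integral-image local mean,
  strict `p > (1 - s) * mean_w(p)` rule), connected-component labeling,
  area filtering, seed-point selection, and a grid tuner that maximizes
  the seed-detection success rate over (window, sensitivity).
- **quantify_stats** — per-cell mean intensities, treated/control
  ratio-of-means with propagated SEM, scratch-wound area and closure,
  positive-nuclei fractions with centroid co-localization, and one-way
  ANOVA with Tukey–Kramer post hoc adjustment.
- **morphology** — object shape metrics (area, Crofton perimeter, form
  factor `P²/(4πA)`, second-moment aspect ratio) and skeleton network
  connectivity (branches, junction clusters, step-metric branch length).
- **flim** — mono-exponential lifetime fitting of decay histograms
  (tail fit from the peak bin, Poisson weights with one model-based
  reweighting pass) and ROI-set lifetime averaging.
- **ocr** — mito-stress-test metrics (non-mitochondrial, basal,
  ATP-linked, maximal, spare respiration) from 4-phase traces.
- **interface** — TIFF/CSV/YAML I/O, strict config handling, and the CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end criteria (method
agreement on synthetic treated/control pairs, threshold exactness against
a brute-force oracle, tuner behavior, lifetime-recovery bias, morphology
batteries, stress-metric arithmetic, and statistics reference agreement).

## CLI

All functionality is exposed through `microquant` subcommands
(`synth`, `segment`, `tune`, `pipeline`, `quantify`, `stats`, `morph`,
`flim`, `ocr`, `show-config`). A typical round trip:

```sh
microquant synth --kind cells --seed 5 --out scene/
microquant tune --image scene/image.tif --seeds scene/seeds.csv --out tune.csv
microquant pipeline --image scene/image.tif --seeds scene/seeds.csv \
    --out run/ --save-intermediates
```

`pipeline` chains despeckle → background estimation/correction →
adaptive threshold → label → area filter → seed selection → per-cell
measurement, logging every parameter; `--save-intermediates` writes each
stage raster. Configuration comes from `microquant show-config`
defaults, overridden by a YAML file (`--config`), overridden by CLI
flags; unknown keys are rejected. Exit codes: 0 success, 2 input error,
3 stage failure.

Seed CSVs have columns `x,y[,label]` (0-based pixel coordinates,
x = column). Decay CSVs: `time_ns,counts` (or long `roi_id,time_ns,counts`).
Trace CSVs: `well,group,time_min,ocr_pmol_min,phase`.

## Notes on conventions

- Sensitivity `s ∈ (0, 1)`: foreground iff `p > (1 - s) · mean_w(p)`;
  larger `s` lowers the threshold (foreground grows monotonically).
  Windows are clipped at borders (mean over in-bounds pixels only).
- Junction clusters (8-connected groups of skeleton pixels with ≥3
  neighbors) count as one junction; branch length is 1 per orthogonal and
  √2 per diagonal step.
- The reported "ATP-linked" respiration is the oligomycin-sensitive OCR
  drop, not a vendor-derived pmol-ATP rate.
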
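# perfquant

Quantitative perfusion analysis for dynamic fluorescence (ICG) angiography.
The package turns ROI time-intensity curves — extracted from multi-page TIFF
image stacks or read from CSV — into three perfusion parameters:

* **BSFI** — background-subtracted peak fluorescence intensity during the
  first passage of the dye (robust to residual-dye pooling across repeated
  injections);
* **SFI** — maximal rising slope of the curve between bolus onset and peak
  (sliding-window least squares);
* **TTS** — time from injection to the first detectable signal rise, also
  reported as a ratio to a designated reference ROI.

Around the metrics it provides:

* a **synthetic experiment generator** (`perfquant.synthetic_data`):
  gamma-variate bolus curves for a one-vessel arcade (3 ROIs D1/D2/D3 with a
  proximal-to-distal flow gradient, 4 hemodynamic states T0-T3, 25 fps 8-bit
  acquisition, residual-dye baseline accumulation), plus rendered frame
  stacks and microsphere assay tables — all with known ground truth for
  recovery testing;
* **image IO and ROI extraction** (`perfquant.image_io_roi`): multi-page
  grayscale TIFF stacks, rectangle/mask ROIs (0-based, half-open), per-frame
  mean intensity with saturation bookkeeping, lossless curve CSVs;
* **microsphere reference-sample flows** (`perfquant.microsphere_flow`):
  `flow = tissue_signal / reference_signal * withdrawal_rate`, per gram of
  tissue, with low-count QC and per-region summaries;
* **permutation statistics** (`perfquant.perfusion_stats`): reciprocal
  transform, two-way fixed-effects area x state model with block-permutation
  p-values (exact enumeration when feasible), bootstrap marginal means, rank
  correlation of metrics against microsphere flows, and area-ordering
  summaries;
* a **config-driven pipeline and CLI** (`perfquant.cli_pipeline`,
  `perfquant` command) that runs simulate -> metrics -> flow -> stats
  deterministically from a single seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance properties (oracle
equivalence of the slope scan, analytic metric recovery, invariance suite,
flow-recovery/ordering ensemble, microsphere round-trips, permutation-test
calibration, end-to-end determinism).

## CLI

```bash
# full demo run (bundled config): simulate -> metrics -> flows -> report
perfquant run --out demo_run --seed 0

# individual stages
perfquant simulate --config my.yaml --out run/ --seed 1 --frames
perfquant extract  --stack stack.tiff --rois rois.json --fps 25 \
                   --injection-time 10.0 --out curves/
perfquant metrics  --curves run/curves --reference-roi D3 --out metrics.csv
perfquant flow     --tissue tissue.csv --reference ref.csv --out flows.csv
perfquant stats    --metrics metrics.csv --flows flows.csv --seed 1 --out report/
```

The run configuration is a single YAML/JSON file (see
`src/perfquant/configs/demo.yaml` for the documented schema); unknown keys
are rejected by name, and every run writes its resolved configuration and a
log next to its outputs. Precedence is CLI > file > defaults, and all
defaults live in `perfquant/defaults.py`.

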
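# flyquant

Quantification of fluorescence signals from classifier probability masks, plus
fly locomotion activity metrics and nonparametric group statistics — a tested
re-implementation of an automated microscopy quantification workflow,
exercised entirely on synthetic data with exact ground truth.

## What it does

- **Segmentation** (`flyquant.segmentation`): binarize a per-pixel probability
  mask at a probability threshold (strict `>`), label connected components
  (4- or 8-connectivity), and drop objects below a minimum pixel size
  (an object of exactly the minimum size is kept). Per-signal defaults follow
  the published workflow: azot → threshold 0.1 / min 17 px, TUNEL → 0.05 / 17,
  amyloid-beta antibody → 0.05 / 18. An intensity-threshold reference
  segmenter supports method-agreement validation.
- **Quantification** (`flyquant.quantify`): signal area inside a
  region of interest as a percentage of the ROI, two-channel colocalization
  (partial = any shared pixel, total = object fully contained), corrected
  total cell fluorescence (CTCF), and reference-vs-automated object matching.
- **Locomotion** (`flyquant.locomotion`): time a fly's speed is strictly
  above a threshold (default 2.7 mm/s) over a 5-minute assay, with exclusion
  of flies immobile for a contiguous run of more than 1 minute.
- **Statistics** (`flyquant.stats`): tie-corrected Kruskal–Wallis, Dunn's
  post hoc with Bonferroni/Holm adjustment, and distribution-free
  order-statistic 95% confidence intervals for medians.
- **Synthetic data** (`flyquant.synthetic`): seeded scenes of disk-shaped
  objects with pixel-exact areas and engineered inter-channel overlap,
  piecewise-constant-speed trajectories with analytic activity values, and
  shifted group samples — so every pipeline stage is testable offline.
- **Pipeline/CLI** (`flyquant.pipeline`, `flyquant.cli`): manifest-driven
  batch runs producing deterministic CSV tables.

## CLI

Generate a self-contained synthetic fixture set, then run the stages:

```bash
flyquant simulate --out demo --seed 1
flyquant quantify   --config demo/config.yaml --out demo/out
flyquant locomotion --config demo/config.yaml --out demo/out
flyquant stats      --config demo/config.yaml \
    --table demo/out/quantification.csv --out demo/out
flyquant validate   --config demo/config.yaml --out demo/out
```

`quantify` reads an image manifest (CSV with `image_id`, `roi`,
`mask_<signal>` columns and optional `genotype`/`diet`/`timepoint` metadata),
segments each configured signal, and writes one row per signal plus one per
configured colocalization pair. `locomotion` reads `t,x,y` trajectory CSVs;
excluded flies stay in the output flagged `excluded=true`. `stats` groups a
results table into comparison families and reports Kruskal–Wallis, Dunn pairs
and median CIs with significance stars. `validate` compares
intensity-threshold (reference) and probability-mask (automated) segmentation
object counts. See the docstring of `flyquant/pipeline.py` for the YAML
config schema. ROIs are accepted as ImageJ `.roi` polygon files or plain-text
`x,y` vertex lists.

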
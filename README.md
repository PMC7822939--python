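# plaquemap

Quantitative-MRI plaque characterization as a reusable, fully synthetic
pipeline: digital plaque phantoms (four tissue classes plus background),
spoiled gradient-echo forward simulation, voxel-wise T1 (variable flip
angle) and T2* (mono-exponential) mapping, small-ROI feature extraction,
and quadratic discriminant analysis of tissue classes with per-plaque
misclassification reporting.

## What it does

1. **synthetic** — paints 3D label volumes from box/ellipsoid regions and
   draws per-voxel T1/T2*/M0 from truncated normal distributions
   parameterized per tissue class (fibrous, lipid, inflammation,
   hemorrhage). Simulates two acquisitions: a VFA series
   (TR 10 ms, FA 5/10/20/30/40°) and a multi-echo series
   (TR 22 ms, TE 4/8/12/16/20 ms), with optional Gaussian/Rician noise and
   k-space zero-filling interpolation.
2. **relaxometry** — linearized VFA regression (S/sin α on S/tan α; T1 from
   the slope, M0 from the intercept) and log-linear T2* fits, vectorized
   over whole volumes, with NaN + validity-mask handling of degenerate
   voxels.
3. **roi** — samples 4–9-voxel, 4-connected, single-slice ROIs that are
   homogeneous in the ground-truth label, extracts the seven predictors
   (mean/sd/min/max T1, mean/sd T2*, pixel count), and builds per-class
   summary tables (n, min, max, mean, sd, range).
4. **qda** — per-plaque (or pooled) Gaussian discriminants with
   diagonal-shrinkage covariances, resubstitution classification, and a
   misclassification report with a Student-t confidence interval across
   eligible plaques; near-single-class plaques are reported as
   "QDA not applicable" rather than fitted.
5. **pipeline / CLI** — seeded, deterministic orchestration of all stages
   with NIfTI/CSV/JSON/YAML artifacts.

## CLI

```sh
# full run with the packaged 12-plaque default config
plaquemap run --out runs/demo

# or with your own config / overrides
plaquemap run --config cfg.yaml --out runs/demo --seed 7 --scope pooled

# individual stages on a shared run directory
plaquemap simulate --config cfg.yaml --out runs/demo
plaquemap fitmaps  --config cfg.yaml --out runs/demo
plaquemap roi      --config cfg.yaml --out runs/demo [--rois external.csv]
plaquemap classify --config cfg.yaml --out runs/demo [--shrinkage 0.1]
plaquemap report   --config cfg.yaml --out runs/demo
```

Outputs: per-plaque NIfTI volumes (phantom truth, signal stacks, fitted
maps and masks) under `plaques/`, plus `rois.csv`, `features.csv`,
`summary.csv`, `models/*.json`, `predictions.csv`, `report.{json,csv}`,
`scatter.csv` and a `manifest.json`. Re-running the same config and seed
reproduces the CSV/JSON outputs byte for byte.

The default configuration (see
`src/plaquemap/data/default_config.yaml`) builds 12 synthetic plaques:
nine with all four tissue classes, two predominantly fibrous (excluded as
not applicable for QDA) and one with only fibrous tissue and lipids.

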
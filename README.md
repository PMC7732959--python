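# bbbdce

Dual-time-resolution DCE-MRI Patlak pipeline for blood–brain-barrier (BBB)
leakage analysis, with a built-in digital phantom and cohort simulator so the
whole chain is testable end to end without any external data.

The package covers five stages:

1. **phantom** — simulate a dual-time-resolution dynamic contrast-enhanced
   acquisition (fast bolus series of 29 × 3.2 s volumes, slow leakage series
   of 30 × 30.5 s volumes), a T1 map, tissue labels (white matter, grey
   matter, hippocampus, venous sinus), ground-truth leakage maps, and a
   synthetic cohort with a planted standardized leakage–decline effect.
2. **concentration** — extract the vascular input function (VIF) from ≥ 20
   sinus voxels, convert the blood signal through an in-vitro-style
   calibration table (with hematocrit correction), and convert tissue signal
   via the linearised T10 relation `C = (S/S0 − 1) / (T10 · r1)`.
3. **patlak** — merge the fast and slow series onto one time axis and
   estimate voxel-wise leakage rate `Ki` (min⁻¹) and plasma volume `vp` by
   ordinary least squares on the Patlak design
   `C_t(t) = Ki·∫C_p dτ + vp·C_p(t)` (no reflux; negative estimates kept for
   the downstream noise correction).
4. **roi_leakage** — per-region histograms with mirrored-negative-tail noise
   correction and noise-corrected ROI mean `Ki` / `vp`.
5. **cogstats** — decline scores (Stroop reversed), cube-root and
   log(vol/ICV) transforms, covariate-adjusted regression (age, sex,
   education) with standardized coefficients, Benjamini–Hochberg FDR,
   noncentral-F power analysis, and the worked-example calculators.

`pipeline_io` orchestrates everything into a single deterministic run with a
JSON manifest of checksummed artifacts.

## CLI

```sh
bbbdce simulate --outdir sim --seed 1 --grid 16 16 8 --noise-sd 0
bbbdce convert  --dataset-dir sim --outdir conv
bbbdce fit      --dataset-dir sim --outdir maps
bbbdce summarize --ki-map maps/ki_map.nii --vp-map maps/vp_map.nii \
                 --labels sim/labels.nii --out roi.csv
bbbdce regress  --cohort sim/cohort.csv --outcome delayed_recall
bbbdce power    --f2 0.15 --alpha 0.05 --power 0.80
bbbdce run-all  --seed 1 --outdir run    # full pipeline + manifest.json
```

Images are NIfTI (`.nii`), curves and tables CSV, configuration YAML, and
the run manifest JSON. Identical seeds reproduce every artifact byte for
byte.

## Library example

```python
from bbbdce import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=1, grid_shape=(16, 16, 8)), "out/")
print(manifest["metrics"]["roi_summary"])   # noise-corrected ROI mean Ki
```

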
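# aidp

Free-water diffusion-MRI biomarker extraction and disease-specific
classification of parkinsonism (PD vs MSA vs PSP), exercised end-to-end on
synthetic diffusion cohorts.

The package contains six modules under `src/aidp/`:

| module | contents |
| --- | --- |
| `synthetic` | cohort tables (prospective + retrospective), ROI atlases, ground-truth FW/tensor maps, regional disease effects, Rician-noise DWI synthesis |
| `fwmodel` | single-tensor (WLS) and two-compartment free-water fits producing FW and FAt maps; deterministic profile search with a noise-adaptive MD-anchored regularizer |
| `features` | b0 SNR quality control, brain masking, reduction to the 266-feature vector (regional mean FW + FAt for 132 regions, age, sex) |
| `classify` | the four binary endpoints, stratified and site-holdout splits, 5-fold-tuned linear SVM with Platt-calibrated probabilities, verification runs |
| `stats` | Mann-Whitney AUROC, DeLong variance/CI/z tests, confusion metrics, Benjamini-Hochberg, pooled run summaries, severity regressions, power analysis, pathology concordance |
| `pipeline` / `cli` / `niio` / `gradients` | orchestration, run manifests, NIfTI and FSL bval/bvec I/O, seed-substream reproducibility |

## CLI

```sh
aidp simulate --config config.json --out sim/ --seed 1   # cohort + DWI volumes
aidp fit --dwi sub-0000_dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
         --mask atlas.nii.gz --out maps/                 # FW / FAt / QC maps
aidp extract --fw maps/fw.nii.gz --fat maps/fat.nii.gz --atlas atlas.nii.gz \
         --cohort cohort.csv --subject sub-0000 --out features.csv
aidp train --features features.csv --cohort cohort.csv --endpoint PD_vs_AP \
         --splits primary --seed 1 --out models/
aidp evaluate --predictions preds.csv --truth cohort.csv --null-auroc 0.8 \
         --out report.json
aidp demo --out demo/ --seed 1                           # small end-to-end run
```

Configs are JSON (`aidp.pipeline.RunConfig`); every stage derives its
randomness from the single top-level seed through named substreams, so
reruns with the same config are bit-identical for deterministic stages.

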
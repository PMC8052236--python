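# ecogloc

Automated localization of intracranial (ECoG and depth) electrodes in
post-implant head CT volumes via 3D shape analysis.

The pipeline:

1. **Load** a CT volume (NIfTI, or a single-series DICOM directory with the
   optional `pydicom` extra) in Hounsfield units, reoriented to a canonical
   right-handed frame.
2. **Resample** to isotropic 0.5 mm cubic voxels with cubic spline
   interpolation (makes the shape descriptors rotation invariant).
3. **Threshold** metal at HU > 2500 (above compact bone).
4. **Label** 6-connected voxel clusters (face adjacency only).
5. **Describe** each cluster with six geometric features: voxel-count volume,
   the three principal axis lengths of the moment-equivalent ellipsoid
   (`2·sqrt(5·λ)` per covariance eigenvalue, with a 1/12 voxel-spread
   correction), circularity (primary/secondary axis ratio) and cylinder
   similarity (`((p+s)/4)²·π·t / volume`).
6. **Classify** clusters as `ECOG` / `DEPTH` / `NON_ELECTRODE` with a
   Gaussian-kernel SVM (standardized features, one-vs-one multiclass),
   evaluated by seeded stratified tenfold cross-validation, cross-dataset
   transfer testing, and confusion-matrix metrics (rows = true classes).

A synthetic head-CT **phantom generator** (`ecogloc.phantom`) renders disc
electrodes in strips/grids, depth-electrode contact arrays, and
wire/stitch/screw distractors with per-object ground truth, including
partial-volume blurring and noise, so every stage is testable without
patient data.

## Test

```sh
python -m pytest tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with the analytic / simulation acceptance
criteria (the full run takes a few minutes; most of it is phantom
rendering).

## CLI

```sh
# generate a phantom with ground truth
ecogloc phantom --seed 1 --strips 8,12 --grids 6x8 \
    --out-nifti phantom.nii --out-truth truth.csv

# extract per-cluster features (auto-labeled from phantom truth)
ecogloc extract-features phantom.nii --out features.csv --truth-csv truth.csv

# train / cross-validate / ablate
ecogloc train features.csv --out model.joblib
ecogloc cv features.csv --k 10 --seed 0
ecogloc ablation features.csv --out ablation.csv
ecogloc transfer --model model.joblib other_features.csv

# full detection on a CT volume
ecogloc detect scan.nii --model model.joblib --out detections.csv
```

Key flags: `--target-spacing` (default 0.5 mm), `--hu-threshold`
(default 2500), `--axis-mode` (`moment`/`extent`), `--tolerance-mm`
(centroid matching, default 2.0), `--seed` everywhere randomness exists.

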
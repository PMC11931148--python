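# brainquant

Lesion-aware brain MRI quantification toolkit for unilateral pediatric brain
injury, built to run at desk scale on synthetic data:

- **imaging_core** — typed 3D volumes / label maps / label schemes, NIfTI I/O,
  label-grouping remaps (RAS convention, no implicit resampling).
- **preprocess** — percentile clipping plus a robust z-scoring variant
  (median of above-P10 voxels as centre, std over the central 5–95% band as
  spread); invariant under positive affine intensity rescalings.
- **phantom** — seeded synthetic brain generator: nested ellipsoid shells
  (CSF / cortical GM / WM), paired deep grey structures, cerebellum and
  brainstem, FLAIR-hyperintense lesions and T1-hypointense cavities, paired
  pre-/post-lesion images, exact voxel ground truth, analytic (closed-form)
  region volumes, hemisphere shrinking and a toy lobar/PLIC atlas.
- **silver_labels** — silver-ground-truth fusion of a lesion-affected and a
  lesion-filled segmentation inside a dilated lesion mask using T1 CSF
  intensity percentiles.
- **unet_seg** — desk-scale 3D U-Net pair (structural: T1 → tissues;
  lesion: T1+FLAIR+tissue channels → lesion classes) written in plain NumPy
  with hand-derived backprop, soft-Dice + weighted cross-entropy loss, Adam,
  and convergence-based early stopping. Fully seeded.
- **volumetry** — per-region total / lesion / lesion-free volumes
  (lesion-free = total − lesion), hemisphere splitting by world-x sign,
  affected-vs-less-affected relative asymmetry, atlas WM-lobe/PLIC
  postprocessing.
- **evaluation** — Dice, 95th-percentile Hausdorff distance (mm), benchmark
  region grouping (CSF/GM/WM/deep GM/brainstem/cerebellum), defect-severity
  and review-status classifiers.
- **clinical_stats** — Spearman with seeded percentile-bootstrap CIs,
  Mann-Whitney U and Wilcoxon signed-rank (exact for small tie-free samples),
  ICC(A,k), significance stars, structure–function result tables.
- **cli / pipeline** — `brainquant` entry point wiring the stages together
  with provenance manifests.

## CLI

```bash
brainquant phantom generate --config phantom.yaml --out phantom/ --seed 1
brainquant silver-gt fuse --t1 t1.nii.gz --affected s1.nii.gz \
    --filled s2.nii.gz --lesion mask.nii.gz --scheme scheme.yaml \
    --out silver.nii.gz --dilate 1 --csf-pct 1 95
brainquant train structural --data subjects/ --config train.yaml --out model/
brainquant segment --model model/ --t1 t1.nii.gz --out seg.nii.gz
brainquant volumetry report --seg seg.nii.gz --scheme scheme.yaml \
    --lesions lesions.nii.gz --clinical-side left --out report.csv
brainquant evaluate --pred seg.nii.gz --truth gt.nii.gz \
    --scheme scheme.yaml --out metrics.csv
brainquant stats run --scores scores.csv --spec spec.yaml --seed 1 --out stats.csv
brainquant pipeline run --config pipeline.yaml --out run/
```

Training data directories contain one subdirectory per subject with
`t1.nii.gz` and `labels.nii.gz` (class indices); the lesion task also needs
`flair.nii.gz` and `tissues.nii.gz` (0 background / 1 CSF / 2 GM / 3 WM).

A pipeline config (YAML):

```yaml
inputs: {t1: phantom/t1.nii.gz, flair: phantom/flair.nii.gz}
scheme: phantom/scheme.yaml
structural: {labels: phantom/labels.nii.gz}   # or {model: model_dir/}
lesion: {masks: [phantom/lesions_cavity.nii.gz]}  # or {model: lesion_model/}
volumetry: {clinical_side: left}
seed: 1
```

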
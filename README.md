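# perirad

Peritumoral DCE-MRI radiomics pipeline for binary recurrence-risk
classification, exercised end-to-end on synthetic 3-D phantom cohorts.

The pipeline chains:

1. **Synthetic cohorts** (`perirad.synthetic`) — two-phase ("early"/"peak")
   contrast-enhanced volumes with ellipsoidal lesions, configurable
   class-linked internal texture and peritumoral rim enhancement, two noisy
   reader segmentations, and a 0–100 recurrence score per subject
   (binary label at the > 25 cutoff).
2. **Ring masks** (`perirad.geometry`) — isotropic resampling and the 4-mm
   peritumoral shell built as `dilate(2 mm) − erode(2 mm)` with
   physical-unit ball structuring elements.
3. **Feature extraction** (`perirad.features`) — an IBSI-style battery:
   first-order, shape, GLCM, GLRLM, GLSZM, GLDM and NGTDM features over the
   original image and 14 derived image types (Haar wavelet sub-bands,
   square, square root, logarithm, exponential, gradient, 2-D LBP), at
   three isotropic resolutions. The pinned default yields exactly 1409
   features per masked image and 33,816 per subject (2 phases ×
   2 compartments × 3 resolutions × 2 readers).
4. **Repeatability selection** (`perirad.repeatability`) — keep features
   with between-reader correlation r > 0.95; model on the reader-mean
   consensus table.
5. **PLS classification** (`perirad.pls`, `perirad.ncv`) — PLS1 regression
   of the binary label on standardized features, component count tuned by
   inner leave-one-out AUC inside a leave-one-out nested cross-validation;
   per-feature β-weights with a top-5 % magnitude profile.
6. **Significance** (`perirad.significance`) — out-of-sample ROC AUC
   against a label-shuffling permutation null (z-score, normal and
   empirical one-sided p-values).

## CLI

```sh
perirad simulate --config demo.yaml --outdir cohort/   # NIfTI + cohort CSV
perirad ncv --config demo.yaml --combination peak/TST  # one analysis
perirad all --config demo.yaml --outdir out/           # everything
```

Combinations are the seven (phase, compartment) groups `a`–`g` or selectors
such as `early+peak/T+TST`. Config is YAML; see
`tests/test_pipeline_cli.py` for a worked example.

## Notes

- Feature definitions follow the image-biomarker standardization
  conventions (entropies in bits, merged 13-direction matrices, fixed
  25-unit bin width anchored at the region minimum); reproducing any
  specific extractor bit-for-bit is a non-goal.
- Laplacian-of-Gaussian and 3-D LBP filters are configured off by default
  (no smoothing scales); enabling them changes the per-image feature count.
- Standardization is refit inside each outer CV fold by default;
  `zscore_mode: global` gives the single-pass variant. Repeatability
  selection is computed once on the full cohort by default (documented
  leakage); `selection_mode: fold` recomputes it per training fold.
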
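# npxpred

Plasma-proteomics treatment-response prediction from Olink-style NPX
(Normalised Protein Expression) data:

- **`npxpred.ingest`** — NPX matrix and clinical table IO (wide/long
  CSV/TSV), QC-warning masking, below-LoD masking, k-NN imputation,
  per-protein standardisation, and z-scoring of new patient records
  against a reference cohort.
- **`npxpred.metrics`** — ROC/AUC (Mann–Whitney), Youden best-point
  thresholding, confusion summaries incl. MCC, Welch-t / chi-square
  group comparisons.
- **`npxpred.enet`** — elastic-net penalized logistic regression in the
  glmnet parameterisation (`alpha = 0.9` means 90% L1 / 10% L2), solved
  by a numba-compiled IRLS + cyclic coordinate-descent kernel with warm
  starts, strong-rule screening and active-set iteration; lambda tuned
  on a log-spaced path by stratified k-fold CV maximising out-of-fold
  AUC.
- **`npxpred.discovery`** — the two discovery procedures: selection
  frequency over repeated stratified 80/20 resamples (AUC > 0.5 gated),
  and stepwise protein inclusion evaluated by 5-fold nested
  cross-validation with inner 10-fold lambda tuning, followed by a
  full-cohort refit and a Youden decision threshold.
- **`npxpred.scorer`** — the packaged published signature (17 plasma
  proteins + gender + baseline DAS28-ESR, intercept 3.800, threshold
  0.7136) with `S = Σ βᵢxᵢ + b` and `p = 1/(1 + e^−(S−t))`.
- **`npxpred.endotype`** — PCA endotype discovery: sign-of-component
  patient assignment, leave-one-out PRESS (naive and pseudoinverse
  variants) for choosing the component count, and clinical comparison
  tables.
- **`npxpred.synth`** — synthetic cohort generation with known ground
  truth (planted effects, correlated blocks, latent endotype factor,
  below-LoD missingness, QC flags), including an 89 × 352 preset.

## CLI

```sh
# synthetic cohort (NPX + LoD + QC + clinical + ground truth)
npxpred simulate --preset paper --seed 0 --out-dir cohort/

# full discovery pipeline: feature importance, nested-CV stepwise
# selection, final model with Youden threshold
npxpred discover --npx cohort/npx.csv --lod cohort/lod.csv \
    --qc cohort/qc.csv --clinical cohort/clinical.csv \
    --n-sim 500 --seed 200 --k-max 30 --out run/

# score a single patient with the packaged published model
npxpred predict --input patient.csv --out prediction.json

# PCA endotypes on the third principal component
npxpred endotype --npx cohort/npx.csv --lod cohort/lod.csv \
    --qc cohort/qc.csv --clinical cohort/clinical.csv \
    --component 3 --out endo/
```

The patient template is a two-column CSV of `feature,value` rows:
`gender` (M/F or 1/0), `baseline_das`, and one NPX value per signature
protein (a protein assayed on two panels may appear twice; its z-scores
are averaged).

**Reference statistics caveat:** the packaged per-protein reference
means/SDs are a clearly-labelled *synthetic stand-in* (the original
cohort's statistics are not public; the baseline-DAS entry uses the
published cohort summary of 5.4 ± 1.3). Predictions on real patients
require a user-supplied `--reference` file. The scorer is bit-exact on
the published coefficients and threshold regardless.

**Reproducibility:** every stochastic step honours its seed and is
deterministic within one build; bit-level reproduction of the original
R implementation's resampling streams is not possible across languages.

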
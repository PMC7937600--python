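# ibrad — field-strength-independent MR radiomics for pCR prediction

`ibrad` implements a radiomics pipeline for predicting pathological complete
response (pCR) to neoadjuvant chemo-radiotherapy in locally advanced rectal
cancer from pre-treatment T2-weighted MR, designed so that one model serves
cohorts acquired at different field strengths (1.5 T and 3 T). It is aimed at
researchers studying multi-scanner harmonisation of radiomic features and at
anyone who needs a tested, deterministic reference implementation of the
intensity-based (IB) filtering approach.

## The method

The harmonisation mechanism is the **IB filter**: ROI intensities are
normalised between the 1st and 99th percentile of the ROI histogram,

```
v' = clip((v − P1) / (P99 − P1), 0, 1),
```

and pixel clusters are selected between percent thresholds
`l/100 ≤ v' < u/100` over all C(11,2) = 55 lower<upper pairs on the 0–100
by-10 grid. Because `v'` is invariant under any positive affine map
`v → a·v + b`, every feature computed on a cluster — first-order statistics,
grey-level run-length matrix features (GLNU = Σ_g r_g²/N, RLNU = Σ_r c_r²/N),
per-slice box-counting fractal dimension, and morphological descriptors —
is identical across scanner gain/offset differences by construction.

Model building follows a two-cohort screening design: features are Z-scored
per cohort, tested against outcome (Shapiro–Wilk-gated t or
Wilcoxon–Mann–Whitney, Benjamini–Hochberg within cohort), the most
significant feature of each cohort seeds a logistic model, a third feature is
chosen by training AUC, and further features are accepted only while the AIC
(2k − 2 log L) decreases. Robustness is evaluated by stratified 10-fold
cross-validation repeated 300 times with fold-wise re-standardisation.

No imaging data ship with the package; a synthetic two-scanner cohort
generator (`ibrad.synthetic`) emulates the two acquisitions
(0.703 mm/3 mm vs 0.45 mm/3.5 mm, different gain/offset/noise, prevalences
0.22/0.25) with a planted outcome-linked texture effect of controllable
strength, so the entire pipeline is testable end to end.

## Worked example

```
python analysis/01_simulate_cohorts.py
python analysis/02_extract_features.py
python analysis/03_screen_features.py
python analysis/04_build_model.py
python analysis/05_crossvalidate.py
python analysis/06_recovery_check.py
```

`01` writes 136 + 59 synthetic patients (reduced image grids) under
`scratch/cohorts/` and prints the cohort composition:

```
       n  events  pcr_rate_pct
cohort
1.5T  136      30          22.1
3T     59      15          25.4
response homogeneity p = 0.74 (chi2, Yates)
```

The two cohorts are homogeneous in response rate (p = 0.74), so they can be
merged into one training set, as the screening design assumes.

`02` extracts the feature table (195 patients × 1260 features on the default
grid: 55 IB bands × 4 families, LoG 0.35/0.7 mm, unfiltered base set; 0
failures). `03` screens each cohort and prints its most significant features
(texture and LoG-filtered statistics dominate both cohorts, e.g.
`textural.run_pct.log_0.35mm`, WMW p = 8.4e-07 at 1.5 T). `04` builds the
seeded model and prints its coefficients and AIC; on this synthetic draw the
greedy AIC search keeps 19 features (AIC 67.8, training AUC 0.991) — far
deeper than it goes on clinical data, because the generator's features are
complementary views of one latent parameter. `05` cross-validates the
selected features (10-fold × 300):

```
10-fold x 300 CV: mean AUC 0.893 [0.854, 0.928] (2.5-97.5 pct over repetitions)
```

`06` runs the parameter-recovery study at n = 200: with a planted effect
whose theoretical single-feature AUC is 0.80 it prints

```
selected 8 features; repeated-CV AUC 0.923 (selection optimism included)
fresh-cohort AUC 0.702 vs theoretical ceiling 0.80
null-cohort CV AUC 0.509 (chance level)
```

The gap between the repeated-CV estimate and the fresh-cohort AUC is the
selection optimism of choosing features on the same data that is then
cross-validated (selection precedes cross-validation in this protocol); the fresh-cohort value
sits below the 0.80 ceiling, as it must when outcome depends only on the
latent heterogeneity. See `docs/methods.md` ("Known limitations").

A `ibrad` console command exposes the same stages (`simulate`, `extract`,
`select`, `crossval`, `report`) for file-to-file use; see `ibrad --help`.

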
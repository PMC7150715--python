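# Methods

This note documents the models, numerical choices and limitations of
`glucopcs`: the glucometabolic index formulas, the principal-component
scoring procedure, the synthetic cohort mechanism, and the statistical
stage. Everything stated here is computed by the test suite or the analysis
scripts; nothing is asserted from data the package cannot see.

## Index panel

All formulas operate on canonical units — glucose mg/dl, insulin μU/ml,
C-peptide ng/ml — converted once by `UnitPolicy` (factors 18.016 mg/dl per
mmol/l, 6.0 pmol/l per μU/ml, 0.331 nmol/l per ng/ml). Conversions are
involutions to 1e-9 relative, and a full panel computed after a unit
round-trip changes by less than 1e-9 relative (tested).

- **HOMA-IR** = (G0[mmol/l]·I0[μU/ml])/22.5.
- **QUICKI** = 1/(ln G0 + ln I0) with *natural* logarithms on mg/dl and
  μU/ml. The common base-10 variant yields ≈0.33–0.40; the natural-log
  variant yields the 0.15–0.20 range reported for pregnancy cohorts and is
  the one this package implements (documented deliberately, since both
  circulate under the same name).
- **Matsuda** = 10000/√(G0·I0·Ḡ·Ī), means over all five sampling points.
  Scale property: multiplying insulin by k divides the index by k (tested).
- **OGIS** (2-hour variant): model-based glucose clearance from G(0), G(90),
  G(120), I(0), I(90), dose (default 75 g) and body surface area (default
  1.73 m², since height is not collected; configurable). The published
  constants are transcribed into `constants.OgisConstants` with a citation
  string. Validation is by behaviour: Table-calibrated mean inputs give
  ≈494 ml·min⁻¹·m⁻² (within the reported 505 ± 85 band) and the index is
  strictly decreasing in I(90).
- **Stumvoll MCR/ISI and PH1/PH2**: the published demographic regression
  formulas, coefficients in `constants.StumvollConstants`; inputs converted
  to mmol/l / pmol/l internally.
- **Insulinogenic indices**: Sec-early = ΔI(30−0)/ΔG(30−0);
  Sec-late and Sec-total are AUC_I/AUC_G ratios over 60–120 and 0–120 min.
  AUCs use the trapezoid rule on the 30-min grid (total, not incremental
  area); the rule is pinned by a brute-force panel-summation oracle at
  1e-10. A flat 0–30 glucose segment makes Sec-early undefined — it is
  flagged, never silently dropped.
- **ISSI-2** = Matsuda × Sec-total, an exact product (identity tested to
  1e-12).
- **Insulin secretion rate (ISR)**: two-compartment C-peptide deconvolution
  with population (Van Cauter-type) kinetics — fast half-life 4.95 min,
  fast fraction 0.76, slow half-life 29.2 + 0.14·age min, rate constants
  k2 = f·b + (1−f)·a, k3 = a·b/k2, k1 = a + b − k2 − k3. C-peptide is
  interpolated linearly on a 0.25-min grid, the peripheral pool starts at
  its fasting steady state, and ISR = V·(dC1/dt + (k1+k3)C1 − k2·C2).
  The distribution volume is taken proportional to body surface area
  (3.11 l/m², ≈5.4 l at 1.73 m²). **TIS** is the trapezoid integral of ISR
  over 0–120 min, per m² by default (the absolute variant is exposed, since
  the per-m²-vs-per-subject normalization of published values is
  ambiguous). On calibrated mean curves log TIS ≈ 4.05, within one SD of
  the reported 3.70 ± 0.37. Constant C-peptide reduces exactly to
  ISR = k3·V·C (steady state); zero C-peptide gives TIS = 0.
- **g_sens / rate_sens** are *regression surrogates*, not a mechanistic
  dose-response fit: g_sens is the least-squares slope of ISR on concurrent
  glucose over the five points; rate_sens the early (0–30 min) incremental
  ISR per unit rate of glucose change. Constant glucose is flagged
  undefined. They are labelled surrogates in all outputs.
- **IADPSG classification**: GDM iff fasting ≥ 5.1, 1-h ≥ 10.0 or 2-h
  ≥ 8.5 mmol/l (inclusive, on mg/dl equivalents). Missing values propagate
  to "unknown" unless an observed value already meets a criterion.

`compute_panel` evaluates everything for one row after a single central
unit conversion; indices with missing or degenerate inputs come back NaN
with a named flag, complete rows come back fully finite (tested).

## Scoring (PCS1–3)

The 17 features are, in fixed order, G0…G120, I0…I120 (natural log),
CP0…CP120 (square root), age, BMI (natural log). Standardization constants
always come from a designated *training* source — an external stats file or
the derivation cohort — never silently from the cohort being scored; this
mirrors applying previously derived eigenvectors to a new sample.
Self-standardization is the explicit default only when loadings are also
derived from the same cohort.

Loadings are the top-3 unit eigenvectors of the training feature
correlation matrix (AᵀA/(n−1) of the standardized features). Eigenvector
signs are arbitrary, so a convention is imposed: component 1 is oriented so
its loading on fasting insulin is negative (higher PCS1 = higher insulin
sensitivity); components 2–3 so their largest-magnitude loading is
positive. With the synthetic mechanism below, component 3's largest loading
is a fasting variable, so the convention orients it toward fasting insulin
resistance. External loading files are matched to features by *name*, never
by position; shuffled row order is canonicalized and wrong or missing
variable names are hard errors.

Scores are S = A×V, rescaled elementwise to PCS = (S+100)/17 (the
constants are implemented literally as published; their provenance is not
stated in the source and is treated as a fixed definition). Exact
properties pinned by tests: projection equals brute-force dot products
(1e-10); scores on a derivation cohort are pairwise uncorrelated (<1e-8);
self-standardized rescaled columns average 100/17 (1e-9); the 17
correlation eigenvalues sum to 17 (1e-6); row permutation permutes scores
identically.

## Synthetic cohort mechanism

Each subject carries two lognormal latents — insulin sensitivity `si`
(log-SD 0.5, weakly decreasing with age) and β-cell function `beta`
(log-SD 0.4) — with log-scale correlation −0.3 (compensation). Insulin
sensitivity is multiplied per visit by (1.0, 0.72, 1.25) at V1/V2/V3: it
falls in late gestation and overshoots its early-pregnancy value after
delivery, deterministic per subject.

Per subject-visit, with d = centred log-latents and x = d_si + d_beta:

- fasting glucose is lognormal around the visit target, ∝ exp(−0.12·x);
- the post-load excursion is `target increment × amplitude`, with lognormal
  mean-1 amplitude ∝ exp(−0.55·x) plus shared and per-time noise — low
  disposition means larger excursions, which is what pushes subjects over
  the IADPSG thresholds;
- log insulin sits at the per-time visit target plus −0.55·d_si + 0.50·d_beta,
  an extra stimulated β-cell response (+0.50·d_beta) and an excursion
  coupling (+0.35·log amplitude) at the post-load times, shared and
  per-time noise;
- C-peptide (on the square-root scale) follows the visit target plus a
  slow causal exponential smoothing (time constant 75 min) of the insulin
  deviations — the slower, more stable peripheral kinetics of C-peptide;
- a *fasting (hepatic) insulin-resistance factor* loads jointly on the
  fasting glucose, insulin and C-peptide cells only. It exists so that the
  data contain a genuine fasting axis: the third principal component then
  emerges as fasting insulin resistance — the interpretation the score
  system assigns it — and its negative relation to the disposition index
  is structural rather than a seed accident;
- BMI is lognormal around visit targets, negatively tied to `si`; age is a
  subject constant; parity and family history are Bernoulli draws; a prior
  GDM history (multiparous subjects only) is enriched at low disposition.

Marginal *means* are anchored exactly (lognormal corrections included) to
the per-visit target table, whose defaults are the published marginal
summaries of a 67-woman pregnancy cohort; generated V1 means land within
~1% at n=1000 (the tested contract is 15%). Marginal SDs are approximate
only — insulin log-SDs are under-dispersed (≈0.7 vs reported 0.83–1.35)
because the reported dispersion includes real-world heterogeneity the
two-latent mechanism does not model. GDM labels are assigned by applying
the IADPSG thresholds to the generated V1/V2 curves; prevalence emerges at
≈11–14% against the study's 9% and is strongly enriched in low
`si·beta` subjects (rank-test p < 0.01 at n=500, tested). The dropout
schedule retains 67/57/23 per 67 subjects (nested subsets). Injected
missingness is restricted to post-load cells and completely at random; the
source gives no missingness mechanism, so MCAR is the neutral choice.

What passing tests on this generator do **not** show: realism of
within-subject correlation across time points beyond what the shared
factors imply, ethnicity or parity physiology, fetal outcomes, or the
absolute values of real-data regression coefficients (Table-level ORs and
importance magnitudes depend on the confidential cohort). Direction-level
conclusions — sign patterns, rank correlations, visit dynamics — are the
claims the synthetic checks support.

## Statistical stage

- **Imputation**: chained equations via posterior-sampling Bayesian-ridge
  conditionals (scikit-learn's iterative imputer) on the normalizing scales
  (log insulin, √C-peptide, raw glucose) with age and BMI as predictors;
  m = 50 completed datasets averaged cellwise. Observed cells are restored
  bit-identically. Averaging across m reduces between-run dispersion
  (tested m=1 vs m=50), and imputed-cell error stays below each variable's
  marginal SD at the study's missingness level (tested with known truth).
- **Group tests**: Welch's t (Satterthwaite df) from summaries or raw
  samples (two routes agree to 1e-12); Pearson χ² on 2×2 tables *without*
  continuity correction — the published 0.978 and 0.413 reproduce only
  without Yates' correction; Fisher's exact two-sided p by summation of
  tables as or less probable (pinned against exhaustive hypergeometric
  enumeration). The published multiparous GDM-history p = 0.043 is
  reproduced by Fisher's test, not by χ² — both are provided. The published
  age contrast "<0.001" is not reproducible from the printed summaries by
  Welch's test (t ≈ 3.83, df ≈ 6, p ≈ 0.009); the t-statistic is the tested
  quantity.
- **Logistic GDM models**: maximum-likelihood univariable fits; odds
  ratios reported per configurable predictor units (0.01 score units for
  PCS); p from the likelihood-ratio test; 95% CI from the profile
  likelihood (intercept profiled out by bounded scalar minimization on the
  centred predictor; bounds located by root-finding on the deviance).
  Complete separation is detected and flagged, with the unbounded CI side
  reported as 0/∞, never raised. Null calibration: type-I error within
  [0.03, 0.07] over 2000 replicates (tested).
- **Variable importance**: own bagging of CART trees (√p features per
  split); per tree, out-of-bag accuracy before vs after permuting one
  predictor, averaged over all trees — the permutation-importance principle
  of conditional-inference forests, whose reference implementation is not
  available here. The *ranking* is the supported contract; absolute
  magnitudes are algorithm-dependent. ntree defaults to 10⁴ (10⁶ is
  accepted but slow); tests use 1000–5000.
- **ISSI-2 model**: OLS of the raw disposition index on the three scores
  (a log-response option exists; the response scale of the published fit is
  unstated). Signs and R² are reported; on synthetic cohorts the pattern is
  b(PCS1) > 0, b(PCS2) < 0, b(PCS3) < 0.
- **Visit dynamics**: random-intercept-per-subject linear mixed model with
  visit as fixed effect, ML-fitted; the global visit test is a likelihood
  ratio against the intercept-only model. All-singleton data fall back to
  OLS ANOVA with a warning. Null p-values are uniform (KS-tested over 200
  label permutations).

## Problem sizes and determinism

Default validation sizes: n=1000 subjects for structure/direction checks,
n=500 for recovery studies, 2000 replicates for null calibrations, ntree
1000–5000 for importance — chosen so the whole suite runs in a few minutes
on one CPU while leaving comfortable statistical margins. Every stochastic
component takes an explicit integer seed (numpy `default_rng`); cohort
generation, imputation, forests and the full pipeline are bit-reproducible
under a fixed seed (tested by checksum), and every report embeds the seed
and a hash of the analytic configuration.

## Known limitations

- OGIS/Stumvoll/kinetic constants are transcribed from the primary
  literature without access to reference implementations; they are
  validated behaviourally (ranges, monotonicity, steady states), not
  against an external oracle.
- The C-peptide distribution volume (3.11 l/m²) is a population
  approximation; TIS levels shift proportionally with it, rank structure
  does not.
- The generator reproduces means, direction structure and a realistic
  top-3 explained-variance fraction (≈75–78% at n=1000), but not the exact
  published loading matrix, which is not redistributable; external loading
  files are supported for exact score transfer.
- `g_sens`/`rate_sens` are linearized surrogates and should not be
  compared numerically against model-based β-cell parameters.
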
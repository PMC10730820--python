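# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices and the limitations of the `metabotype` package. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Discriminant model

OPLS-DA is fitted by NIPALS-family algorithms on unit-variance-scaled
predictors and a centered 0/1-coded class variable.

**Orthogonal filtering.** The class-predictive direction
w ∝ Xᵀy/‖Xᵀy‖ is computed first; each orthogonal component takes the
loading p of the current predictive score and splits off
w⊥ ∝ p − (wᵀp)w, extracts t⊥ = Xw⊥ and deflates X by t⊥p⊥ᵀ. Predictive
PLS1 components are then extracted from the filtered matrix with the
standard deflation of both X and y. Since scaling, filtering and
regression are all linear, the fit collapses into a single coefficient
vector b on the scaled scale plus an intercept (the training class
mean); this linear form is what gets serialized and applied to new
cohorts. Orthogonal and predictive R²X are reported separately plus
their sum, since conventions differ on whether the cumulative figure
should include class-orthogonal variance.

**Class coding and decision rule.** Classes are coded 0/1 (the "case"
label is 1 when present); a sample is called positive when ŷ ≥ 0.5, the
midpoint of the codes. RMSEE uses the denominator n − 1 − n_pred.
Default structure is one predictive plus one orthogonal component, the
standard choice for a two-class problem.

**Cross-validation.** Q²Y = 1 − PRESS/SS with stratified K-fold CV
(default 7 folds; reduced to the minority-class count if needed so every
training split keeps both classes). The scaler and the full component
structure are refit inside every training fold; PRESS accumulates
squared out-of-fold errors of the coded response and SS is the total sum
of squares of the centered coded response.

**Permutation diagnostics.** Labels are permuted uniformly; each
permutation triggers a full refit plus cross-validation. pQ² uses the
add-one estimator (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), which can
never report zero. The default permutation count in the orchestrated
pipeline is 199 (resolution 0.005); the Monte-Carlo studies in the
acceptance script use 99 per seed (resolution 0.01, sufficient for the
0.05 decision threshold while keeping 200 model refits per cohort
affordable).

**Verdict rule.** Q²Y > 0.5 "good", 0 < Q²Y < 0.5 "some", Q²Y < 0
"none"; a branch is *rejected* when Q²Y < 0 or pQ² ≥ 0.05. This is the
rule that discards the information-free urine branch while accepting the
plasma model.

**VIP.** Computed over predictive components only —
VIPⱼ = √(p Σₐ SSₐwₐⱼ²/ΣₐSSₐ) with SSₐ = qₐ²tₐᵀtₐ — because orthogonal
variation is by construction uncorrelated with class. This is one of
several published VIP variants; mean VIP² = 1 holds by construction and
is asserted in tests.

**NIPALS numerics.** Components are initialized from the column of
maximal variance (deterministic, no randomness), iterated to a relative
score change below 1e-10 with a 500-iteration cap (exceeding it raises,
naming the iteration count), and sign-fixed so the largest-magnitude
weight entry is positive, removing the sign indeterminacy from stored
artifacts.

## Univariate screen

Mann–Whitney U (pair counting with half-credit for ties) with the exact
enumeration when the pooled sample is ≤ 12 and untied, otherwise the
tie-corrected normal approximation with continuity correction — n = 10
per group sits right at this boundary, and the choice is made per
metabolite. BH adjustment preserves input order and caps q at 1;
p-values are floored at the smallest positive normal double and never
reported as zero. Fold change is case mean over control mean. Volcano
selection is two-sided (FC ≥ 2 or ≤ 0.5, boundary inclusive) with
q < 0.1 strict, so down-regulated metabolites are selectable even though
the usual phrasing quotes only the upper threshold.

## Clinical indices

With glucose G converted mg/dL → mmol/L (÷18) and insulin I in µg/L as
measured: HOMA-IR = G·I/22.5; HOMA-β = 20I/(G − 3.5), undefined (reported
missing) when G ≤ 3.5 mmol/L; R-QUICKI = 1/(log₁₀ glucose[mg/dL] +
log₁₀ insulin + log₁₀ NEFA). This unit convention reproduces standard
fasting-control HOMA-IR values; R-QUICKI is highly sensitive to the
insulin unit convention, which assays rarely state, and published values
for comparable inputs can differ by ~0.04 — the implementation documents
this rather than tuning constants.

## Normalizations

**QC block correction.** Each value is multiplied by
(global QC mean)/(block QC mean) for its metabolite, equalizing QC means
across run-day blocks. A metabolite with a zero or undefined QC mean in
any block cannot be anchored and is dropped into the report. The
correction inverts injected multiplicative drift exactly when the QC
samples are a common pooled spectrum and the drift factors preserve the
global QC mean; otherwise the table is recovered up to one global
constant per metabolite — intrinsic to any QC-ratio method, not an
implementation artifact.

**PQN.** Each sample is divided by the median of its feature-wise ratios
to a reference spectrum (default: the median spectrum of non-QC
samples), using only features positive in both; a sample sharing fewer
than 3 positive features with the reference is an error. Dilution is
identifiable only up to a cohort-wide constant. With 43 features at 10%
CV the per-sample estimator SE is ≈ 1.25·CV/√43 ≈ 2%.

**Z-scoring** uses the sample SD (n − 1). It is exposed as an explicit
optional stage; the discriminant model applies its own internal scaling,
so z-scoring is not silently applied twice.

## Synthetic cohorts

The generators define the study conditions; they are not tuning knobs.

**Preclinical plasma** (default): 10 animals per group, 126 metabolites
across TG/DG/PC/LPC/SM/ChoE/amino-acid/other classes, multiplicative
group effects of 1.17–1.51 planted on an 11-lipid signature whose
control-group abundances anchor to reference response ratios
(0.12–50.4). Abundances are log-normal — positive by construction, with
SEM/mean scale-proportional as observed in real response-ratio tables —
with the log-SD derived from a per-metabolite CV drawn uniformly from
10–15%. Features of one class share a single Gaussian factor
(equicorrelation 0.4) because lipid classes co-regulate and discriminant
model behaviour depends on that collinearity. QC samples are the exact
pooled mean spectrum, interleaved per run-day block; optional block
drift multiplies whole blocks.

At these conditions the realized fold change of a planted 1.46 effect
has a ratio-of-means SE of ≈ 0.10, so individual 10-vs-10 cohorts
scatter visibly around the planted value; convergence to the effect map
is verified at n = 500 within 2%.

**Urine null**: 43 small-molecule metabolites, no group signal, wider
CVs (20–40%) and per-sample log-normal dilution factors (SD 0.3 on the
log scale) recorded in the truth table so quotient normalization can be
tested against them.

**Human cohort**: 140 subjects, latent at-risk prevalence 0.5; at-risk
subjects carry a multiplicative ``signature_effect`` (default 1.4) on
the signature metabolites and additive mean shifts on clinical lipids
(TG +0.5, TC +0.4, LDL +0.35 mmol/L, ApoB +0.12 g/L). Healthy TG centers
at 1.1 mmol/L (SD 0.45) so both guideline classes occur on either side
of the 1.7 mmol/L threshold. Between-subject CVs of 25–35% reflect
biological variation exceeding preclinical within-group noise. Clinical
variables are Gaussian with positivity floors.

What the generators deliberately do **not** emulate: spectral artifacts,
missingness patterns, realistic inter-metabolite biochemical networks
beyond class equicorrelation, platform batch interactions between
cohorts, or the covariance between the clinical lipids and the
metabolome (the two are coupled only through the latent class). Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own assumptions — not that those assumptions exhaust real
cohort behaviour.

## Cross-cohort projection

The largest interpretive choice in the package: the target cohort is
standardized with **its own** means and SDs before the trained linear
form is applied, because rat and human abundance scales differ by
platform, species and units, and the trained scaler would import the
training cohort's location wholesale. The model is *refit* on the
training cohort restricted to name-matched features (case-normalized
exact matching, default minimum coverage 80%) rather than subsetting
coefficients, since dropping predictors invalidates fitted coefficients.
Two modes exist: `full` (all matched features; default) and
`signature-only`.

Guideline TG categories: normal < 1.7 ≤ borderline < 2.3 ≤ high < 5.6 ≤
severe (mmol/L), with binary risk at TG ≥ 1.7; the boundary value counts
as at-risk so the two categories partition all values. The published
category tables leave a gap between the 5.6 upper end of "high" and a
5.7 "severe" lower bound; a single cut at 5.6 is used.

## Degenerate inputs and tie-breaks

Constant features after scaling, one-class responses, blocks without QC
samples, samples sharing too few positive features with a PQN reference,
zero-SD target features at projection time and non-positive TG all raise
errors that name the offending item. Empty signatures are a valid
selection outcome, not an error. Verdict boundaries: Q²Y exactly 0.5 is
"some", exactly 0 is "none"; pQ² exactly 0.05 rejects.

## Problem sizes

The Monte-Carlo studies run at the study's own scale — 10 vs 10 animals,
126 metabolites, 140 human subjects — with 100 seeds for the preclinical
validation/recovery rates and urine rejection rate, 50 seeds per
signature-effect level for translation recovery, and 99 permutations per
cohort for pQ²: chosen so each rate's Monte-Carlo error is a few percent
while a full acceptance run stays around a minute on one CPU.

## Known limitations

* Two-class problems only; no multi-class OPLS-DA, O2PLS or kernel
  variants, and no automatic component-number selection.
* The permutation test permutes labels freely (no exchangeability
  restrictions such as blocked permutation within run days).
* Feature matching is exact-name (case-normalized); no mass/retention
  or ontology-based reconciliation across platforms.
* Missing values must be resolved before model fitting; only the screen
  and normalization stages tolerate NaNs (pairwise exclusion).
* The subgroup comparison conditions on guideline-normal TG, which
  truncates the very shifts it tests; with moderate clinical coupling
  the per-variable effect in that subgroup is ~0.4 SD, so FDR-corrected
  significance is not expected in every cohort — the tests assert
  directionality and null calibration, matching what the design can
  actually detect.
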
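# Methods

This note documents the models, the synthetic data, and the numerical
choices behind `adsig`, in the order the pipeline runs them.

## Signature scoring

Per wave, each of the 16 ROI × hemisphere measures is residualized by OLS on
age (years) and scanner (unordered indicators, reference = first label
alphabetically); hippocampal *volume* is additionally residualized on
estimated intracranial volume (ICV adjustment for hippocampal MD is off by
default and switchable).  Residuals are standardized (ddof = 1), multiplied
by the published weights and **summed** — not divided by Σw.  "Weighted
average" and "summed" describe the same estimator here because the composite
is z-scored within wave afterwards, which absorbs any positive scale factor;
the sum is the simpler choice.  Residualization is fit on the full analysis
sample at each wave, not on the cognitively normal subset, so the covariate
model cannot leak diagnosis; this is switchable by filtering the input
table.  Any missing ROI makes that subject-wave score missing: the 16 fixed
components define the signature, and partial reweighting would silently
change its meaning.

PBAD = chronological age − predicted brain age (more negative = older
appearing brain).  PBAD adjustment residualizes scores on PBAD per wave and
re-standardizes; it errors out (rather than returning zeros) when PBAD is
constant or explains the scores exactly.

## Grey-matter MD estimation

MD is `(λ1+λ2+λ3)/3`.  Cortical profiles carry 7 samples at depths
0.8–2.0 mm (0.2 mm steps) along the surface normal; each sample is weighted
by the grey-matter volume fraction `v` of its voxel through Tukey's bisquare
weight

    w(v) = (1 − ((1−v)/t)²)²   if 1−v < t,   else 0,      t = 0.5.

The printed form of this function in the source literature is
typographically garbled; the formula above is the unique bisquare-form
reading consistent with both stated behaviours — zero for fractions below
0.5, a weight in (0, 1] above — and it is continuous at the gate, so the
boundary `v = 0.5` maps to weight 0 (strict inequality).  Samples are
treated independently even when several fall in one voxel.

Subcortical ROI averaging weights each voxel by
`u = (md − median)/(4.7 · MAD)` with weight `(1−u²)²` for |u| < 1, else 0.
The MAD is the ROI's *across-subject average* dispersion, supplied as an
input; it is not recomputed per subject, which would let a contaminated ROI
widen its own acceptance window.  The estimator presumes clean voxels form
the majority of the ROI (the median must sit in tissue, not CSF) — the
phantom demonstrations therefore exclude the outermost rim layer from
subcortical masks.  In every operator, "all weights zero" returns NaN
(flagged missing), never 0.

Resampling and registration of real images are out of scope; phantoms are
generated directly at working resolution as `f·MD_gm + (1−f)·MD_csf`
mixtures, with a pure-grey interior and a rim below the 0.5 gate so that
ground truth is recoverable exactly in the noise-free case.

## Synthetic twin cohort

The generator emulates the cohort structure the analysis assumes: twin
pairs (default 50% MZ), baseline age uniform on 51–60 (twins share age),
three waves ~5.7 ± 0.5 y apart, AD-PRS ~ N(58.4, 7.5²), per-wave scanner
batches with small offsets, 18 cognitive tests in 6 domains, ~12% latent
conversion, 12% per-wave dropout with like-sized replacement entry.

Each ROI measure decomposes as `sqrt(g)·F + sqrt(1−g)·ε` with a subject-wave
global factor F (share g = 0.75) that itself splits into pair, stable
subject and wave components; the pair share is set so each trait's
within-pair correlation equals the configured ICC (0.5 DZ, +0.1 MZ).  The
MD factor is mixed from the thickness/volume factor with wave-specific
negative coefficients (−0.28, −0.50, −0.62), which the scored composites
reproduce almost exactly because the global factor dominates the composite.

**Effect injection.**  Latent converters are assigned at baseline with
probability tilted by age and PRS (log-odds 0.35 and 0.30 per SD, intercept
solved so the marginal rate matches the configured 11.8%).  Their ROI
measures are shifted — MD up, thickness/volume down — by a per-ROI delta
derived in closed form so that the *downstream signature* SMD equals the
configured value: with weights `w` (S1 = Σw, S2 = Σw²) the composite SD is
`sqrt(g·S1² + (1−g)·S2)`, so `delta = SMD · sqrt(g·S1² + (1−g)·S2)/S1`.
A closed form is used instead of a pilot-simulation calibration because it
is exact and keeps the generator deterministic.  The imaging shift is
constant across waves — the cohort this emulates already shows the
converter/CN MD gap at baseline — while cognitive decline ramps linearly
from zero at wave 1 to full size at the final wave (general decline 0.3 SD
plus 2.2 SD in two affected domains, memory always among them), which is
what makes converters CN at baseline and MCI by wave 3.

**Practice and attrition.**  Returnees get a one-time +0.15 SD shift on
every test.  Attrition is injected by flagging "low-functioning" subjects —
everyone who will drop out before the final wave, plus replacement entrants
marked at rate `dropout_rate` so their composition matches the prior-wave
population they stand in for — and depressing their ability by 0.2 SD.
This construction makes the replacement-subjects practice estimator
unbiased by design (residual bias from multi-wave selection is < 0.005 SD
at the default rates).  Cognitive dispersions (domain SD 0.45, test noise
SD 0.35) were set so that the full diagnostic pipeline's conversion rate
matches the configured rate; normative scores are treated as age-adjusted,
so stable subjects have no secular drift.

**What the generator does not emulate:** real MRI noise physics, non-linear
ageing trajectories, MZ/DZ differences in cognition, domain-specific test
difficulty, informative (outcome-dependent) dropout, or genuine normative
calibration.  Passing tests therefore demonstrate internal consistency of
the estimators at the assumed data-generating process, not robustness to
real-data violations of it.

## Diagnosis

A domain is impaired iff ≥ 2 of its tests have z strictly below −1.5 on the
adjusted normative scale; MCI = any impaired domain (single vs multi-domain
subtypes are not distinguished).  GCA adjustment removes only the per-test,
per-wave slope on age-20 ability (`z − b·(gca − mean)`), preserving the
level relative to the external norms.  Practice effects are estimated per
test and wave as (returnee mean − replacement mean) − (returnee prior-wave
mean − full prior-wave mean) and subtracted from returnee scores only.
Domains with < 2 scoreable tests are indeterminate; a subject-wave label is
missing when a domain is indeterminate and nothing else is already
impaired (conservative).  Longitudinally, robust-CN = CN at every attended
wave; any MCI→CN transition excludes the subject as a reverter; converter =
CN at wave 1 and MCI at the final wave.  Without the practice correction
the measured conversion rate is biased *downward*: inflated returnee scores
at waves 2–3 hide emerging impairment.

## Concurrent comparisons

Linear mixed models (statsmodels `MixedLM`, REML): fixed effects for group,
wave, and initially their interaction; random intercepts for pair and for
subject within pair.  If the joint Wald test of the interaction is
non-significant at 0.05 the model is refit with main effects only.
Denominator degrees of freedom are residual (n − p) and labelled as such in
the output — a deliberate approximation, since the installed mixed-model
routine does not provide Satterthwaite df; at the sample sizes involved
(hundreds of subjects) the difference is negligible.  The SMD divides the
model-adjusted group difference by the raw pooled within-group SD of the
outcome (model-adjusted numerator, raw denominator).  Non-convergence falls
back to an independence OLS fit flagged `ols-fallback`.  BH-FDR at q = 0.05
is applied within exactly two families: concurrent outcomes and predictive
model comparisons.

## Risk prediction

Models 1–5 use z-scored predictors and a twin-pair random intercept.  The
marginal likelihood of the pair-intercept logistic model is maximized with
Gauss–Hermite quadrature (25 nodes; clusters have ≤ 2 members, so
non-adaptive quadrature is accurate), written in-package because no
installed library fits this model by quadrature.  `log σ` is bounded in
[−8, log 5]: below the floor the model is indistinguishable from
independence, and above the ceiling the intercept variance is no longer
identified (the classic β–σ ridge with weakly informative clusters).
Predicted probabilities come from the fixed effects only; the random
intercept absorbs twin dependence during estimation but plays no role in
scoring.  Wald CIs give odds ratios; |β| > 10 raises a separation warning.

AUC is the Mann–Whitney concordance with midrank ties.  Youden thresholds
scan the midpoints of sorted unique scores plus ±∞, calling a subject
positive at or above the cutoff; J-ties break toward higher specificity
(the higher cutoff).  Confusion counts derived from printed operating
points use nearest-integer rounding, which reproduces every published table
cell from the published rates and group sizes.

The stratified bootstrap resamples cases and controls separately with
replacement, scoring both models on the same resamples (hence p(a,b) =
p(b,a) and exact determinism given the seed).  The default two-sided p
treats observed-difference / bootstrap-SD as standard normal; a percentile
variant is available.  The normal approximation is mildly anti-conservative
with very few cases (null rejection ~5–8% at 30 cases), which stays within
Monte-Carlo error of nominal at the calibration sizes used (500 simulations
× 500 replicates — scaled down from the production 2000 replicates, which
the pipeline default retains).

## Problem sizes

Parameter-recovery checks run at 5000 twin pairs (SMD within ±0.05,
practice effect within ±0.03 of the injected values), the odds-ratio sign
rate at 200 cohorts of 1000 pairs, and the analysis drivers at 1000 pairs —
sizes at which Monte-Carlo error is comfortably inside the stated
tolerances while the whole suite runs in minutes.

## Known limitations

Satterthwaite df are approximated by residual df; the SMD definition
(adjusted mean difference over raw pooled SD) is one of several reasonable
readings and is recorded in the output metadata; PBAD adjustment on
synthetic data removes part of the genuine MD signal because the simulated
brain-age difference loads on the same latent factor; the synthetic
cohort's absolute AUCs (~0.6) are far below the published ones, by
construction — only signs and orderings are comparable at desk scale.
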
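# Methods

This note documents the models implemented in `lipidrisk`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Relationship matrices

Pedigrees are records of (individual, father, mother, sex); parents must
precede children in the implied DAG (cycles are rejected).  The classical
kinship coefficient φ is computed by the founder-down recursion
φ(i,i) = (1 + φ(f_i, m_i))/2, φ(i,j) = (φ(f_i,j) + φ(m_i,j))/2, with
unknown parents contributing zero.  Reported coefficients are on the
doubled scale 2φ (numerator relationship matrix), so self/MZ-twin = 1,
parent–offspring and full siblings = 0.5, grandparent–grandchild,
avuncular, half-siblings and double first cousins = 0.25, first cousins
= 0.125.  Under this recursion third- through sixth-degree relatives have
coefficients 2φ = 0.125, 0.0625, 0.03125, 0.015625; published tables
occasionally list much smaller values for these classes (e.g. 0.0078 for
third degree), which do not follow from the recursion and are not
reproduced here.  The recursion is validated in the test suite against a
Monte-Carlo gene-dropping estimate of expected allele sharing.

## Trait normalization and multiplicity

Lipid concentrations enter every model through the rank-based
inverse-normal transform z_i = Φ⁻¹((r_i − c)/n) with average ranks for
ties.  The rank offset c is 0.5 by default (symmetric plotting
positions); c = 0.375 gives Blom scores and is configurable.  The offset
and tie rule are our choices — the transform is usually described only as
"ranking, CDF, z-values" — and neither affects rank-based downstream
statistics.  Lipidome-wide p-values are adjusted by Benjamini–Hochberg
step-up FDR (delegated to statsmodels, checked in tests against an O(m²)
definitional implementation).  Tertile grouping cuts at the empirical 1/3
and 2/3 quantiles; grouping that would empty a tertile (heavy ties)
raises instead of silently collapsing.

## Kinship-frailty Cox model

The hazard is λ_i(t) = λ₀(t)·exp(x_i'β + b_i) with b ~ N(0, σ²R), R the
relationship matrix.  Estimation maximizes the penalized partial
likelihood ppl(β,b) = pl(Xβ + b) − b'(σ²R)⁻¹b/2 by Newton–Raphson with
step-halving; σ² is profiled on the Laplace-approximate marginal
likelihood, log L(σ²) ≈ ppl(β̂,b̂) − ½log|σ²R| − ½log|H_bb + (σ²R)⁻¹|,
using a coarse log grid (0.01–8, 7 points) followed by bounded Brent
refinement (xatol 0.05 on log σ²).  With σ² = 0 or no kinship matrix the
model reduces exactly to an ordinary Cox fit, which is verified against
an independent partial-likelihood implementation (lifelines) to |Δβ| <
1e-4 in the test suite.  Tied event times use the Efron approximation; a
vectorized cumulative-sum path handles the common untied case and is
checked against the generic Efron loop.  Fixed-effect covariances come
from the inverse penalized information (β block); p-values are Wald.
Absolute risks use the Breslow baseline cumulative hazard with
fixed-effects linear predictors.

Screening fits one frailty-Cox model per inverse-normalized species,
adjusted for age, age², sex, age×sex, age²×sex, systolic and diastolic
blood pressure, waist, BMI, total and HDL cholesterol, triglycerides and
anti-lipid/anti-hypertensive drug use (age is centred before squaring to
tame collinearity).  By default the frailty variance is profiled once on
the covariates-only model and held fixed across species — one outer
optimization instead of 319 — which is our efficiency choice; per-species
profiling is available.  Per-species fit failures are recorded in the
output table, never fatal.  Backward elimination starts from the joint
adjusted model with all candidate species, repeatedly drops the candidate
with the largest Wald p above `alpha_stay` (default 0.05, our choice) and
refits; clinical covariates are never dropped.  Mixed refits are the
default at each step (plain Cox refits available).  The score weights are
the final model's species coefficients.

## Liability-threshold model and the family ROC

For a binary outcome the latent liability is l = μ + x'β + g + e with
g ~ N(0, σ_g²R), e ~ N(0,1), y = 1{l > 0}, heritability
h² = σ_g²/(1+σ_g²).  For fixed σ_g² the joint penalized probit likelihood
is maximized by Newton; h² is profiled on the Laplace marginal over the
grid {0, 0.2, 0.4, 0.6, 0.8} (fixable).  The implied prevalence is
Φ(η_ref/√(1+σ_g²)) at reference (mean) covariates.  With no kinship
matrix the model is ordinary probit (statsmodels); with no covariates the
prevalence is exactly the sample case fraction.  All-case or all-control
subsets clamp the prevalence to (0.5/n, 1−0.5/n) with a warning.

The family ROC evaluates, at each cutoff c of a continuous predictor, the
adjusted proportion above the cutoff p, and the adjusted outcome
prevalences p1 (above) and p0 (below), then maps them to

    sens = p·p1 / [p·p1 + (1−p)·p0]
    spec = (1−p)(1−p0) / [(1−p)(1−p0) + p(1−p1)] .

All distinct observed values serve as cutoffs up to 200, beyond which a
200-point quantile grid is used (a practical cap on "the entire spectrum
of cutoffs").  Whether p itself should be model-adjusted is ambiguous; the
default uses the same liability machinery, with the plain proportion
available (`adjusted_proportion=False`).  The curve is anchored at (0,0)
and (1,1) with monotone sensitivity; the AUC is trapezoidal with the
Hanley–McNeil standard error (Q1 = A/(2−A), Q2 = 2A²/(1+A)), and two AUCs
are compared via z = (A₁−A₂)/√(SE₁²+SE₂²−2r·SE₁SE₂), χ² = z² on 1 df
(the AUC correlation r defaults to 0 and can be estimated by bootstrap).
With identity R and no covariates the whole construction collapses
algebraically to the empirical ROC — the key correctness property, tested
at n = 2000.

## Incremental value

Uno's C is the IPCW concordance truncated at a horizon τ: comparable
pairs (i events before τ and before T_j) weighted by 1/Ĝ(T_i⁻)², Ĝ the
Kaplan–Meier of the censoring distribution.  IDI is the change in
discrimination slope on predicted risks at τ; continuous NRI counts
signed risk-change directions; both use IPCW status weights (cases before
τ: 1/Ĝ(T⁻); at-risk past τ: 1/Ĝ(τ); censored before τ: 0).  The
five-metric report (LRχ², ΔAIC, ΔC, IDI, NRI) fits nested frailty-Cox
models and bootstraps families as blocks in pedigree cohorts (subjects
otherwise).  Default horizons: 10 years for exact-time cohorts, 5 for
interval cohorts.  Under no censoring all three metrics reduce exactly to
their definitional brute-force forms, which the tests assert.

## Poisson person-time validation

When only end-of-follow-up status is known, incidence is modelled as
log-linear Poisson with log person-years as offset; three designs are
standard: unadjusted, clinical-covariate-adjusted, prediabetes-adjusted.
Rate ratios are reported per SD of the score, the SD taken from the
validation cohort itself.  Recalibration refits the score species jointly
in the Poisson design and adopts the new coefficients as weights.
Bootstrap CIs are percentile-type over subject resamples (the CI type is
our choice).  Cuzick's trend test uses group scores 1..k on average ranks
with a tie-corrected variance and normal approximation; it is validated
against a permutation oracle.

## Insulin-resistance panel

HOMA-IR = FPG[mg/dl]·FPI[IU/L]/405; QUICKI = 1/(log₁₀FPI + log₁₀FPG) —
base-10 logs per the original index definition, since bare "log" is
ambiguous; McAuley = exp(2.63 − 0.28·ln FPI − 0.31·ln TG[mmol/l]) with
natural logs as printed in its source.  FPI units are taken as printed
(IU/L); µIU/ml conventions rescale McAuley and are left to the caller.
Non-positive inputs yield per-measure missing values.  Tertile
association reports medians/IQRs, Kruskal–Wallis p, and the
Koenker–Machado pseudo-R1 at the median from quantile regression on
tertile indicators (the "R² from quantile regression" is not otherwise
pinned down).

## Cost-effectiveness

Each strategy is a mechanical tree: screen → risk groups (HR/MR/LR, the
no-screening arm uses a population-average group) → per-group
intervention → 5-year diabetes chance node with p_group·(1−efficacy) →
cost/QALY leaf.  Efficacies are 0.58 (lifestyle) and 0.31 (metformin
500 mg daily).  Screening costs: LRS assay 11 US$ (≈1 US$ × 3 species +
4 US$ mass spectrometry + 4 US$ manpower), plus once-only plasma
preparation (29 US$) and primary-care visit (50 US$) for LRS-containing
strategies — charged once even when FPG and LRS are combined.  Costs and
QALYs are undiscounted 5-year totals from a single-payer perspective;
WTP is 4450.12 US$ per 5-year program.  Rollback is exact backward
induction (tested against path enumeration); ICERs flag non-positive
incremental QALYs as undefined/dominated; NMB = WTP·QALY − cost.
Sensitivity analysis: one-way tornado scans of the expected NMB and a
one-way microsimulation (default 1000 uniform draws over the parameter
range) smoothed per strategy by degree-4 least-squares polynomials of the
cost/QALY ratio.

The default cost/utility table is a *reconstruction* on the scale of
published Diabetes Prevention Program economics (5-year lifestyle program
≈ 2780 US$, generic metformin ≈ 270 US$, 5-year medical costs 13 700 vs
3 600 US$ with/without diabetes, 5-year QALYs 4.50/4.10 without/with
diabetes, small intervention-specific utility offsets); the exact
published tables are not available, every value is overridable through
`CeaInputs`, and the composition of the combined strategies (which group
receives which intervention) is likewise a documented assumption.  The
LRS high-score cutoff for risk grouping uses the Youden-optimal point of
the family ROC.  Risk-group probabilities are treated as shared across
screening tests of the same cohort, which makes cross-strategy total risk
only approximately constant — adequate for the qualitative comparisons
the defaults support, not for policy numbers.

## Synthetic cohorts

The generator emulates two designs: a pedigree cohort (default 42
three-generation families, ≈750 subjects, follow-up capped at 23 years
with exponential dropout giving ≈10 person-years per subject and ≈20%
cumulative incidence) with usable event times, and an unrelated cohort
(default 644 subjects, ≈6000 person-years) recording only
end-of-follow-up status — the interval-detection setting that motivates
the Poisson validation models.  Lipid species are generated on a latent
scale with per-species polygenic covariance h²R + (1−h²)I (default
h² = 0.35), optional within-block factor correlation, then mapped to
log-normal concentrations (wide inter-individual spread).  Three of ten
candidate species carry planted log hazard ratios per SD of the
inverse-normal scale (+0.42, −0.34, +0.54 — the signs and magnitudes of
the published three-species score); the remaining 309 species are null.
Event times follow an exponential baseline (Weibull shape configurable;
exponential chosen for closed-form inversion), baseline hazard 0.013 per
person-year.  Whether detected events carry their exact time, the
interval midpoint, or the visit date is configurable
(`event_time_convention`), since the source analyses imply usable event
times without stating the convention.  Insulin-resistance measures are
attached post hoc with a tunable latent coupling to the planted lipid
signal: fasting insulin, leptin (+BMI dependence) and adiponectin
(inverse) move monotonically with the coupling; fasting glucose stays
consistent with the baseline glycemic class.

Cohort tables are plain pandas DataFrames written/read as CSV/TSV
(`write_cohort`/`read_cohort`).  Column dictionary: `subject_id`;
`family_id` (pedigree cohort only); `sex` (1 = male); `age` (years);
`bmi` (kg/m²); `waist` (cm); `sbp`/`dbp` (mmHg); `total_chol`,
`hdl_chol`, `triglycerides` (mmol/l); `antilipid_drug`, `antihtn_drug`,
`family_history_t2d` (0/1); `prediabetes` (0/1) with `glycemic_class`
(`NGT`/`prediabetes`); `fpg` (mg/dl, consistent with the glycemic
class); one positive concentration column per lipid species (arbitrary
units; planted species carry their shorthand names, others
`SPECIES_###`); outcome columns `time` (years) and `event` (0/1) for the
pedigree cohort, or `person_years` and `event` for the unrelated cohort;
and, after `simulate_ir_measures`, `fpi` (IU/L), `leptin` and
`adiponectin` (µg/l-scale).  Pedigrees are written as 4-column PED files
(id, father, mother, sex; 0 = missing parent).

What the generator does *not* emulate: assortative mating, shared
household environment, age-dependent lipid trajectories, measurement
batch effects, competing mortality, or the real cohorts' marginal
distributions beyond order of magnitude.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under a known truth, not the reproducibility of any real-data estimate.

## Numerical and scale choices

Problem sizes in the test suite and the end-to-end script (e.g. 319
species at n ≈ 750, 200-replicate coverage studies, 1000-replicate
bootstrap) were chosen so a full run completes in minutes on one core
while keeping Monte-Carlo error well inside the asserted bands.  Newton
iterations stop at relative log-likelihood change 1e-8–1e-9; semidefinite
relationship matrices are floored at eigenvalue 1e-8; exponentials in
partial likelihoods are max-shifted.  Known limitations: no left
truncation, no time-varying covariates, no competing risks, categorical
NRI not implemented, and the liability model uses a Laplace/PQL
approximation whose heritability estimate is biased toward zero in small
subsets (its prevalence output, the quantity the ROC consumes, is far
less sensitive).
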
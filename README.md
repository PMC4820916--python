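# lipidrisk

Development, validation and health-economic evaluation of **lipidomic risk
scores (LRS)** for predicting incident type 2 diabetes (T2D) from
family-cohort data.

Disturbed lipid metabolism precedes overt dysglycemia, so a weighted
combination of plasma lipid species can flag future diabetes in people who
are still normoglycemic.  The statistical obstacle is that discovery
cohorts are often *family* studies: subjects are genetically related, so
naive survival screens, ROC curves and prevalence estimates are biased by
kinship.  `lipidrisk` implements the full methodology for this setting,
for biostatisticians and epidemiologists who want to build or stress-test
such scores:

* **Kinship machinery** — pairwise genetic-relationship matrices from
  PED-style pedigrees (parent–offspring/sibling 0.5,
  grandparent/avuncular/half-sibling/double-first-cousin 0.25, …).
* **Kinship-frailty Cox models** — proportional hazards with a correlated
  Gaussian random effect, covariance σ²·R, fitted by penalized partial
  likelihood with a Laplace profile over σ².  Used for lipidome-wide
  screening (one adjusted model per inverse-normalized species,
  Benjamini–Hochberg FDR), backward-elimination stepwise selection, and
  tertile survival contrasts.
* **The score** — `LRS = Σ_s w_s · i(concentration_s)`, where `i(·)` is
  the rank-based inverse-normal transform and the weights are the
  coefficients of the final multivariable survival model, e.g. the
  three-species development-cohort score
  `0.4176·i(Cer(d18:0/18:0)) − 0.3443·i(LPC(O-22:1)) + 0.5361·i(TG(16:0_18:0_18:1))`.
* **Family-data ROC** — cutoff-wise liability-threshold (polygenic probit)
  prevalence estimates transformed to Bayesian sensitivity/specificity,
  assembled into an ROC curve with Hanley–McNeil AUC standard errors and
  χ² AUC comparisons.
* **Incremental value** — likelihood-ratio χ², ΔAIC, Uno's IPCW survival
  C-statistic, integrated discrimination improvement (IDI) and continuous
  net reclassification (NRI) for adding the LRS to clinical predictors.
* **External validation** — Poisson person-time models (log follow-up as
  offset) for cohorts without exact event dates, direct and recalibrated
  score application, bootstrap CIs, Cuzick trend tests.
* **Insulin resistance** — HOMA-IR, QUICKI, McAuley index and the
  leptin/adiponectin ratio, with tertile associations (Kruskal–Wallis,
  quantile-regression pseudo-R²).
* **Cost-effectiveness** — decision-tree rollback for seven
  screening-and-intervention strategies (no screening, FPG- and LRS-based
  screening with lifestyle or metformin, combined strategies), ICER and
  net monetary benefit at a willingness-to-pay of 4450.12 US$ per 5-year
  prevention program, tornado scans and one-way microsimulation with
  fourth-order polynomial smoothing.
* **Synthetic cohorts** — a generator for pedigree-structured and
  unrelated cohorts with heritable lipid species, planted
  proportional-hazards effects and coupled insulin-resistance measures,
  so the entire pipeline is testable without restricted data.

## Worked example

```python
import numpy as np
from lipidrisk import (
    SimulationConfig, simulate_pedigree_cohort, build_relationship_matrix,
    screen_lipidome, backward_eliminate, build_lrs, tertile_hazards,
)

cfg = SimulationConfig(seed=1)                  # ~42 families, ~750 subjects
cohort, pedigree = simulate_pedigree_cohort(cfg)
R = build_relationship_matrix(pedigree)

table = screen_lipidome(cohort, species=cfg.species_names, kinship=R,
                        fdr_threshold=0.2)
candidates = list(table.loc[table.significant, "species"])
fit, retained = backward_eliminate(cohort, candidates, kinship=R)
lrs = build_lrs(fit, retained)
score = lrs.score(cohort)

out = tertile_hazards(cohort, score, kinship=R)
print(out["stratified"].summary().loc[["tertile_middle", "tertile_upper"], ["HR", "p"]])
```

With seed 1 this prints

```
                      HR             p
tertile_middle  1.941814  1.181908e-02
tertile_upper   5.693663  9.016053e-13
```

i.e. subjects in the middle and upper LRS tertiles progress to diabetes
roughly 2 and 6 times faster than the lower tertile after adjusting for
the clinical covariate set and the kinship structure (prediabetes-
stratified frailty Cox model; the generator plants effects on three of
319 species, so the magnitudes reflect the planted signal plus selection).

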
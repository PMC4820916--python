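"""Lipidome-wide survival screening and backward elimination.

Each lipid species is inverse-normalized and tested one at a time in a
kinship-frailty Cox model adjusted for the standard clinical covariate
set (age, age squared, sex, age-by-sex interactions, systolic and
diastolic blood pressure, waist circumference, BMI, total and HDL
cholesterol, triglycerides and drug-use flags).  Species-level Wald
p-values are corrected by the Benjamini-Hochberg procedure and species
passing the FDR threshold become candidates for backward-elimination
stepwise modeling, which retains the jointly significant species that
define the lipidomic risk score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cox import FrailtyCox, SingularModelError, ConvergenceError
from .transforms import bh_fdr, inverse_normalize

#: Clinical adjustment covariates expected as cohort-table columns.
ADJUSTMENT_COLUMNS = [
    "age",
    "sex",
    "sbp",
    "dbp",
    "waist",
    "bmi",
    "total_chol",
    "hdl_chol",
    "triglycerides",
    "antilipid_drug",
    "antihtn_drug",
]


def adjustment_design(cohort: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Build the standard covariate design: adds age^2 and age-by-sex terms."""
    cols = list(columns) if columns is not None else list(ADJUSTMENT_COLUMNS)
    X = cohort[cols].astype(float).copy()
    if "age" in X:
        age_c = X["age"] - X["age"].mean()  # centred to tame collinearity
        X["age"] = age_c
        X["age_sq"] = age_c**2
        if "sex" in X:
            X["age_x_sex"] = age_c * X["sex"]
            X["age_sq_x_sex"] = age_c**2 * X["sex"]
    return X


def screen_lipidome(
    cohort: pd.DataFrame,
    species=None,
    kinship=None,
    fdr_threshold: float = 0.2,
    adjustment=None,
    sigma2=None,
    share_frailty_variance: bool = True,
) -> pd.DataFrame:
    """Species-by-species adjusted frailty-Cox screen of the lipidome.

    Parameters
    ----------
    cohort : DataFrame
        Must contain ``time``, ``event``, the species columns and the
        clinical adjustment columns.
    species : sequence of str, optional
        Columns to screen.  Pass explicitly in pipelines; the default
        heuristically picks columns that look like lipid-species names
        (generator-style ``SPECIES_###`` or shorthand with parentheses).
    kinship : DataFrame/ndarray, optional
        Relationship matrix; ``None`` screens with ordinary Cox models.
    sigma2 : float, optional
        Fix the frailty variance.  When ``share_frailty_variance`` and
        ``sigma2`` is None, the variance is profiled once on the
        covariates-only model and reused across species (one outer
        optimization instead of one per species).

    Returns
    -------
    DataFrame with one row per species: ``beta``, ``se``, ``p``, ``p_fdr``,
    ``significant`` (p_fdr below threshold), ``error`` (fit failures are
    recorded, not raised), sorted by p.
    """
    if species is None:
        species = [c for c in cohort.columns if c.startswith("SPECIES_") or "(" in c]
    if len(species) < 2:
        raise ValueError("need at least 2 species to screen")
    if not 0 <= fdr_threshold <= 1:
        raise ValueError("fdr_threshold must lie in [0, 1]")
    X_adj = adjustment_design(cohort) if adjustment is None else adjustment.copy()

    if kinship is not None and sigma2 is None and share_frailty_variance:
        base = FrailtyCox(cohort["time"], cohort["event"], X_adj, kinship=kinship)
        sigma2 = base.fit().frailty_variance

    rows = []
    for sp in species:
        X = X_adj.copy()
        X.insert(0, sp, inverse_normalize(cohort[sp].to_numpy(), name=sp).values)
        try:
            model = FrailtyCox(cohort["time"], cohort["event"], X, kinship=kinship)
            fit = model.fit(sigma2=sigma2)
            rows.append(
                {
                    "species": sp,
                    "beta": fit.params[0],
                    "se": fit.bse[0],
                    "p": fit.pvalues[0],
                    "error": "",
                }
            )
        except (SingularModelError, ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"species": sp, "beta": np.nan, "se": np.nan, "p": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_fdr"] = np.nan
    table.loc[ok, "p_fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["significant"] = table["p_fdr"] <= fdr_threshold
    return table.sort_values("p", na_position="last").reset_index(drop=True)


def backward_eliminate(
    cohort: pd.DataFrame,
    candidates,
    kinship=None,
    alpha_stay: float = 0.05,
    adjustment=None,
    sigma2=None,
):
    """Backward-elimination stepwise selection among candidate species.

    Starting from the joint adjusted model containing every candidate
    (inverse-normalized), repeatedly drops the candidate with the largest
    Wald p-value above ``alpha_stay`` and refits, until all remaining
    candidates are significant.  Clinical covariates are never dropped.

    Returns ``(fit, retained)``; an empty candidate survival set returns
    ``(None, [])`` with a warning.
    """
    import warnings

    candidates = list(candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate species")
    X_adj = adjustment_design(cohort) if adjustment is None else adjustment.copy()
    retained = list(candidates)
    fit = None
    while retained:
        X = X_adj.copy()
        for k, sp in enumerate(retained):
            X.insert(k, sp, inverse_normalize(cohort[sp].to_numpy(), name=sp).values)
        model = FrailtyCox(cohort["time"], cohort["event"], X, kinship=kinship)
        fit = model.fit(sigma2=sigma2)
        pvals = fit.pvalues[: len(retained)]
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha_stay:
            return fit, retained
        retained.pop(worst)
    warnings.warn("backward elimination removed every candidate species")
    return None, []
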
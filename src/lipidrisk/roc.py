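"""Kinship-adjusted ROC curves for family data.

In a pedigree cohort the empirical sensitivity and specificity of a
dichotomized continuous predictor are biased by the relatedness of the
subjects.  The family-data ROC replaces the empirical 2x2 proportions at
each cutoff with liability-threshold (polygenic probit) prevalence
estimates: for a cutoff c,

    p  = adjusted proportion of subjects above c,
    p1 = adjusted outcome prevalence among subjects above c,
    p0 = adjusted outcome prevalence among subjects below c,

which are converted to the Bayesian sensitivity/specificity pair

    sens = p*p1 / [p*p1 + (1-p)*p0]
    spec = (1-p)*(1-p0) / [(1-p)*(1-p0) + p*(1-p1)].

Scanning the observed cutoffs yields the ROC curve; the area under it is
the trapezoidal AUC with the Hanley-McNeil standard error, and two AUCs
are compared with a 1-df chi-square statistic.  With an identity
relationship matrix and no covariates the whole construction collapses to
the classical empirical ROC, which is the key correctness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skmetrics

from .liability import estimate_prevalence


@dataclass
class RocCurve:
    """An ROC curve: cutoffs with (sensitivity, specificity), AUC and SE."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float = field(default=np.nan)
    auc_se: float = field(default=np.nan)
    n_pos: int = 0
    n_neg: int = 0

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "one_minus_specificity": self.fpr,
            }
        )


def bayes_sens_spec(p: float, p1: float, p0: float):
    """Bayesian sensitivity and specificity from cutoff-wise prevalences.

    ``p`` is the probability of lying above the cutoff, ``p1``/``p0`` the
    outcome prevalences above/below the cutoff.
    """
    for name, v in (("p", p), ("p1", p1), ("p0", p0)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    den_sens = p * p1 + (1 - p) * p0
    den_spec = (1 - p) * (1 - p0) + p * (1 - p1)
    if den_sens == 0 or den_spec == 0:
        # the two denominators sum to 1, so at most one can vanish; either
        # way the corresponding rate is undefined (0/0)
        raise ZeroDivisionError("undefined sensitivity/specificity (zero denominator)")
    return p * p1 / den_sens, (1 - p) * (1 - p0) / den_spec


def _augmented(fpr, sens):
    """Sort by FPR and anchor the curve at (0,0) and (1,1)."""
    order = np.argsort(np.asarray(fpr), kind="stable")
    fpr = np.concatenate([[0.0], np.asarray(fpr)[order], [1.0]])
    sens = np.concatenate([[0.0], np.asarray(sens)[order], [1.0]])
    # enforce monotone non-decreasing sensitivity along the curve
    sens = np.maximum.accumulate(sens)
    return fpr, sens


def roc_curve(
    outcome,
    predictor,
    covariates=None,
    kinship=None,
    heritability=None,
    max_cutoffs: int = 200,
    adjusted_proportion: bool = True,
) -> RocCurve:
    """Family-data ROC for a continuous predictor of a binary outcome.

    At each observed cutoff the three probabilities (p, p1, p0) are
    estimated by the liability-threshold machinery (accounting for the
    kinship matrix and fixed covariates when supplied) and mapped through
    :func:`bayes_sens_spec`.  All distinct predictor values are used as
    cutoffs up to ``max_cutoffs``, beyond which a quantile-spaced grid of
    that size is taken.  ``adjusted_proportion=False`` uses the plain
    sample proportion above each cutoff for p.
    """
    y = np.asarray(outcome, dtype=int)
    x = np.asarray(predictor, dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 10:
        raise ValueError("predictor needs at least 10 distinct values")
    if len(distinct) > max_cutoffs:
        qs = np.linspace(0, 1, max_cutoffs + 2)[1:-1]
        cutoffs = np.unique(np.quantile(x, qs))
    else:
        cutoffs = distinct[:-1]  # topmost value leaves an empty 'above' side
    K = None
    if kinship is not None:
        K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
    Xc = None
    if covariates is not None:
        Xc = covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else np.asarray(covariates)

    sens_list, spec_list, used = [], [], []
    for c in cutoffs:
        above = x > c
        if above.sum() == 0 or (~above).sum() == 0:
            continue
        if adjusted_proportion:
            p = estimate_prevalence(above.astype(int), exog=Xc, kinship=K,
                                    heritability=heritability).prevalence
        else:
            p = above.mean()
        sub_args = {}
        p1 = estimate_prevalence(
            y[above],
            exog=None if Xc is None else Xc[above],
            kinship=None if K is None else K[np.ix_(above, above)],
            heritability=heritability,
        ).prevalence
        p0 = estimate_prevalence(
            y[~above],
            exog=None if Xc is None else Xc[~above],
            kinship=None if K is None else K[np.ix_(~above, ~above)],
            heritability=heritability,
        ).prevalence
        s, sp = bayes_sens_spec(p, p1, p0)
        sens_list.append(s)
        spec_list.append(sp)
        used.append(c)
    if len(used) < 3:
        raise ValueError("fewer than 3 valid cutoffs")
    fpr, sens = _augmented([1 - s for s in spec_list], sens_list)
    auc = float(np.trapezoid(sens, fpr))
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    return RocCurve(
        cutoffs=np.asarray(used),
        sensitivity=np.asarray(sens_list),
        specificity=np.asarray(spec_list),
        auc=auc, auc_se=se, n_pos=n_pos, n_neg=n_neg,
    )


def empirical_roc(outcome, predictor) -> RocCurve:
    """Classical empirical ROC (no kinship adjustment)."""
    y = np.asarray(outcome, dtype=int)
    x = np.asarray(predictor, dtype=float)
    fpr, tpr, thr = _skmetrics.roc_curve(y, x)
    auc = float(_skmetrics.auc(fpr, tpr))
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    return RocCurve(
        cutoffs=thr,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=auc,
        auc_se=hanley_mcneil_se(auc, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC.

    Uses Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case and one control")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def auc_hanley(curve: RocCurve, n_pos: int = None, n_neg: int = None):
    """Trapezoidal AUC with Hanley-McNeil SE for an assembled curve."""
    fpr, sens = _augmented(curve.fpr, curve.sensitivity)
    auc = float(np.trapezoid(sens, fpr))
    n_pos = curve.n_pos if n_pos is None else n_pos
    n_neg = curve.n_neg if n_neg is None else n_neg
    return auc, hanley_mcneil_se(auc, n_pos, n_neg)


def compare_aucs(auc_a, se_a, auc_b, se_b, correlation: float = 0.0):
    """1-df chi-square comparison of two AUC estimates.

    z = (A1 - A2) / sqrt(se1^2 + se2^2 - 2 r se1 se2); returns
    (chi2, p) with chi2 = z^2.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    var = se_a**2 + se_b**2 - 2 * correlation * se_a * se_b
    if var <= 0:
        raise ValueError("non-positive variance of the AUC difference")
    z = (auc_a - auc_b) / np.sqrt(var)
    chi2 = z**2
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def auc_correlation_bootstrap(outcome, predictor_a, predictor_b,
                              n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap correlation between two predictors' AUC estimates.

    Needed by :func:`compare_aucs` when both curves come from the same
    subjects: resamples subjects with replacement and correlates the two
    empirical AUCs across replicates.
    """
    y = np.asarray(outcome, dtype=int)
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].sum() in (0, n):
            continue
        aucs.append(
            (_skmetrics.roc_auc_score(y[idx], a[idx]), _skmetrics.roc_auc_score(y[idx], b[idx]))
        )
    aucs = np.asarray(aucs)
    if len(aucs) < 10:
        raise ValueError("too few valid bootstrap replicates")
    return float(np.corrcoef(aucs[:, 0], aucs[:, 1])[0, 1])


def youden_cutoff(curve: RocCurve) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    j = curve.sensitivity + curve.specificity - 1.0
    return float(curve.cutoffs[int(np.argmax(j))])
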
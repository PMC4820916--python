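"""External-cohort validation with Poisson person-time models.

When only end-of-follow-up diabetes status is available (exact diagnosis
dates unknown), the score is validated with log-link Poisson regression
using the log person-time of follow-up as an offset, which accounts for
length-time bias.  Three standard designs are provided: unadjusted (U),
adjusted for clinical covariates (C) and adjusted for baseline
prediabetes (P).  The incidence-rate ratio is reported per standard
deviation of the score.  The score can also be recalibrated by refitting
the three-species Poisson model on the validation cohort; robustness is
assessed with a subject-resampling bootstrap, and the gradient of median
scores across ordered outcome groups is tested with Cuzick's
nonparametric trend test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .score import LrsModel
from .transforms import inverse_normalize

#: Clinical adjustment set for the validation models.
VALIDATION_ADJUSTMENT = [
    "age",
    "sex",
    "sbp",
    "dbp",
    "bmi",
    "total_chol",
    "hdl_chol",
    "triglycerides",
    "family_history_t2d",
    "antihtn_drug",
    "antilipid_drug",
]


class PoissonOffset:
    """Poisson person-time model (statsmodels GLM with log offset).

    ``endog`` is the event count (0/1 for single-record subjects),
    ``exposure`` the person-years of follow-up.
    """

    def __init__(self, endog, exog, exposure, names=None):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            exog = exog.to_numpy()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            self.exog = self.exog.T
        self.exposure = np.asarray(exposure, dtype=float)
        if np.any(self.exposure <= 0):
            raise ValueError("person-time must be positive for every subject")
        if self.endog.sum() == 0:
            raise ValueError("zero events in cohort")
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]

    def fit(self) -> "PoissonOffsetResults":
        X = sm.add_constant(self.exog, has_constant="add")
        glm = sm.GLM(
            self.endog, X, family=sm.families.Poisson(), offset=np.log(self.exposure)
        )
        res = glm.fit()
        return PoissonOffsetResults(self, res)


@dataclass
class PoissonOffsetResults:
    model: PoissonOffset
    _res: object

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._res.params)[1:]  # drop intercept

    @property
    def intercept(self) -> float:
        return float(self._res.params[0])

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._res.bse)[1:]

    @property
    def pvalues(self) -> np.ndarray:
        return np.asarray(self._res.pvalues)[1:]

    @property
    def irr(self) -> np.ndarray:
        """Incidence-rate ratios per unit of each predictor."""
        return np.exp(self.params)

    @property
    def deviance(self) -> float:
        return float(self._res.deviance)

    @property
    def aic(self) -> float:
        return float(self._res.aic)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    def irr_conf_int(self, alpha=0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.irr_conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "IRR": self.irr,
                "se": self.bse,
                "p": self.pvalues,
                "irr_ci95_low": ci[:, 0],
                "irr_ci95_high": ci[:, 1],
            },
            index=self.model.names,
        )


def fit_poisson_offset(
    cohort: pd.DataFrame,
    predictors,
    design: str = "U",
    adjustment=None,
    per_sd: bool = True,
) -> PoissonOffsetResults:
    """Fit one of the three validation designs.

    design 'U' = unadjusted, 'C' = clinical-covariate adjusted,
    'P' = prediabetes-adjusted.  ``per_sd`` scales each predictor by its
    own cohort SD so the IRR refers to a one-SD change.
    """
    predictors = list(predictors)
    X = cohort[predictors].astype(float).copy()
    if per_sd:
        X = X / X.std(ddof=1)
    if design == "C":
        cols = adjustment if adjustment is not None else VALIDATION_ADJUSTMENT
        X = pd.concat([X, cohort[list(cols)].astype(float)], axis=1)
    elif design == "P":
        X = pd.concat([X, cohort[["prediabetes"]].astype(float)], axis=1)
    elif design != "U":
        raise ValueError("design must be one of 'U', 'C', 'P'")
    return PoissonOffset(cohort["event"], X, cohort["person_years"]).fit()


def recalibrate_lrs(cohort: pd.DataFrame, species, training_tag="recalibrated") -> LrsModel:
    """Refit the score species jointly in a Poisson person-time model.

    The new weights are the fitted per-species coefficients on the
    inverse-normal scale of each species in the validation cohort.
    """
    species = list(species)
    missing = [sp for sp in species if sp not in cohort.columns]
    if missing:
        raise KeyError(f"species missing from cohort: {missing}")
    X = pd.DataFrame(
        {sp: inverse_normalize(cohort[sp].to_numpy(), name=sp).values for sp in species}
    )
    res = PoissonOffset(cohort["event"], X, cohort["person_years"]).fit()
    return LrsModel(species=species, weights=[float(w) for w in res.params],
                    training_tag=training_tag)


def bootstrap_validate(
    cohort: pd.DataFrame,
    score: np.ndarray,
    n_reps: int = 1000,
    design: str = "U",
    seed: int = 0,
    alpha: float = 0.05,
):
    """Percentile bootstrap CI for the per-SD IRR of a score.

    Resamples subjects with replacement ``n_reps`` times, refitting the
    chosen Poisson design each time.  Returns (irr_point, (lo, hi), reps).
    """
    if n_reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    df["_score"] = np.asarray(score, dtype=float)
    point = float(fit_poisson_offset(df, ["_score"], design=design).irr[0])
    n = len(df)
    reps = []
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        sample = df.iloc[idx].reset_index(drop=True)
        if sample["event"].sum() == 0:
            continue
        try:
            reps.append(float(fit_poisson_offset(sample, ["_score"], design=design).irr[0]))
        except (ValueError, np.linalg.LinAlgError):
            continue
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, (float(lo), float(hi)), reps


def cuzick_trend(values, groups):
    """Cuzick's nonparametric test for trend across ordered groups.

    Wilcoxon-type rank statistic with group scores 1..k and a normal
    approximation (average ranks for ties; tie-corrected variance).
    Returns (z, p_two_sided).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cats = pd.unique(groups)
    if len(cats) < 2:
        raise ValueError("need at least 2 ordered groups")
    scores = {c: i + 1 for i, c in enumerate(cats)}
    l = np.array([scores[g] for g in groups], dtype=float)
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    T = float(np.sum(l * ranks))
    n_j = np.array([(groups == c).sum() for c in cats], dtype=float)
    l_j = np.arange(1, len(cats) + 1, dtype=float)
    L1 = float(np.sum(l_j * n_j))
    L2 = float(np.sum(l_j**2 * n_j))
    ET = L1 * (n + 1) / 2.0
    # tie correction factor on the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    varT = tie * (n + 1) / 12.0 * (n * L2 - L1**2)
    if varT <= 0:
        raise ValueError("degenerate trend statistic (all values tied?)")
    z = (T - ET) / np.sqrt(varT)
    return float(z), float(2 * stats.norm.sf(abs(z)))
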
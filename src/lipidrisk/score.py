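"""Lipidomic risk score (LRS) construction, scoring and tertile survival.

The LRS is a weighted sum of inverse-normalized plasma concentrations of
the retained lipid species, the weights being the coefficients of the
final backward-elimination Cox model, e.g. for the three-species score

    LRS = 0.4176 * i(Cer(d18:0/18:0)) - 0.3443 * i(LPC(O-22:1))
          + 0.5361 * i(TG(16:0_18:0_18:1))

where i(L) is the inverse-normal transform of species L.  Subjects are
grouped by LRS tertiles (lower tertile = reference) and contrasted in
three complementary frailty-Cox designs: prediabetes-stratified,
restricted to normoglycemic subjects, and with tertile-by-prediabetes
interaction terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cox import FrailtyCox
from .screening import adjustment_design
from .transforms import inverse_normalize, tertile_groups

#: Published development-cohort weights for the three-species score.
PUBLISHED_WEIGHTS = {
    "Cer(d18:0/18:0)": 0.4176,
    "LPC(O-22:1)": -0.3443,
    "TG(16:0_18:0_18:1)": 0.5361,
}


@dataclass
class LrsModel:
    """A linear lipidomic risk score: species names and per-SD weights."""

    species: list
    weights: list
    training_tag: str = ""

    def __post_init__(self):
        if len(self.species) != len(self.weights):
            raise ValueError("species and weights must align")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in score")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")

    def score(self, cohort: pd.DataFrame, normalized: bool = False) -> np.ndarray:
        """Score a cohort: sum of weight * inverse-normal concentration.

        ``normalized=True`` treats the stored columns as already on the
        inverse-normal scale.
        """
        total = np.zeros(len(cohort))
        for sp, w in zip(self.species, self.weights):
            if sp not in cohort.columns:
                raise KeyError(f"species {sp!r} missing from cohort")
            col = cohort[sp].to_numpy(dtype=float)
            values = col if normalized else inverse_normalize(col, name=sp).values
            total += w * values
        return total

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "LrsModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls(**json.loads(source))
        with open(source) as fh:
            return cls(**json.load(fh))


def published_lrs() -> LrsModel:
    """The three-species development-cohort score with published weights."""
    return LrsModel(
        species=list(PUBLISHED_WEIGHTS),
        weights=list(PUBLISHED_WEIGHTS.values()),
        training_tag="development-published",
    )


def build_lrs(fit, species, training_tag: str = "") -> LrsModel:
    """Extract score weights for ``species`` from a fitted Cox model."""
    if not fit.converged:
        raise ValueError("cannot build a score from a non-converged fit")
    name_to_coef = dict(zip(fit.model.names, fit.params))
    missing = [sp for sp in species if sp not in name_to_coef]
    if missing:
        raise KeyError(f"species not in fitted model: {missing}")
    return LrsModel(
        species=list(species),
        weights=[float(name_to_coef[sp]) for sp in species],
        training_tag=training_tag,
    )


def tertile_hazards(
    cohort: pd.DataFrame,
    score: np.ndarray,
    kinship=None,
    adjustment=None,
    sigma2=None,
) -> dict:
    """Tertile relative hazards under three designs, plus Kaplan-Meier curves.

    Designs: (1) prediabetes-stratified frailty Cox; (2) restricted to NGT
    subjects; (3) tertile-by-prediabetes interaction model.  The lower
    tertile is the reference in each.  Kaplan-Meier curves per tertile
    come with an event-fraction-by-time extractor.
    """
    groups = tertile_groups(score)
    cohort = cohort.copy()
    cohort["_tertile"] = groups
    X_adj = adjustment_design(cohort) if adjustment is None else adjustment.copy()

    def indicator_design(df, Xa, with_interaction=False):
        X = Xa.copy()
        X.insert(0, "tertile_middle", (df["_tertile"] == "middle").astype(float).to_numpy())
        X.insert(1, "tertile_upper", (df["_tertile"] == "upper").astype(float).to_numpy())
        if with_interaction:
            pre = df["prediabetes"].astype(float).to_numpy()
            X["prediabetes"] = pre
            X["middle_x_prediab"] = X["tertile_middle"].to_numpy() * pre
            X["upper_x_prediab"] = X["tertile_upper"].to_numpy() * pre
        return X

    out = {}
    # 1. stratified by prediabetes
    X = indicator_design(cohort, X_adj)
    fit = FrailtyCox(
        cohort["time"], cohort["event"], X, kinship=kinship,
        strata=cohort["prediabetes"].to_numpy(),
    ).fit(sigma2=sigma2)
    out["stratified"] = fit
    # 2. NGT-restricted
    ngt = cohort["prediabetes"].to_numpy() == 0
    if ngt.sum() == 0 or cohort.loc[ngt, "event"].sum() == 0:
        raise ValueError("empty or event-free NGT stratum")
    kin_ngt = None
    if kinship is not None:
        K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
        kin_ngt = K[np.ix_(ngt, ngt)]
    sub = cohort.loc[ngt].reset_index(drop=True)
    X_sub = indicator_design(sub, X_adj.loc[ngt].reset_index(drop=True))
    out["ngt_only"] = FrailtyCox(
        sub["time"], sub["event"], X_sub, kinship=kin_ngt
    ).fit(sigma2=sigma2)
    # 3. interaction model
    X_int = indicator_design(cohort, X_adj, with_interaction=True)
    out["interaction"] = FrailtyCox(
        cohort["time"], cohort["event"], X_int, kinship=kinship
    ).fit(sigma2=sigma2)
    # Kaplan-Meier per tertile
    km = {}
    for lab in groups.categories:
        mask = (groups == lab)
        fitter = KaplanMeierFitter(label=str(lab))
        fitter.fit(cohort.loc[np.asarray(mask), "time"], cohort.loc[np.asarray(mask), "event"])
        km[str(lab)] = fitter
    out["kaplan_meier"] = km
    out["tertiles"] = groups
    return out


def km_event_fraction(km_fitter, at_time: float) -> float:
    """Cumulative event fraction 1 - S(t) from a fitted Kaplan-Meier curve."""
    s = float(km_fitter.predict(at_time))
    return 1.0 - s
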
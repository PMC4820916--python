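"""Incremental predictive value of an added biomarker in survival models.

Five complementary aspects of improvement when a marker (the LRS) is
added to a baseline risk model: model fit (likelihood-ratio chi-square),
information content (AIC difference), accuracy (Uno's IPCW survival
C-statistic at a fixed horizon), discrimination (integrated
discrimination improvement, IDI) and reclassification (continuous net
reclassification index, NRI).  Event status at the horizon is estimated
with inverse-probability-of-censoring weights (IPCW) from the censoring
Kaplan-Meier curve; confidence intervals come from a bootstrap that
resamples families as blocks in pedigree cohorts (subjects otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cox import FrailtyCox


def _censoring_survival(time, event):
    """KM of the censoring distribution; returns a left-limit evaluator."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - np.asarray(event))
    ts = kmf.survival_function_.index.to_numpy()
    ss = kmf.survival_function_.iloc[:, 0].to_numpy()

    def G(t, left=True):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tq = np.nextafter(t, -np.inf) if left else t
        idx = np.searchsorted(ts, tq, side="right") - 1
        out = np.where(idx >= 0, ss[np.clip(idx, 0, len(ss) - 1)], 1.0)
        return out

    return G


def uno_c(time, event, risk, horizon: float) -> float:
    """Uno's IPCW concordance for risk scores truncated at ``horizon``.

    Comparable pairs (i, j) have subject i experiencing the event before
    both ``horizon`` and T_j; each pair is weighted by the inverse squared
    censoring-survival at T_i.  Ties in risk count one half.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if event[(time <= horizon)].sum() < 2:
        raise ValueError("need at least 2 events before the horizon")
    G = _censoring_survival(time, event)
    num = den = 0.0
    cases = np.flatnonzero((event == 1) & (time < horizon))
    g_at_case = G(time[cases], left=True)
    for k, i in enumerate(cases):
        gi = g_at_case[k]
        if gi <= 0:
            continue
        w = 1.0 / gi**2
        later = time > time[i]
        if not later.any():
            continue
        cmp = np.where(
            risk[i] > risk[later], 1.0, np.where(risk[i] == risk[later], 0.5, 0.0)
        )
        num += w * cmp.sum()
        den += w * later.sum()
    if den == 0:
        raise ValueError("no comparable pairs before horizon")
    return float(num / den)


def _ipcw_status_weights(time, event, horizon):
    """IPCW case/control weights for event status at the horizon.

    Cases: event before/at horizon, weight 1/G(T-).  Controls: still at
    risk past the horizon, weight 1/G(horizon).  Subjects censored before
    the horizon get zero weight.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G = _censoring_survival(time, event)
    is_case = (event == 1) & (time <= horizon)
    is_ctrl = time > horizon
    w = np.zeros(len(time))
    gcase = G(time[is_case], left=True)
    w[is_case] = np.where(gcase > 0, 1.0 / np.where(gcase > 0, gcase, 1.0), 0.0)
    g_h = float(G(np.array([horizon]), left=False)[0])
    if g_h > 0:
        w[is_ctrl] = 1.0 / g_h
    return is_case, is_ctrl, w


def idi_nri(time, event, risk_old, risk_new, horizon: float, n_boot: int = 0, seed: int = 0):
    """IDI and continuous NRI for predicted risks at a horizon, with IPCW.

    IDI is the change in discrimination slope: mean risk difference
    (new - old) among events minus the same among non-events.  Continuous
    NRI counts the signed direction of the risk change:
    [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)].
    Optional bootstrap (``n_boot`` > 0) gives percentile CIs and normal
    p-values.  Identical risk vectors short-circuit to (0, 0).
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)

    def _point(time, event, ro, rn):
        is_case, is_ctrl, w = _ipcw_status_weights(time, event, horizon)
        d = rn - ro
        wc, wn = w[is_case], w[is_ctrl]
        if wc.sum() == 0 or wn.sum() == 0:
            return np.nan, np.nan
        idi = np.average(d[is_case], weights=wc) - np.average(d[is_ctrl], weights=wn)
        up_c = np.average(d[is_case] > 0, weights=wc)
        dn_c = np.average(d[is_case] < 0, weights=wc)
        up_n = np.average(d[is_ctrl] > 0, weights=wn)
        dn_n = np.average(d[is_ctrl] < 0, weights=wn)
        nri = (up_c - dn_c) + (dn_n - up_n)
        return float(idi), float(nri)

    if np.array_equal(risk_old, risk_new):
        result = {"idi": 0.0, "nri": 0.0}
    else:
        idi, nri = _point(np.asarray(time, float), np.asarray(event, int), risk_old, risk_new)
        result = {"idi": idi, "nri": nri}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(risk_old)
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                reps.append(_point(time[idx], event[idx], risk_old[idx], risk_new[idx]))
            except ValueError:
                continue
        reps = np.asarray([r for r in reps if np.all(np.isfinite(r))])
        for k, name in enumerate(("idi", "nri")):
            se = reps[:, k].std(ddof=1)
            result[f"{name}_ci"] = tuple(np.percentile(reps[:, k], [2.5, 97.5]))
            result[f"{name}_p"] = float(2 * stats.norm.sf(abs(result[name]) / se)) if se > 0 else 1.0
    return result


@dataclass
class IncrementalReport:
    """Improvement metrics from adding a marker to a baseline model."""

    lr_chi2: float
    lr_p: float
    delta_aic: float
    c_base: float
    c_augmented: float
    delta_c: float
    idi: float
    nri: float
    horizon: float
    n_boot: int
    idi_ci: tuple = (np.nan, np.nan)
    idi_p: float = np.nan
    nri_ci: tuple = (np.nan, np.nan)
    nri_p: float = np.nan
    delta_c_ci: tuple = (np.nan, np.nan)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.lr_chi2, self.delta_aic, self.delta_c, self.idi, self.nri],
                "p": [self.lr_p, np.nan, np.nan, self.idi_p, self.nri_p],
            },
            index=["LR chi2", "delta AIC", "delta Uno C", "IDI", "continuous NRI"],
        )


def incremental_report(
    cohort: pd.DataFrame,
    base_covariates,
    added_covariates,
    horizon: float,
    kinship=None,
    n_boot: int = 0,
    family_col: str = None,
    seed: int = 0,
    sigma2=None,
) -> IncrementalReport:
    """Fit nested Cox models and quantify the added marker's value.

    The augmented model contains ``base_covariates + added_covariates``;
    risks at ``horizon`` come from each model's Breslow baseline hazard.
    When ``n_boot`` > 0, CIs for the IDI/NRI/delta-C resample families as
    blocks if ``family_col`` is given, else subjects.
    """
    base_covariates = list(base_covariates)
    added_covariates = list(added_covariates)
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=int)

    def fit_pair(df, kin):
        t = df["time"].to_numpy(float)
        e = df["event"].to_numpy(int)
        Xb = df[base_covariates].to_numpy(float) if base_covariates else np.empty((len(df), 0))
        Xa = df[base_covariates + added_covariates].to_numpy(float)
        fb = FrailtyCox(t, e, Xb, kinship=kin, names=base_covariates).fit(sigma2=sigma2)
        fa = FrailtyCox(t, e, Xa, kinship=kin,
                        names=base_covariates + added_covariates).fit(sigma2=sigma2)
        return fb, fa

    fit_base, fit_aug = fit_pair(cohort, kinship)
    lr = max(2 * (fit_aug.llf - fit_base.llf), 0.0)
    df_diff = max(fit_aug.df_model - fit_base.df_model, 1)
    lr_p = float(stats.chi2.sf(lr, df_diff))
    delta_aic = fit_aug.aic - fit_base.aic
    risk_base = fit_base.predict_risk(horizon)
    risk_aug = fit_aug.predict_risk(horizon)
    c_base = uno_c(time, event, risk_base, horizon)
    c_aug = uno_c(time, event, risk_aug, horizon)
    inri = idi_nri(time, event, risk_base, risk_aug, horizon)
    report = IncrementalReport(
        lr_chi2=lr, lr_p=lr_p, delta_aic=delta_aic,
        c_base=c_base, c_augmented=c_aug, delta_c=c_aug - c_base,
        idi=inri["idi"], nri=inri["nri"], horizon=horizon, n_boot=n_boot,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        if family_col is not None:
            blocks = [np.flatnonzero(cohort[family_col] == f) for f in cohort[family_col].unique()]
        else:
            blocks = [np.array([i]) for i in range(len(cohort))]
        reps = []
        for _ in range(n_boot):
            chosen = rng.integers(0, len(blocks), len(blocks))
            idx = np.concatenate([blocks[c] for c in chosen])
            df = cohort.iloc[idx].reset_index(drop=True)
            kin = None
            if kinship is not None:
                K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
                kin = K[np.ix_(idx, idx)]
            try:
                fb, fa = fit_pair(df, kin)
                t = df["time"].to_numpy(float)
                e = df["event"].to_numpy(int)
                rb, ra = fb.predict_risk(horizon), fa.predict_risk(horizon)
                r = idi_nri(t, e, rb, ra, horizon)
                dc = uno_c(t, e, ra, horizon) - uno_c(t, e, rb, horizon)
                reps.append((r["idi"], r["nri"], dc))
            except (ValueError, np.linalg.LinAlgError):
                continue
        if reps:
            reps = np.asarray(reps)
            report.idi_ci = tuple(np.percentile(reps[:, 0], [2.5, 97.5]))
            report.nri_ci = tuple(np.percentile(reps[:, 1], [2.5, 97.5]))
            report.delta_c_ci = tuple(np.percentile(reps[:, 2], [2.5, 97.5]))
            for k, name in ((0, "idi"), (1, "nri")):
                se = reps[:, k].std(ddof=1)
                val = getattr(report, name)
                setattr(report, f"{name}_p",
                        float(2 * stats.norm.sf(abs(val) / se)) if se > 0 else 1.0)
    return report
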
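"""Surrogate insulin-resistance indices and their association with the score.

Six established fasting-state measures of insulin resistance:

* FPG  -- fasting plasma glucose (mg/dl)
* FPI  -- fasting plasma insulin (IU/L)
* HOMA-IR  = FPG * FPI / 405
* QUICKI   = 1 / (log10 FPI + log10 FPG)
* McAuley  = exp(2.63 - 0.28 ln FPI - 0.31 ln TG),  TG in mmol/l
* leptin/adiponectin ratio

QUICKI uses base-10 logarithms (the original index definition); the
McAuley index uses natural logarithms as printed in its source.  Each
index is associated with score tertiles via medians/IQRs, the
Kruskal-Wallis test and the Koenker-Machado pseudo-R1 from median
regression on tertile indicators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

IR_MEASURES = ["fpg", "fpi", "homa_ir", "quicki", "mcauley", "leptin_adiponectin_ratio"]


def compute_ir_panel(fpg, fpi, triglycerides, leptin, adiponectin) -> pd.DataFrame:
    """Evaluate the six insulin-resistance measures element-wise.

    Non-positive inputs yield missing values for the affected measures
    only.  Units: FPG mg/dl, FPI IU/L, triglycerides mmol/l.
    """
    fpg = np.asarray(fpg, dtype=float)
    fpi = np.asarray(fpi, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    lep = np.asarray(leptin, dtype=float)
    adi = np.asarray(adiponectin, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_gi = (fpg > 0) & (fpi > 0)
        homa = np.where(pos_gi, fpg * fpi / 405.0, np.nan)
        quicki = np.where(pos_gi, 1.0 / (np.log10(fpi) + np.log10(fpg)), np.nan)
        mcauley = np.where(
            (fpi > 0) & (tg > 0),
            np.exp(2.63 - 0.28 * np.log(fpi) - 0.31 * np.log(tg)),
            np.nan,
        )
        la = np.where((lep > 0) & (adi > 0), lep / adi, np.nan)
    return pd.DataFrame(
        {
            "fpg": np.where(fpg > 0, fpg, np.nan),
            "fpi": np.where(fpi > 0, fpi, np.nan),
            "homa_ir": homa,
            "quicki": quicki,
            "mcauley": mcauley,
            "leptin_adiponectin_ratio": la,
        }
    )


def koenker_machado_r1(y, X, q: float = 0.5) -> float:
    """Koenker-Machado goodness-of-fit pseudo-R1 at quantile ``q``.

    1 - V(full)/V(intercept-only), V the minimized check-function sum.
    """
    y = np.asarray(y, dtype=float)

    def check_sum(resid):
        return float(np.sum(resid * (q - (resid < 0))))

    full = QuantReg(y, sm.add_constant(np.asarray(X, dtype=float))).fit(q=q)
    v_full = check_sum(y - full.fittedvalues)
    null = QuantReg(y, np.ones((len(y), 1))).fit(q=q)
    v_null = check_sum(y - null.fittedvalues)
    if v_null <= 0:
        return 0.0
    return max(1.0 - v_full / v_null, 0.0)


def tertile_ir_association(cohort: pd.DataFrame, tertiles, measures=None,
                           ngt_only: bool = False) -> pd.DataFrame:
    """Per-measure association of IR indices with score tertiles.

    Returns one row per measure: tertile medians and IQRs, the
    Kruskal-Wallis p-value across tertiles, and the quantile-regression
    pseudo-R2 (Koenker-Machado R1 at the median) from regressing the
    measure on tertile indicators.  ``ngt_only`` restricts to
    normoglycemic subjects.
    """
    df = cohort.copy()
    df["_tertile"] = np.asarray(tertiles)
    if ngt_only:
        df = df[df["prediabetes"] == 0]
    labels = ["lower", "middle", "upper"]
    for lab in labels:
        if (df["_tertile"] == lab).sum() < 3:
            raise ValueError(f"tertile {lab!r} has fewer than 3 subjects")
    measures = measures if measures is not None else [
        m for m in IR_MEASURES if m in df.columns
    ]
    rows = []
    for m in measures:
        sub = df[[m, "_tertile"]].dropna()
        groups = [sub.loc[sub["_tertile"] == lab, m].to_numpy() for lab in labels]
        if any(len(g) < 3 for g in groups):
            raise ValueError(f"tertile with fewer than 3 non-missing values for {m!r}")
        kw_stat, kw_p = stats.kruskal(*groups)
        X = np.column_stack(
            [(sub["_tertile"] == "middle").astype(float), (sub["_tertile"] == "upper").astype(float)]
        )
        r2 = koenker_machado_r1(sub[m].to_numpy(), X)
        row = {"measure": m, "kw_stat": float(kw_stat), "kw_p": float(kw_p), "r2": r2}
        for lab, g in zip(labels, groups):
            row[f"median_{lab}"] = float(np.median(g))
            q1, q3 = np.percentile(g, [25, 75])
            row[f"iqr_{lab}"] = float(q3 - q1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
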
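"""Trait normalization, FDR control and tertile grouping.

Shared by every downstream stage: lipid concentrations are analysed on the
rank-based inverse-normal scale, lipidome-wide p-values are controlled by
the Benjamini-Hochberg step-up procedure, and risk scores are categorised
into tertile groups for survival and insulin-resistance contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class InverseNormalizedTrait:
    """Inverse-normal transformed values with provenance."""

    values: np.ndarray
    source: str = ""
    ties: str = "average"
    offset: float = 0.5

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def inverse_normalize(values, name: str = "", offset: float = 0.5) -> InverseNormalizedTrait:
    """Rank-based inverse-normal transform z_i = Phi^-1((r_i - offset) / n).

    Ties receive average ranks.  ``offset`` 0.5 gives symmetric plotting
    positions; 0.375 gives Blom scores.  Raises on fewer than two values or
    non-finite input; warns when all values are identical (degenerate ranks).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if x.size < 2:
        raise ValueError("inverse normalization needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if not 0 < offset < 1:
        raise ValueError("rank offset must be in (0, 1)")
    if np.all(x == x[0]):
        warnings.warn("all values identical: inverse-normal ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - offset) / x.size)
    return InverseNormalizedTrait(values=z, source=name, offset=offset)


def inverse_normalize_columns(table: pd.DataFrame, columns, offset: float = 0.5) -> pd.DataFrame:
    """Inverse-normalize named columns of a cohort table (copy returned)."""
    out = table.copy()
    for col in columns:
        out[col] = inverse_normalize(table[col].to_numpy(), name=col, offset=offset).values
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def tertile_groups(score, labels=("lower", "middle", "upper")) -> pd.Categorical:
    """Assign tertile group labels by the empirical 1/3 and 2/3 quantiles.

    The lower tertile serves as the reference group downstream.  Heavy ties
    that would empty a tertile raise a ``ValueError``.
    """
    x = np.asarray(score, dtype=float)
    if x.size < 3:
        raise ValueError("tertile grouping needs at least 3 values")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    codes = np.where(x <= q1, 0, np.where(x <= q2, 1, 2))
    counts = np.bincount(codes, minlength=3)
    if np.any(counts == 0):
        raise ValueError(
            f"degenerate tertiles (group sizes {counts.tolist()}): too many ties in score"
        )
    return pd.Categorical.from_codes(codes, categories=list(labels), ordered=True)
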
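"""Cox proportional-hazards models with a kinship-structured Gaussian frailty.

The hazard for subject i is

    lambda_i(t) = lambda_0(t) * exp(x_i' beta + b_i),      b ~ N(0, sigma2 * R)

where R is the pairwise genetic relationship matrix (2*phi scale).  The
fixed effects and random effects are estimated jointly by maximizing the
penalized partial likelihood

    ppl(beta, b) = pl(X beta + b) - b' (sigma2 R)^{-1} b / 2

with Newton-Raphson inner iterations; the frailty variance sigma2 is
estimated on the Laplace-approximate marginal (integrated) likelihood by a
one-dimensional outer search (coarse log grid followed by bounded Brent
refinement).  With sigma2 = 0 (or no kinship matrix) the model reduces
exactly to an ordinary Cox model.  Tied event times use the Efron
approximation throughout.

The interface follows the statsmodels convention: ``FrailtyCox`` is the
model, ``fit`` returns a ``FrailtyCoxResults`` carrying coefficients,
standard errors, the (integrated) log-likelihood, AIC and a ``summary``
table, plus Breslow baseline-hazard prediction of absolute risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


class ConvergenceError(RuntimeError):
    pass


class SingularModelError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# Efron partial-likelihood machinery
# ---------------------------------------------------------------------------


def _group_by_strata(strata, n):
    if strata is None:
        return [np.arange(n)]
    strata = np.asarray(strata)
    return [np.flatnonzero(strata == s) for s in pd.unique(strata)]


def _efron_ll_grad_eta(time, event, eta, want_hessian=False):
    """Partial log-likelihood, gradient and (optionally) Hessian in eta space.

    Efron approximation for ties.  Returns (ll, grad, H) with H the negative
    second derivative (positive semi-definite, n x n) or None.  Untied event
    times take a vectorized O(n^2) path.
    """
    ev_times = time[event.astype(bool)]
    if len(ev_times) == len(np.unique(ev_times)):
        return _untied_ll_grad_hess_eta(time, event, eta, want_hessian)
    return _efron_loop_ll_grad_eta(time, event, eta, want_hessian)


def _untied_ll_grad_hess_eta(time, event, eta, want_hessian=False):
    """Vectorized eta-space quantities for untied event times.

    Uses H = diag(w * A) - (w w') .* min(C_j, C_k) with A_j the cumulative
    sum of 1/S0 and C_j of 1/S0^2 over events whose risk sets contain j.
    """
    n = len(time)
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    eta_s = eta[order]
    shift = eta_s.max()
    w = np.exp(eta_s - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    ri = np.searchsorted(t, t[e], side="left")
    s0 = S0[ri]
    ll = float((eta_s[e] - shift).sum() - np.log(s0).sum())
    # per-position cumulative sums over events with risk set containing j
    inv = np.zeros(n)
    inv2 = np.zeros(n)
    np.add.at(inv, ri, 1.0 / s0)
    np.add.at(inv2, ri, 1.0 / s0**2)
    A = np.cumsum(inv)
    C = np.cumsum(inv2)
    grad_s = e.astype(float) - w * A
    H = None
    if want_hessian:
        H_s = -np.outer(w, w) * np.minimum.outer(C, C)
        H_s[np.diag_indices(n)] += w * A
        H = np.empty((n, n))
        H[np.ix_(order, order)] = H_s
    grad = np.empty(n)
    grad[order] = grad_s
    return ll, grad, H


def _efron_loop_ll_grad_eta(time, event, eta, want_hessian=False):
    """Generic Efron-tie implementation in eta space."""
    n = len(time)
    ll = 0.0
    grad = np.zeros(n)
    H = np.zeros((n, n)) if want_hessian else None
    w = np.exp(eta)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    # iterate distinct event times
    event_times = np.unique(time[event.astype(bool)])
    for t in event_times:
        risk = order[np.searchsorted(t_sorted, t, side="left"):]
        dead = risk[(event[risk].astype(bool)) & (time[risk] == t)]
        d = len(dead)
        s0_r = w[risk].sum()
        s0_d = w[dead].sum()
        ll += eta[dead].sum()
        grad[dead] += 1.0
        for l in range(d):
            frac = l / d
            denom = s0_r - frac * s0_d
            ll -= np.log(denom)
            a = np.zeros(n)
            a[risk] = w[risk]
            a[dead] -= frac * w[dead]
            grad -= a / denom
            if want_hessian:
                H += np.diag(a) / denom - np.outer(a, a) / denom**2
    return ll, grad, H


def _efron_ll_grad_info_beta(time, event, X, eta_offset, beta):
    """O(n p^2) quantities in beta space (plain Cox path).

    ``eta_offset`` allows a fixed additive offset (e.g. frozen frailties).
    Returns (ll, grad_p, info_pxp).  Dispatches to a vectorized
    cumulative-sum implementation when event times are untied (where the
    Efron and Breslow treatments coincide) and to the generic Efron loop
    otherwise.
    """
    ev_times = time[event.astype(bool)]
    if len(ev_times) == len(np.unique(ev_times)):
        return _untied_ll_grad_info_beta(time, event, X, eta_offset, beta)
    return _efron_loop_ll_grad_info_beta(time, event, X, eta_offset, beta)


def _untied_ll_grad_info_beta(time, event, X, eta_offset, beta):
    """Vectorized partial-likelihood quantities for untied event times."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    Xs = X[order]
    eta = Xs @ beta + eta_offset[order]
    eta_stab = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta_stab)
    wX = w[:, None] * Xs
    wXX = wX[:, :, None] * Xs[:, None, :]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    # risk set = subjects with t_j >= t_i (censoring ties included)
    ri = np.searchsorted(t, t[e], side="left")
    s0 = S0[ri]
    xbar = S1[ri] / s0[:, None]
    ll = float(eta_stab[e].sum() - np.log(s0).sum())
    grad = Xs[e].sum(axis=0) - xbar.sum(axis=0)
    info = (S2[ri] / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
    return ll, grad, info


def _efron_loop_ll_grad_info_beta(time, event, X, eta_offset, beta):
    """Generic Efron-tie implementation (loop over distinct event times)."""
    p = X.shape[1]
    eta = X @ beta + eta_offset
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    order = np.argsort(time, kind="stable")[::-1]  # descending time
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    n = len(time)
    while i < n:
        t = time[order[i]]
        block = []
        while i < n and time[order[i]] == t:
            block.append(order[i])
            i += 1
        for j in block:
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
        dead = [j for j in block if event[j]]
        d = len(dead)
        if d == 0:
            continue
        s0_d = sum(w[j] for j in dead)
        s1_d = np.sum([w[j] * X[j] for j in dead], axis=0)
        s2_d = np.sum([w[j] * np.outer(X[j], X[j]) for j in dead], axis=0)
        ll += sum(eta[j] for j in dead)
        grad += np.sum([X[j] for j in dead], axis=0)
        for l in range(d):
            frac = l / d
            denom = s0 - frac * s0_d
            xbar = (s1 - frac * s1_d) / denom
            ll -= np.log(denom)
            grad -= xbar
            info += (s2 - frac * s2_d) / denom - np.outer(xbar, xbar)
    return ll, grad, info


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class FrailtyCox:
    """Cox proportional-hazards model with optional kinship frailty.

    Parameters
    ----------
    time, event : array-like
        Follow-up time (> 0) and event indicator (1 = incident case).
    exog : array-like or DataFrame, shape (n, p)
        Fixed-effect design matrix (no intercept; the baseline hazard
        absorbs it).
    kinship : DataFrame or ndarray, optional
        Relationship matrix (2*phi scale) aligned to subjects.  ``None``
        fits an ordinary Cox model.
    strata : array-like, optional
        Categorical stratification variable; the baseline hazard is
        stratum-specific.
    names : sequence of str, optional
        Covariate names (taken from DataFrame columns when available).
    """

    def __init__(self, time, event, exog, kinship=None, strata=None, names=None):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            exog = exog.to_numpy()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.time):
            self.exog = self.exog.T
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        self.strata = None if strata is None else np.asarray(strata)
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")
        if isinstance(kinship, pd.DataFrame):
            kinship = kinship.to_numpy()
        self.kinship = None if kinship is None else np.asarray(kinship, dtype=float)
        if self.kinship is not None and self.kinship.shape != (len(self.time),) * 2:
            raise ValueError("kinship matrix not aligned to subjects")
        if self.exog.size == 0:
            self.exog = self.exog.reshape(len(self.time), 0)
            self.names = []
        col_sd = self.exog.std(axis=0)
        if self.exog.shape[1] and np.any(col_sd == 0):
            bad = [self.names[j] for j in np.flatnonzero(col_sd == 0)]
            raise SingularModelError(f"constant covariate(s): {bad}")

    @classmethod
    def from_dataframe(cls, df, time_col, event_col, covariates, kinship=None, strata_col=None):
        kin = kinship
        if isinstance(kinship, pd.DataFrame):
            ids = df.index.astype(str) if df.index.name else df.get("subject_id", df.index).astype(str)
            kin = kinship.loc[ids, ids]
        strata = df[strata_col].to_numpy() if strata_col else None
        return cls(df[time_col], df[event_col], df[list(covariates)], kinship=kin, strata=strata)

    # -- plain Cox -----------------------------------------------------------

    def _fit_plain(self, offset=None, tol=1e-9, maxiter=60):
        n, p = self.exog.shape
        offset = np.zeros(n) if offset is None else offset
        beta = np.zeros(p)
        groups = _group_by_strata(self.strata, n)
        if p == 0:  # null model: partial likelihood at the empty design
            ll = sum(
                _efron_ll_grad_info_beta(
                    self.time[g], self.event[g], self.exog[g], offset[g], beta
                )[0]
                for g in groups
            )
            return beta, np.zeros((0, 0)), ll, True, np.zeros(n)
        ll_prev = -np.inf
        for it in range(maxiter):
            ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
            for g in groups:
                li, gi, Ii = _efron_ll_grad_info_beta(
                    self.time[g], self.event[g], self.exog[g], offset[g], beta
                )
                ll += li
                grad += gi
                info += Ii
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise SingularModelError("singular information matrix") from exc
            # step-halving for stability
            shrink = 1.0
            while shrink > 1e-4:
                cand = beta + shrink * step
                ll_new = 0.0
                for g in groups:
                    li, _, _ = _efron_ll_grad_info_beta(
                        self.time[g], self.event[g], self.exog[g], offset[g], cand
                    )
                    ll_new += li
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                shrink /= 2
            beta = beta + shrink * step
            if abs(ll - ll_prev) < tol * (abs(ll) + 1):
                break
            ll_prev = ll
        ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
        for g in groups:
            li, gi, Ii = _efron_ll_grad_info_beta(
                self.time[g], self.event[g], self.exog[g], offset[g], beta
            )
            ll += li
            grad += gi
            info += Ii
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise SingularModelError("singular information matrix") from exc
        converged = bool(np.max(np.abs(grad)) < 1e-4 * (1 + np.max(np.abs(beta))))
        return beta, cov, ll, converged, np.zeros(n)

    # -- penalized (frailty) fit --------------------------------------------

    def _penalized_mode(self, sigma2, Q, beta0, b0, tol=1e-8, maxiter=50):
        """Inner Newton over (beta, b) for fixed sigma2; returns mode and pieces."""
        n, p = self.exog.shape
        X = self.exog
        beta, b = beta0.copy(), b0.copy()
        groups = _group_by_strata(self.strata, n)

        def pieces(beta, b, want_hessian):
            eta = X @ beta + b
            ll = 0.0
            grad = np.zeros(n)
            H = np.zeros((n, n)) if want_hessian else None
            for g in groups:
                li, gi, Hi = _efron_ll_grad_eta(
                    self.time[g], self.event[g], eta[g], want_hessian=want_hessian
                )
                ll += li
                grad[g] += gi
                if want_hessian:
                    H[np.ix_(g, g)] += Hi
            return ll, grad, H

        ppl_prev = -np.inf
        for it in range(maxiter):
            ll, g_eta, H = pieces(beta, b, want_hessian=True)
            ppl = ll - 0.5 * b @ Q @ b
            grad_full = np.concatenate([X.T @ g_eta, g_eta - Q @ b])
            HX = H @ X
            K = np.block([[X.T @ HX, HX.T], [HX, H + Q]])
            jitter = 1e-10 * (1 + np.trace(K) / (n + p))
            for _ in range(8):
                try:
                    L = np.linalg.cholesky(K + jitter * np.eye(n + p))
                    break
                except np.linalg.LinAlgError:
                    jitter *= 100
            else:
                raise SingularModelError("singular penalized information matrix")
            step = np.linalg.solve(L.T, np.linalg.solve(L, grad_full))
            shrink = 1.0
            while shrink > 1e-4:
                nb = beta + shrink * step[:p]
                nbb = b + shrink * step[p:]
                ll_new, _, _ = pieces(nb, nbb, want_hessian=False)
                ppl_new = ll_new - 0.5 * nbb @ Q @ nbb
                if np.isfinite(ppl_new) and ppl_new >= ppl - 1e-12:
                    break
                shrink /= 2
            beta = beta + shrink * step[:p]
            b = b + shrink * step[p:]
            if abs(ppl - ppl_prev) < tol * (abs(ppl) + 1):
                break
            ppl_prev = ppl
        ll, g_eta, H = pieces(beta, b, want_hessian=True)
        ppl = ll - 0.5 * b @ Q @ b
        HX = H @ X
        K = np.block([[X.T @ HX, HX.T], [HX, H + Q]])
        return beta, b, ll, ppl, H, K

    def _laplace_loglik(self, sigma2, state):
        """Laplace-approximate marginal log-likelihood at sigma2 (profiled)."""
        n = len(self.time)
        Q = state["Rinv"] / sigma2
        beta, b, ll, ppl, H, K = self._penalized_mode(
            sigma2, Q, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b
        sign, logdet_HQ = np.linalg.slogdet(H + Q)
        lmarg = ppl - 0.5 * (n * np.log(sigma2) + state["logdetR"]) - 0.5 * logdet_HQ
        state["cache"][sigma2] = (beta, b, ll, ppl, H, K, lmarg)
        return lmarg

    def fit(self, sigma2=None, grid=None, refine=True):
        """Fit the model.

        Parameters
        ----------
        sigma2 : float, optional
            Fix the frailty variance (0 or ``kinship=None`` gives an
            ordinary Cox fit).  ``None`` profiles sigma2 on the Laplace
            marginal likelihood.
        grid : sequence, optional
            Coarse sigma2 grid for the outer search (default log-spaced
            0.01 .. 8).
        """
        n, p = self.exog.shape
        if self.kinship is None or (sigma2 is not None and sigma2 == 0):
            beta, cov, ll, converged, b = self._fit_plain()
            return FrailtyCoxResults(
                self, beta, cov, llf=ll, llf_penalized=ll, frailty_variance=0.0,
                frailties=b, converged=converged, df_model=p,
            )

        R = self.kinship
        # guard against a semi-definite R (possible after subsetting)
        evals = np.linalg.eigvalsh(R)
        if evals.min() < 1e-8:
            R = R + (1e-8 - min(evals.min(), 0)) * np.eye(n)
        Rinv = np.linalg.inv(R)
        sign, logdetR = np.linalg.slogdet(R)
        state = {
            "Rinv": Rinv, "logdetR": logdetR,
            "beta": np.zeros(p), "b": np.zeros(n), "cache": {},
        }
        # warm start at the plain Cox solution
        try:
            beta0, _, _, _, _ = self._fit_plain()
            state["beta"] = beta0
        except SingularModelError:
            pass

        if sigma2 is None:
            grid = np.asarray(
                grid if grid is not None else np.exp(np.linspace(np.log(0.01), np.log(8.0), 7))
            )
            vals = [self._laplace_loglik(s2, state) for s2 in grid]
            k = int(np.argmax(vals))
            sigma2_hat = grid[k]
            if refine:
                lo = grid[max(k - 1, 0)]
                hi = grid[min(k + 1, len(grid) - 1)]
                if lo < hi:
                    res = minimize_scalar(
                        lambda ls2: -self._laplace_loglik(np.exp(ls2), state),
                        bounds=(np.log(lo), np.log(hi)), method="bounded",
                        options={"xatol": 0.05},
                    )
                    sigma2_hat = float(np.exp(res.x))
        else:
            sigma2_hat = float(sigma2)
            self._laplace_loglik(sigma2_hat, state)

        if sigma2_hat not in state["cache"]:
            self._laplace_loglik(sigma2_hat, state)
        beta, b, ll, ppl, H, K, lmarg = state["cache"][sigma2_hat]
        jitter = 1e-10 * (1 + np.trace(K) / (n + p))
        try:
            Kinv_block = np.linalg.inv(K + jitter * np.eye(n + p))[:p, :p]
        except np.linalg.LinAlgError as exc:
            raise SingularModelError("singular penalized information matrix") from exc
        return FrailtyCoxResults(
            self, beta, Kinv_block, llf=lmarg, llf_penalized=ppl,
            frailty_variance=sigma2_hat, frailties=b, converged=True,
            df_model=p + (1 if sigma2 is None else 0),
        )


@dataclass
class FrailtyCoxResults:
    """Fitted frailty-Cox model: coefficients, uncertainty, fit statistics."""

    model: FrailtyCox
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    llf_penalized: float
    frailty_variance: float
    frailties: np.ndarray
    converged: bool
    df_model: int
    _baseline: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.df_model

    @property
    def n_events(self) -> int:
        return int(self.model.event.sum())

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha=0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def lr_test(self, restricted: "FrailtyCoxResults"):
        """Likelihood-ratio test against a nested restricted fit."""
        lrchi2 = max(2 * (self.llf - restricted.llf), 0.0)
        df = self.df_model - restricted.df_model
        p = stats.chi2.sf(lrchi2, max(df, 1))
        return lrchi2, df, p

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
            },
            index=self.model.names,
        )

    # -- absolute risk -------------------------------------------------------

    def baseline_cumulative_hazard(self) -> pd.DataFrame:
        """Breslow baseline cumulative hazard at the fitted fixed effects."""
        if self._baseline is None:
            m = self.model
            eta = m.exog @ self.params + self.frailties
            w = np.exp(eta)
            rows = []
            groups = _group_by_strata(m.strata, len(m.time))
            strata_vals = (
                pd.unique(m.strata) if m.strata is not None else [None]
            )
            for g, sval in zip(groups, strata_vals):
                t, e, wg = m.time[g], m.event[g], w[g]
                order = np.argsort(t, kind="stable")
                ts, es, ws = t[order], e[order], wg[order]
                rev_cum = np.cumsum(ws[::-1])[::-1]
                h0 = 0.0
                for ti in np.unique(ts[es.astype(bool)]):
                    at_risk = rev_cum[np.searchsorted(ts, ti, side="left")]
                    d = int(((ts == ti) & es.astype(bool)).sum())
                    h0 += d / at_risk
                    rows.append({"stratum": sval, "time": ti, "cumhaz": h0})
            self._baseline = pd.DataFrame(rows)
        return self._baseline

    def predict_risk(self, horizon: float, exog=None) -> np.ndarray:
        """Probability of an event by ``horizon`` from fixed effects only."""
        m = self.model
        X = m.exog if exog is None else np.asarray(exog, dtype=float)
        base = self.baseline_cumulative_hazard()
        eta = X @ self.params
        if m.strata is None:
            sub = base[base["time"] <= horizon]
            H0 = float(sub["cumhaz"].iloc[-1]) if len(sub) else 0.0
            return 1.0 - np.exp(-H0 * np.exp(eta))
        risks = np.empty(len(X))
        for sval in pd.unique(m.strata):
            sub = base[(base["stratum"] == sval) & (base["time"] <= horizon)]
            H0 = float(sub["cumhaz"].iloc[-1]) if len(sub) else 0.0
            mask = m.strata == sval
            risks[mask] = 1.0 - np.exp(-H0 * np.exp(eta[mask]))
        return risks
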
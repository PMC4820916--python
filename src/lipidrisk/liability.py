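"""Liability-threshold (polygenic probit) prevalence estimation.

A binary trait y is modelled as the indicator that a latent liability
exceeds zero:

    l_i = mu + x_i' beta + g_i + e_i,    g ~ N(0, sg2 * R),  e ~ N(0, 1)

with R the relationship matrix.  The heritability is h2 = sg2/(1 + sg2).
The implied prevalence at reference covariates is the standard-normal
upper-tail mass beyond the fitted threshold, Phi(eta_ref / sqrt(1 + sg2)).

Estimation uses a Laplace approximation: for fixed sg2 the joint
penalized probit log-likelihood is maximized over (mu, beta, g) by
Newton-Raphson, and sg2 is profiled on the Laplace marginal likelihood.
With no kinship matrix (or h2 = 0) the model reduces to an ordinary
probit regression, delegated to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class LiabilityFit:
    """Fitted liability model: threshold, covariate effects, prevalence."""

    mu: float
    beta: np.ndarray
    heritability: float
    prevalence: float
    converged: bool = True
    degenerate: bool = False

    @property
    def polygenic_variance(self) -> float:
        h2 = self.heritability
        return h2 / (1 - h2) if h2 < 1 else np.inf


class LiabilityThreshold:
    """Polygenic probit model for a binary trait.

    Parameters
    ----------
    endog : array-like of {0, 1}
    exog : array-like, optional
        Covariates (no constant; the threshold mu is always included).
    kinship : ndarray/DataFrame, optional
        Relationship matrix; ``None`` gives ordinary probit.
    """

    def __init__(self, endog, exog=None, kinship=None):
        self.endog = np.asarray(endog, dtype=int)
        if exog is not None:
            if isinstance(exog, pd.DataFrame):
                exog = exog.to_numpy()
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != len(self.endog):
                exog = exog.T
        self.exog = exog
        if isinstance(kinship, pd.DataFrame):
            kinship = kinship.to_numpy()
        self.kinship = None if kinship is None else np.asarray(kinship, dtype=float)

    # -- plain probit --------------------------------------------------------

    def _fit_probit(self) -> LiabilityFit:
        y = self.endog
        n = len(y)
        frac = y.mean()
        if frac in (0.0, 1.0):
            clamped = np.clip(frac, 0.5 / n, 1 - 0.5 / n)
            warnings.warn("degenerate outcome subset: prevalence clamped")
            return LiabilityFit(
                mu=float(stats.norm.ppf(clamped)),
                beta=np.zeros(0 if self.exog is None else self.exog.shape[1]),
                heritability=0.0, prevalence=float(clamped), degenerate=True,
            )
        if self.exog is None:
            mu = float(stats.norm.ppf(frac))
            return LiabilityFit(mu=mu, beta=np.zeros(0), heritability=0.0,
                                prevalence=float(frac))
        X = sm.add_constant(self.exog, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(y, X).fit(disp=False, maxiter=200)
        mu = float(res.params[0])
        beta = np.asarray(res.params[1:])
        eta_ref = mu + self.exog.mean(axis=0) @ beta
        return LiabilityFit(mu=mu, beta=beta, heritability=0.0,
                            prevalence=float(stats.norm.cdf(eta_ref)),
                            converged=bool(res.mle_retvals.get("converged", True)))

    # -- polygenic probit ----------------------------------------------------

    def _joint_mode(self, sg2, Rinv, theta0, g0, maxiter=60, tol=1e-8):
        """Newton maximization of the penalized probit joint likelihood."""
        y = self.endog
        n = len(y)
        s = 2.0 * y - 1.0
        X = np.column_stack([np.ones(n)] + ([] if self.exog is None else [self.exog]))
        p = X.shape[1]
        theta, g = theta0.copy(), g0.copy()
        Q = Rinv / sg2

        def pieces(theta, g):
            eta = X @ theta + g
            v = s * eta
            logcdf = stats.norm.logcdf(v)
            lam = np.exp(stats.norm.logpdf(v) - logcdf)  # inverse Mills ratio
            ll = logcdf.sum()
            grad_eta = s * lam
            W = lam * (v + lam)  # -d2/deta2, >= 0
            return ll, grad_eta, W

        pen_prev = -np.inf
        for _ in range(maxiter):
            ll, grad_eta, W = pieces(theta, g)
            pen = ll - 0.5 * g @ Q @ g
            grad = np.concatenate([X.T @ grad_eta, grad_eta - Q @ g])
            WX = X * W[:, None]
            K = np.block([[X.T @ WX, WX.T], [WX, np.diag(W) + Q]])
            step = np.linalg.solve(K + 1e-10 * np.eye(n + p), grad)
            shrink = 1.0
            while shrink > 1e-4:
                t_new = theta + shrink * step[:p]
                g_new = g + shrink * step[p:]
                ll_new, _, _ = pieces(t_new, g_new)
                if np.isfinite(ll_new) and ll_new - 0.5 * g_new @ Q @ g_new >= pen - 1e-12:
                    break
                shrink /= 2
            theta = theta + shrink * step[:p]
            g = g + shrink * step[p:]
            if abs(pen - pen_prev) < tol * (abs(pen) + 1):
                break
            pen_prev = pen
        ll, grad_eta, W = pieces(theta, g)
        pen = ll - 0.5 * g @ Q @ g
        sign, logdet = np.linalg.slogdet(np.diag(W) + Q)
        lmarg = pen - 0.5 * (n * np.log(sg2) + self._logdetR) - 0.5 * logdet
        return theta, g, lmarg

    def fit(self, heritability=None, h2_grid=(0.0, 0.2, 0.4, 0.6, 0.8)) -> LiabilityFit:
        """Fit; profiles the heritability on a grid unless fixed."""
        if self.kinship is None or (heritability is not None and heritability == 0):
            return self._fit_probit()
        if heritability is not None and not 0 <= heritability < 1:
            raise ValueError("heritability must lie in [0, 1)")
        y = self.endog
        n = len(y)
        if y.mean() in (0.0, 1.0):
            return self._fit_probit()
        R = self.kinship
        evals = np.linalg.eigvalsh(R)
        if evals.min() < 1e-8:
            R = R + (1e-8 - min(evals.min(), 0)) * np.eye(n)
        Rinv = np.linalg.inv(R)
        _, self._logdetR = np.linalg.slogdet(R)
        p = 1 + (0 if self.exog is None else self.exog.shape[1])
        theta0, g0 = np.zeros(p), np.zeros(n)
        grid = [heritability] if heritability is not None else list(h2_grid)
        best = None
        for h2 in grid:
            if h2 == 0:
                # sg2 -> 0: the Laplace marginal tends to the probit loglik
                plain = self._fit_probit()
                X0 = (
                    sm.add_constant(self.exog, has_constant="add")
                    if self.exog is not None
                    else np.ones((n, 1))
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    probit_ll = sm.Probit(y, X0).fit(disp=False).llf
                if best is None or probit_ll > best[1]:
                    best = (plain, probit_ll, 0.0)
                continue
            sg2 = h2 / (1 - h2)
            theta, g, lmarg = self._joint_mode(sg2, Rinv, theta0, g0)
            theta0, g0 = theta, g
            mu = float(theta[0])
            beta = np.asarray(theta[1:])
            eta_ref = mu + (0.0 if self.exog is None else self.exog.mean(axis=0) @ beta)
            prev = float(stats.norm.cdf(eta_ref / np.sqrt(1 + sg2)))
            fit = LiabilityFit(mu=mu, beta=beta, heritability=float(h2), prevalence=prev)
            if best is None or lmarg > best[1]:
                best = (fit, lmarg, h2)
        return best[0]


def estimate_prevalence(endog, exog=None, kinship=None, heritability=None) -> LiabilityFit:
    """Prevalence of a binary outcome via the liability-threshold model.

    Thin functional wrapper over :class:`LiabilityThreshold`; with no
    covariates and no kinship matrix the estimate is exactly the sample
    case fraction.
    """
    return LiabilityThreshold(endog, exog=exog, kinship=kinship).fit(heritability=heritability)
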
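"""Association statistics for PRS–longevity regressions.

Logistic regression of a binary longevity phenotype on a (standardized)
polygenic score, likelihood-based pseudo-variance-explained, and the
multiple-testing machinery used across traits and annotation sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "nagelkerke_r2",
    "bh_fdr",
    "bonferroni_threshold",
]


@dataclass
class LogisticFit:
    """Result of a univariate (plus covariates) logistic association fit."""

    coef: float
    se: float
    p: float
    ll_null: float
    ll_full: float
    n: int
    separated: bool = False

    @property
    def direction(self) -> str:
        return "positive" if self.coef > 0 else "negative"

    @property
    def pseudo_r2(self) -> float:
        return nagelkerke_r2(self.ll_null, self.ll_full, self.n)


def fit_logistic(y, x, covariates=None) -> LogisticFit:
    """Maximum-likelihood logistic regression of ``y`` on ``x``.

    The model is ``logit P(y=1) = a + b*x (+ covariates)``; the returned
    p-value is the Wald test for ``b``. The null model contains the
    intercept and covariates only. Under (quasi-)perfect separation the
    Wald statistic degenerates, so the fit is flagged and the p-value is
    taken from the likelihood-ratio test instead.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise ValueError("y and x must be 1-d vectors of equal length")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])) or uniq.size < 2:
        raise ValueError("phenotype must be binary and non-constant")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")

    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.shape[0]:
            covariates = covariates.T
        design = np.column_stack([np.ones_like(x), x, covariates])
        null_design = np.column_stack([np.ones_like(x), covariates])
    else:
        design = np.column_stack([np.ones_like(x), x])
        null_design = np.ones((y.shape[0], 1))

    n = y.shape[0]
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, design).fit(disp=0, maxiter=200)
            coef = float(full.params[1])
            se = float(full.bse[1])
            p = float(full.pvalues[1])
            ll_full = float(full.llf)
            # a log-likelihood at ~0 means the fit predicts perfectly:
            # the Wald statistic is degenerate under (quasi-)separation
            if not np.isfinite(se) or abs(coef) > 1e3 or ll_full > -1e-3:
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
            coef, se, p, ll_full = np.nan, np.nan, np.nan, 0.0
        null = sm.Logit(y, null_design).fit(disp=0, maxiter=200)
        ll_null = float(null.llf)

    if separated:
        # Wald collapses; fall back to the likelihood-ratio test.
        lrt = 2.0 * (ll_full - ll_null)
        p = float(sps.chi2.sf(max(lrt, 0.0), df=1))
        warnings.warn("perfect separation detected; p from likelihood ratio")
        if not np.isfinite(coef):
            coef = np.inf if np.corrcoef(x, y)[0, 1] > 0 else -np.inf
            se = np.inf
    return LogisticFit(coef=coef, se=se, p=p, ll_null=ll_null,
                       ll_full=ll_full, n=n, separated=separated)


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell R² rescaled to a [0, 1] range.

    ``(1 - exp(2(ll_null - ll_full)/n)) / (1 - exp(2*ll_null/n))``
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_full < ll_null - 1e-9:
        raise ValueError("full-model log-likelihood below null")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def bh_fdr(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m`` optionally declares a larger test family than the p-values
    supplied (e.g. 220 annotation sets × 16 traits = 3520 when only one
    trait's sets are adjusted at a time); adjusted values use ``m`` in the
    denominator and keep the step-up monotonicity.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None or m == p.size:
        return multipletests(p, method="fdr_bh")[1]
    if m < p.size:
        raise ValueError("declared family smaller than the p-value list")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cutoff ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m
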
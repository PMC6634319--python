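"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force
percentiles, normal-equations OLS with partial F, and a fixed fine-grid
Simpson quadrature for the JZS Bayes factor.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from scipy.integrate import simpson


def brute_force_central_mask(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Keep-mask from explicit per-trial 5th/95th percentiles (1-D input)."""
    vals = np.asarray(values, dtype=float)
    ok = np.asarray(valid, dtype=bool)
    if not ok.any():
        return np.zeros_like(ok)
    lo, hi = np.percentile(vals[ok], [5, 95])
    return ok & (vals >= lo) & (vals <= hi)


def ols_fit(x: np.ndarray, y: np.ndarray):
    """Normal-equations OLS: beta, residual variance (df-adjusted), XtX inv."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    s2 = float(resid @ resid) / df
    return beta, s2, np.linalg.inv(xtx), df


def ols_partial_f(x: np.ndarray, y: np.ndarray, idx: list[int]):
    """Wald partial F for a coefficient block, classical OLS."""
    beta, s2, xtx_inv, df = ols_fit(x, y)
    b = beta[idx]
    cov = s2 * xtx_inv[np.ix_(idx, idx)]
    f = float(b @ np.linalg.solve(cov, b)) / len(idx)
    p = float(stats.f.sf(f, len(idx), df))
    return f, len(idx), df, p


def jzs_bf_grid(t: float, n1: int, n2: int, r: float = np.sqrt(2.0) / 2.0) -> float:
    """Fixed fine-grid Simpson quadrature of the JZS two-sample BF10."""
    v = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    x = np.linspace(-40.0, 40.0, 200001)
    g = np.exp(x)
    ng1 = 1.0 + n_eff * g
    log_lr = -0.5 * np.log(ng1) - 0.5 * (v + 1) * (
        np.log1p(t * t / (ng1 * v)) - np.log1p(t * t / v)
    )
    log_prior = (
        0.5 * np.log(r * r / 2.0)
        - special.gammaln(0.5)
        - 1.5 * np.log(g)
        - r * r / (2.0 * g)
    )
    return float(simpson(np.exp(log_lr + log_prior + x), x=x))


def pooled_t_f(x: np.ndarray, y: np.ndarray) -> float:
    """Two-group F = t^2 from the pooled two-sample t statistic."""
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t * t)
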
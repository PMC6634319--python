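"""Random-intercept linear mixed model with residual-df F tests.

The model is y_ij = x_ij' beta + u_j + e_ij with a single random intercept
u_j ~ N(0, sigma2_u) per subject and e_ij ~ N(0, sigma2_e).  Estimation
profiles the likelihood over the variance ratio theta = sigma2_u / sigma2_e:
for fixed theta the GLS solution for beta and the residual variance are
closed-form (per-group Woodbury identity, V_j^-1 = I - theta/(1+theta n_j) J),
so the fit reduces to a 1-D bounded optimization over log(theta) plus an
explicit check of the theta = 0 boundary.  ML is the default; REML is
available.

F statistics use the residual degrees of freedom N - p (observations minus
fixed-effect parameters), the convention that reproduces published mixed-
model ANOVA tables of this design; the fixed-effect covariance is scaled by
the residual-df variance estimate so that at theta = 0 every F equals its
OLS partial-F exactly.

The fixed-effect design crosses a categorical condition with a continuous
position covariate (treatment coding, full interaction), so a k-condition
model has p = 2k parameters and the interaction block k - 1 numerator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LMMSpec",
    "RandomInterceptLMM",
    "RandomInterceptLMMResults",
    "FTestResult",
    "fit_lmm",
    "anova_interaction",
    "posthoc_pairwise",
    "split_half",
    "two_sample_t",
]


@dataclass(frozen=True)
class LMMSpec:
    """Column names binding a tidy summary table to the model."""

    response: str = "value_mm"
    condition: str = "condition"
    position: str = "position"
    groups: str = "subject_id"
    reference: str | None = None  # reference level; defaults to first sorted


@dataclass(frozen=True)
class FTestResult:
    term: str
    fvalue: float
    df1: int
    df2: int
    pvalue: float

    def __str__(self) -> str:
        return (
            f"{self.term}: F({self.df1},{self.df2}) = {self.fvalue:.5f}, "
            f"p = {self.pvalue:.5g}"
        )


class ConvergenceError(RuntimeError):
    """Raised when the profiled-likelihood optimizer fails; carries the trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


class RandomInterceptLMM:
    """Model object: response, fixed-effect design and grouping."""

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: list[str] | None = None,
        term_slices: dict[str, list[int]] | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or self.exog.ndim != 2:
            raise ValueError("endog must be 1-D and exog 2-D")
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if np.any(~np.isfinite(self.endog)) or np.any(~np.isfinite(self.exog)):
            raise ValueError("model data contain non-finite values")
        self.nobs, self.k_params = self.exog.shape
        if np.linalg.matrix_rank(self.exog) < self.k_params:
            raise np.linalg.LinAlgError(
                "fixed-effect design is rank deficient; drop collinear terms"
            )
        self.exog_names = exog_names or [f"x{i}" for i in range(self.k_params)]
        self.term_slices = term_slices or {}
        # group bookkeeping: sort rows by group for reduceat-style sums
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self._order = order
        g_sorted = groups[order]
        _, starts, counts = np.unique(g_sorted, return_index=True, return_counts=True)
        self._starts = starts
        self._gn = counts.astype(float)
        self.n_groups = len(counts)
        X = self.exog[order]
        y = self.endog[order]
        self._X, self._y = X, y
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        self._Sx = np.add.reduceat(X, starts, axis=0)  # per-group column sums
        self._Sy = np.add.reduceat(y, starts)

    @classmethod
    def from_summaries(
        cls, data: pd.DataFrame, spec: LMMSpec | None = None
    ) -> "RandomInterceptLMM":
        """Build the condition x position interaction model from a tidy
        summary table (one row per epoch-position)."""
        spec = spec or LMMSpec()
        for col in (spec.response, spec.condition, spec.position, spec.groups):
            if col not in data.columns:
                raise ValueError(f"summary table lacks column {col!r}")
        if data[spec.response].isna().any():
            raise ValueError("summary table contains missing response values")
        levels = sorted(data[spec.condition].astype(str).unique())
        ref = spec.reference
        if ref is None:
            for preferred in ("control", "other"):
                if preferred in levels:
                    ref = preferred
                    break
            else:
                ref = levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among conditions {levels}")
        others = [l for l in levels if l != ref]
        if len(levels) < 2:
            raise ValueError("need at least 2 conditions")
        if data[spec.position].nunique() < 2:
            raise ValueError("need at least 2 positions")
        if data[spec.groups].nunique() < 2:
            raise ValueError("need at least 2 subjects")

        cond = data[spec.condition].astype(str).to_numpy()
        pos = data[spec.position].to_numpy(dtype=float)
        cols = [np.ones(len(data))]
        names = ["Intercept"]
        for l in others:
            cols.append((cond == l).astype(float))
            names.append(f"C[{l}]")
        cols.append(pos)
        names.append("position")
        inter_idx = []
        for l in others:
            cols.append((cond == l) * pos)
            names.append(f"C[{l}]:position")
            inter_idx.append(len(names) - 1)
        term_slices = {
            "condition": list(range(1, 1 + len(others))),
            "position": [1 + len(others)],
            "condition:position": inter_idx,
        }
        return cls(
            endog=data[spec.response].to_numpy(dtype=float),
            exog=np.column_stack(cols),
            groups=data[spec.groups].to_numpy(),
            exog_names=names,
            term_slices=term_slices,
        )

    # -- profiled likelihood machinery ------------------------------------

    def _gls_pieces(self, theta: float):
        """X'V^-1X, X'V^-1y, y'V^-1y and logdet(V)/sigma2_e for given theta."""
        c = theta / (1.0 + theta * self._gn)  # per-group shrinkage weight
        XtViX = self._XtX - (self._Sx * c[:, None]).T @ self._Sx
        XtViy = self._Xty - self._Sx.T @ (c * self._Sy)
        ytViy = self._yty - float(c @ self._Sy**2)
        logdet = float(np.sum(np.log1p(theta * self._gn)))
        return XtViX, XtViy, ytViy, logdet

    def _profile(self, theta: float, reml: bool):
        XtViX, XtViy, ytViy, logdet = self._gls_pieces(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - float(beta @ XtViy), 0.0)  # r'V^-1 r at the GLS solution
        n, p = self.nobs, self.k_params
        if reml:
            sigma2 = rss / (n - p)
            sign, ld_x = np.linalg.slogdet(XtViX)
            nll = 0.5 * (
                (n - p) * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0)
                + logdet + ld_x
            )
        else:
            sigma2 = rss / n
            nll = 0.5 * (n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0) + logdet)
        return nll, beta, sigma2, rss, XtViX

    def fit(self, reml: bool = False) -> "RandomInterceptLMMResults":
        """Profile the likelihood over theta = sigma2_u / sigma2_e."""
        trace: list[tuple[float, float]] = []

        def obj(log_theta: float) -> float:
            nll = self._profile(float(np.exp(log_theta)), reml)[0]
            trace.append((float(np.exp(log_theta)), nll))
            return nll

        res = optimize.minimize_scalar(
            obj, bounds=(-18.0, 18.0), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise ConvergenceError(f"profiled optimizer failed: {res.message}", trace)
        theta = float(np.exp(res.x))
        nll_hat = float(res.fun)
        nll0 = self._profile(0.0, reml)[0]
        if nll0 <= nll_hat:  # boundary solution: no between-subject variance
            theta, nll_hat = 0.0, nll0
        _, beta, sigma2, rss, XtViX = self._profile(theta, reml)
        return RandomInterceptLMMResults(
            model=self,
            fe_params=beta,
            theta=theta,
            sigma2_e=sigma2,
            sigma2_u=theta * sigma2,
            llf=-nll_hat,
            rss_gls=rss,
            xtvix=XtViX,
            reml=reml,
            converged=True,
        )


class RandomInterceptLMMResults:
    """Estimates, uncertainties and tests for a fitted random-intercept LMM."""

    def __init__(
        self,
        model: RandomInterceptLMM,
        fe_params: np.ndarray,
        theta: float,
        sigma2_e: float,
        sigma2_u: float,
        llf: float,
        rss_gls: float,
        xtvix: np.ndarray,
        reml: bool,
        converged: bool,
    ):
        self.model = model
        self.fe_params = pd.Series(fe_params, index=model.exog_names)
        self.theta = theta
        self.sigma2_e = sigma2_e
        self.sigma2_u = sigma2_u
        self.llf = llf
        self.reml = reml
        self.converged = converged
        self.nobs = model.nobs
        self.k_params = model.k_params
        self.df_resid = model.nobs - model.k_params
        self._rss_gls = rss_gls
        self._xtvix = xtvix
        # residual-df variance estimate used for all F tests
        self._s2_df = rss_gls / self.df_resid

    def cov_params(self) -> pd.DataFrame:
        cov = self._s2_df * np.linalg.inv(self._xtvix)
        return pd.DataFrame(cov, index=self.fe_params.index, columns=self.fe_params.index)

    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params().to_numpy())), index=self.fe_params.index
        )

    def f_test(self, indices: list[int], term: str = "") -> FTestResult:
        """Wald F test that the listed coefficients are jointly zero."""
        idx = list(indices)
        if not idx:
            raise ValueError("empty coefficient set for F test")
        beta = self.fe_params.to_numpy()[idx]
        cov = self.cov_params().to_numpy()[np.ix_(idx, idx)]
        f = float(beta @ np.linalg.solve(cov, beta)) / len(idx)
        df1, df2 = len(idx), self.df_resid
        p = float(stats.f.sf(f, df1, df2))
        name = term or "+".join(self.fe_params.index[i] for i in idx)
        return FTestResult(term=name, fvalue=f, df1=df1, df2=df2, pvalue=max(p, 1e-300))

    def anova(self) -> pd.DataFrame:
        """F table over the model's named term blocks (residual df)."""
        if not self.model.term_slices:
            raise ValueError("model has no term structure; use f_test directly")
        rows = []
        for term, idx in self.model.term_slices.items():
            ft = self.f_test(idx, term=term)
            rows.append(
                {"term": ft.term, "F": ft.fvalue, "df1": ft.df1, "df2": ft.df2,
                 "p": ft.pvalue}
            )
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model"
            f" ({'REML' if self.reml else 'ML'})",
            f"  observations: {self.nobs}   groups: {self.model.n_groups}"
            f"   fixed params: {self.k_params}   residual df: {self.df_resid}",
            f"  log-likelihood: {self.llf:.3f}",
            f"  sigma2_u (between-subject): {self.sigma2_u:.6g}"
            f"   sigma2_e (residual): {self.sigma2_e:.6g}",
            "",
            f"  {'coef':<22}{'estimate':>12}{'se':>12}",
        ]
        se = self.bse()
        for name, b in self.fe_params.items():
            lines.append(f"  {name:<22}{b:>12.6f}{se[name]:>12.6f}")
        if self.model.term_slices:
            lines.append("")
            lines.append(self.anova().to_string(float_format=lambda v: f"{v:.5g}"))
        return "\n".join(lines)


def fit_lmm(
    summaries: pd.DataFrame, spec: LMMSpec | None = None, reml: bool = False
) -> RandomInterceptLMMResults:
    """Fit the condition x position random-intercept model to a summary table."""
    return RandomInterceptLMM.from_summaries(summaries, spec).fit(reml=reml)


def anova_interaction(fit: RandomInterceptLMMResults) -> FTestResult:
    """F test of the condition-by-position interaction block."""
    idx = fit.model.term_slices.get("condition:position")
    if not idx:
        raise ValueError("model does not include a condition:position interaction")
    return fit.f_test(idx, term="condition:position")


def posthoc_pairwise(
    summaries: pd.DataFrame,
    conditions: tuple[str, str],
    position: float,
    spec: LMMSpec | None = None,
    reml: bool = False,
) -> FTestResult:
    """Two-condition contrast at a single position (df2 = n - 2).

    Refits the random-intercept model restricted to the two conditions at
    that position, with intercept + condition indicator as fixed effects,
    and tests the condition coefficient.
    """
    spec = spec or LMMSpec()
    a, b = conditions
    sub = summaries[
        summaries[spec.condition].isin([a, b])
        & np.isclose(summaries[spec.position].astype(float), position)
    ]
    for c in conditions:
        if not (sub[spec.condition] == c).any():
            raise ValueError(f"condition {c!r} empty at position {position}")
    x = np.column_stack(
        [np.ones(len(sub)), (sub[spec.condition] == b).astype(float)]
    )
    model = RandomInterceptLMM(
        endog=sub[spec.response].to_numpy(dtype=float),
        exog=x,
        groups=sub[spec.groups].to_numpy(),
        exog_names=["Intercept", f"C[{b}]"],
    )
    res = model.fit(reml=reml)
    ft = res.f_test([1], term=f"{b} - {a} @ position {position:g}")
    return ft


def split_half(
    summaries: pd.DataFrame, spec: LMMSpec | None = None, reml: bool = False
) -> dict[str, tuple[RandomInterceptLMMResults, FTestResult]]:
    """Odd/even split-half re-analysis on the epoch ordinal within subject.

    Epoch order follows first appearance of ``reference_id`` within each
    subject (deterministic).  Each half is refitted and its interaction F
    recomputed, giving a reliability check at half the sample size.
    """
    spec = spec or LMMSpec()
    if "reference_id" not in summaries.columns:
        raise ValueError("summary table lacks 'reference_id' for the epoch ordinal")
    df = summaries.copy()
    key = df[spec.groups].astype(str) + "::" + df["reference_id"].astype(str)
    first_row = {}
    for i, k in enumerate(key):
        first_row.setdefault(k, i)
    subj_of = {k: k.split("::")[0] for k in first_row}
    ordinal: dict[str, int] = {}
    counters: dict[str, int] = {}
    for k, _ in sorted(first_row.items(), key=lambda kv: kv[1]):
        s = subj_of[k]
        ordinal[k] = counters.get(s, 0)
        counters[s] = ordinal[k] + 1
    parity = key.map(ordinal).to_numpy() % 2

    out = {}
    for name, mask in (("even", parity == 0), ("odd", parity == 1)):
        half = df[mask]
        if half.empty:
            raise ValueError(f"{name} half is empty")
        res = fit_lmm(half, spec, reml=reml)
        out[name] = (res, anova_interaction(res))
    return out


def two_sample_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test (two-sided).

    Returns (t, df, p) with df = n1 + n2 - 2.  Degenerate zero-variance
    input with equal means gives t = 0, p = 1; with unequal means it is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    diff = float(np.mean(x) - np.mean(y))
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p
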
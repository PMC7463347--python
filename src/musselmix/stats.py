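"""Inferential layer: group tests, linear models, the random-intercept
mixed model with parametric-bootstrap likelihood-ratio tests, and
environment correlations with Benjamini–Hochberg FDR control.

The mixed model is the Gaussian random-intercept model

    y = X beta + u_site + eps,   u_site ~ N(0, s2_site),  eps ~ N(0, s2_resid),

fitted by maximum likelihood (not REML: likelihood-ratio tests on fixed
effects require ML) via direct optimisation of the profile log-likelihood
over the variance ratio lam = s2_site / s2_resid. For a given lam the GLS
estimate of beta and the ML residual variance are available in closed
form through the Woodbury identity, so each fit is a one-dimensional
optimisation — fast enough to refit thousands of bootstrap replicates.

Significance of a fixed term is assessed by a parametric bootstrap: the
observed LR = 2(loglik_full − loglik_null) is compared against LRs from
responses simulated under the *fitted* null model (site intercepts drawn
first, then residuals); p = (1 + #{LR* ≥ LR_obs}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# simple group tests
# ---------------------------------------------------------------------------

def t_test(x, y, pooled: bool = False):
    """Two-sided two-sample t test; Welch by default, pooled optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("t statistic undefined: zero variance, equal means")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    if pooled:
        df = len(x) + len(y) - 2
    else:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def anova_oneway(values, groups):
    """Classical one-way F test. Returns (F, df1, df2, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("at least 2 groups required")
    samples = [values[groups == g] for g in levels]
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    if df2 < 1:
        raise ValueError("insufficient residual degrees of freedom")
    res = sps.f_oneway(*samples)
    return float(res.statistic), df1, df2, float(res.pvalue)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Fit summary shared by the linear and mixed models."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    loglik: float
    f_table: pd.DataFrame | None = None  # sequential per-term F tests
    sigma2_site: float | None = None
    sigma2_resid: float | None = None
    converged: bool = True
    lr_stat: float | None = None
    boot_p: float | None = None
    n_boot: int | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    table: pd.DataFrame  # species, covariate, r, p, q, flagged


# ---------------------------------------------------------------------------
# fixed-effects linear model
# ---------------------------------------------------------------------------

def fit_lm(formula: str, data: pd.DataFrame) -> ModelResult:
    """OLS with sequential (type-I) per-term F tests.

    Terms are tested in formula order. Rank-deficient designs raise,
    naming the aliased term.
    """
    for col in data.columns:
        if col in formula and data[col].dtype == object and data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level; term is aliased")
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        aliased = X.columns[np.abs(np.diag(R)) < 1e-8 * np.abs(R).max()].tolist()
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased}")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    fit = ols(formula, data=data).fit()
    ftab = anova_lm(fit, typ=1)
    return ModelResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        loglik=float(fit.llf),
        f_table=ftab,
        sigma2_resid=float(fit.scale),
        extra={"pvalues": fit.pvalues, "rsquared": float(fit.rsquared)},
    )


def species_slopes(
    data: pd.DataFrame,
    y_col: str,
    x_col: str = "introgression",
    group_col: str = "main",
    min_group: int = 2,
) -> pd.DataFrame:
    """Within-background regression slopes of y on introgression.

    One OLS per main-ancestry level with at least ``min_group`` members
    (levels below that — typically MT, with a single pure site — are
    reported without a test). Returns (group, n, b, t, p).
    """
    rows = []
    for g, sub in data.groupby(group_col, sort=True):
        sub = sub.dropna(subset=[y_col, x_col])
        n = len(sub)
        if n < max(min_group, 3) or np.std(sub[x_col]) < 1e-4:
            rows.append({"group": g, "n": n, "b": np.nan, "t": np.nan, "p": np.nan})
            continue
        fit = ols(f"{y_col} ~ {x_col}", data=sub).fit()
        rows.append(
            {
                "group": g,
                "n": n,
                "b": float(fit.params[x_col]),
                "t": float(fit.tvalues[x_col]),
                "p": float(fit.pvalues[x_col]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept mixed model (profile-likelihood ML)
# ---------------------------------------------------------------------------

def _group_codes(groups) -> np.ndarray:
    return pd.factorize(np.asarray(groups))[0]


class _LmmWork:
    """Sufficient statistics reused across profile-likelihood evaluations."""

    def __init__(self, y, X, g):
        self.y = y
        self.X = X
        self.g = g
        self.n, self.p = X.shape
        self.G = int(g.max()) + 1
        self.ng = np.bincount(g, minlength=self.G).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Xg = np.zeros((self.G, self.p))
        np.add.at(self.Xg, g, X)
        self.yg = np.bincount(g, weights=y, minlength=self.G)

    def profile(self, lam: float):
        """(−2·profile loglik, beta, sigma2_resid) at variance ratio lam."""
        c = lam / (1.0 + lam * self.ng)  # per-group Woodbury weight
        A = self.XtX - self.Xg.T @ (c[:, None] * self.Xg)
        b = self.Xty - self.Xg.T @ (c * self.yg)
        beta = np.linalg.solve(A, b)
        quad = (self.yty - c @ self.yg**2) - 2 * beta @ b + beta @ A @ beta
        quad = max(quad, 1e-300)
        sigma2 = quad / self.n
        logdet = np.log1p(lam * self.ng).sum()
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return -2 * ll, beta, sigma2, A


def fit_lmm(y, X, groups, param_names=None) -> ModelResult:
    """ML fit of the Gaussian random-intercept model.

    ``X`` must include the intercept column. The profile log-likelihood
    is maximised over log(lam), lam = sigma2_site/sigma2_resid, with the
    lam = 0 boundary (plain OLS) checked explicitly.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    g = _group_codes(groups)
    if int(g.max()) + 1 < 2:
        raise ValueError("at least 2 sites required for a random intercept")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    work = _LmmWork(y, X, g)

    def nll_at(theta):
        return work.profile(np.exp(theta))[0]

    res = minimize_scalar(
        nll_at, bounds=(-18.0, 12.0), method="bounded", options={"xatol": 1e-7}
    )
    converged = bool(res.success)
    cand = [(work.profile(0.0)[0], 0.0), (res.fun, float(np.exp(res.x)))]
    nll, lam = min(cand, key=lambda t: t[0])
    _, beta, sigma2, A = work.profile(lam)
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    names = param_names or [f"b{i}" for i in range(len(beta))]
    params = pd.Series(beta, index=names)
    return ModelResult(
        params=params,
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(beta / se, index=names),
        loglik=-nll / 2.0,
        sigma2_site=lam * sigma2,
        sigma2_resid=sigma2,
        converged=converged,
        extra={"lam": lam, "n_groups": work.G},
    )


@dataclass
class LmmSpec:
    """Declarative mixed-model specification: fixed formula + grouping."""

    response: str
    fixed: str  # patsy right-hand side, e.g. "main * introgression"
    groups: str  # column holding the site labels

    def design(self, data: pd.DataFrame):
        X = patsy.dmatrix(self.fixed, data, return_type="dataframe")
        y = data[self.response].to_numpy(dtype=float)
        return y, X.to_numpy(), list(X.columns), data[self.groups].to_numpy()

    def fit(self, data: pd.DataFrame) -> ModelResult:
        y, X, names, g = self.design(data)
        return fit_lmm(y, X, g, param_names=names)


def parametric_bootstrap_lrt(
    full: LmmSpec,
    null: LmmSpec,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> ModelResult:
    """Bootstrap LRT of ``full`` against the nested ``null``.

    LR_obs = 2(loglik_full − loglik_null), clamped at 0. Each replicate
    simulates a response from the fitted null (group intercepts then
    residuals), refits both models, and records LR*. The p-value uses the
    +1 convention, so it lies in [1/(B+1), 1]. Bitwise reproducible given
    (data, B, seed).
    """
    data = data.reset_index(drop=True)
    fit_f = full.fit(data)
    fit_n = null.fit(data)
    lr_obs = 2.0 * (fit_f.loglik - fit_n.loglik)
    if lr_obs < -1e-8:
        raise FloatingPointError("negative LR beyond tolerance: models not nested?")
    lr_obs = max(lr_obs, 0.0)

    y_n, X_n, _, g_raw = null.design(data)
    _, X_f, _, _ = full.design(data)
    g = _group_codes(g_raw)
    G = int(g.max()) + 1
    mu = X_n @ fit_n.params.to_numpy()
    sd_site = np.sqrt(max(fit_n.sigma2_site, 0.0))
    sd_res = np.sqrt(max(fit_n.sigma2_resid, 0.0))

    rng = np.random.default_rng(seed)
    lrs, failures = [], 0
    sim = data.copy()
    for _ in range(B):
        u = rng.normal(0.0, sd_site, size=G)
        eps = rng.normal(0.0, sd_res, size=len(mu))
        ystar = mu + u[g] + eps
        try:
            rf = fit_lmm(ystar, X_f, g)
            rn = fit_lmm(ystar, X_n, g)
            lrs.append(max(2.0 * (rf.loglik - rn.loglik), 0.0))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    lrs = np.asarray(lrs)
    p = (1.0 + int((lrs >= lr_obs).sum())) / (len(lrs) + 1.0)
    out = fit_f
    out.lr_stat = lr_obs
    out.boot_p = float(p)
    out.n_boot = int(len(lrs))
    out.extra["null_loglik"] = fit_n.loglik
    out.extra["n_failures"] = failures
    return out


# ---------------------------------------------------------------------------
# FDR and environment correlations
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlate_environment(pop_ancestry, covariates: pd.DataFrame) -> CorrelationResult:
    """Pearson correlations of per-site mean ancestry dosage with SST and salinity.

    Six tests (three species × two covariates), two-sided p-values from
    the t transform, BH adjustment across the tests actually performed.
    Constant covariates are flagged and excluded from the BH family.
    """
    pa = pop_ancestry.to_frame().merge(covariates, on="site", how="inner")
    if len(pa) < 4:
        raise ValueError("at least 4 sites with covariates required")
    rows = []
    for sp in pop_ancestry.species:
        for cov in ("sst_celsius", "salinity_psu"):
            x = pa[f"dosage_{sp}"].to_numpy()
            y = pa[cov].to_numpy()
            flagged = np.std(y) == 0 or np.std(x) == 0
            if flagged:
                r = p = np.nan
            else:
                r, p = sps.pearsonr(x, y)
            rows.append(
                {"species": sp, "covariate": cov, "r": r, "p": p, "flagged": flagged}
            )
    tab = pd.DataFrame(rows)
    ok = ~tab["flagged"]
    q = np.full(len(tab), np.nan)
    q[ok.to_numpy()] = bh_adjust(tab.loc[ok, "p"].to_numpy())
    tab["q"] = q
    return CorrelationResult(table=tab)
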
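"""Inference layer: t/F tests, OLS, random-intercept ML, bootstrap, BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from musselmix import stats as ms
from musselmix.ancestry import PopulationAncestry


# -- t test ------------------------------------------------------------------

def test_t_test_textbook_values():
    """x=(1,2,3), y=(4,5,6) pooled: t = -3/sqrt(2/3), df = 4."""
    t, df, p = ms.t_test([1, 2, 3], [4, 5, 6], pooled=True)
    assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
    assert df == 4
    from scipy.stats import t as tdist
    assert p == pytest.approx(2 * tdist.sf(abs(t), 4))


def test_t_test_properties():
    t1, _, p1 = ms.t_test([1, 2, 3, 4], [2, 3, 4, 5])
    t2, _, p2 = ms.t_test([2, 3, 4, 5], [1, 2, 3, 4])
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
    t0, _, p0 = ms.t_test([1, 2, 3], [3, 1, 2])
    assert t0 == pytest.approx(0.0) and p0 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ms.t_test([1.0, 1.0], [1.0, 1.0])


# -- one-way ANOVA -----------------------------------------------------------

def test_anova_hand_computed_sums_of_squares():
    """3 groups: SSB/SSW computed by hand define F."""
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    grp = np.array(["a", "a", "b", "b", "c", "c"])
    F, df1, df2, p = ms.anova_oneway(vals, grp)
    # group means 1.5, 3.5, 5.5; grand 3.5; SSB = 2*(4+0+4)=16, SSW = 3*0.5=1.5
    assert df1 == 2 and df2 == 3
    assert F == pytest.approx((16 / 2) / (1.5 / 3))


def test_anova_equal_means_and_errors():
    F, *_ = ms.anova_oneway([1, 2, 1, 2], ["a", "a", "b", "b"])
    assert F == pytest.approx(0.0)
    with pytest.raises(ValueError):
        ms.anova_oneway([1, 2], ["a", "a"])


# -- OLS ---------------------------------------------------------------------

def test_lm_exact_fit_no_noise():
    df = pd.DataFrame({"x": np.arange(8.0), "g": list("abab" * 2)})
    df["y"] = 2.0 + 3.0 * df["x"] + (df["g"] == "b") * 1.5
    res = ms.fit_lm("y ~ C(g) + x", df)
    assert res.params["x"] == pytest.approx(3.0)
    assert res.params["C(g)[T.b]"] == pytest.approx(1.5)
    assert res.sigma2_resid == pytest.approx(0.0, abs=1e-20)


def test_lm_matches_normal_equations():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=8)})
    df["y"] = 1.0 + 0.7 * df["x"] + rng.normal(size=8)
    res = ms.fit_lm("y ~ x", df)
    X = np.column_stack([np.ones(8), df["x"]])
    beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
    np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-10)


def test_lm_rank_deficient_names_alias():
    df = pd.DataFrame({
        "y": [1.0, 2.0, 3.0, 4.0],
        "g": ["a", "a", "a", "a"],
        "x": [0.0, 1.0, 2.0, 3.0],
    })
    with pytest.raises(ValueError, match="aliased|rank"):
        ms.fit_lm("y ~ C(g) * x", df)


def test_species_slopes_skips_tiny_groups():
    df = pd.DataFrame({
        "main": ["ME"] * 6 + ["MT"],
        "introgression": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.0],
        "ho": [0.1, 0.12, 0.13, 0.15, 0.17, 0.18, 0.2],
    })
    out = ms.species_slopes(df, "ho")
    me = out[out["group"] == "ME"].iloc[0]
    mt = out[out["group"] == "MT"].iloc[0]
    assert me["b"] > 0 and np.isnan(mt["b"])


# -- mixed model -------------------------------------------------------------

def test_lmm_reduces_to_ols_without_site_variance():
    """Data with no group effect: beta equals least squares within 1e-6."""
    rng = np.random.default_rng(1)
    n = 120
    g = np.repeat(np.arange(6), 20)
    x = rng.normal(size=n)
    y = 0.5 + 1.2 * x + rng.normal(0, 1, n)  # sigma2_site = 0
    X = np.column_stack([np.ones(n), x])
    res = ms.fit_lmm(y, X, g)
    beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(res.params.to_numpy(), beta_ols, atol=1e-6)
    rss = float(((y - X @ beta_ols) ** 2).sum())
    ll_ols = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)  # Gaussian ML at s2u=0
    assert res.loglik >= ll_ols - 1e-9


def test_lmm_matches_exhaustive_grid_on_balanced_layout():
    """Intercept-only balanced design: ML matches a direct likelihood grid."""
    rng = np.random.default_rng(2)
    G, per = 6, 8
    g = np.repeat(np.arange(G), per)
    y = 2.0 + rng.normal(0, 1.0, G)[g] + rng.normal(0, 0.7, G * per)
    X = np.ones((G * per, 1))
    res = ms.fit_lmm(y, X, g)

    def exact_nll(mu, s2u, s2e):
        ll = 0.0
        for grp in range(G):
            r = y[g == grp] - mu
            V = s2e * np.eye(per) + s2u
            sign, logdet = np.linalg.slogdet(V)
            ll += -0.5 * (per * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
        return ll

    grid_mu = np.linspace(y.mean() - 0.4, y.mean() + 0.4, 17)
    grid_u = np.linspace(0.0, 3.0, 31)
    grid_e = np.linspace(0.2, 1.5, 27)
    best = max(
        ((exact_nll(m, u, e), m, u, e) for m in grid_mu for u in grid_u for e in grid_e),
    )
    ll_best, m_b, u_b, e_b = best
    assert res.loglik >= ll_best - 1e-6
    assert res.params.iloc[0] == pytest.approx(m_b, abs=0.06)
    assert res.sigma2_site == pytest.approx(u_b, abs=0.11)
    assert res.sigma2_resid == pytest.approx(e_b, abs=0.06)


def test_lmm_matches_statsmodels_ml():
    """Independent route: statsmodels MixedLM with ML gives the same fit."""
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    g = np.repeat(np.arange(10), 15)
    x = rng.normal(size=150)
    y = 1.0 - 0.8 * x + rng.normal(0, 1.1, 10)[g] + rng.normal(0, 0.9, 150)
    X = np.column_stack([np.ones(150), x])
    res = ms.fit_lmm(y, X, g)
    md = sm.MixedLM(y, X, groups=g).fit(reml=False)
    np.testing.assert_allclose(res.params.to_numpy(), np.asarray(md.params)[:2], atol=1e-5)
    assert res.loglik == pytest.approx(float(md.llf), abs=1e-5)
    assert res.sigma2_resid == pytest.approx(float(md.scale), abs=1e-4)
    assert res.sigma2_site == pytest.approx(float(np.asarray(md.cov_re)[0, 0]), abs=1e-3)


def test_lmm_parameter_recovery():
    """Mean estimates over replicates sit within 3 Monte-Carlo SEs of truth."""
    rng = np.random.default_rng(4)
    G, per = 25, 20
    beta, s2u, s2e = np.array([1.0, 0.6]), 0.8, 1.2
    est = []
    for _ in range(60):
        g = np.repeat(np.arange(G), per)
        x = rng.normal(size=G * per)
        y = beta[0] + beta[1] * x + rng.normal(0, np.sqrt(s2u), G)[g] \
            + rng.normal(0, np.sqrt(s2e), G * per)
        X = np.column_stack([np.ones(G * per), x])
        r = ms.fit_lmm(y, X, g)
        est.append([r.params.iloc[0], r.params.iloc[1], r.sigma2_site, r.sigma2_resid])
    est = np.array(est)
    truth = np.array([beta[0], beta[1], s2u, s2e])
    mean = est.mean(axis=0)
    se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
    assert (np.abs(mean - truth) < 3 * se + 0.05 * truth).all()


# -- parametric bootstrap ----------------------------------------------------

def _toy_lmm_data(seed, n_g=8, per=10, slope=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_g), per)
    x = rng.normal(size=n_g * per)
    y = 1.0 + slope * x + rng.normal(0, 0.8, n_g)[g] + rng.normal(0, 1.0, n_g * per)
    return pd.DataFrame({"y": y, "x": x, "site": g.astype(str)})


def test_bootstrap_p_bounds_and_reproducibility():
    df = _toy_lmm_data(0, slope=1.0)
    full = ms.LmmSpec("y", "x", "site")
    null = ms.LmmSpec("y", "1", "site")
    r1 = ms.parametric_bootstrap_lrt(full, null, df, B=99, seed=7)
    r2 = ms.parametric_bootstrap_lrt(full, null, df, B=99, seed=7)
    assert r1.boot_p == r2.boot_p and r1.lr_stat == r2.lr_stat
    assert 1 / 100 <= r1.boot_p <= 1.0
    assert r1.boot_p == pytest.approx(1 / 100)  # strong effect: boundary p
    assert r1.lr_stat > 0


def test_bootstrap_null_effect_large_p():
    df = _toy_lmm_data(1, slope=0.0)
    full = ms.LmmSpec("y", "x", "site")
    null = ms.LmmSpec("y", "1", "site")
    r = ms.parametric_bootstrap_lrt(full, null, df, B=99, seed=3)
    assert r.boot_p > 0.05


# -- BH and correlations -----------------------------------------------------

def test_bh_stepup_by_hand():
    np.testing.assert_allclose(ms.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(ms.bh_adjust([0.03, 0.01, 0.02]), [0.03, 0.03, 0.03])
    # classic staircase: q_(i) = min_{j>=i} m p_(j) / j
    p = [0.01, 0.04, 0.03, 0.005]
    q = ms.bh_adjust(p)
    np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])
    assert ms.bh_adjust([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(ms.bh_adjust([1.0, 1.0]), [1.0, 1.0])
    with pytest.raises(ValueError):
        ms.bh_adjust([0.5, 1.5])


def _pop_ancestry(dosages, sites):
    d = np.asarray(dosages, dtype=float)
    main = np.array(["ME"] * len(sites), dtype=object)
    return PopulationAncestry(
        sites=list(sites), mean_dosage=d, main=main,
        introgression=np.zeros(len(sites)),
        mean_individual_introgression=np.zeros(len(sites)),
        n_individuals=np.full(len(sites), 10),
    )


def test_environment_perfect_correlation():
    sites = [f"s{i}" for i in range(6)]
    qme = np.linspace(0.2, 0.8, 6)
    d = np.column_stack([2 * qme, 2 * (1 - qme), np.zeros(6)])
    cov = pd.DataFrame({
        "site": sites,
        "sst_celsius": 20 - 10 * qme,  # exactly linear in ME dosage
        "salinity_psu": np.full(6, 33.0),  # constant: flagged
    })
    res = ms.correlate_environment(_pop_ancestry(d, sites), cov)
    tab = res.table.set_index(["species", "covariate"])
    assert tab.loc[("ME", "sst_celsius"), "r"] == pytest.approx(-1.0)
    assert tab.loc[("MG", "sst_celsius"), "r"] == pytest.approx(1.0)
    assert tab.loc[("ME", "salinity_psu"), "flagged"]
    qs = tab.loc[~tab["flagged"], "q"]
    assert (qs >= tab.loc[~tab["flagged"], "p"] - 1e-15).all()


def test_environment_permuted_covariate_rarely_significant():
    rng = np.random.default_rng(0)
    sites = [f"s{i}" for i in range(12)]
    hits = 0
    n_seeds = 40
    for _ in range(n_seeds):
        qme = rng.uniform(0, 1, 12)
        d = np.column_stack([2 * qme, 2 * (1 - qme), np.zeros(12)])
        cov = pd.DataFrame({
            "site": sites,
            "sst_celsius": rng.permutation(np.linspace(8, 20, 12)),
            "salinity_psu": rng.permutation(np.linspace(20, 35, 12)),
        })
        res = ms.correlate_environment(_pop_ancestry(d, sites), cov)
        ok = ~res.table["flagged"]
        hits += int((res.table.loc[ok, "q"] < 0.05).any())
    assert hits / n_seeds <= 0.05


def test_environment_requires_enough_sites():
    d = np.array([[2, 0, 0], [0, 2, 0]])
    cov = pd.DataFrame({"site": ["a", "b"], "sst_celsius": [1.0, 2.0],
                        "salinity_psu": [3.0, 4.0]})
    with pytest.raises(ValueError, match="4 sites"):
        ms.correlate_environment(_pop_ancestry(d, ["a", "b"]), cov)
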
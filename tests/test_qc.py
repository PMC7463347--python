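"""Filter chain: boundary semantics, brute-force equivalence, planted truth."""

import numpy as np
import pytest

from musselmix import qc, simdata
from musselmix.genio import MISSING, GenotypeMatrix

from conftest import (
    make_random_gm,
    oracle_callrate_keep,
    oracle_depthcap_keep,
    oracle_indiv_keep,
    oracle_ld_keep,
    oracle_maf_keep,
    oracle_mask,
)


def _gm_from(G, DP=None, GQ=None):
    G = np.asarray(G, dtype=np.int8)
    n, L = G.shape
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        loci=[f"c:{j+1}" for j in range(L)],
        ref=["A"] * L,
        alt=["T"] * L,
        G=G,
        DP=None if DP is None else np.asarray(DP, dtype=np.int32),
        GQ=None if GQ is None else np.asarray(GQ, dtype=np.int32),
        popmap={s: "x" for s in samples},
    )


# -- genotype masking ------------------------------------------------------

def test_gq_exactly_at_threshold_is_masked():
    """'greater than five' is strict: GQ=5 or DP=5 fails."""
    gm = _gm_from([[1, 1, 1]], DP=[[6, 6, 5]], GQ=[[5, 6, 99]])
    out = qc.mask_low_quality_genotypes(gm, qc.QcConfig())
    np.testing.assert_array_equal(out.G[0], [MISSING, 1, MISSING])


def test_high_quality_matrix_unchanged():
    gm = make_random_gm(0, missing=0.0)
    gm.GQ[:] = 99
    gm.DP[:] = 30
    out = qc.mask_low_quality_genotypes(gm, qc.QcConfig())
    np.testing.assert_array_equal(out.G, gm.G)


def test_masking_without_dp_gq_warns_noop():
    gm = make_random_gm(0, with_dpgq=False)
    with pytest.warns(UserWarning):
        out = qc.mask_low_quality_genotypes(gm, qc.QcConfig())
    np.testing.assert_array_equal(out.G, gm.G)


# -- site call rate --------------------------------------------------------

def test_callrate_boundary_inclusive():
    """59% typed removed, exactly 60% kept."""
    G = np.ones((100, 2), dtype=np.int8)
    G[:41, 0] = MISSING  # 59% call rate
    G[:40, 1] = MISSING  # 60%
    out = qc.filter_site_callrate(_gm_from(G), qc.QcConfig())
    assert out.loci == ["c:2"]


# -- depth cap -------------------------------------------------------------

def test_depth_cap_strictly_greater():
    """Cap = 2 x 17.2 = 34.4: mean depth 34.5 removed, 34.4 kept."""
    G = np.ones((2, 2), dtype=np.int8)
    DP = np.array([[35, 34], [34, 34]], dtype=np.int32)  # means 34.5, 34.0
    gm = _gm_from(G, DP=DP)
    out = qc.filter_depth_cap(gm, qc.QcConfig(), raw_mean=17.2)
    assert out.loci == ["c:2"]
    # exactly at the cap is kept
    gm2 = _gm_from(G, DP=np.full((2, 2), 40, dtype=np.int32))
    out2 = qc.filter_depth_cap(gm2, qc.QcConfig(), raw_mean=20.0)
    assert out2.n_loci == 2


def test_depth_cap_requires_dp():
    gm = make_random_gm(0, with_dpgq=False)
    with pytest.raises(ValueError, match="DP"):
        qc.filter_depth_cap(gm, qc.QcConfig(), raw_mean=10.0)


# -- individual missingness ------------------------------------------------

def test_individual_missingness_boundary():
    """51% missing removed, exactly 50% kept."""
    G = np.ones((2, 100), dtype=np.int8)
    G[0, :51] = MISSING
    G[1, :50] = MISSING
    out = qc.filter_individuals(_gm_from(G), qc.QcConfig())
    assert out.samples == ["s1"]


def test_all_individuals_removed_errors():
    G = np.full((2, 10), MISSING, dtype=np.int8)
    with pytest.raises(ValueError, match="all samples"):
        qc.filter_individuals(_gm_from(G), qc.QcConfig())


# -- MAF -------------------------------------------------------------------

def test_maf_boundary_strict():
    """One het among 100 diploids (MAF .005) and MAF exactly .01 both drop."""
    G = np.zeros((100, 3), dtype=np.int8)
    G[0, 0] = 1  # MAF 0.005
    G[0, 1] = 2  # MAF 0.01 exactly
    G[:30, 2] = 1  # MAF 0.15
    out = qc.filter_maf(_gm_from(G), qc.QcConfig())
    assert out.loci == ["c:3"]


# -- LD pruning ------------------------------------------------------------

def test_duplicated_locus_pruned_and_r2_half_kept():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.5, size=40).astype(np.int8)
    # build a pair with r² exactly 0.5 is fiddly; use planted duplicate + weak pair
    G = np.column_stack([g, g, rng.binomial(2, 0.5, size=40)]).astype(np.int8)
    out = qc.ld_prune(_gm_from(G), qc.QcConfig(ld_window=3, ld_step=1))
    assert out.n_loci == 2  # one copy of the duplicate pair removed


def test_r2_exactly_at_threshold_kept():
    """Strict '>': a pair at exactly r² = 0.5 survives."""
    # dosage vectors with correlation sqrt(0.5) constructed by hand:
    x = np.array([0, 0, 1, 1], dtype=np.int8)
    y = np.array([0, 1, 0, 1], dtype=np.int8)
    z = ((x + y) >= 1).astype(np.int8)  # corr(x, x+y) = sqrt(.5) if vars equal
    G = np.column_stack([x, (x + y).astype(np.int8)])
    from conftest import oracle_pair_r2
    assert oracle_pair_r2(G[:, 0], G[:, 1]) == pytest.approx(0.5)
    out = qc.ld_prune(_gm_from(G), qc.QcConfig(ld_window=2, ld_step=1))
    assert out.n_loci == 2


@pytest.mark.parametrize("seed", range(5))
def test_ld_prune_matches_naive_oracle(seed):
    gm = make_random_gm(seed, n_samples=40, n_loci=60, missing=0.15)
    # plant a few duplicates to create real LD
    rng = np.random.default_rng(seed + 100)
    for j in rng.choice(50, size=5, replace=False):
        gm.G[:, j + 5] = gm.G[:, j]
    cfg = qc.QcConfig(ld_window=12, ld_step=3)
    out = qc.ld_prune(gm, cfg)
    keep = oracle_ld_keep(gm, 12, 3, 0.5)
    assert out.loci == [gm.loci[j] for j in keep]


# -- chain -----------------------------------------------------------------

def test_permissive_config_is_identity():
    gm = make_random_gm(1, n_samples=20, n_loci=40, missing=0.1)
    cfg = qc.QcConfig(
        min_gq=0, min_dp=0, min_site_callrate=0.0, depth_cap_multiplier=1e9,
        max_indiv_missing=1.0, min_maf=0.0, ld_r2_max=1.0,
    )
    # min_maf=0 strict would still drop monomorphic loci; keep all polymorphic
    out, rep = qc.run_qc(gm, cfg)
    polymorphic = [j for j in range(gm.n_loci)
                   if len({int(v) for v in gm.G[:, j] if v != MISSING}) > 1]
    assert out.n_loci == len(polymorphic) or out.n_loci == gm.n_loci


def test_chain_monotone_and_idempotent():
    gm = make_random_gm(2, n_samples=30, n_loci=80, missing=0.25)
    out, rep = qc.run_qc(gm, qc.QcConfig())
    counts = [(s["n_samples"], s["n_loci"]) for s in rep.steps]
    for (a1, b1), (a2, b2) in zip(counts, counts[1:]):
        assert a2 <= a1 and b2 <= b1
    out2, rep2 = qc.run_qc(out, qc.QcConfig())
    assert out2.n_samples == out.n_samples
    assert out2.loci == out.loci


def test_planted_violations_reported_with_reason():
    """Each planted QC violation is removed under its own reason."""
    cfg = simdata.SimConfig(seed=5, n_loci=400, n_diagnostic=12, missing_rate=0.02)
    data = simdata.simulate_dataset(cfg, plant=True)
    gm = data["gm"]
    manifest = data["manifest"]
    out, rep = qc.run_qc(gm, qc.QcConfig())
    for locus in manifest["low_callrate"]:
        assert rep.removed.get(locus) == "callrate", locus
    for locus in manifest["high_depth"]:
        assert rep.removed.get(locus) == "depth_cap", locus
    for locus in manifest["sub_maf"]:
        assert rep.removed.get(locus) == "maf", locus
    for sample in manifest["high_missing"]:
        assert rep.removed.get(sample) == "indiv_missing", sample
    for orig, dup in manifest["duplicates"]:
        survivors = set(out.loci)
        assert not ({orig, dup} <= survivors), (orig, dup)


def test_qc_report_serialises(tmp_path):
    gm = make_random_gm(4)
    out, rep = qc.run_qc(gm, qc.QcConfig())
    payload = rep.to_json(tmp_path / "r.json")
    assert "raw_mean_depth" in payload
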
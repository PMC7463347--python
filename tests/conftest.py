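"""Shared fixtures: random genotype matrices and brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
no vectorisation) so they stay independent of the package's code paths.
"""

import numpy as np
import pytest

from musselmix.genio import MISSING, GenotypeMatrix


def make_random_gm(
    seed, n_samples=12, n_loci=30, missing=0.2, with_dpgq=True, n_sites=3
):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_loci)
    G = rng.binomial(2, p, size=(n_samples, n_loci)).astype(np.int8)
    G[rng.random((n_samples, n_loci)) < missing] = MISSING
    DP = GQ = None
    if with_dpgq:
        DP = rng.integers(0, 60, size=(n_samples, n_loci)).astype(np.int32)
        GQ = rng.integers(0, 100, size=(n_samples, n_loci)).astype(np.int32)
    samples = [f"s{i:02d}" for i in range(n_samples)]
    sites = [f"site{(i % n_sites) + 1}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=samples,
        loci=[f"chr1:{100 + j}" for j in range(n_loci)],
        ref=["A"] * n_loci,
        alt=["T"] * n_loci,
        G=G,
        DP=DP,
        GQ=GQ,
        popmap=dict(zip(samples, sites)),
        panelmap={f"site{k + 1}": sp for k, sp in enumerate(["ME", "MG", "MT"])},
    )


@pytest.fixture
def gm_factory():
    return make_random_gm


# ---------------------------------------------------------------------------
# brute-force QC oracles (explicit loops)
# ---------------------------------------------------------------------------

def oracle_mask(gm, min_gq, min_dp):
    G = gm.G.copy()
    for i in range(gm.n_samples):
        for j in range(gm.n_loci):
            if G[i, j] == MISSING:
                continue
            if gm.GQ is not None and gm.GQ[i, j] <= min_gq:
                G[i, j] = MISSING
            elif gm.DP is not None and gm.DP[i, j] <= min_dp:
                G[i, j] = MISSING
    return G


def oracle_callrate_keep(gm, min_callrate):
    keep = []
    for j in range(gm.n_loci):
        typed = sum(1 for i in range(gm.n_samples) if gm.G[i, j] != MISSING)
        if typed / gm.n_samples >= min_callrate:
            keep.append(j)
    return keep


def oracle_depthcap_keep(gm, mult, raw_mean):
    keep = []
    for j in range(gm.n_loci):
        dps = [gm.DP[i, j] for i in range(gm.n_samples) if gm.G[i, j] != MISSING]
        mean_dp = sum(dps) / len(dps) if dps else 0.0
        if not mean_dp > mult * raw_mean:
            keep.append(j)
    return keep


def oracle_indiv_keep(gm, max_missing):
    keep = []
    for i in range(gm.n_samples):
        miss = sum(1 for j in range(gm.n_loci) if gm.G[i, j] == MISSING)
        if not miss / gm.n_loci > max_missing:
            keep.append(i)
    return keep


def oracle_maf_keep(gm, min_maf):
    keep = []
    for j in range(gm.n_loci):
        alt = tot = 0
        for i in range(gm.n_samples):
            if gm.G[i, j] != MISSING:
                alt += gm.G[i, j]
                tot += 2
        if tot == 0:
            continue
        p = alt / tot
        if min(p, 1 - p) > min_maf:
            keep.append(j)
    return keep


def oracle_pair_r2(g1, g2):
    xs = [(a, b) for a, b in zip(g1, g2) if a != MISSING and b != MISSING]
    if len(xs) < 2:
        return 0.0
    x = np.array([a for a, _ in xs], dtype=float)
    y = np.array([b for _, b in xs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def oracle_ld_keep(gm, window, step, r2_max):
    """Naive re-implementation of the windowed pruning rule."""
    L = gm.n_loci
    callrate = [
        sum(1 for i in range(gm.n_samples) if gm.G[i, j] != MISSING) / gm.n_samples
        for j in range(L)
    ]
    alive = [True] * L
    starts = list(range(0, max(L - window, 0) + 1, step))
    if not starts or starts[-1] + window < L:
        starts.append(max(L - window, 0))
    for s in starts:
        idx = [j for j in range(s, min(s + window, L)) if alive[j]]
        for a_i in range(len(idx)):
            for b_i in range(a_i + 1, len(idx)):
                a, b = idx[a_i], idx[b_i]
                if not (alive[a] and alive[b]):
                    continue
                if oracle_pair_r2(gm.G[:, a], gm.G[:, b]) > r2_max:
                    if callrate[a] < callrate[b]:
                        alive[a] = False
                    else:
                        alive[b] = False
    return [j for j in range(L) if alive[j]]


def oracle_smlh(gm, subset_cols):
    """Per-individual sMLH by explicit double loop."""
    n = gm.n_samples
    baseline = {}
    for j in subset_cols:
        typed = [i for i in range(n) if gm.G[i, j] != MISSING]
        if typed:
            baseline[j] = sum(1 for i in typed if gm.G[i, j] == 1) / len(typed)
    out = []
    for i in range(n):
        het = denom = 0.0
        n_used = 0
        for j in subset_cols:
            if gm.G[i, j] == MISSING or j not in baseline:
                continue
            n_used += 1
            denom += baseline[j]
            if gm.G[i, j] == 1:
                het += 1
        out.append(het / denom if (n_used and denom > 0) else np.nan)
    return np.array(out)


def oracle_population_ho(gm):
    sites = {}
    for i, s in enumerate(gm.samples):
        sites.setdefault(gm.popmap[s], []).append(i)
    out = {}
    for site, idx in sites.items():
        per_locus = []
        for j in range(gm.n_loci):
            typed = [i for i in idx if gm.G[i, j] != MISSING]
            if typed:
                per_locus.append(sum(1 for i in typed if gm.G[i, j] == 1) / len(typed))
        out[site] = sum(per_locus) / len(per_locus)
    return out
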
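"""Synthetic three-species admixture datasets.

The generator reproduces the statistical structure the analysis assumes,
so every stage is testable without external downloads:

* loci fall into cross-species polymorphism classes with configurable
  fractions (private to one species / shared by two / shared by three /
  monomorphic), plus a planted set of MT-diagnostic fixed differences;
* polymorphic allele frequencies follow symmetric Beta(a_s, a_s) spectra
  calibrated per species so the expected all-locus observed
  heterozygosity of a pure population hits the targets
  Ho(ME) < Ho(MG) < Ho(MT) (defaults 0.09 / 0.11 / 0.13);
* shared loci carry one common ancestral frequency across their member
  species, and species in which a private locus is monomorphic are fixed
  at the owner's major allele — both reflect shared ancestral variation;
* individuals are admixed: per site, Q is drawn from a Dirichlet (or
  fixed at a simplex vertex for the pure reference sites), and at each
  locus the two allele copies descend from ONE ancestry source drawn
  from Cat(Q) (a diploid local-ancestry mosaic, ``ancestry_correlation``
  = 1; setting it to 0 samples each copy's source independently, the
  classic admixture-LD-free model);
* MCAR missingness plus negative-binomial depth and a deterministic
  depth→GQ map populate the fields every QC filter reads, and optional
  "plants" inject known violations of each filter rule;
* per-site SST decreases (and salinity is flat) in mean ME ancestry,
  SST increases in MG, salinity decreases in MT, with Gaussian noise.

Everything is driven by one integer seed and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import SPECIES, UNKNOWN, GenotypeMatrix

CLASS_LABELS = ("ME", "MG", "MT", "ME+MG", "ME+MT", "MG+MT", "ME+MG+MT")


def beta_shape_for_het(h: float) -> float:
    """Shape a of a symmetric Beta with E[2p(1-p)] = h (h < 0.5).

    For p ~ Beta(a, a): E[p(1-p)] = a² / (2a (2a+1)) = a / (2(2a+1)),
    hence E[2p(1-p)] = a/(2a+1) and a = h/(1-2h).
    """
    if not 0 < h < 0.5:
        raise ValueError("target heterozygosity must lie in (0, 0.5)")
    return h / (1.0 - 2.0 * h)


@dataclass
class PopulationSpec:
    site: str
    n: int
    q_mean: tuple  # mean ancestry proportions (ME, MG, MT)
    fixed: bool = False  # pure reference site: Q fixed at q_mean
    species: str = UNKNOWN  # panel label


def default_populations() -> list:
    """Three pure reference sites plus a 12-site admixture cline.

    The cline spans MG-dominated southern sites with increasing ME
    introgression, and ME-dominated northern sites with varying MG and
    small MT fractions (largest near the Baltic) — the sampling structure
    of a European hybrid-zone survey.
    """
    pure = [
        PopulationSpec("GE1", 17, (1, 0, 0), fixed=True, species="ME"),
        PopulationSpec("ITA", 16, (0, 1, 0), fixed=True, species="MG"),
        PopulationSpec("CAN", 18, (0, 0, 1), fixed=True, species="MT"),
    ]
    admixed = [
        PopulationSpec("PO1", 18, (0.04, 0.95, 0.01)),
        PopulationSpec("PO2", 18, (0.10, 0.89, 0.01)),
        PopulationSpec("PO3", 18, (0.17, 0.82, 0.01)),
        PopulationSpec("FRA", 15, (0.30, 0.69, 0.01)),
        PopulationSpec("UK1", 16, (0.80, 0.18, 0.02)),
        PopulationSpec("UK2", 15, (0.90, 0.08, 0.02)),
        PopulationSpec("UK3", 14, (0.72, 0.25, 0.03)),
        PopulationSpec("UK4", 18, (0.82, 0.10, 0.08)),
        PopulationSpec("UK5", 18, (0.68, 0.27, 0.05)),
        PopulationSpec("NET", 17, (0.88, 0.10, 0.02)),
        PopulationSpec("GE2", 17, (0.78, 0.10, 0.12)),
        PopulationSpec("SWE", 17, (0.76, 0.09, 0.15)),
    ]
    return pure + admixed


@dataclass
class SimConfig:
    seed: int = 0
    n_loci: int = 2000
    # fractions of loci private to one species / shared by two / by three
    class_fractions: tuple = (0.523, 0.243, 0.090)
    n_diagnostic: int = 60
    ho_targets: dict = field(
        default_factory=lambda: {"ME": 0.09, "MG": 0.11, "MT": 0.13}
    )
    shared_het: float = 0.25  # E[2p(1-p)] at shared (ancestral) loci
    populations: list = field(default_factory=default_populations)
    dirichlet_concentration: float = 30.0
    ancestry_correlation: float = 1.0  # 1 = diploid mosaic, 0 = per-copy
    missing_rate: float = 0.05
    depth_mean: float = 20.0
    depth_shape: float = 8.0  # negative-binomial size parameter
    gq_per_depth: int = 4  # GQ = min(99, gq_per_depth * DP)
    sst_base: float = 14.0
    sst_slope: float = 6.0  # SST = base + slope*(qMG - qME) + noise
    sst_noise: float = 0.8
    salinity_base: float = 33.0
    salinity_slope: float = -20.0  # salinity = base + slope*qMT + noise
    salinity_noise: float = 1.0

    def __post_init__(self):
        if sum(self.class_fractions) > 1 + 1e-9:
            raise ValueError("class fractions must sum to at most 1")
        if self.n_diagnostic > self.n_loci:
            raise ValueError("n_diagnostic exceeds n_loci")
        if not 0 <= self.ancestry_correlation <= 1:
            raise ValueError("ancestry_correlation must lie in [0,1]")
        for p in self.populations:
            if not p.fixed and min(p.q_mean) <= 0:
                raise ValueError(f"Dirichlet mean must be positive ({p.site})")

    def beta_shapes(self) -> dict:
        """Per-species private-locus Beta shapes hitting the Ho targets.

        A pure population of species s is expected to show
        Ho_s = f_private * h_private,s + f_shared,s * shared_het
        over all loci, where f_shared,s counts the two- and three-species
        classes containing s; solve for h_private,s and convert to a.
        """
        f_priv = self.class_fractions[0] / 3.0
        f_pair = self.class_fractions[1] / 3.0
        f_shared = 2 * f_pair + self.class_fractions[2]
        shapes = {}
        for s, target in self.ho_targets.items():
            h_priv = (target - f_shared * self.shared_het) / f_priv
            if not 0 < h_priv < 0.5:
                raise ValueError(
                    f"Ho target {target} for {s} not attainable with these "
                    f"class fractions (implied private het {h_priv:.3f})"
                )
            shapes[s] = beta_shape_for_het(h_priv)
        return shapes


@dataclass
class PanelTruth:
    """True per-species allele frequencies and locus labels."""

    loci: list
    p: np.ndarray  # (3, n_loci)
    poly_class: np.ndarray  # labels as in refpanel ("" = none)
    mt_diagnostic: np.ndarray
    class_counts_planted: dict


def simulate_panel_freqs(cfg: SimConfig, rng=None) -> PanelTruth:
    """Assign locus classes and draw true per-species allele frequencies.

    Class counts are exact (deterministic rounding of the configured
    fractions); locus order is a seeded permutation so classes
    interleave. Private loci draw from the owner's Beta and are fixed at
    the owner's major allele elsewhere; shared loci carry one common
    Beta(shared) frequency in every member species; diagnostic loci set
    p_MT = 1 and p_ME = p_MG = 0; remaining loci are monomorphic (all
    species fixed for the same random allele).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    shapes = cfg.beta_shapes()
    a_shared = beta_shape_for_het(cfg.shared_het)

    n_free = L - cfg.n_diagnostic
    n_priv = int(round(cfg.class_fractions[0] / 3.0 * L))
    n_pair = int(round(cfg.class_fractions[1] / 3.0 * L))
    n_three = int(round(cfg.class_fractions[2] * L))
    counts = {
        "ME": n_priv, "MG": n_priv, "MT": n_priv,
        "ME+MG": n_pair, "ME+MT": n_pair, "MG+MT": n_pair,
        "ME+MG+MT": n_three,
    }
    if sum(counts.values()) > n_free:
        raise ValueError("class fractions leave no room for diagnostic loci")

    labels = ["DIAG"] * cfg.n_diagnostic
    for lab, c in counts.items():
        labels += [lab] * c
    labels += [""] * (L - len(labels))
    labels = np.array(labels, dtype=object)[rng.permutation(L)]

    p = np.zeros((3, L))
    member = np.zeros((3, L), dtype=bool)
    for i, s in enumerate(SPECIES):
        member[i] = np.array([s in lab.split("+") for lab in labels])
    shared = member.sum(axis=0) >= 2

    # shared loci: one ancestral frequency for every member species
    p0 = rng.beta(a_shared, a_shared, size=L)
    for i in range(3):
        p[i, shared & member[i]] = p0[shared & member[i]]
    # private loci: owner's spectrum
    for i, s in enumerate(SPECIES):
        own = member[i] & ~shared
        p[i, own] = rng.beta(shapes[s], shapes[s], size=int(own.sum()))
    # non-members fixed at the members' major allele
    n_member = member.sum(axis=0)
    mean_member = np.where(member, p, 0.0).sum(axis=0) / np.maximum(n_member, 1)
    major = np.where(n_member == 0, 0.0, (mean_member >= 0.5).astype(float))
    p = np.where(member, p, major[None, :])

    # monomorphic loci: random shared allele
    mono = labels == ""
    p[:, mono] = rng.integers(0, 2, size=int(mono.sum())).astype(float)[None, :]
    # diagnostic: MT fixed alt, ME/MG fixed ref
    diag = labels == "DIAG"
    p[:, diag] = 0.0
    p[2, diag] = 1.0
    labels = np.where(labels == "DIAG", "", labels).astype(object)

    planted = dict(counts)
    planted["none"] = int(mono.sum()) + cfg.n_diagnostic
    planted["diagnostic"] = cfg.n_diagnostic
    loci = [f"L{j:05d}" for j in range(L)]
    return PanelTruth(loci, p, labels, diag, planted)


def simulate_genotypes(truth: PanelTruth, cfg: SimConfig, rng=None):
    """Draw admixed individuals and their genotypes.

    Returns ``(GenotypeMatrix, truth_Q DataFrame)``. Per individual, Q is
    the site's fixed vertex or a Dirichlet(concentration × mean) draw. At
    each locus, with probability ``ancestry_correlation`` both allele
    copies descend from one source s ~ Cat(Q) (genotype ~ Binomial(2,
    p_s)); otherwise each copy draws its own source.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    samples, sites, Qs = [], [], []
    for pop in cfg.populations:
        for k in range(pop.n):
            samples.append(f"{pop.site}_{k+1:02d}")
            sites.append(pop.site)
        if pop.fixed:
            Qs.append(np.tile(np.asarray(pop.q_mean, dtype=float), (pop.n, 1)))
        else:
            alpha = cfg.dirichlet_concentration * np.asarray(pop.q_mean, dtype=float)
            Qs.append(rng.dirichlet(alpha, size=pop.n))
    Q = np.vstack(Qs)
    n, L = Q.shape[0], cfg.n_loci
    P = truth.p  # (3, L)

    cum = Q.cumsum(axis=1)
    u1 = rng.random((n, L))
    src1 = (u1[:, :, None] > cum[:, None, :]).sum(axis=2)  # (n, L) in {0,1,2}
    rho = cfg.ancestry_correlation
    if rho >= 1.0:
        f = np.take_along_axis(P.T[None, :, :], src1[:, :, None], axis=2)[:, :, 0]
        G = rng.binomial(2, f).astype(np.int8)
    else:
        u2 = rng.random((n, L))
        src2 = (u2[:, :, None] > cum[:, None, :]).sum(axis=2)
        same = rng.random((n, L)) < rho
        src2 = np.where(same, src1, src2)
        p1 = np.take_along_axis(P.T[None, :, :], src1[:, :, None], axis=2)[:, :, 0]
        p2 = np.take_along_axis(P.T[None, :, :], src2[:, :, None], axis=2)[:, :, 0]
        G = (rng.binomial(1, p1) + rng.binomial(1, p2)).astype(np.int8)

    popmap = dict(zip(samples, sites))
    panelmap = {p_.site: p_.species for p_ in cfg.populations}
    gm = GenotypeMatrix(
        samples=samples,
        loci=list(truth.loci),
        ref=["A"] * L,
        alt=["T"] * L,
        G=G,
        popmap=popmap,
        panelmap=panelmap,
    )
    qdf = pd.DataFrame(Q, columns=[f"q_{s}" for s in SPECIES])
    qdf.insert(0, "sample_id", samples)
    qdf.insert(1, "site", sites)
    return gm, qdf


def degrade(gm: GenotypeMatrix, cfg: SimConfig, rng=None, plant: bool = False):
    """Add MCAR missingness, depth and GQ; optionally plant QC violations.

    Returns ``(GenotypeMatrix, manifest)``. The manifest lists planted
    low-call-rate loci, over-deep loci, high-missingness individuals,
    sub-MAF loci and duplicated (perfect-LD) loci, for planted-truth
    filter tests.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    out = gm.copy()
    manifest = {k: [] for k in ("low_callrate", "high_depth", "high_missing",
                                "sub_maf", "duplicates")}
    n, L = out.n_samples, out.n_loci

    dup_names: set = set()
    if plant:
        # duplicated loci (r² = 1 pre-missingness) inserted NEXT TO their
        # source so windowed pruning sees the pair
        dup_src = np.sort(rng.choice(L, size=3, replace=False))
        src_names = [out.loci[j] for j in dup_src]
        dup_ids = [f"{out.loci[j]}_dup" for j in dup_src]
        loci, ref, alt = list(out.loci), list(out.ref), list(out.alt)
        for k, j in enumerate(dup_src):  # insert right after each source
            loci.insert(j + 1 + k, dup_ids[k])
            ref.insert(j + 1 + k, out.ref[j])
            alt.insert(j + 1 + k, out.alt[j])
        G = np.insert(out.G, dup_src + 1, out.G[:, dup_src], axis=1)
        out = GenotypeMatrix(
            samples=out.samples, loci=loci, ref=ref, alt=alt, G=G,
            popmap=out.popmap, panelmap=out.panelmap,
        )
        manifest["duplicates"] = [list(pair) for pair in zip(src_names, dup_ids)]
        dup_names = {x for pair in manifest["duplicates"] for x in pair}
        n, L = out.n_samples, out.n_loci

    miss = rng.random((n, L)) < cfg.missing_rate
    nb_p = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    DP = rng.negative_binomial(cfg.depth_shape, nb_p, size=(n, L)).astype(np.int32)
    GQ = np.minimum(99, cfg.gq_per_depth * DP).astype(np.int32)

    if plant:
        free = [j for j in range(L) if out.loci[j] not in dup_names]
        picks = rng.choice(free, size=9, replace=False)
        lowcall, highdep, submaf = picks[:3], picks[3:6], picks[6:9]
        for j in lowcall:
            rows = rng.choice(n, size=int(0.45 * n), replace=False)
            miss[rows, j] = True
            manifest["low_callrate"].append(out.loci[j])
        for j in highdep:
            DP[:, j] = int(cfg.depth_mean * 4)
            manifest["high_depth"].append(out.loci[j])
        for j in submaf:
            out.G[:, j] = 0
            out.G[rng.integers(0, n), j] = 1
            manifest["sub_maf"].append(out.loci[j])
        bad_ind = rng.choice(n, size=2, replace=False)
        for i in bad_ind:
            cols = rng.choice(L, size=int(0.6 * L), replace=False)
            miss[i, cols] = True
            manifest["high_missing"].append(out.samples[i])

    out.G[miss] = -1
    out.DP = DP
    out.GQ = GQ
    return out, manifest


def simulate_covariates(sites, site_q_means: np.ndarray, cfg: SimConfig, rng=None):
    """Per-site SST and salinity correlated with true mean ancestry.

    SST = base + slope·(q_MG − q_ME) + N(0, sd): decreasing in ME,
    increasing in MG ancestry. Salinity = base + slope·q_MT + N(0, sd)
    with a negative slope: MT favours brackish water.
    """
    if len(sites) < 2:
        raise ValueError("at least 2 sites required")
    rng = rng or np.random.default_rng(cfg.seed + 3)
    q = np.asarray(site_q_means, dtype=float)
    sst = cfg.sst_base + cfg.sst_slope * (q[:, 1] - q[:, 0])
    sst = sst + rng.normal(0, cfg.sst_noise, size=len(sites))
    sal = cfg.salinity_base + cfg.salinity_slope * q[:, 2]
    sal = sal + rng.normal(0, cfg.salinity_noise, size=len(sites))
    return pd.DataFrame(
        {"site": list(sites), "sst_celsius": sst, "salinity_psu": sal}
    )


def simulate_dataset(cfg: SimConfig | None = None, plant: bool = False) -> dict:
    """Full synthetic study: genotypes, maps, covariates and truth.

    Returns a dict with keys ``gm`` (degraded GenotypeMatrix), ``truth``
    (PanelTruth), ``q_truth`` (per-individual Q), ``covariates``,
    ``manifest`` (planted violations) and ``config``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_panel_freqs(cfg, rng)
    gm, qdf = simulate_genotypes(truth, cfg, rng)
    gm, manifest = degrade(gm, cfg, rng, plant=plant)
    site_means = qdf.groupby("site", sort=False)[
        [f"q_{s}" for s in SPECIES]
    ].mean()
    cov = simulate_covariates(
        list(site_means.index), site_means.to_numpy(), cfg, rng
    )
    return {
        "gm": gm,
        "truth": truth,
        "q_truth": qdf,
        "covariates": cov,
        "manifest": manifest,
        "config": cfg,
    }
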
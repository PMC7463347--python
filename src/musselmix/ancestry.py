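"""Supervised three-way admixture estimation.

Each diploid genotype g_l at locus l is modelled as Binomial(2, f_l) with

    f_l = q_ME * p_ME,l + q_MG * p_MG,l + q_MT * p_MT,l,

where p_s,l are the pure-panel allele frequencies and Q = (q_ME, q_MG,
q_MT) lies on the 3-simplex. Q is estimated per individual by maximum
likelihood with an EM algorithm: each observed allele copy is attributed
to source species s with posterior responsibility proportional to
q_s * p_s,l (alt copies) or q_s * (1 - p_s,l) (ref copies), and q is
updated as the mean responsibility over copies. The log-likelihood is
concave in Q, so EM converges to the global maximum; multi-starts are
kept as a safeguard against flat directions.

Derived quantities follow the conventions of genome-average local-
ancestry summaries: "ancestry dosage" = 2·Q (expected allele copies per
source, 0–2 scale), "main ancestry" = argmax species, and the
introgression score I = 1 − q_main, the ancestry fraction not
attributable to the focal species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import SPECIES, GenotypeMatrix
from .refpanel import RefPanel

MIN_LOCI_DEFAULT = 50


@dataclass
class AncestryProfile:
    """Per-individual admixture estimates (rows align with ``samples``)."""

    samples: list
    Q: np.ndarray  # (n, 3) on the simplex; NaN rows for unprofiled samples
    loglik: np.ndarray
    n_iter: np.ndarray
    n_loci: np.ndarray
    species: tuple = SPECIES

    @property
    def dosage(self) -> np.ndarray:
        return 2.0 * self.Q

    def main_ancestry(self):
        return assign_main_and_introgression(self.Q)

    def to_frame(self, popmap=None) -> pd.DataFrame:
        main, intro, tie = assign_main_and_introgression(self.Q)
        df = pd.DataFrame({"sample_id": self.samples})
        if popmap:
            df["site"] = [popmap.get(s, "NA") for s in self.samples]
        for i, s in enumerate(self.species):
            df[f"q_{s}"] = self.Q[:, i]
        for i, s in enumerate(self.species):
            df[f"dosage_{s}"] = self.dosage[:, i]
        df["main"] = main
        df["introgression"] = intro
        df["tie_flag"] = tie
        df["loglik"] = self.loglik
        df["n_loci"] = self.n_loci
        df["n_iter"] = self.n_iter
        return df


def _prepare_panel(panel: RefPanel, loci, eps: float) -> np.ndarray:
    """Panel frequencies aligned to ``loci``, clamped into [eps, 1-eps].

    Clamping keeps the likelihood finite when an introgressed allele is
    absent from a finite pure panel. Loci with an undefined frequency in
    any species are excluded (NaN column).
    """
    pos = {lid: j for j, lid in enumerate(panel.loci)}
    idx = np.array([pos.get(l, -1) for l in loci])
    P = np.full((len(loci), len(panel.species)), np.nan)
    ok = idx >= 0
    P[ok] = panel.p.T[idx[ok]]
    P = np.clip(P, eps, 1 - eps)
    return P


def estimate_q(
    gm: GenotypeMatrix,
    panel: RefPanel,
    eps: float = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_starts: int = 5,
    seed: int = 0,
    min_loci: int = MIN_LOCI_DEFAULT,
) -> AncestryProfile:
    """Maximum-likelihood Q for every individual (vectorised EM).

    Individuals typed at fewer than ``min_loci`` usable loci are flagged
    (NaN row). Five runs are kept: one from the uniform start plus
    ``n_starts - 1`` Dirichlet(1,1,1) starts with a fixed seed; the best
    log-likelihood wins (the surface is concave, so starts agree up to
    tolerance — retained as a numerical safeguard).
    """
    P = _prepare_panel(panel, gm.loci, eps)
    usable = np.isfinite(P).all(axis=1)
    G = gm.G[:, usable].astype(float)
    P = P[usable]
    G[G < 0] = np.nan

    n, L = G.shape
    typed = np.isfinite(G)
    n_loci = typed.sum(axis=1)
    profiled = n_loci >= min_loci

    rng = np.random.default_rng(seed)
    starts = [np.full(3, 1.0 / 3)]
    starts += [rng.dirichlet(np.ones(3)) for _ in range(max(n_starts - 1, 0))]

    bestQ = np.full((n, 3), np.nan)
    bestll = np.full(n, -np.inf)
    best_iter = np.zeros(n, dtype=int)
    for q0 in starts:
        Q, ll, iters = _em(G, P, np.tile(q0, (n, 1)), tol, max_iter)
        better = ll > bestll
        bestQ[better] = Q[better]
        bestll[better] = ll[better]
        best_iter[better] = iters[better]

    bestQ[~profiled] = np.nan
    bestll[~profiled] = np.nan
    if not np.isfinite(bestll[profiled]).all():
        raise FloatingPointError("non-finite admixture likelihood")
    return AncestryProfile(
        samples=list(gm.samples),
        Q=bestQ,
        loglik=bestll,
        n_iter=best_iter,
        n_loci=n_loci,
    )


def _em(G, P, Q, tol, max_iter):
    """Vectorised EM over all individuals simultaneously.

    G: (n, L) dosages with NaN missing; P: (L, 3) clamped frequencies;
    Q: (n, 3) initial points. Returns (Q, loglik, n_iter).
    """
    n, L = G.shape
    typed = np.isfinite(G)
    Gz = np.where(typed, G, 0.0)
    G2z = np.where(typed, 2.0 - G, 0.0)
    Q = Q.copy()
    ll = np.full(n, -np.inf)
    iters = np.zeros(n, dtype=int)
    act = np.arange(n)  # rows still iterating
    ll_old = np.full(n, -np.inf)
    for it in range(max_iter):
        Qa = Q[act]
        F = Qa @ P.T  # (n_active, L)
        np.clip(F, 1e-12, 1 - 1e-12, out=F)
        ll_new = (Gz[act] * np.log(F) + G2z[act] * np.log1p(-F)).sum(axis=1)
        ll[act] = ll_new
        # E-step responsibilities summed over loci, per species
        A = Qa * ((Gz[act] / F) @ P + (G2z[act] / (1 - F)) @ (1 - P))
        tot = A.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            Qn = np.where(tot > 0, A / tot, Qa)
        conv = np.abs(ll_new - ll_old[act]) <= tol * (np.abs(ll_new) + 1e-12)
        iters[act[~conv]] = it + 1
        Q[act[~conv]] = Qn[~conv]
        ll_old[act] = ll_new
        act = act[~conv]
        if act.size == 0:
            break
    return Q, ll, iters


def loglik_profile(gm_row: np.ndarray, P: np.ndarray, Q_grid: np.ndarray):
    """Exact log-likelihood of one individual at each simplex grid point.

    ``gm_row``: dosages with NaN missing (length L); ``P``: (L, 3) clamped
    panel frequencies; ``Q_grid``: (m, 3) points. Returns (loglik vector,
    argmax row). Intended for ≤ ~10^4 points per call.
    """
    typed = np.isfinite(gm_row)
    g = gm_row[typed]
    p = P[typed]
    F = Q_grid @ p.T
    np.clip(F, 1e-12, 1 - 1e-12, out=F)
    ll = (g * np.log(F) + (2 - g) * np.log1p(-F)).sum(axis=1)
    return ll, Q_grid[int(np.argmax(ll))]


def simplex_grid(step: float) -> np.ndarray:
    """All points (q1, q2, 1-q1-q2) with q on a grid of the given step."""
    k = int(round(1.0 / step))
    pts = []
    for i in range(k + 1):
        for j in range(k - i + 1):
            pts.append((i / k, j / k, (k - i - j) / k))
    return np.array(pts)


def grid_search_q(gm_row, P, resolution: float = 0.001, coarse: float = 0.005):
    """Grid-search ML of Q at ``resolution`` via a coarse-then-fine scheme.

    A full pass at ``coarse`` resolution locates the optimum; a second
    pass evaluates every ``resolution``-grid point within one coarse cell
    of it. Because the log-likelihood is concave in Q, the result equals
    the argmax of the full fine grid.
    """
    ll, q0 = loglik_profile(gm_row, P, simplex_grid(coarse))
    fine = simplex_grid(resolution)
    near = np.abs(fine - q0).max(axis=1) <= coarse + resolution / 2
    ll2, q1 = loglik_profile(gm_row, P, fine[near])
    return q1


def assign_main_and_introgression(Q: np.ndarray):
    """Main ancestry (argmax species) and introgression I = 1 − q_main.

    Exact ties are broken in fixed species order ME < MG < MT and
    flagged. Works on a single Q vector or an (n, 3) array. I lies in
    [0, 2/3] by construction.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    idx = np.nanargmax(np.where(np.isnan(Q), -np.inf, Q), axis=1)
    qmax = Q[np.arange(len(Q)), idx]
    tie = (np.abs(Q - qmax[:, None]) < 1e-12).sum(axis=1) > 1
    main = np.array([SPECIES[i] for i in idx], dtype=object)
    intro = 1.0 - qmax
    allnan = np.isnan(Q).all(axis=1)
    main[allnan] = ""
    intro[allnan] = np.nan
    if len(Q) == 1:
        return main[0], float(intro[0]), bool(tie[0])
    return main, intro, tie


@dataclass
class PopulationAncestry:
    """Per-site mean ancestry dosages and site-level introgression."""

    sites: list
    mean_dosage: np.ndarray  # (n_sites, 3), sums to 2 per row
    main: np.ndarray
    introgression: np.ndarray
    mean_individual_introgression: np.ndarray
    n_individuals: np.ndarray
    species: tuple = SPECIES

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"site": self.sites})
        for i, s in enumerate(self.species):
            df[f"dosage_{s}"] = self.mean_dosage[:, i]
        df["main"] = self.main
        df["introgression"] = self.introgression
        df["mean_individual_introgression"] = self.mean_individual_introgression
        df["n_individuals"] = self.n_individuals
        return df


def population_ancestry(profile: AncestryProfile, popmap: dict) -> PopulationAncestry:
    """Average individual dosages within each site.

    Site introgression is 1 − mean(q_main) of the site's main species
    (computed from the mean dosage); the mean of individual introgression
    scores is reported alongside, since the two differ when main ancestry
    varies within a site.
    """
    site_of = np.array([popmap[s] for s in profile.samples])
    ok = np.isfinite(profile.Q).all(axis=1)
    sites = list(dict.fromkeys(site_of))
    md, mains, intro, mind, counts = [], [], [], [], []
    for site in sites:
        rows = np.flatnonzero((site_of == site) & ok)
        if rows.size == 0:
            raise ValueError(f"site {site} has no profiled individuals")
        mean_dos = profile.dosage[rows].mean(axis=0)
        main, I, _ = assign_main_and_introgression(mean_dos / 2.0)
        _, ind_I, _ = assign_main_and_introgression(profile.Q[rows])
        md.append(mean_dos)
        mains.append(main)
        intro.append(I)
        mind.append(float(np.mean(ind_I)))
        counts.append(rows.size)
    return PopulationAncestry(
        sites=sites,
        mean_dosage=np.array(md),
        main=np.array(mains, dtype=object),
        introgression=np.array(intro),
        mean_individual_introgression=np.array(mind),
        n_individuals=np.array(counts),
    )
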
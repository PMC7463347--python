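"""Reference-panel construction, polymorphism classes, and diagnostic loci.

Pure reference populations of the three species (ME = *M. edulis*,
MG = *M. galloprovincialis*, MT = *M. trossulus*) provide per-locus
alt-allele frequencies ``p[s, l]``. From these the module derives

* the cross-species polymorphism class of every locus — the subset of
  species in which the locus segregates (0 < p < 1), the input of the
  three-set Venn summary and of the class-partitioned heterozygosity
  analysis (ME-only, MG-only, and ME∧MG "shared" SNPs);
* MT-diagnostic loci — fixed differences where MT carries one allele and
  both ME and MG are fixed for the other, usable to track *M. trossulus*
  introgression allele-by-allele.

Classification is always based on the pure panels only, never on admixed
sites. ``min_typed`` guards against calling fixation or polymorphism on
tiny denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import SPECIES, GenotypeMatrix

CLASS_NONE = ""


@dataclass
class RefPanel:
    """Per-species reference allele frequencies and derived locus labels.

    ``p`` and ``n`` are (3, n_loci) arrays in species order (ME, MG, MT);
    ``p`` is NaN where a species has zero typed pure genotypes at a locus.
    """

    loci: list
    p: np.ndarray
    n: np.ndarray
    species: tuple = SPECIES
    poly_class: np.ndarray | None = None  # e.g. "ME", "ME+MG", "" (none)
    mt_diagnostic: np.ndarray | None = None
    mt_allele: np.ndarray | None = None  # "ref"/"alt"/"" at diagnostic loci

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.p.shape != (len(self.species), len(self.loci)):
            raise ValueError("p must be (n_species, n_loci)")
        ok = np.isnan(self.p) | ((self.p >= 0) & (self.p <= 1))
        if not ok.all():
            raise ValueError("panel frequencies must lie in [0,1] or be NaN")

    @classmethod
    def from_frequencies(cls, loci, p, n_typed=None) -> "RefPanel":
        """Build a panel directly from known per-species frequencies.

        Used with the simulator's truth table, where frequencies are exact
        (``n_typed`` defaults to a large pseudo-count).
        """
        p = np.asarray(p, dtype=float)
        n = (
            np.full(p.shape, 10**6, dtype=int)
            if n_typed is None
            else np.asarray(n_typed, dtype=int)
        )
        return cls(list(loci), p, n)

    def to_frame(self) -> pd.DataFrame:
        cols = {"locus": self.loci}
        for i, s in enumerate(self.species):
            cols[f"p_{s}"] = self.p[i]
            cols[f"n_{s}"] = self.n[i]
        if self.poly_class is not None:
            cols["class"] = self.poly_class
        if self.mt_diagnostic is not None:
            cols["mt_diagnostic"] = self.mt_diagnostic
            cols["mt_allele"] = self.mt_allele
        return pd.DataFrame(cols)


def build_panel(gm: GenotypeMatrix) -> RefPanel:
    """Estimate per-species alt-allele frequencies from the pure sites.

    A sample contributes to species *s* when its site maps to *s* in the
    panelmap. Frequencies are computed over non-missing genotypes; loci
    with zero typed genotypes in some species are flagged NaN there.
    """
    sp = gm.species_of_sample()
    p = np.full((len(SPECIES), gm.n_loci), np.nan)
    n = np.zeros((len(SPECIES), gm.n_loci), dtype=int)
    for i, s in enumerate(SPECIES):
        rows = np.flatnonzero(sp == s)
        if rows.size == 0:
            raise ValueError(f"no pure samples for species {s}")
        G = gm.G[rows]
        typed = G >= 0
        n[i] = typed.sum(axis=0)
        alt = np.where(typed, G, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(n[i] > 0, alt / np.maximum(2 * n[i], 1), np.nan)
    return RefPanel(list(gm.loci), p, n)


def classify_polymorphism(panel: RefPanel, min_typed: int = 10) -> np.ndarray:
    """Assign each locus the subset of species in which it segregates.

    A locus is polymorphic in species *s* iff 0 < p_s < 1 and at least
    ``min_typed`` pure genotypes of *s* were typed there. Returns labels
    like ``"ME"``, ``"ME+MG"``, ``"ME+MG+MT"``; loci polymorphic nowhere
    get the empty label. The result is stored on the panel.
    """
    polys = []
    with np.errstate(invalid="ignore"):
        seg = (panel.p > 0) & (panel.p < 1) & (panel.n >= min_typed)
    for l in range(len(panel.loci)):
        members = [s for i, s in enumerate(panel.species) if seg[i, l]]
        polys.append("+".join(members) if members else CLASS_NONE)
    panel.poly_class = np.array(polys, dtype=object)
    return panel.poly_class


def class_counts(panel: RefPanel) -> dict:
    """Venn summary: locus count per polymorphism class (incl. none)."""
    if panel.poly_class is None:
        raise ValueError("classify_polymorphism has not been run")
    labels, counts = np.unique(panel.poly_class, return_counts=True)
    out = {(lab if lab else "none"): int(c) for lab, c in zip(labels, counts)}
    out["total"] = len(panel.loci)
    return out


def find_mt_diagnostic(panel: RefPanel, min_typed: int = 10) -> list:
    """Loci fixed for alternative alleles between MT and both ME and MG.

    Requires exact fixation (p ∈ {0,1}) in all three panels with at least
    ``min_typed`` typed genotypes each, ME and MG fixed for the same
    allele and MT for the other. Records which allele is the MT-fixed one.
    """
    p, n = panel.p, panel.n
    with np.errstate(invalid="ignore"):
        fixed = (p == 0) | (p == 1)
        enough = (n >= min_typed).all(axis=0)
        ok = fixed.all(axis=0) & enough & (p[0] == p[1]) & (p[0] != p[2])
    panel.mt_diagnostic = ok
    alleles = np.where(ok & (p[2] == 1), "alt", np.where(ok, "ref", ""))
    panel.mt_allele = alleles.astype(object)
    return [panel.loci[l] for l in np.flatnonzero(ok)]


def count_diagnostic_alleles(gm: GenotypeMatrix, panel: RefPanel, by: str = "site"):
    """Per-site presence of MT-diagnostic alleles.

    For each site: the number of diagnostic loci at which at least one
    copy of the MT-fixed allele occurs in at least one sample of that
    site, plus the total number of allele copies observed. This is the
    sanity check that apparent *M. trossulus* ancestry is carried by loci
    actually fixed between the species.
    """
    if panel.mt_diagnostic is None:
        raise ValueError("find_mt_diagnostic has not been run")
    diag = np.flatnonzero(panel.mt_diagnostic)
    if diag.size == 0:
        raise ValueError("no diagnostic loci")
    locus_pos = {lid: j for j, lid in enumerate(gm.loci)}
    cols = np.array([locus_pos[panel.loci[l]] for l in diag if panel.loci[l] in locus_pos])
    alleles = np.array([panel.mt_allele[l] for l in diag if panel.loci[l] in locus_pos])

    sites = gm.sites()
    rows_by_site = {s: np.flatnonzero(sites == s) for s in dict.fromkeys(sites)}
    out = {}
    for site, rows in rows_by_site.items():
        G = gm.G[np.ix_(rows, cols)].astype(float)
        G[G < 0] = np.nan
        # copies of the MT-fixed allele per genotype
        copies = np.where(alleles == "alt", G, 2 - G)
        with np.errstate(invalid="ignore"):
            n_loci = int(np.nansum(np.nanmax(copies, axis=0) >= 1))
            n_copies = int(np.nansum(copies))
        out[site] = {"n_diagnostic_loci_hit": n_loci, "n_allele_copies": n_copies}
    return out
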
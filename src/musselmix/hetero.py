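"""Observed heterozygosity and standardized multilocus heterozygosity.

Population-level diversity is observed heterozygosity Ho: per locus, the
heterozygote frequency among the site's typed genotypes, averaged
(unweighted) over loci with at least one typed genotype in the site.

Individual-level diversity is standardized multilocus heterozygosity,

    sMLH_i = (number of heterozygous typed loci of i)
             / (sum over i's typed loci of the dataset-wide heterozygote
                frequency at each locus),

which equals 1 on average for complete data and corrects an individual's
heterozygote count for which loci happened to be typed in it. sMLH can
be restricted to a locus subset — here the polymorphism classes derived
from the pure panels (ME-only, MG-only, ME∧MG SNPs) — with the baseline
recomputed within the subset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .refpanel import RefPanel


def locus_het_baseline(gm: GenotypeMatrix) -> np.ndarray:
    """Heterozygote frequency per locus over all typed individuals (NaN if untyped)."""
    typed = ~gm.missing_mask
    het = gm.G == 1
    n = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het.sum(axis=0) / np.maximum(n, 1), np.nan)


def population_ho(gm: GenotypeMatrix, popmap: dict | None = None) -> pd.DataFrame:
    """Observed heterozygosity per site.

    Per locus the heterozygote frequency among the site's non-missing
    genotypes; Ho is the unweighted mean over loci typed at least once in
    the site. Returns a frame (site, ho, n_loci).
    """
    popmap = popmap or gm.popmap
    site_of = np.array([popmap[s] for s in gm.samples])
    rows = []
    for site in dict.fromkeys(site_of):
        idx = np.flatnonzero(site_of == site)
        sub = gm.G[idx]
        typed = sub >= 0
        n = typed.sum(axis=0)
        if (n == 0).all():
            raise ValueError(f"site {site} has no typed genotypes")
        with np.errstate(invalid="ignore", divide="ignore"):
            hl = np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        rows.append(
            {"site": site, "ho": float(np.nanmean(hl)), "n_loci": int((n > 0).sum())}
        )
    return pd.DataFrame(rows)


def smlh(gm: GenotypeMatrix, locus_subset=None) -> pd.DataFrame:
    """Standardized multilocus heterozygosity per individual.

    ``locus_subset`` may be locus IDs or a boolean/index array; the
    heterozygote-frequency baseline is computed over ALL individuals at
    the subset loci. Individuals typed at zero subset loci get NaN.
    Returns a frame (sample_id, smlh, n_loci_used).
    """
    cols = _resolve_subset(gm, locus_subset)
    if cols.size == 0:
        raise ValueError("empty locus subset")
    sub = gm.subset(locus_idx=cols)
    baseline = locus_het_baseline(sub)
    typed = ~sub.missing_mask
    het = (sub.G == 1) & typed
    denom = np.where(typed, np.nan_to_num(baseline, nan=0.0)[None, :], 0.0).sum(axis=1)
    numer = het.sum(axis=1).astype(float)
    if np.nansum(baseline) == 0:
        raise ZeroDivisionError("no heterozygote anywhere in the locus subset")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
    n_used = typed.sum(axis=1)
    vals = np.where(n_used > 0, vals, np.nan)
    return pd.DataFrame(
        {"sample_id": gm.samples, "smlh": vals, "n_loci_used": n_used}
    )


def _resolve_subset(gm: GenotypeMatrix, locus_subset) -> np.ndarray:
    if locus_subset is None:
        return np.arange(gm.n_loci)
    arr = np.asarray(locus_subset)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr
    pos = {lid: j for j, lid in enumerate(gm.loci)}
    return np.array([pos[l] for l in arr if l in pos], dtype=int)


# classes used by the partitioned heterozygosity analysis
PARTITION_CLASSES = {"ME": "ME", "MG": "MG", "MEMG": "ME+MG"}


def smlh_partitioned(gm: GenotypeMatrix, panel: RefPanel) -> pd.DataFrame:
    """sMLH per individual within each pure-panel polymorphism class.

    Classes: loci polymorphic only in pure ME ("ME-SNPs"), only in pure
    MG ("MG-SNPs"), and in both ("ME/MG-SNPs"); baselines are recomputed
    within each class. Empty classes are skipped with a warning; cells
    with no typed loci are NaN.
    """
    if panel.poly_class is None:
        raise ValueError("panel has no polymorphism classes")
    pos = {lid: j for j, lid in enumerate(gm.loci)}
    out = pd.DataFrame({"sample_id": gm.samples})
    for short, label in PARTITION_CLASSES.items():
        loci = [
            panel.loci[l]
            for l in np.flatnonzero(panel.poly_class == label)
            if panel.loci[l] in pos
        ]
        if not loci:
            warnings.warn(f"polymorphism class {label} is empty; skipped")
            out[f"smlh_{short}"] = np.nan
            out[f"n_loci_{short}"] = 0
            continue
        part = smlh(gm, loci)
        out[f"smlh_{short}"] = part["smlh"].to_numpy()
        out[f"n_loci_{short}"] = part["n_loci_used"].to_numpy()
    return out
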
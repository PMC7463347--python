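"""Genotype data model and file I/O.

The central container is :class:`GenotypeMatrix`: an individuals × loci
matrix of alt-allele dosages (0/1/2, with -1 for missing) together with
optional per-genotype read depth (DP) and genotype quality (GQ), a sample →
site map (popmap) and a site → species map (panelmap). Phase is discarded:
no downstream analysis uses it.

Supported formats: VCF v4.2 (GT and optionally DP/GQ FORMAT fields) read
through cyvcf2 and written as plain text; tab-separated tables for the
popmap, the reference-panel map and the per-site environmental covariates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1

SPECIES = ("ME", "MG", "MT")
UNKNOWN = "UNKNOWN"


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class SchemaError(ValueError):
    """Raised when a tabular input does not match its expected schema."""


@dataclass
class GenotypeMatrix:
    """Individuals × loci genotype matrix with QC side-channels.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``G``).
    loci : list of str
        Ordered locus identifiers (columns of ``G``), ``CHROM:POS`` or the
        VCF ID field when set.
    ref, alt : lists of str
        Reference and alternate allele per locus (biallelic only).
    G : int8 ndarray, shape (n_samples, n_loci)
        Alt-allele dosage in {0, 1, 2}, or ``MISSING`` (-1).
    DP, GQ : int32 ndarray or None
        Per-genotype depth / quality, same shape as ``G``.
    popmap : dict
        sample id → site label; every sample must be present.
    panelmap : dict
        site label → species label in {"ME", "MG", "MT", "UNKNOWN"}.
    """

    samples: list
    loci: list
    ref: list
    alt: list
    G: np.ndarray
    DP: np.ndarray | None = None
    GQ: np.ndarray | None = None
    popmap: dict = field(default_factory=dict)
    panelmap: dict = field(default_factory=dict)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"G has shape {self.G.shape}, expected "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("G entries must be 0, 1, 2 or MISSING")
        for name in ("DP", "GQ"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=np.int32)
                if m.shape != self.G.shape:
                    raise ValueError(f"{name} shape {m.shape} != G shape")
                setattr(self, name, m)
        if self.popmap:
            absent = [s for s in self.samples if s not in self.popmap]
            if absent:
                raise ValueError(f"samples absent from popmap: {absent}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.G == MISSING

    def sites(self) -> np.ndarray:
        """Site label per sample, in sample order."""
        return np.array([self.popmap[s] for s in self.samples])

    def species_of_sample(self) -> np.ndarray:
        """Species label per sample via popmap → panelmap (UNKNOWN default)."""
        return np.array(
            [self.panelmap.get(self.popmap.get(s), UNKNOWN) for s in self.samples]
        )

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        take = lambda m: None if m is None else m[np.ix_(si, li)]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            ref=[self.ref[j] for j in li],
            alt=[self.alt[j] for j in li],
            G=self.G[np.ix_(si, li)],
            DP=take(self.DP),
            GQ=take(self.GQ),
            popmap=dict(self.popmap),
            panelmap=dict(self.panelmap),
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            G=self.G.copy(),
            DP=None if self.DP is None else self.DP.copy(),
            GQ=None if self.GQ is None else self.GQ.copy(),
            popmap=dict(self.popmap),
            panelmap=dict(self.panelmap),
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    popmap_path: str | None = None,
    panelmap_path: str | None = None,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF (v4.2, diploid GT with optional DP/GQ) into a GenotypeMatrix.

    ``./.`` and ``.|.`` genotypes map to MISSING. Multi-allelic records are
    skipped when ``skip_multiallelic`` is true, otherwise they raise
    :class:`VcfParseError`. Locus order follows the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    has_dp = "DP" in _format_ids(vcf)
    has_gq = "GQ" in _format_ids(vcf)

    loci, ref, alt, g_rows, dp_rows, gq_rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise VcfParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT)})"
            )
        lid = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
        loci.append(lid)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        g = var.gt_types.astype(np.int8)  # gts012: 0,1,2 and 3=missing
        g[g == 3] = MISSING
        g_rows.append(g)
        if has_dp:
            dp = var.format("DP")
            dp_rows.append(_fmt_ints(dp, len(samples)))
        if has_gq:
            gq = var.format("GQ")
            gq_rows.append(_fmt_ints(gq, len(samples)))
    vcf.close()

    G = (
        np.stack(g_rows, axis=1)
        if g_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    DP = np.stack(dp_rows, axis=1) if dp_rows and has_dp else None
    GQ = np.stack(gq_rows, axis=1) if gq_rows and has_gq else None

    popmap = read_popmap(popmap_path) if popmap_path else {s: "NA" for s in samples}
    missing_pm = [s for s in samples if s not in popmap]
    if missing_pm:
        raise ValueError(f"samples in VCF absent from popmap: {missing_pm}")
    panelmap = read_panelmap(panelmap_path) if panelmap_path else {}

    return GenotypeMatrix(samples, loci, ref, alt, G, DP, GQ, popmap, panelmap)


def _format_ids(vcf) -> set:
    ids = set()
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.add(line.split("ID=")[1].split(",")[0])
    return ids


def _fmt_ints(arr, n) -> np.ndarray:
    if arr is None:
        return np.zeros(n, dtype=np.int32)
    a = np.asarray(arr).reshape(n, -1)[:, 0]
    a = np.where(np.isfinite(a.astype(float)), a, 0)
    return np.clip(a.astype(np.int32), 0, None)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as VCF v4.2 text.

    Round-trips exactly through :func:`read_vcf` (G, DP, GQ, sample and
    locus order). Loci named ``CHROM:POS`` recover their coordinates;
    other IDs are placed on synthetic contig ``RAD`` with sequential
    positions and the original ID in the ID column.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    has_dp, has_gq = gm.DP is not None, gm.GQ is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=musselmix\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, lid in enumerate(gm.loci):
            if ":" in lid:
                chrom, pos = lid.rsplit(":", 1)
                ident = "."
                if not pos.isdigit():
                    chrom, pos, ident = "RAD", str(j + 1), lid
            else:
                chrom, pos, ident = "RAD", str(j + 1), lid
            cells = []
            for i in range(gm.n_samples):
                parts = [gt_strings[int(gm.G[i, j])]]
                if has_dp:
                    parts.append(str(int(gm.DP[i, j])))
                if has_gq:
                    parts.append(str(int(gm.GQ[i, j])))
                cells.append(":".join(parts))
            fh.write(
                f"{chrom}\t{pos}\t{ident}\t{gm.ref[j]}\t{gm.alt[j]}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path: str, schema: dict) -> pd.DataFrame:
    """Read a TSV with a header row and coerce columns per ``schema``.

    ``schema`` maps required column name → dtype ("str" or "float").
    String columns are stripped of surrounding whitespace (case preserved).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, dtype in schema.items():
        if dtype == "float":
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                raise SchemaError(f"{path}: column {col} is not numeric: {exc}")
        else:
            df[col] = df[col].str.strip()
    return df


def read_popmap(path: str) -> dict:
    """sample_id → site TSV; duplicate sample IDs are an error."""
    df = read_table(path, {"sample_id": "str", "site": "str"})
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicated sample IDs in popmap: {dups}")
    return dict(zip(df["sample_id"], df["site"]))


def read_panelmap(path: str) -> dict:
    """site → species TSV; species must be ME, MG, MT or UNKNOWN."""
    df = read_table(path, {"site": "str", "species": "str"})
    if df["site"].duplicated().any():
        raise SchemaError("duplicated site in panelmap")
    bad = set(df["species"]) - set(SPECIES) - {UNKNOWN}
    if bad:
        raise SchemaError(f"unknown species labels in panelmap: {sorted(bad)}")
    return dict(zip(df["site"], df["species"]))


def read_covariates(path: str) -> pd.DataFrame:
    """Per-site environmental covariates (site, sst_celsius, salinity_psu)."""
    return read_table(
        path, {"site": "str", "sst_celsius": "float", "salinity_psu": "float"}
    )


def write_popmap(popmap: dict, path: str) -> None:
    pd.DataFrame(
        {"sample_id": list(popmap), "site": [popmap[s] for s in popmap]}
    ).to_csv(path, sep="\t", index=False)


def write_panelmap(panelmap: dict, path: str) -> None:
    pd.DataFrame(
        {"site": list(panelmap), "species": [panelmap[s] for s in panelmap]}
    ).to_csv(path, sep="\t", index=False)
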
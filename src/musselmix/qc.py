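"""Post-genotyping SNP quality-control chain for RAD-seq data.

The chain mirrors standard reduced-representation practice: per-genotype
masking on genotype quality and depth (both strictly greater-than
thresholds), a site call-rate filter (inclusive), removal of
suspiciously deep loci (putative paralogs, mean depth strictly above a
multiple of the raw-dataset mean), removal of high-missingness
individuals (strictly above), a minor-allele-frequency floor (strict),
and sliding-window LD pruning on the squared Pearson correlation of
dosage vectors (strict).

Steps are applied in a fixed order; :class:`QcReport` records attrition
and the IDs removed at each step with their (single, primary) reason.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass
class QcConfig:
    """Thresholds of the filter chain.

    min_gq / min_dp are exclusive ("greater than five"); the site call
    rate is inclusive ("at least 60%"); the depth cap and individual
    missingness are exclusive; the MAF floor is exclusive ("greater than
    0.01"); LD pruning removes one locus of any within-window pair with
    r² strictly above ``ld_r2_max``. Window/step are SNP counts.
    """

    min_gq: int = 5
    min_dp: int = 5
    min_site_callrate: float = 0.60
    depth_cap_multiplier: float = 2.0
    max_indiv_missing: float = 0.50
    min_maf: float = 0.01
    ld_r2_max: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    fixed_point: bool = False

    def __post_init__(self):
        for name in ("min_site_callrate", "max_indiv_missing", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("GQ/DP thresholds must be non-negative")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValueError("ld_window >= 2 and ld_step >= 1 required")


@dataclass
class QcReport:
    raw_mean_depth: float | None = None
    steps: list = field(default_factory=list)
    removed: dict = field(default_factory=dict)  # id -> reason
    n_masked_genotypes: int = 0
    iterations: int = 1

    def record(self, step, n_samples, n_loci):
        self.steps.append({"step": step, "n_samples": n_samples, "n_loci": n_loci})

    def to_json(self, path=None):
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def raw_mean_depth(gm: GenotypeMatrix) -> float:
    """Mean DP over all non-missing genotypes of the (pre-filter) dataset."""
    if gm.DP is None:
        raise ValueError("DP absent: raw mean depth cannot be computed")
    typed = ~gm.missing_mask
    if not typed.any():
        raise ValueError("no typed genotypes")
    return float(gm.DP[typed].mean())


def mask_low_quality_genotypes(
    gm: GenotypeMatrix, cfg: QcConfig, report: QcReport | None = None
) -> GenotypeMatrix:
    """Set genotypes with GQ <= min_gq or DP <= min_dp to MISSING."""
    if gm.DP is None and gm.GQ is None:
        warnings.warn("DP and GQ absent; genotype masking is a no-op")
        return gm.copy()
    out = gm.copy()
    typed = ~out.missing_mask
    bad = np.zeros_like(typed)
    if out.GQ is not None:
        bad |= out.GQ <= cfg.min_gq
    if out.DP is not None:
        bad |= out.DP <= cfg.min_dp
    bad &= typed
    out.G[bad] = MISSING
    if report is not None:
        report.n_masked_genotypes = int(bad.sum())
    return out


def _site_callrate(gm: GenotypeMatrix) -> np.ndarray:
    return (~gm.missing_mask).mean(axis=0)


def filter_site_callrate(
    gm: GenotypeMatrix, cfg: QcConfig, report: QcReport | None = None
) -> GenotypeMatrix:
    """Drop loci genotyped in fewer than min_site_callrate of individuals."""
    keep = _site_callrate(gm) >= cfg.min_site_callrate
    _note_removed(report, gm, ~keep, axis="locus", reason="callrate")
    return gm.subset(locus_idx=np.flatnonzero(keep))


def filter_depth_cap(
    gm: GenotypeMatrix,
    cfg: QcConfig,
    raw_mean: float,
    report: QcReport | None = None,
) -> GenotypeMatrix:
    """Drop loci whose mean depth over typed genotypes exceeds the cap.

    The cap is ``depth_cap_multiplier × raw_mean`` where ``raw_mean`` is the
    mean depth of the raw (pre-filter) SNP dataset, passed in explicitly.
    Strictly greater-than: a locus exactly at the cap is kept.
    """
    if gm.DP is None:
        raise ValueError("DP absent: depth cap cannot be evaluated")
    typed = ~gm.missing_mask
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(
            n_typed > 0, (gm.DP * typed).sum(axis=0) / np.maximum(n_typed, 1), 0.0
        )
    keep = mean_dp <= cfg.depth_cap_multiplier * raw_mean
    _note_removed(report, gm, ~keep, axis="locus", reason="depth_cap")
    return gm.subset(locus_idx=np.flatnonzero(keep))


def filter_individuals(
    gm: GenotypeMatrix, cfg: QcConfig, report: QcReport | None = None
) -> GenotypeMatrix:
    """Drop samples with strictly more than max_indiv_missing missing data."""
    if gm.n_loci == 0:
        return gm.copy()
    frac = gm.missing_mask.mean(axis=1)
    keep = frac <= cfg.max_indiv_missing
    if not keep.any():
        raise ValueError("all samples removed by the missingness filter")
    _note_removed(report, gm, ~keep, axis="sample", reason="indiv_missing")
    return gm.subset(sample_idx=np.flatnonzero(keep))


def minor_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """MAF per locus over non-missing genotypes (NaN where untyped)."""
    typed = ~gm.missing_mask
    n_alleles = 2 * typed.sum(axis=0)
    alt = np.where(typed, gm.G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1 - p)


def filter_maf(
    gm: GenotypeMatrix, cfg: QcConfig, report: QcReport | None = None
) -> GenotypeMatrix:
    """Keep loci with MAF strictly greater than min_maf."""
    maf = minor_allele_frequency(gm)
    keep = maf > cfg.min_maf  # NaN compares False: untyped loci dropped
    _note_removed(report, gm, ~keep, axis="locus", reason="maf")
    return gm.subset(locus_idx=np.flatnonzero(keep))


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns, pairwise-complete.

    X holds dosages with NaN for missing. Pairs with < 2 complete
    observations or zero variance get r² = 0 (treated as unlinked).
    """
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    Mf = M.astype(float)
    n = Mf.T @ Mf
    sx = X0.T @ Mf
    sy = sx.T
    sxy = X0.T @ X0
    sxx = (X0**2).T @ Mf
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r2 = cov**2 / (varx * vary)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix, cfg: QcConfig, report: QcReport | None = None
) -> GenotypeMatrix:
    """Sliding-window LD pruning.

    Windows of ``ld_window`` loci advance by ``ld_step`` over locus order.
    Within a window, for each pair with r² strictly above ``ld_r2_max``
    (pairwise-complete Pearson on dosages), the locus with the lower call
    rate is removed; on ties the later locus goes. After completion no
    retained pair within any window exceeds the threshold.
    """
    L = gm.n_loci
    if L < 2:
        return gm.copy()
    X = gm.G.astype(float)
    X[gm.missing_mask] = np.nan
    callrate = _site_callrate(gm)
    alive = np.ones(L, dtype=bool)

    starts = list(range(0, max(L - cfg.ld_window, 0) + 1, cfg.ld_step))
    if not starts or starts[-1] + cfg.ld_window < L:
        starts.append(max(L - cfg.ld_window, 0))
    for s in starts:
        idx = np.arange(s, min(s + cfg.ld_window, L))
        idx = idx[alive[idx]]
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(X[:, idx])
        local_alive = np.ones(len(idx), dtype=bool)
        # deterministic pass: repeatedly drop the worse locus of any hot pair
        hot = np.argwhere(np.triu(r2 > cfg.ld_r2_max, k=1))
        for a, b in hot:
            if not (local_alive[a] and local_alive[b]):
                continue
            ia, ib = idx[a], idx[b]
            if callrate[ia] < callrate[ib]:
                drop = a
            elif callrate[ib] < callrate[ia]:
                drop = b
            else:
                drop = b  # tie: later locus
            local_alive[drop] = False
            alive[idx[drop]] = False
    _note_removed(report, gm, ~alive, axis="locus", reason="ld")
    return gm.subset(locus_idx=np.flatnonzero(alive))


def _note_removed(report, gm, removed_mask, axis, reason):
    if report is None:
        return
    ids = gm.loci if axis == "locus" else gm.samples
    for i in np.flatnonzero(removed_mask):
        report.removed.setdefault(ids[i], reason)


def run_qc(gm: GenotypeMatrix, cfg: QcConfig | None = None):
    """Apply the full chain: mask → call rate → depth cap → individuals → MAF → LD.

    Returns ``(filtered GenotypeMatrix, QcReport)``. With
    ``cfg.fixed_point`` the site filters are re-run after individual
    removal until no further attrition (MAF can newly fail once samples
    drop); the report records the iteration count.
    """
    cfg = cfg or QcConfig()
    report = QcReport()
    report.record("input", gm.n_samples, gm.n_loci)

    if gm.DP is not None:
        report.raw_mean_depth = raw_mean_depth(gm)

    out = mask_low_quality_genotypes(gm, cfg, report)
    report.record("mask_gq_dp", out.n_samples, out.n_loci)

    out = filter_site_callrate(out, cfg, report)
    report.record("site_callrate", out.n_samples, out.n_loci)

    if out.DP is not None:
        out = filter_depth_cap(out, cfg, report.raw_mean_depth, report)
    report.record("depth_cap", out.n_samples, out.n_loci)

    out = filter_individuals(out, cfg, report)
    report.record("indiv_missing", out.n_samples, out.n_loci)

    out = filter_maf(out, cfg, report)
    report.record("maf", out.n_samples, out.n_loci)

    out = ld_prune(out, cfg, report)
    report.record("ld_prune", out.n_samples, out.n_loci)

    if cfg.fixed_point:
        while True:
            before = (out.n_samples, out.n_loci)
            out = filter_site_callrate(out, cfg, report)
            out = filter_individuals(out, cfg, report)
            out = filter_maf(out, cfg, report)
            report.iterations += 1
            if (out.n_samples, out.n_loci) == before:
                break
        report.record("fixed_point", out.n_samples, out.n_loci)

    return out, report
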
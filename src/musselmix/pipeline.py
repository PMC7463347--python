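"""End-to-end orchestration: QC → panel → ancestry → heterozygosity →
ordination → models, behind one YAML config and one CLI.

Also houses the composition of the introgression–heterozygosity analysis:
merging ancestry with heterozygosity tables, the population-level linear
model of Ho, the individual-level random-intercept mixed model of sMLH
with parametric-bootstrap tests, the within-background slopes, and the
SNP-class-partitioned slopes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import genio, hetero, ordination, qc, refpanel
from . import stats as mstats

log = logging.getLogger("musselmix")


# ---------------------------------------------------------------------------
# analysis composition
# ---------------------------------------------------------------------------

def population_dataset(pop_anc, ho_df: pd.DataFrame) -> pd.DataFrame:
    """Merge per-site Ho with main ancestry and introgression."""
    return pop_anc.to_frame().merge(ho_df, on="site", how="inner")


def population_models(pop_df: pd.DataFrame, min_group: int = 2) -> dict:
    """Population level: ME-vs-MG t test on Ho, the Ho GLM, per-background slopes.

    Main-ancestry classes with fewer than ``min_group`` populations
    (typically MT, represented by a single pure site) are excluded from
    the GLM and reported without a test.
    """
    out = {}
    me = pop_df.loc[pop_df["main"] == "ME", "ho"]
    mg = pop_df.loc[pop_df["main"] == "MG", "ho"]
    if len(me) >= 2 and len(mg) >= 2:
        t, df, p = mstats.t_test(me, mg)
        out["t_test_ho_me_vs_mg"] = {"t": t, "df": df, "p": p}
    counts = pop_df["main"].value_counts()
    keep = pop_df["main"].map(counts) >= min_group
    sub = pop_df.loc[keep].copy()
    fit = mstats.fit_lm("ho ~ C(main) * introgression", sub)
    out["glm_ho"] = {
        "F": {
            term: float(fit.f_table.loc[term, "F"])
            for term in fit.f_table.index
            if term != "Residual"
        },
        "p": {
            term: float(fit.f_table.loc[term, "PR(>F)"])
            for term in fit.f_table.index
            if term != "Residual"
        },
        "loglik": fit.loglik,
    }
    out["slopes_ho"] = mstats.species_slopes(
        pop_df, "ho", min_group=min_group
    ).to_dict(orient="records")
    return out


def individual_dataset(profile, het_df: pd.DataFrame, popmap: dict) -> pd.DataFrame:
    """Merge per-individual sMLH with main ancestry and introgression."""
    q = profile.to_frame(popmap)
    df = q.merge(het_df, on="sample_id", how="inner")
    return df.dropna(subset=["smlh", "introgression"])


def individual_models(
    ind_df: pd.DataFrame, B: int = 1000, seed: int = 0, min_group: int = 2
) -> dict:
    """Individual level: sMLH ANOVA, mixed model with bootstrap LRTs, slopes.

    The mixed model is sMLH ~ main ancestry × introgression with a random
    site intercept; each fixed term is tested by parametric bootstrap of
    the nested comparison (interaction, then the main effects against the
    additive model).
    """
    out = {}
    F, df1, df2, p = mstats.anova_oneway(ind_df["smlh"], ind_df["main"])
    out["anova_smlh"] = {"F": F, "df1": df1, "df2": df2, "p": p}

    counts = ind_df["main"].value_counts()
    sub = ind_df.loc[ind_df["main"].map(counts) >= min_group].copy()
    full = mstats.LmmSpec("smlh", "C(main) * introgression", "site")
    no_int = mstats.LmmSpec("smlh", "C(main) + introgression", "site")
    no_main = mstats.LmmSpec("smlh", "introgression", "site")
    no_intro = mstats.LmmSpec("smlh", "C(main)", "site")
    tests = {}
    for name, null in [
        ("interaction", no_int),
        ("main", no_main),
        ("introgression", no_intro),
    ]:
        fullspec = full if name == "interaction" else no_int
        res = mstats.parametric_bootstrap_lrt(fullspec, null, sub, B=B, seed=seed)
        tests[name] = {"LR": res.lr_stat, "p": res.boot_p, "B": res.n_boot}
    fit = full.fit(sub)
    out["lmm_smlh"] = {
        "params": fit.params.to_dict(),
        "sigma2_site": fit.sigma2_site,
        "sigma2_resid": fit.sigma2_resid,
        "loglik": fit.loglik,
        "bootstrap": tests,
    }
    out["slopes_smlh"] = mstats.species_slopes(
        ind_df, "smlh", min_group=min_group
    ).to_dict(orient="records")
    return out


def class_partition_slopes(ind_part_df: pd.DataFrame) -> dict:
    """Slopes of class-restricted sMLH on introgression, per background.

    For ME- and MG-background individuals separately: how sMLH at ME-only,
    MG-only and ME∧MG SNPs responds to introgression. The expected
    pattern: positive at the donor species' private SNPs, negative at the
    recipient's own private SNPs.
    """
    out = {}
    for bg in ("ME", "MG"):
        sub = ind_part_df[ind_part_df["main"] == bg]
        res = {}
        for short in ("ME", "MG", "MEMG"):
            col = f"smlh_{short}"
            s = mstats.species_slopes(
                sub.assign(main=bg).dropna(subset=[col]), col, min_group=2
            )
            row = s[s["group"] == bg]
            res[short] = (
                row.iloc[0][["n", "b", "t", "p"]].to_dict() if len(row) else None
            )
        out[bg] = res
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    vcf: str
    popmap: str
    panelmap: str
    covariates: str | None = None
    out_dir: str = "results"
    qc: dict = field(default_factory=dict)
    ancestry: dict = field(default_factory=lambda: {"eps": 1e-3, "tol": 1e-6, "seed": 0})
    models: dict = field(default_factory=lambda: {"B": 1000, "seed": 0})
    min_typed: int = 10
    stages: tuple = ("qc", "panel", "ancestry", "het", "ordination", "models")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("vcf", "popmap", "panelmap"):
            p = getattr(cfg, key)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{key}: {p}")
        if cfg.covariates and not os.path.exists(cfg.covariates):
            raise FileNotFoundError(f"covariates: {cfg.covariates}")
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write every module's outputs.

    Returns the in-memory result bundle; a ``manifest.json`` in the
    output directory records per-stage wall time, input/output counts,
    seeds and a hash of the configuration.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.__dict__, default=str, sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": [],
    }
    bundle: dict = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            fn()
        except Exception:
            manifest["stages"].append({"stage": name, "status": "failed"})
            _write_manifest(cfg, manifest)
            raise
        entry = {"stage": name, "status": "ok", "seconds": round(time.time() - t0, 2)}
        if "gm" in bundle:
            entry["n_samples"] = bundle["gm"].n_samples
            entry["n_loci"] = bundle["gm"].n_loci
        manifest["stages"].append(entry)
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    def _load():
        bundle["gm"] = genio.read_vcf(cfg.vcf, cfg.popmap, cfg.panelmap)

    stage("load", _load)

    if "qc" in cfg.stages:
        def _qc():
            qcfg = qc.QcConfig(**cfg.qc)
            gm2, report = qc.run_qc(bundle["gm"], qcfg)
            bundle["gm"], bundle["qc_report"] = gm2, report
            genio.write_vcf(gm2, os.path.join(cfg.out_dir, "pruned.vcf"))
            report.to_json(os.path.join(cfg.out_dir, "qc_report.json"))
        stage("qc", _qc)

    if "panel" in cfg.stages:
        def _panel():
            panel = refpanel.build_panel(bundle["gm"])
            refpanel.classify_polymorphism(panel, cfg.min_typed)
            refpanel.find_mt_diagnostic(panel, cfg.min_typed)
            bundle["panel"] = panel
            panel.to_frame().to_csv(
                os.path.join(cfg.out_dir, "panel.tsv"), sep="\t", index=False
            )
            with open(os.path.join(cfg.out_dir, "venn.json"), "w") as fh:
                json.dump(refpanel.class_counts(panel), fh, indent=2)
        stage("panel", _panel)

    if "ancestry" in cfg.stages:
        def _ancestry():
            a = cfg.ancestry
            profile = anc.estimate_q(
                bundle["gm"], bundle["panel"],
                eps=a.get("eps", 1e-3), tol=a.get("tol", 1e-6),
                seed=a.get("seed", 0),
            )
            bundle["profile"] = profile
            bundle["pop_ancestry"] = anc.population_ancestry(
                profile, bundle["gm"].popmap
            )
            profile.to_frame(bundle["gm"].popmap).to_csv(
                os.path.join(cfg.out_dir, "q.tsv"), sep="\t", index=False
            )
            bundle["pop_ancestry"].to_frame().to_csv(
                os.path.join(cfg.out_dir, "pop_ancestry.tsv"), sep="\t", index=False
            )
        stage("ancestry", _ancestry)

    if "het" in cfg.stages:
        def _het():
            gm = bundle["gm"]
            bundle["pop_ho"] = hetero.population_ho(gm)
            sm = hetero.smlh(gm)
            part = hetero.smlh_partitioned(gm, bundle["panel"])
            bundle["het"] = sm.merge(part, on="sample_id")
            bundle["pop_ho"].to_csv(
                os.path.join(cfg.out_dir, "pop_ho.tsv"), sep="\t", index=False
            )
            bundle["het"].to_csv(
                os.path.join(cfg.out_dir, "het.tsv"), sep="\t", index=False
            )
        stage("het", _het)

    if "ordination" in cfg.stages:
        def _ord():
            gm = bundle["gm"]
            pres = ordination.pca(gm, n_components=5)
            scores = pd.DataFrame(
                pres.scores, columns=[f"PC{i+1}" for i in range(pres.scores.shape[1])]
            )
            scores.insert(0, "sample_id", pres.samples)
            scores.to_csv(
                os.path.join(cfg.out_dir, "pca_scores.tsv"), sep="\t", index=False
            )
            tree = ordination.bootstrap_support(
                gm, B=100, seed=cfg.models.get("seed", 0)
            )
            with open(os.path.join(cfg.out_dir, "tree.nwk"), "w") as fh:
                fh.write(tree.newick() + "\n")
            bundle["pca"], bundle["tree"] = pres, tree
        stage("ordination", _ord)

    if "models" in cfg.stages:
        def _models():
            B = cfg.models.get("B", 1000)
            seed = cfg.models.get("seed", 0)
            pop_df = population_dataset(bundle["pop_ancestry"], bundle["pop_ho"])
            models = {"population": population_models(pop_df)}
            ind = individual_dataset(
                bundle["profile"], bundle["het"], bundle["gm"].popmap
            )
            models["individual"] = individual_models(ind, B=B, seed=seed)
            models["class_partition"] = class_partition_slopes(ind)
            if cfg.covariates:
                cov = genio.read_covariates(cfg.covariates)
                corr = mstats.correlate_environment(bundle["pop_ancestry"], cov)
                models["environment"] = corr.table.to_dict(orient="records")
            bundle["models"] = models
            with open(os.path.join(cfg.out_dir, "models.json"), "w") as fh:
                json.dump(models, fh, indent=2, default=float)
        stage("models", _models)

    _write_manifest(cfg, manifest)
    bundle["manifest"] = manifest
    return bundle


def _write_manifest(cfg, manifest):
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
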
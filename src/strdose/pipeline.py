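"""End-to-end orchestration: genotypes -> GRM -> association -> adjusted
phenotypes -> correlation (-> expression), with stage-level logging and a
machine-readable run report.

Thresholds default to the study values: call posterior >= 0.90, flank-indel
and stutter read fractions <= 0.15, GWAS locus presence rate > 0.2, GRM
locus missing rate < 0.1, suggestive association p < 5e-4, correlation
filter |r| > 0.5, differential-expression alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blup as blup_mod
from . import expression as expr_mod
from . import genotypes as geno
from . import gwas as gwas_mod
from . import relatedness as rel
from . import scan as scan_mod
from .simulate import CohortSim, SimConfig, simulate_cohort, simulate_str_vcf

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("strdose")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # inputs (all optional; a synthetic cohort is generated when the
    # genotype/phenotype/pedigree inputs are absent)
    fasta: str | None = None
    vcf: str | None = None
    catalog: str | None = None
    pheno: str | None = None
    ped: str | None = None
    counts: str | None = None
    groups: str | None = None
    genes: str | None = None
    sim: SimConfig | None = None
    # thresholds (study defaults)
    min_posterior: float = 0.90
    max_flank: float = 0.15
    max_stutter: float = 0.15
    min_presence: float = 0.2
    grm_max_missing: float = 0.1
    n_pcs: int = 5
    alpha: float = gwas_mod.SUGGESTIVE_ALPHA
    r_threshold: float = 0.5
    de_alpha: float = expr_mod.DE_ALPHA
    gwas_mode: str = "p3d"
    merge_revcomp: bool = False
    max_gene_distance: int = 25_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the report dict (also written as
    report.json beside the outputs, with the resolved configuration)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    catalog = None
    if config.catalog:
        catalog = scan_mod.read_catalog_bed(config.catalog)

    if config.fasta:
        catalog = _run_scan(config, out, report, catalog)

    vcf_path, pheno_path, ped_path = config.vcf, config.pheno, config.ped
    if vcf_path is None or pheno_path is None or ped_path is None:
        vcf_path, pheno_path, ped_path = _run_simulate(config, out, report)

    dm, callset = _run_genotypes(config, out, report, vcf_path, catalog)
    grm, pcs, dm_grm = _run_grm(config, out, report, dm)
    gwas_tab, suggestive, pheno = _run_gwas(config, out, report, dm, grm, pcs, pheno_path)
    _run_adjust(config, out, report, dm, pheno, ped_path, suggestive)
    if config.counts and config.groups:
        _run_expression(config, out, report)

    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


@_stage("scan")
def _run_scan(config, out, report, catalog):
    thresholds = scan_mod.ScanThresholds()
    cat = scan_mod.scan_fasta(config.fasta, thresholds)
    scan_mod.write_catalog_bed(cat, out / "catalog.bed")
    stats = scan_mod.landscape_stats(cat, merge_revcomp=config.merge_revcomp)
    pd.DataFrame([dataclasses.asdict(stats)]).to_csv(
        out / "landscape.tsv", sep="\t", index=False
    )
    report["stages"].append({"stage": "scan", "n_str": stats.n_str,
                             "percent_genome": stats.percent_genome})
    return catalog if catalog is not None else cat


@_stage("simulate")
def _run_simulate(config, out, report):
    sim_cfg = config.sim if config.sim is not None else SimConfig(seed=config.seed)
    cohort = simulate_cohort(sim_cfg)
    vcf_path = out / "sim_calls.vcf"
    pheno_path = out / "sim_pheno.tsv"
    ped_path = out / "sim_ped.tsv"
    simulate_str_vcf(cohort, vcf_path)
    cohort.phenotypes.to_csv(pheno_path, sep="\t", index_label="id")
    cohort.pedigree.records.fillna("0").to_csv(ped_path, sep="\t", index=False)
    cohort.truth.causal.to_csv(out / "sim_truth_causal.tsv", sep="\t")
    report["stages"].append(
        {"stage": "simulate", "n_individuals": len(cohort.phenotypes),
         "n_loci": len(cohort.dosage.locus_ids),
         "causal_loci": list(cohort.truth.causal.index)}
    )
    return str(vcf_path), str(pheno_path), str(ped_path)


@_stage("genotypes")
def _run_genotypes(config, out, report, vcf_path, catalog):
    callset = geno.read_str_vcf(vcf_path, catalog=catalog)
    n_raw = len(callset.calls)
    filtered = geno.filter_calls(
        callset, q_min=config.min_posterior,
        flank_max=config.max_flank, stutter_max=config.max_stutter,
    )
    dm = geno.dosage_matrix(filtered)
    geno.write_dosage_tsv(dm, out / "dosage.tsv")
    qc = geno.locus_qc(dm)
    qc.to_csv(out / "locus_qc.tsv", sep="\t")
    report["stages"].append(
        {"stage": "genotypes", "n_loci": len(dm.locus_ids), "n_samples": len(dm.samples),
         "calls_in": n_raw, "calls_pass": len(filtered.calls),
         "pic_high_fraction": float((qc["polymorphism_class"] == "high").mean())}
    )
    return dm, filtered


@_stage("grm")
def _run_grm(config, out, report, dm):
    dm_grm = geno.filter_loci(dm, max_missing=config.grm_max_missing, purpose="grm")
    grm = rel.vanraden_grm(dm_grm)
    pcs = rel.grm_pca(grm, k=config.n_pcs)
    rel.write_grm_tsv(grm, out / "grm.tsv")
    rel.write_pcs_tsv(pcs, out / "pcs.tsv")
    report["stages"].append(
        {"stage": "grm", "n_loci_used": len(dm_grm.locus_ids),
         "mean_diagonal": float(np.mean(np.diag(grm.matrix)))}
    )
    return grm, pcs, dm_grm


@_stage("gwas")
def _run_gwas(config, out, report, dm, grm, pcs, pheno_path):
    pheno = pd.read_csv(pheno_path, sep="\t", index_col="id")
    pheno.index = pheno.index.astype(str)
    spec = gwas_mod.build_design(pheno, grm, pcs=pcs)
    vc = gwas_mod.reml_fit(spec)
    dm_gwas = geno.filter_loci(dm, min_presence=config.min_presence, purpose="gwas")
    tab = gwas_mod.assoc_scan(
        spec, dm_gwas, mode=config.gwas_mode, vc=vc, alpha=config.alpha
    )
    tab = tab.join(dm_gwas.loci[["scaffold", "pos"]])
    suggestive = list(tab.index[tab["suggestive"]])
    # HWE among suggestive loci (degenerate single-allele loci report p = 1)
    hwe_p = {}
    for locus_id in suggestive:
        res = geno.hwe_test(
            geno.genotype_counts(dm_gwas, locus_id), n_perm=2000, seed=config.seed
        )
        hwe_p[locus_id] = res.p_value
    tab["hwe_p"] = pd.Series(hwe_p)
    tab.to_csv(out / "gwas.tsv", sep="\t")
    man = tab.dropna(subset=["p_value"])[["scaffold", "pos", "p_value"]].copy()
    man["neg_log10_p"] = -np.log10(man.pop("p_value"))
    man.to_csv(out / "manhattan.tsv", sep="\t")
    n_hwe_ok = int(sum(p > 0.05 for p in hwe_p.values()))
    report["stages"].append(
        {"stage": "gwas", "n_loci_tested": int((~tab["degenerate"]).sum()),
         "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2, "h2": vc.h2,
         "n_suggestive": len(suggestive), "suggestive": suggestive,
         "n_suggestive_hwe_pass": n_hwe_ok}
    )
    return tab, suggestive, pheno


@_stage("adjust")
def _run_adjust(config, out, report, dm, pheno, ped_path, suggestive):
    ped = blup_mod.read_pedigree_tsv(ped_path)
    fit = blup_mod.animal_model_blup(pheno, ped)
    y_star = blup_mod.adjust_phenotypes(fit)
    adj = pd.DataFrame(
        {"a_hat": fit.a_hat.loc[y_star.index], "e_hat": fit.e_hat, "y_star": y_star}
    )
    adj.to_csv(out / "adjusted.tsv", sep="\t", index_label="id")
    corr = blup_mod.correlate_dosage(
        dm, y_star, loci=[l for l in suggestive if l in dm.locus_ids],
        threshold=config.r_threshold,
    )
    corr.to_csv(out / "correlations.tsv", sep="\t")
    n_pass = int(corr["passes"].sum()) if len(corr) else 0
    report["stages"].append(
        {"stage": "adjust", "n_adjusted": len(y_star),
         "blup_sigma_a2": fit.varcomp.sigma_a2, "blup_sigma_e2": fit.varcomp.sigma_e2,
         "n_correlated": n_pass,
         "passing_loci": list(corr.index[corr["passes"]]) if len(corr) else []}
    )
    return corr


@_stage("expression")
def _run_expression(config, out, report):
    counts, lengths = expr_mod.read_counts_tsv(config.counts)
    groups = pd.read_csv(config.groups, sep="\t", index_col="sample")["group"]
    fpkm = expr_mod.fpkm_normalize(counts, lengths)
    de = expr_mod.de_ttest(fpkm, groups, alpha=config.de_alpha)
    de.to_csv(out / "de.tsv", sep="\t", index_label="gene")
    n_sig = int(de["significant"].sum())
    stage = {"stage": "expression", "n_genes": len(de), "n_significant": n_sig}
    if config.genes:
        genes = expr_mod.read_gene_annotation(config.genes)
        gwas_tab = pd.read_csv(out / "gwas.tsv", sep="\t", dtype={"scaffold": str})
        hits = gwas_tab[gwas_tab["suggestive"] == True]  # noqa: E712
        ann = expr_mod.annotate_str_to_genes(
            hits[["locus_id", "scaffold", "pos"]], genes,
            max_distance_bp=config.max_gene_distance,
        )
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        stage["n_annotated"] = int(ann["locus_id"].nunique()) if len(ann) else 0
    report["stages"].append(stage)
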
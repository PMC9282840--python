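"""End-to-end orchestration of the PRS–longevity analysis.

A single YAML configuration names the inputs (genotypes, phenotype, one or
more traits' summary statistics, optional annotations/regions/genes) and
the per-stage parameters. Stages run in dependency order, each writing a
tab-separated table plus a manifest entry (input hashes, parameters, row
counts) so that re-running an identical config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import harmonize as hz
from . import prs, stratify, target, tradeoff
from .predict import assemble_prs_matrix, model_selection_cv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("qc", "harmonize", "scan", "stratify", "bins", "mask", "dissect",
          "predict")


@dataclass
class PipelineConfig:
    genotypes: str
    phenotype: str
    sumstats: dict                      # trait -> path
    build: str = "hg19"
    seed: int = 0
    longevity_sumstats: str | None = None
    annotations: str | None = None
    set_groups: str | None = None
    regions: str | None = None
    genes: str | None = None
    qc: dict = field(default_factory=lambda: {
        "max_missing": 0.05, "min_maf": 0.01, "hwe_p_min": 1e-5})
    clump: dict = field(default_factory=lambda: {"r2": 0.1, "window_kb": 500})
    alpha: float = 0.05
    fine_scan: bool = False
    keep_palindromic: bool = False
    cv: dict = field(default_factory=lambda: {"k": 10, "iterations": 100})
    schema_version: int = 1


def validate_config(path) -> tuple[PipelineConfig | None, list]:
    """Load and validate a YAML config; all problems reported at once."""
    errors: list = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"unreadable config: {exc}"]
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    for key in ("genotypes", "phenotype", "sumstats"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    sumstats = raw.get("sumstats") or {}
    if not isinstance(sumstats, dict):
        errors.append("sumstats must map trait name -> path")
        sumstats = {}
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    for key in ("genotypes", "phenotype", "longevity_sumstats", "annotations",
                "set_groups", "regions", "genes"):
        p = raw.get(key)
        if p is not None:
            raw[key] = _resolve(p)
            if not os.path.exists(raw[key]):
                errors.append(f"{key} path does not exist: {p}")
    for trait, p in list(sumstats.items()):
        sumstats[trait] = _resolve(p)
        if not os.path.exists(sumstats[trait]):
            errors.append(f"sumstats[{trait}] path does not exist: {p}")
    raw["sumstats"] = sumstats

    clump = raw.get("clump", {})
    r2 = clump.get("r2", 0.1)
    if not 0 <= r2 <= 1:
        errors.append(f"clump.r2 out of range [0, 1]: {r2}")
    if clump.get("window_kb", 500) <= 0:
        errors.append("clump.window_kb must be positive")
    seed = raw.get("seed", 0)
    if not isinstance(seed, (int, np.integer)):
        errors.append(f"seed must be an integer, got {seed!r}")
    alpha = raw.get("alpha", 0.05)
    if not 0 < alpha <= 1:
        errors.append(f"alpha out of range (0, 1]: {alpha}")
    if errors:
        return None, errors
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    return cfg, []


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, outdir, name, manifest, inputs, params):
    path = os.path.join(outdir, f"{name}.tsv")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest[name] = {
        "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
        "params": params,
        "rows": int(len(df)),
    }
    return path


def run_pipeline(config: PipelineConfig, stages=None, outdir="longprs_run"):
    """Execute the requested stages in dependency order.

    Returns a dict of stage -> output table. Outputs and a manifest.json
    are written under ``outdir``.
    """
    requested = list(stages) if stages else list(STAGES)
    bad = [s for s in requested if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()}}
    results: dict = {}

    geno = target.read_genotypes(config.genotypes)
    pheno = target.read_phenotype(config.phenotype)
    pheno = pheno.reindex(geno.samples)
    if pheno.isna().any():
        raise ValueError("phenotype file missing ids present in the VCF")
    y = pheno.to_numpy()

    if "qc" in requested:
        geno, report = target.snp_qc_filter(geno, controls=(y == 0),
                                            **config.qc)
        results["qc"] = report
        _write(report, outdir, "qc_report", manifest,
               [config.genotypes], config.qc)

    harmonized: dict = {}
    if any(s in requested for s in
           ("harmonize", "scan", "stratify", "bins", "mask", "dissect",
            "predict")):
        for trait, path in config.sumstats.items():
            try:
                ss = hz.read_sumstats(path)
            except ValueError as exc:
                raise ValueError(f"failed reading sumstats for {trait} "
                                 f"({path}): {exc}") from exc
            aligned, report = hz.harmonize_alleles(
                ss, geno.variants, keep_palindromic=config.keep_palindromic)
            harmonized[trait] = aligned
            if "harmonize" in requested:
                _write(aligned, outdir, f"harmonized_{trait}", manifest,
                       [path, config.genotypes],
                       {"build": config.build,
                        "report": report.to_dict()})
        results["harmonize"] = harmonized

    window_bp = int(config.clump["window_kb"] * 1000)
    r2 = config.clump["r2"]
    clumps, scans, best_scores = {}, {}, {}
    if any(s in requested for s in ("scan", "dissect", "predict")):
        ladder = prs.fine_ladder() if config.fine_scan else prs.DEFAULT_LADDER
        for trait, ss in harmonized.items():
            clump = prs.greedy_clump(ss, geno, r2_threshold=r2,
                                     window_bp=window_bp)
            clumps[trait] = clump
            scan = prs.threshold_scan(ss, geno, y, clump, ladder=ladder)
            scan.insert(0, "trait", trait)
            scans[trait] = scan
            best_cut = scan.loc[scan["best"], "threshold"].iloc[0]
            p_by_id = ss.set_index("snp_id")["p"]
            best_ids = [s for s in clump.index_snps if p_by_id[s] <= best_cut]
            res = prs.score_prs(geno, ss, best_ids, threshold=best_cut)
            best_scores[trait] = pd.Series(res.scores, index=geno.samples)
        if "scan" in requested:
            all_scans = pd.concat(scans.values(), ignore_index=True)
            _write(all_scans, outdir, "threshold_scan", manifest,
                   list(config.sumstats.values()),
                   {"r2": r2, "window_bp": window_bp})
            results["scan"] = all_scans

    if "stratify" in requested:
        if not config.annotations:
            raise ValueError("stratify stage requires an annotations path")
        bed, groups = stratify.read_bed_sets(config.annotations,
                                             config.set_groups)
        sets = stratify.snps_in_sets(geno.variants, bed, groups)
        frames = []
        for trait, ss in harmonized.items():
            fam = stratify.stratified_family_size(len(sets.sets),
                                                  len(harmonized))
            tab = stratify.set_prs_scan(ss, geno, y, sets,
                                        r2_threshold=r2, window_bp=window_bp,
                                        family_size=fam, alpha=config.alpha)
            tab.insert(0, "trait", trait)
            frames.append(tab)
        table = pd.concat(frames, ignore_index=True)
        _write(table, outdir, "set_prs", manifest,
               [config.annotations], {"alpha": config.alpha})
        results["stratify"] = table

    if "bins" in requested:
        frames = []
        for trait, ss in harmonized.items():
            tab = stratify.pvalue_bin_prs_scan(ss, geno, y,
                                               r2_threshold=r2,
                                               window_bp=window_bp)
            tab.insert(0, "trait", trait)
            frames.append(tab)
        table = pd.concat(frames, ignore_index=True)
        _write(table, outdir, "bin_prs", manifest,
               list(config.sumstats.values()), {})
        results["bins"] = table

    if "mask" in requested:
        if not config.regions:
            raise ValueError("mask stage requires a regions path")
        regions = pd.read_csv(config.regions, sep="\t")
        frames = []
        for trait, ss in harmonized.items():
            masked = ss
            for _, r in regions.iterrows():
                masked = stratify.mask_region(
                    masked, stratify.Region(str(r["chrom"]), int(r["start"]),
                                            int(r["end"])))
            clump = prs.greedy_clump(masked, geno, r2_threshold=r2,
                                     window_bp=window_bp)
            scan = prs.threshold_scan(masked, geno, y, clump)
            scan.insert(0, "trait", trait)
            frames.append(scan)
        table = pd.concat(frames, ignore_index=True)
        _write(table, outdir, "masked_scan", manifest,
               [config.regions], {})
        results["mask"] = table

    if "dissect" in requested:
        if not config.longevity_sumstats:
            raise ValueError("dissect stage requires longevity_sumstats")
        lss = hz.read_sumstats(config.longevity_sumstats)
        lss, _ = hz.harmonize_alleles(lss, geno.variants,
                                      keep_palindromic=config.keep_palindromic)
        frames = []
        for trait, ss in harmonized.items():
            risk = hz.orient_to_risk(ss)
            scan = scans[trait]
            best_cut = scan.loc[scan["best"], "threshold"].iloc[0]
            p_by_id = ss.set_index("snp_id")["p"]
            best_ids = [s for s in clumps[trait].index_snps
                        if p_by_id[s] <= best_cut]
            panel = tradeoff.select_pleiotropic(best_ids, risk, lss,
                                                alpha=config.alpha)
            if config.genes and len(panel):
                genes = pd.read_csv(config.genes, sep="\t")
                panel["gene_label"] = tradeoff.annotate_nearest_genes(
                    panel, genes).to_numpy()
            panel.insert(0, "trait", trait)
            frames.append(panel)
        table = pd.concat(frames, ignore_index=True)
        _write(table, outdir, "pleiotropy_panels", manifest,
               [config.longevity_sumstats], {"alpha": config.alpha})
        results["dissect"] = table

    if "predict" in requested:
        matrix, traits = assemble_prs_matrix(best_scores)
        yy = pheno.reindex(matrix.index).to_numpy()
        report = model_selection_cv(matrix, yy, k=config.cv.get("k", 10),
                                    iterations=config.cv.get("iterations", 100),
                                    seed=config.seed)
        _write(report.per_model, outdir, "model_comparison", manifest,
               list(config.sumstats.values()), config.cv)
        summary = pd.DataFrame([{
            "best_model": report.best_model,
            "best_params": repr(report.best_params),
            "final_auc": report.final_auc,
            "final_pseudo_r2": report.final_pseudo_r2,
            "n_train": report.n_train, "n_test": report.n_test,
        }])
        _write(summary, outdir, "prediction_summary", manifest, [], {})
        if report.coefficients is not None:
            _write(report.coefficients.rename_axis("trait").reset_index(),
                   outdir, "prediction_coefficients", manifest, [], {})
        results["predict"] = report

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results
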
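"""Dissection of pleiotropic SNPs shared by a disease and longevity.

SNPs from a disease's best PRS that are nominally significant in both the
disease and the longevity summary statistics are classified by
effect-direction concordance: panel 1 raises both disease risk and the
chance of longevity (the trade-off signature), panel 2 raises disease risk
and lowers it. Longevity effects are always expressed on the disease risk
allele so the panel signs are meaningful.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "select_pleiotropic",
    "annotate_nearest_genes",
    "effect_lookup",
    "export_panel_genes",
]

Z95 = 1.959964  # two-sided 95% normal quantile


def _fmt_dist(d: int) -> str:
    # comma grouping only for large distances, matching the published style
    return f"{d:,}" if d >= 10_000 else str(d)


def _align_longevity(merged: pd.DataFrame) -> pd.Series:
    """Longevity beta re-expressed on the disease effect allele."""
    same = merged["effect_allele_long"] == merged["effect_allele"]
    flipped = (merged["effect_allele_long"] == merged["other_allele"]) \
        & (merged["other_allele_long"] == merged["effect_allele"])
    bad = ~(same | flipped)
    if bad.any():
        offender = merged.loc[bad, "snp_id"].iloc[0]
        raise ValueError(f"allele mismatch between disease and longevity "
                         f"tables at SNP {offender}")
    return np.where(same, merged["beta_long"], -merged["beta_long"])


def select_pleiotropic(best_prs_snps, ss_disease: pd.DataFrame,
                       ss_longevity: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Classify shared nominally-significant SNPs into trade-off panels.

    Restricts to the disease best-PRS SNP set, keeps SNPs with p < alpha
    in both studies, aligns the longevity effect to the disease risk
    allele, and labels each SNP panel1 (longevity log-odds > 0) or panel2
    (< 0). The disease table must already be risk-allele oriented.
    """
    best = set(best_prs_snps)
    dis = ss_disease[ss_disease["snp_id"].isin(best)]
    merged = dis.merge(
        ss_longevity[["snp_id", "effect_allele", "other_allele", "beta", "p"]],
        on="snp_id", suffixes=("", "_long"))
    merged = merged[(merged["p"] < alpha) & (merged["p_long"] < alpha)].copy()
    if merged.empty:
        return pd.DataFrame(columns=["snp_id", "beta_disease", "beta_longevity",
                                     "p_disease", "p_longevity", "panel"])
    merged["beta_longevity"] = _align_longevity(merged)
    merged = merged[merged["beta_longevity"] != 0]
    out = pd.DataFrame({
        "snp_id": merged["snp_id"].to_numpy(),
        "chrom": merged["chrom"].to_numpy(),
        "pos": merged["pos"].to_numpy(),
        "risk_allele": merged["effect_allele"].to_numpy(),
        "beta_disease": merged["beta"].to_numpy(),
        "beta_longevity": merged["beta_longevity"],
        "p_disease": merged["p"].to_numpy(),
        "p_longevity": merged["p_long"].to_numpy(),
    })
    out["panel"] = np.where(out["beta_longevity"] > 0, "panel1", "panel2")
    return out.reset_index(drop=True)


def annotate_nearest_genes(variants: pd.DataFrame,
                           genes: pd.DataFrame) -> pd.Series:
    """Nearest-gene label per SNP in the ``"NAME(dist = D)"`` convention.

    ``genes`` needs columns chrom, start, end (1-based inclusive), name. A
    SNP inside a gene gets that gene's bare name; otherwise the nearest
    gene on each side is reported with its base-pair distance, comma
    separated. Chromosomes with no genes yield "intergenic".
    """
    labels = []
    if len(genes):
        genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    for _, snp in variants.iterrows():
        sub = genes[genes["chrom"].astype(str) == str(snp["chrom"])] \
            if len(genes) else genes
        if len(sub) == 0:
            labels.append("intergenic")
            continue
        pos = snp["pos"]
        inside = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
        if len(inside):
            labels.append(",".join(inside["name"]))
            continue
        parts = []
        left = sub[sub["end"] < pos]
        if len(left):
            g = left.loc[left["end"].idxmax()]
            parts.append(f"{g['name']}(dist = {_fmt_dist(pos - g['end'])})")
        right = sub[sub["start"] > pos]
        if len(right):
            g = right.loc[right["start"].idxmin()]
            parts.append(f"{g['name']}(dist = {_fmt_dist(g['start'] - pos)})")
        labels.append(", ".join(parts) if parts else "intergenic")
    return pd.Series(labels, index=variants.index, name="gene_label")


def effect_lookup(snp_list, ss_disease: pd.DataFrame,
                  ss_longevity: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Odds ratios with 95% CIs for chosen SNPs in both studies.

    OR = exp(beta), CI = exp(beta ± 1.959964·se). SNPs absent from a table
    get NaN fields with a warning. A nominal-significance flag is set at
    p < ``alpha`` in both studies.
    """
    dis = ss_disease.set_index("snp_id")
    lon = ss_longevity.set_index("snp_id")
    rows = []
    for sid in snp_list:
        rec = {"snp_id": sid}
        for tag, tab in (("dis", dis), ("long", lon)):
            if sid in tab.index:
                beta = float(tab.loc[sid, "beta"])
                se = float(tab.loc[sid, "se"])
                rec[f"or_{tag}"] = np.exp(beta)
                rec[f"or_{tag}_lo"] = np.exp(beta - Z95 * se)
                rec[f"or_{tag}_hi"] = np.exp(beta + Z95 * se)
                rec[f"p_{tag}"] = float(tab.loc[sid, "p"])
            else:
                logger.warning("SNP %s absent from %s sumstats", sid, tag)
                for f in (f"or_{tag}", f"or_{tag}_lo", f"or_{tag}_hi",
                          f"p_{tag}"):
                    rec[f] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["both_significant"] = (out["p_dis"] < alpha) & (out["p_long"] < alpha)
    return out


def export_panel_genes(panel_table: pd.DataFrame, gene_labels: pd.Series,
                       path) -> None:
    """Write per-panel gene lists as plain text for external enrichment tools."""
    tab = panel_table.copy()
    tab["gene_label"] = gene_labels.to_numpy()
    with open(path, "w") as fh:
        for panel in ("panel1", "panel2"):
            genes = tab.loc[tab["panel"] == panel, "gene_label"]
            fh.write(f"# {panel}\n")
            for g in genes:
                fh.write(f"{g}\n")
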
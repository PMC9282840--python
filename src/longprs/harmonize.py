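"""GWAS summary-statistic loading and allele harmonization.

Base summary statistics are aligned to the target cohort's variants so
that every effect size refers to the target's counted allele: direct
matches kept, swapped alleles sign-flipped, strand (complementary) flips
rewritten then re-matched, and palindromic or irreconcilable records
excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_sumstats", "or_to_beta", "harmonize_alleles", "orient_to_risk"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header aliases, lower-cased
_ALIASES = {
    "snp_id": ["snp", "snp_id", "id", "rsid", "markername", "variant_id"],
    "chrom": ["chr", "chrom", "chromosome"],
    "pos": ["bp", "pos", "position", "base_pair_location"],
    "effect_allele": ["a1", "effect_allele", "allele1", "ea"],
    "other_allele": ["a2", "other_allele", "allele2", "oa", "nea"],
    "beta": ["beta", "effect", "b"],
    "or": ["or", "odds_ratio"],
    "se": ["se", "standard_error", "stderr"],
    "p": ["p", "pval", "p_value", "pvalue"],
    "n": ["n", "n_samples", "sample_size"],
}

SUMSTATS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "se", "p", "n"]


def or_to_beta(or_value):
    """Convert an odds ratio to a log-odds effect size, ``beta = log(OR)``."""
    arr = np.asarray(or_value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("odds ratios must be positive")
    out = np.log(arr)
    return float(out) if np.isscalar(or_value) or arr.ndim == 0 else out


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read delimited GWAS summary statistics into the canonical table.

    ``column_map`` maps canonical names (snp_id, chrom, pos, effect_allele,
    other_allele, beta or or, se, p, n) to the file's headers; unmapped
    columns are resolved through common aliases. An OR column is converted
    to beta = log(OR). Rows missing p or alleles are dropped with a logged
    count; p = 0 is clamped to the smallest positive float with a warning.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in raw.columns}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon, aliases in _ALIASES.items():
        if canon in column_map:
            if column_map[canon] not in raw.columns:
                raise ValueError(f"mapped column {column_map[canon]!r} absent")
            resolved[canon] = column_map[canon]
            continue
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
    required = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "p"]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise ValueError(f"unmappable sumstats columns: {missing}")
    if "beta" not in resolved and "or" not in resolved:
        raise ValueError("sumstats must provide a beta or OR column")

    df = pd.DataFrame({
        "snp_id": raw[resolved["snp_id"]].astype(str),
        "chrom": raw[resolved["chrom"]].astype(str),
        "pos": raw[resolved["pos"]].astype(int),
        "effect_allele": raw[resolved["effect_allele"]].astype(str).str.upper(),
        "other_allele": raw[resolved["other_allele"]].astype(str).str.upper(),
        "p": raw[resolved["p"]].astype(float),
    })
    if "beta" in resolved:
        df["beta"] = raw[resolved["beta"]].astype(float)
    else:
        df["beta"] = or_to_beta(raw[resolved["or"]].astype(float).to_numpy())
    df["se"] = raw[resolved["se"]].astype(float) if "se" in resolved else np.nan
    df["n"] = raw[resolved["n"]].astype(float) if "n" in resolved else np.nan

    bad = df["p"].isna() | df["effect_allele"].isin(["", "NAN"]) \
        | df["other_allele"].isin(["", "NAN"])
    if bad.any():
        logger.info("dropped %d rows with missing p or alleles", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    zero_p = df["p"] <= 0
    if zero_p.any():
        logger.warning("clamped %d non-positive p-values", int(zero_p.sum()))
        df.loc[zero_p, "p"] = np.nextafter(0.0, 1.0)
    return df[SUMSTATS_COLUMNS]


def _is_palindromic(a1, a2):
    return np.array([COMPLEMENT.get(x) == y for x, y in zip(a1, a2)])


def harmonize_alleles(ss: pd.DataFrame, target: pd.DataFrame,
                      keep_palindromic: bool = False
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Align summary statistics to the target variant table.

    Join is on snp_id when the id sets intersect, else on chrom+pos. Each
    joined record lands in one of four outcomes: direct match (kept),
    allele swap (beta negated), complementary-strand match (alleles
    rewritten, then matched or swapped), or exclusion (palindromic A/T,
    C/G unless ``keep_palindromic``, or irreconcilable alleles). Returns
    the aligned table — every effect_allele equal to the target's
    counted_allele — and a report whose counts partition the input rows.
    """
    tgt = target[["snp_id", "chrom", "pos", "counted_allele", "other_allele"]]
    by_id = len(set(ss["snp_id"]) & set(tgt["snp_id"])) > 0
    if by_id:
        dup = ss["snp_id"].duplicated(keep=False)
        merged = ss.loc[~dup].merge(
            tgt, on="snp_id", how="left", suffixes=("", "_t"))
        n_dup = int(dup.sum())
    else:
        dup = ss.duplicated(subset=["chrom", "pos"], keep=False)
        merged = ss.loc[~dup].merge(
            tgt.drop(columns="snp_id"), on=["chrom", "pos"], how="left",
            suffixes=("", "_t"))
        n_dup = int(dup.sum())

    counted = merged["counted_allele"]
    in_target = counted.notna()
    a1 = merged["effect_allele"].to_numpy()
    a2 = merged["other_allele"].to_numpy()
    t1 = counted.fillna("N").to_numpy()
    t2 = merged["other_allele_t"].fillna("N").to_numpy()

    palindromic = _is_palindromic(a1, a2) & in_target.to_numpy()
    direct = (a1 == t1) & (a2 == t2)
    swapped = (a1 == t2) & (a2 == t1)
    c1 = np.array([COMPLEMENT.get(x, "N") for x in a1])
    c2 = np.array([COMPLEMENT.get(x, "N") for x in a2])
    comp_direct = (c1 == t1) & (c2 == t2) & ~direct & ~swapped
    comp_swapped = (c1 == t2) & (c2 == t1) & ~direct & ~swapped

    if not keep_palindromic:
        for m in (direct, swapped, comp_direct, comp_swapped):
            m &= ~palindromic
    keep = in_target.to_numpy() & (direct | swapped | comp_direct | comp_swapped)
    mismatch = in_target.to_numpy() & ~keep & ~(palindromic & ~keep_palindromic)
    excl_palin = (palindromic & ~keep_palindromic) if not keep_palindromic \
        else np.zeros_like(keep)

    out = merged.loc[keep].copy()
    flip = (swapped | comp_swapped)[keep]
    out["beta"] = np.where(flip, -out["beta"], out["beta"])
    out["effect_allele"] = out["counted_allele"]
    out["other_allele"] = out["other_allele_t"]
    if by_id:
        out["chrom"] = out["chrom_t"] if "chrom_t" in out else out["chrom"]
        out["pos"] = out["pos_t"] if "pos_t" in out else out["pos"]
    else:
        out["snp_id"] = tgt.set_index(["chrom", "pos"]).loc[
            pd.MultiIndex.from_frame(out[["chrom", "pos"]]), "snp_id"].to_numpy()
    out = out[SUMSTATS_COLUMNS].reset_index(drop=True)

    report = pd.Series({
        "matched": int((direct & keep).sum()),
        "swapped": int((swapped & keep).sum()),
        "strand_flip_matched": int((comp_direct & keep).sum()),
        "strand_flip_swapped": int((comp_swapped & keep).sum()),
        "excluded_palindromic": int(excl_palin.sum()),
        "excluded_mismatch": int(mismatch.sum()),
        "excluded_not_in_target": int((~in_target).sum()),
        "excluded_duplicate": n_dup,
    })
    if out.empty:
        raise ValueError("no summary-statistic SNPs align to the target")
    assert report.sum() == len(ss), "harmonization report must partition input"
    return out, report


def orient_to_risk(ss: pd.DataFrame) -> pd.DataFrame:
    """Consolidate effect alleles into risk alleles (all beta >= 0).

    Rows with negative beta have their alleles swapped and beta negated —
    the effect of the counted allele equals minus the effect of the other
    allele. p and se are untouched. Idempotent.
    """
    out = ss.copy()
    neg = out["beta"] < 0
    e, o = out.loc[neg, "effect_allele"].copy(), out.loc[neg, "other_allele"].copy()
    out.loc[neg, "effect_allele"] = o.to_numpy()
    out.loc[neg, "other_allele"] = e.to_numpy()
    out.loc[neg, "beta"] = -out.loc[neg, "beta"]
    return out
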
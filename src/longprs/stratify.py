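"""Stratified polygenic scores: annotation sets, p-value bins, regions.

Partitions the harmonized SNPs into annotation sets (e.g. cell types
grouped into biological systems) or GWAS significance bins, builds a
clumped score per partition, and regresses each on the longevity
phenotype. Also supports masking a genomic region (e.g. the APOE locus,
chr19:45,361,224–45,436,657 on GRCh37) out of the summary statistics, and
detecting LD blocks by the D' confidence-interval rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prs import greedy_clump, score_prs
from .stats import bh_fdr, bonferroni_threshold, fit_logistic
from .target import GenotypeData

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BIN_CUTPOINTS",
    "APOE_REGION",
    "AnnotationSets",
    "Region",
    "read_bed_sets",
    "snps_in_sets",
    "set_prs_scan",
    "pvalue_bin_prs_scan",
    "stratified_family_size",
    "mask_region",
    "detect_ld_blocks",
]

#: significance-bin upper cutpoints: genome-wide significance then decade
#: steps up to nominal significance, defining 8 disjoint SNP sets
DEFAULT_BIN_CUTPOINTS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 5e-2)


@dataclass(frozen=True)
class Region:
    """1-based, endpoint-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


#: the extended APOE locus on GRCh37 masked in the region-sensitivity analysis
APOE_REGION = Region("19", 45_361_224, 45_436_657)


@dataclass
class AnnotationSets:
    """Named SNP-id sets with an optional set → group mapping."""

    sets: dict
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [s for s in self.groups if s not in self.sets]
        if missing:
            raise ValueError(f"grouped sets absent from sets: {missing}")

    def group_sets(self) -> dict:
        """Group-level SNP sets: the union of each group's member sets."""
        out: dict = {}
        for name, group in self.groups.items():
            out.setdefault(group, set()).update(self.sets[name])
        return out

    def at_level(self, level: str) -> dict:
        if level == "set":
            return self.sets
        if level == "group":
            return self.group_sets()
        raise ValueError("level must be 'set' or 'group'")


def read_bed_sets(bed_path, group_path=None) -> tuple[dict, dict]:
    """Read BED intervals (4th column = set name) and a set→group mapping."""
    intervals: dict = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split()[:4]
            intervals.setdefault(name, []).append((chrom, int(start), int(end)))
    groups: dict = {}
    if group_path is not None:
        with open(group_path) as fh:
            for line in fh:
                if line.strip():
                    name, group = line.split()[:2]
                    groups[name] = group
    return intervals, groups


def snps_in_sets(variants: pd.DataFrame, bed_sets: dict,
                 groups: dict | None = None) -> AnnotationSets:
    """Assign SNPs to annotation sets by interval overlap or id list.

    Interval lists are BED-style 0-based half-open ``(chrom, start, end)``
    tuples: a SNP at 1-based position p falls in [start, end) iff
    start < p <= end. Id lists (sets/lists of strings) are taken verbatim.
    Sets may overlap — a SNP can belong to several. Unknown chromosomes in
    intervals are skipped with a warning.
    """
    known_chroms = set(variants["chrom"].astype(str))
    known_ids = set(variants["snp_id"])
    out: dict = {}
    for name, spec in bed_sets.items():
        members: set = set()
        entries = list(spec)
        if entries and isinstance(entries[0], str):
            members = set(entries) & known_ids
        else:
            for chrom, start, end in entries:
                chrom = str(chrom)
                if chrom not in known_chroms:
                    logger.warning("unknown chromosome %s in set %s", chrom, name)
                    continue
                hit = ((variants["chrom"].astype(str) == chrom)
                       & (variants["pos"] > start) & (variants["pos"] <= end))
                members.update(variants.loc[hit, "snp_id"])
        out[name] = members
    groups = {k: v for k, v in (groups or {}).items() if k in out}
    return AnnotationSets(sets=out, groups=groups)


def _scan_one_set(label, snp_ids, ss, geno, pheno, r2_threshold, window_bp,
                  p_max):
    sub = ss[ss["snp_id"].isin(snp_ids) & (ss["p"] <= p_max)]
    present = sub["snp_id"].isin(geno.variants["snp_id"])
    sub = sub.loc[present]
    if sub.empty:
        return None
    clump = greedy_clump(sub, geno, r2_threshold=r2_threshold,
                         window_bp=window_bp)
    res = score_prs(geno, sub, clump.index_snps)
    s = res.scores
    ok = ~np.isnan(s)
    if s[ok].std() == 0:
        return None
    z = (s[ok] - s[ok].mean()) / s[ok].std()
    fit = fit_logistic(np.asarray(pheno, dtype=float)[ok], z)
    return {"label": label, "n_snps": res.n_snps, "coefficient": fit.coef,
            "se": fit.se, "p": fit.p, "pseudo_r2": fit.pseudo_r2,
            "direction": fit.direction}


def stratified_family_size(n_sets: int, n_traits: int) -> int:
    """Size of the multiple-testing family for set-stratified scans."""
    if n_sets < 1 or n_traits < 1:
        raise ValueError("counts must be positive")
    return n_sets * n_traits


def set_prs_scan(ss: pd.DataFrame, geno: GenotypeData, pheno,
                 sets: AnnotationSets, level: str = "set",
                 r2_threshold: float = 0.1, window_bp: int = 500_000,
                 p_max: float = 1.0, family_size: int | None = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-annotation-set PRS association scan.

    For each set (or group): restrict the sumstats to the set's SNPs,
    clump within the set, score all surviving index SNPs at p <= ``p_max``
    (default 1, i.e. no thresholding inside sets), and fit a logistic
    association with the phenotype. BH-FDR is applied across the rows
    with declared family size ``family_size`` (e.g. sets × traits), and a
    Bonferroni flag is set at ``alpha / family_size``.
    """
    level_sets = sets.at_level(level)
    if not level_sets:
        raise ValueError("no annotation sets supplied")
    rows = []
    for name, snp_ids in level_sets.items():
        rec = _scan_one_set(name, snp_ids, ss, geno, pheno, r2_threshold,
                            window_bp, p_max)
        if rec is None:
            logger.info("set %s has no scoreable SNPs; skipped", name)
            continue
        if level == "set" and sets.groups:
            rec["group"] = sets.groups.get(name, "")
        rows.append(rec)
    if not rows:
        raise ValueError("no annotation set produced a score")
    table = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(table)
    table["fdr_p"] = bh_fdr(table["p"].to_numpy(), m=m)
    table["bonferroni_significant"] = (
        table["p"] < bonferroni_threshold(alpha, m))
    return table


def pvalue_bin_prs_scan(ss: pd.DataFrame, geno: GenotypeData, pheno,
                        cutpoints=DEFAULT_BIN_CUTPOINTS,
                        r2_threshold: float = 0.1,
                        window_bp: int = 500_000) -> pd.DataFrame:
    """Per-significance-bin PRS association scan.

    Bins are (0, c1], (c1, c2], ..., (c_{k-1}, c_k]; SNPs with p above the
    last cutpoint are excluded. Each non-empty bin is clumped, scored, and
    regressed on the phenotype. Empty bins are skipped.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.size == 0 or np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be strictly ascending")
    p = ss["p"].to_numpy()
    bin_idx = np.searchsorted(cut, p, side="left")  # p <= cut[i] -> bin i
    rows = []
    for i in range(cut.size):
        in_bin = ss.loc[bin_idx == i, "snp_id"]
        rec = _scan_one_set(f"bin{i + 1}", set(in_bin), ss, geno, pheno,
                            r2_threshold, window_bp, p_max=1.0)
        if rec is None:
            logger.info("p-value bin %d empty; skipped", i + 1)
            continue
        rec["bin"] = i + 1
        rec["p_upper"] = cut[i]
        rows.append(rec)
    if not rows:
        raise ValueError("every p-value bin is empty")
    return pd.DataFrame(rows)


def mask_region(ss: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Drop sumstats rows inside a region (1-based inclusive endpoints)."""
    inside = region.contains(ss["chrom"], ss["pos"])
    if inside.any():
        logger.info("masked %d SNPs in %s:%d-%d", int(inside.sum()),
                    region.chrom, region.start, region.end)
    return ss.loc[~inside].reset_index(drop=True)


# ---------------------------------------------------------------------------
# D'-confidence-interval LD blocks
# ---------------------------------------------------------------------------

def _dprime_ci(g1, g2, grid_size: int = 101, ci: float = 0.90):
    """Likelihood-based confidence interval for |D'| between two SNPs.

    Haplotype frequencies under random mating are profiled over a grid of
    |D'| in [0, 1] (orientation chosen so the MLE D is positive); the CI
    bounds are the 5th/95th percentiles of the normalized likelihood over
    the grid. Returns (lower, upper) or None for uninformative pairs.
    """
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok], g2[ok]
    if a.size < 2:
        return None
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    if min(pa, 1 - pa, pb, 1 - pb) <= 0:
        return None
    # 3x3 genotype table counts
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    # orient so positive D is the relevant direction
    sign = 1.0 if np.cov(a, b)[0, 1] >= 0 else -1.0
    b_or = 2.0 - b if sign < 0 else b
    pb_or = b_or.mean() / 2.0
    if sign < 0:
        counts = counts[:, ::-1]
    d_max = min(pa * (1 - pb_or), (1 - pa) * pb_or)
    if d_max <= 0:
        return None

    grid = np.linspace(0.0, 1.0, grid_size)
    loglik = np.full(grid_size, -np.inf)
    eps = 1e-12
    for k, dprime in enumerate(grid):
        d = dprime * d_max
        h11 = pa * pb_or + d
        h10 = pa * (1 - pb_or) - d
        h01 = (1 - pa) * pb_or - d
        h00 = (1 - pa) * (1 - pb_or) + d
        if min(h11, h10, h01, h00) < -eps:
            continue
        h = np.clip([h00, h01, h10, h11], eps, 1.0)
        h00_, h01_, h10_, h11_ = h
        # genotype-pair probabilities under random union of haplotypes;
        # g counts the "1" allele at each locus (h11 carries 1 at both)
        pg = np.empty((3, 3))
        pg[0, 0] = h00_ ** 2
        pg[0, 1] = 2 * h00_ * h01_
        pg[0, 2] = h01_ ** 2
        pg[1, 0] = 2 * h00_ * h10_
        pg[1, 1] = 2 * (h00_ * h11_ + h01_ * h10_)
        pg[1, 2] = 2 * h01_ * h11_
        pg[2, 0] = h10_ ** 2
        pg[2, 1] = 2 * h10_ * h11_
        pg[2, 2] = h11_ ** 2
        loglik[k] = float(np.sum(counts * np.log(np.clip(pg, eps, 1.0))))
    if not np.any(np.isfinite(loglik)):
        return None
    lik = np.exp(loglik - np.nanmax(loglik[np.isfinite(loglik)]))
    lik[~np.isfinite(loglik)] = 0.0
    cdf = np.cumsum(lik) / lik.sum()
    tail = (1.0 - ci) / 2.0
    lower = grid[int(np.searchsorted(cdf, tail))]
    upper = grid[min(int(np.searchsorted(cdf, 1.0 - tail)), grid_size - 1)]
    return float(lower), float(upper)


def detect_ld_blocks(geno: GenotypeData, window: Region,
                     strong_lower: float = 0.70, strong_upper: float = 0.98,
                     recomb_upper: float = 0.90,
                     min_strong_fraction: float = 0.95) -> list[Region]:
    """LD blocks inside ``window`` by the D' confidence-interval rule.

    A pair is in strong LD when its |D'| CI has lower bound >=
    ``strong_lower`` and upper bound >= ``strong_upper``; it shows strong
    recombination evidence when the upper bound < ``recomb_upper``. A block
    is a maximal SNP span in which at least ``min_strong_fraction`` of the
    informative (strong or recombination) pairs are strong. Deterministic.
    Fewer than 2 SNPs in the window yields an empty list.
    """
    v = geno.variants
    in_win = np.asarray(window.contains(v["chrom"], v["pos"]))
    idx = np.where(in_win)[0]
    if idx.size < 2:
        return []
    order = idx[np.argsort(v["pos"].to_numpy()[idx], kind="mergesort")]
    m = order.size
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            ci = _dprime_ci(geno.matrix[:, order[i]], geno.matrix[:, order[j]])
            if ci is None:
                continue
            lo, hi = ci
            if lo >= strong_lower and hi >= strong_upper:
                strong[i, j] = informative[i, j] = True
            elif hi < recomb_upper:
                informative[i, j] = True

    spans = []
    for i in range(m):
        for j in range(i + 1, m):
            sub_inf = informative[i:j + 1, i:j + 1]
            n_inf = int(sub_inf.sum())
            if n_inf == 0:
                continue
            n_str = int(strong[i:j + 1, i:j + 1].sum())
            if strong[i, j] and n_str / n_inf >= min_strong_fraction:
                spans.append((i, j))
    # keep maximal non-overlapping spans, longest first
    spans.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    pos = v["pos"].to_numpy()
    for i, j in spans:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append(Region(str(v["chrom"].iloc[order[i]]),
                             int(pos[order[i]]), int(pos[order[j]])))
    blocks.sort(key=lambda r: r.start)
    return blocks
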
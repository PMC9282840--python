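"""Polygenic score engine: LD, greedy clumping, scoring, threshold scan.

The score for individual j is ``PRS_j = sum_i S_i * G_ij / M_j`` where
``S_i`` is the per-allele log-odds of the counted allele, ``G_ij`` its
dosage, and ``M_j`` twice the number of SNPs with non-missing calls for j
(each SNP contributes two allele slots). Clumping greedily selects index
SNPs by ascending p-value, absorbing neighbours with r² above threshold
within a window; thresholding scans a ladder of p-value cutoffs and keeps
the cutoff whose score best predicts the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import fit_logistic
from .target import GenotypeData

__all__ = [
    "DEFAULT_LADDER",
    "ClumpResult",
    "PRSResult",
    "pairwise_r2",
    "greedy_clump",
    "score_prs",
    "threshold_scan",
]

#: p-value cutoffs from genome-wide significance up by one order of
#: magnitude per step, with the no-thresholding endpoint 1 appended.
DEFAULT_LADDER = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 5e-2, 5e-1, 1.0)

#: optional fine ladder step for a dense threshold scan
FINE_STEP = 5e-5


def fine_ladder(step: float = FINE_STEP) -> np.ndarray:
    """Dense threshold ladder from ``step`` to 1 in increments of ``step``."""
    return np.arange(step, 1.0 + step / 2, step)


@dataclass
class ClumpResult:
    """Greedy clumping output: index SNPs and the members each absorbed."""

    index_snps: list
    members: dict
    r2_threshold: float
    window_bp: int


@dataclass
class PRSResult:
    """Per-individual scores for one SNP set / threshold."""

    scores: np.ndarray
    threshold: float
    snp_ids: list
    n_snps: int = field(init=False)

    def __post_init__(self):
        self.n_snps = len(self.snp_ids)


def pairwise_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are pairwise-deleted; zero variance after deletion is
    an error.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok], g2[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance after pairwise deletion")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def greedy_clump(ss: pd.DataFrame, geno: GenotypeData,
                 r2_threshold: float = 0.1,
                 window_bp: int = 500_000) -> ClumpResult:
    """LD-clump summary statistics against the target genotypes.

    SNPs are visited by ascending p (ties broken by chrom then position);
    each not-yet-assigned SNP becomes an index and absorbs every unassigned
    SNP on the same chromosome within ±``window_bp`` whose r² with it
    exceeds ``r2_threshold``. LD is computed from the target genotypes.
    """
    present = ss["snp_id"].isin(geno.variants["snp_id"])
    if not present.any():
        raise ValueError("no summary-statistic SNPs overlap the genotypes")
    tab = ss.loc[present, ["snp_id", "chrom", "pos", "p"]].copy()
    tab = tab.sort_values(["p", "chrom", "pos"], kind="mergesort")
    cols = geno.columns(tab["snp_id"])
    chroms = tab["chrom"].to_numpy()
    positions = tab["pos"].to_numpy()
    ids = tab["snp_id"].to_numpy()

    # per-chromosome position-sorted views for fast window lookup
    order_by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        order_by_chrom[c] = idx[np.argsort(positions[idx], kind="mergesort")]

    assigned = np.zeros(len(tab), dtype=bool)
    index_snps: list = []
    members: dict = {}
    mat = geno.matrix
    for i in range(len(tab)):
        if assigned[i]:
            continue
        assigned[i] = True
        index_snps.append(ids[i])
        members[ids[i]] = []
        chrom_idx = order_by_chrom[chroms[i]]
        chrom_pos = positions[chrom_idx]
        lo = np.searchsorted(chrom_pos, positions[i] - window_bp, "left")
        hi = np.searchsorted(chrom_pos, positions[i] + window_bp, "right")
        g_index = mat[:, cols[i]]
        for j in chrom_idx[lo:hi]:
            if assigned[j]:
                continue
            try:
                r2 = pairwise_r2(g_index, mat[:, cols[j]])
            except ValueError:
                continue
            if r2 > r2_threshold:
                assigned[j] = True
                members[ids[i]].append(ids[j])
    return ClumpResult(index_snps=index_snps, members=members,
                       r2_threshold=r2_threshold, window_bp=window_bp)


def score_prs(geno: GenotypeData, ss: pd.DataFrame, snp_set,
              threshold: float = 1.0, mj_mode: str = "alleles") -> PRSResult:
    """Average-per-allele polygenic score over ``snp_set``.

    Missing genotypes drop out of both the weighted sum and the
    denominator; an individual with no non-missing SNP gets a NaN score.
    ``mj_mode='alleles'`` divides by 2 × (non-missing SNPs), ``'snps'`` by
    the SNP count (the two differ by a constant factor that cancels in
    downstream regressions).
    """
    snp_ids = [s for s in snp_set]
    if not snp_ids:
        raise ValueError("empty SNP set")
    w = ss.set_index("snp_id").loc[snp_ids, "beta"].to_numpy(dtype=float)
    g = geno.dosages(snp_ids)
    contrib = w[None, :] * g
    numer = np.nansum(contrib, axis=1)
    n_obs = (~np.isnan(g)).sum(axis=1)
    ploidy = 2 if mj_mode == "alleles" else 1
    denom = ploidy * n_obs.astype(float)
    scores = np.divide(numer, denom, out=np.full_like(numer, np.nan),
                       where=denom > 0)
    return PRSResult(scores=scores, threshold=threshold, snp_ids=snp_ids)


def threshold_scan(ss: pd.DataFrame, geno: GenotypeData, phenotype,
                   clump: ClumpResult, ladder=DEFAULT_LADDER,
                   mj_mode: str = "alleles") -> pd.DataFrame:
    """Scan p-value cutoffs over clump index SNPs and pick the best PRS.

    For each cutoff, score a PRS on index SNPs with p <= cutoff,
    standardize it, and fit a logistic regression of the phenotype on the
    score. The row with the smallest regression p is flagged best (ties:
    smallest threshold). Cutoffs with no SNPs are skipped. Returns a table
    with columns threshold, n_snps, coefficient, se, p, pseudo_r2, best.
    """
    ladder = np.asarray(ladder, dtype=float)
    if ladder.size == 0 or np.any(np.diff(ladder) <= 0):
        raise ValueError("ladder must be nonempty and strictly ascending")
    y = np.asarray(phenotype, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant")
    p_by_id = ss.set_index("snp_id")["p"]
    index_p = p_by_id.loc[clump.index_snps].to_numpy()
    index_ids = np.asarray(clump.index_snps)

    rows = []
    for cutoff in ladder:
        ids = index_ids[index_p <= cutoff]
        if ids.size == 0:
            continue
        res = score_prs(geno, ss, list(ids), threshold=cutoff, mj_mode=mj_mode)
        s = res.scores
        ok = ~np.isnan(s)
        sd = s[ok].std()
        if sd == 0:
            continue
        z = (s - s[ok].mean()) / sd
        fit = fit_logistic(y[ok], z[ok])
        rows.append({"threshold": cutoff, "n_snps": res.n_snps,
                     "coefficient": fit.coef, "se": fit.se, "p": fit.p,
                     "pseudo_r2": fit.pseudo_r2})
    if not rows:
        raise ValueError("no threshold produced a scoreable SNP set")
    scan = pd.DataFrame(rows)
    best = scan["p"].idxmin()  # first minimum -> smallest threshold on ties
    scan["best"] = False
    scan.loc[best, "best"] = True
    return scan
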
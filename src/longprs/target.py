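"""Target-cohort genotypes, phenotypes, and SNP-level quality control.

The target cohort is the case/control longevity sample the polygenic
scores are evaluated in (cases = long-lived individuals, controls =
middle-aged). Genotypes arrive as diploid hard calls in VCF; internally
they live in a dense individuals × variants dosage matrix counting copies
of the VCF ALT allele, with NaN for missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "read_genotypes",
    "read_phenotype",
    "hwe_exact_test",
    "snp_qc_filter",
]

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele", "other_allele", "maf"]


@dataclass
class GenotypeData:
    """Dense genotype matrix plus its per-variant metadata.

    ``matrix`` is individuals × variants, entries in {0, 1, 2} counting
    copies of ``counted_allele`` (the VCF ALT), NaN where the call is
    missing. ``variants`` carries snp_id, chrom, pos (1-based),
    counted_allele, other_allele, maf.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    matrix: np.ndarray
    _col_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        ids = self.variants["snp_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate SNP ids: {dups}")
        if self.matrix.shape != (len(self.samples), len(self.variants)):
            raise ValueError("matrix shape does not match samples × variants")
        self._col_index = {s: i for i, s in enumerate(ids)}

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def columns(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids (KeyError on unknowns)."""
        return np.array([self._col_index[s] for s in snp_ids], dtype=int)

    def dosages(self, snp_ids) -> np.ndarray:
        return self.matrix[:, self.columns(snp_ids)]

    def subset(self, snp_ids) -> "GenotypeData":
        cols = self.columns(snp_ids)
        return GenotypeData(
            samples=self.samples,
            variants=self.variants.iloc[cols].reset_index(drop=True),
            matrix=self.matrix[:, cols],
        )


def read_genotypes(vcf_path) -> GenotypeData:
    """Read diploid hard calls from a VCF into a :class:`GenotypeData`.

    Multi-allelic records and non-SNP records (indels, MNPs) are excluded
    with a logged count; missing GT becomes NaN. The counted allele is ALT.
    """
    vcf = VCF(str(vcf_path))
    samples = np.array(vcf.samples)
    rows, cols, skipped_multi, skipped_nonsnp = [], [], 0, 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped_nonsnp += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = v.gt_types.astype(float)
        dosage = np.select([g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], np.nan)
        freq = np.nanmean(dosage) / 2.0 if np.any(~np.isnan(dosage)) else np.nan
        maf = min(freq, 1.0 - freq) if np.isfinite(freq) else np.nan
        snp_id = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        rows.append((snp_id, str(v.CHROM), int(v.POS), v.ALT[0], v.REF, maf))
        cols.append(dosage)
    vcf.close()
    if skipped_multi or skipped_nonsnp:
        logger.info("excluded %d multi-allelic and %d non-SNP records",
                    skipped_multi, skipped_nonsnp)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {vcf_path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    matrix = np.column_stack(cols)
    return GenotypeData(samples=samples, variants=variants, matrix=matrix)


def read_phenotype(path) -> pd.Series:
    """Read a two-column (individual id, status) phenotype table.

    Status must be strictly 0/1 (1 = long-lived case).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["iid", "status"],
                     dtype={"iid": str})
    if df["iid"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype file")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("phenotype status must be binary 0/1")
    return pd.Series(df["status"].to_numpy(), index=df["iid"], name="status")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg equilibrium test p-value.

    The conditional distribution of the heterozygote count given the
    allele counts is enumerated exactly; the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one. Deterministic (no mid-p correction).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a constant, h of matching parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hets = hets[hets <= n_rare]
    n_common = 2 * n - n_rare
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (hets * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def snp_qc_filter(geno: GenotypeData, max_missing: float = 0.05,
                  min_maf: float = 0.01, hwe_p_min: float = 1e-5,
                  controls=None) -> tuple[GenotypeData, pd.DataFrame]:
    """Remove SNPs failing missingness, MAF, or HWE filters.

    HWE is evaluated in controls only when a boolean ``controls`` mask over
    individuals is supplied (case enrichment legitimately distorts HWE);
    otherwise in the full sample. A SNP deviating at ``p <= hwe_p_min`` is
    removed. Returns the filtered data and a per-filter removal report.
    """
    for name, v in [("max_missing", max_missing), ("min_maf", min_maf),
                    ("hwe_p_min", hwe_p_min)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    g = geno.matrix
    n = g.shape[0]
    miss = np.isnan(g).sum(axis=0) / n
    freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    hwe_g = g[np.asarray(controls, dtype=bool)] if controls is not None else g
    hwe_p = np.ones(g.shape[1])
    for j in range(g.shape[1]):
        col = hwe_g[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        hwe_p[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                  int((col == 2).sum()))

    fail_miss = miss > max_missing
    fail_maf = ~(maf >= min_maf)  # NaN maf (all-missing) also fails
    fail_hwe = hwe_p <= hwe_p_min
    keep = ~(fail_miss | fail_maf | fail_hwe)
    report = pd.DataFrame({
        "filter": ["missingness", "maf", "hwe", "total_removed", "retained"],
        "count": [int(fail_miss.sum()), int(fail_maf.sum()),
                  int(fail_hwe.sum()), int((~keep).sum()), int(keep.sum())],
    })
    if not keep.any():
        binding = report.loc[report["count"].iloc[:3].idxmax(), "filter"]
        raise ValueError(
            f"no SNPs survive QC (binding filter: {binding}); "
            f"removals: missingness={fail_miss.sum()}, maf={fail_maf.sum()}, "
            f"hwe={fail_hwe.sum()}")
    filtered = GenotypeData(
        samples=geno.samples,
        variants=geno.variants.loc[keep].reset_index(drop=True),
        matrix=g[:, keep],
    )
    logger.info("SNP QC: %d of %d retained", filtered.n_snps, geno.n_snps)
    return filtered, report
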
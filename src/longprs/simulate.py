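"""Synthetic cohort generator with planted genetic architecture.

Generates LD-blocked genotypes (Gaussian copula: latent AR(1) normals per
block, thresholded to haplotype alleles at Hardy–Weinberg proportions),
binary case/control phenotypes from a liability-threshold model, and GWAS
summary statistics drawn around planted per-allele effects — so the full
clumping/thresholding/stratification pipeline is testable without external
data. Planted strata can give strongly-associated disease SNPs and weakly-
associated ones opposite-direction effects on the longevity phenotype,
reproducing the significance-band trade-off structure the analysis is
designed to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import SUMSTATS_COLUMNS
from .target import VARIANT_COLUMNS, GenotypeData

__all__ = [
    "LDBlockSpec",
    "Stratum",
    "PlantedArchitecture",
    "simulate_ld_genotypes",
    "simulate_phenotype",
    "simulate_sumstats",
    "write_fixture_bundle",
    "write_vcf",
    "tradeoff_cohort",
    "annotated_cohort",
]

#: non-strand-ambiguous (REF, ALT) pairs; palindromic A/T and C/G pairs are
#: never emitted so no planted signal is lost to ambiguity exclusion
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]

_SNP_SPACING = 1_000  # bp between SNPs inside a block
_BLOCK_GAP = 600_000  # bp between blocks; exceeds the 500 kb clump window


@dataclass
class LDBlockSpec:
    """Layout of the simulated genome: equal-size blocks of correlated SNPs."""

    n_snps_per_block: int = 1
    n_blocks: int = 100
    within_block_r: float = 0.9
    maf_range: tuple = (0.2, 0.4)

    def __post_init__(self):
        if self.n_snps_per_block < 1 or self.n_blocks < 1:
            raise ValueError("block counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_snps_per_block > 1 and not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1) for multi-SNP blocks")


@dataclass
class Stratum:
    """A disjoint SNP set with planted per-allele effects (log-odds)."""

    snp_ids: list
    disease_effect: float
    longevity_effect: float


@dataclass
class PlantedArchitecture:
    """Planted effect strata plus base-GWAS and liability parameters."""

    strata: list = field(default_factory=list)
    gwas_n: int = 100_000
    prevalence: float = 0.5

    def __post_init__(self):
        seen: set = set()
        for s in self.strata:
            ids = set(s.snp_ids)
            if ids & seen:
                raise ValueError("strata SNP sets must be disjoint")
            seen |= ids
            if not (np.isfinite(s.disease_effect) and np.isfinite(s.longevity_effect)):
                raise ValueError("planted effects must be finite")
        if self.gwas_n < 50:
            raise ValueError("gwas_n must be at least 50")

    def effect_map(self, which: str) -> dict:
        attr = {"disease": "disease_effect", "longevity": "longevity_effect"}[which]
        out: dict = {}
        for s in self.strata:
            for sid in s.snp_ids:
                out[sid] = getattr(s, attr)
        return out


def simulate_ld_genotypes(n_individuals: int, spec: LDBlockSpec,
                          seed: int) -> GenotypeData:
    """Simulate diploid hard-call genotypes with block-wise LD.

    Each haplotype's alleles within a block come from a latent AR(1)
    normal (lag-1 correlation ``within_block_r``) thresholded at the
    normal quantile of the SNP's allele frequency, giving exact HWE and
    tunable r². Blocks sit > 500 kb apart so a clump window never spans
    two blocks.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    m_per, n_blocks = spec.n_snps_per_block, spec.n_blocks
    m = m_per * n_blocks
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=m)
    thresh = sps.norm.ppf(maf)

    r = spec.within_block_r
    hap = np.empty((2 * n_individuals, m))
    for b in range(n_blocks):
        z = rng.standard_normal((2 * n_individuals, m_per))
        if m_per > 1 and r > 0:
            for k in range(1, m_per):
                z[:, k] = r * z[:, k - 1] + np.sqrt(1 - r * r) * z[:, k]
        hap[:, b * m_per:(b + 1) * m_per] = z
    alleles = (hap < thresh[None, :]).astype(np.int8)
    matrix = (alleles[0::2] + alleles[1::2]).astype(float)

    block_span = (m_per - 1) * _SNP_SPACING
    stride = block_span + _BLOCK_GAP
    pos = np.concatenate([
        1 + b * stride + np.arange(m_per) * _SNP_SPACING for b in range(n_blocks)
    ])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    emp_freq = matrix.mean(axis=0) / 2.0
    variants = pd.DataFrame({
        "snp_id": [f"rs{100000 + k}" for k in range(m)],
        "chrom": "1",
        "pos": pos,
        "counted_allele": alt,
        "other_allele": ref,
        "maf": np.minimum(emp_freq, 1.0 - emp_freq),
    })[VARIANT_COLUMNS]
    samples = np.array([f"ind{i:05d}" for i in range(n_individuals)])
    return GenotypeData(samples=samples, variants=variants, matrix=matrix)


def simulate_phenotype(geno: GenotypeData, arch: PlantedArchitecture,
                       seed: int) -> np.ndarray:
    """Binary longevity status from a liability-threshold model.

    Liability = sum of planted longevity effects × dosage + N(0, 1) noise;
    an individual is a case iff liability exceeds the empirical
    (1 − prevalence) quantile, so the case fraction matches prevalence.
    """
    if not 0 < arch.prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    effects = arch.effect_map("longevity")
    unknown = [s for s in effects if s not in set(geno.variants["snp_id"])]
    if unknown:
        raise ValueError(f"strata reference unknown SNPs: {unknown[:5]}")
    rng = np.random.default_rng(seed)
    liability = rng.standard_normal(geno.n_individuals)
    if effects:
        ids = list(effects)
        g = geno.dosages(ids)
        w = np.array([effects[s] for s in ids])
        liability = liability + g @ w
    cut = np.quantile(liability, 1.0 - arch.prevalence)
    return (liability > cut).astype(int)


def simulate_sumstats(geno: GenotypeData, arch: PlantedArchitecture,
                      seed: int, effect: str = "disease") -> pd.DataFrame:
    """Simulate base-GWAS summary statistics around planted effects.

    Per SNP, ``se = 1 / sqrt(2 * gwas_n * maf * (1 - maf))`` (the
    large-sample standard error of a per-allele log-odds estimate),
    ``beta ~ Normal(planted, se)``, and p is the two-sided normal tail of
    beta/se. SNPs outside every stratum have planted effect 0. ``effect``
    selects which planted effect ("disease" or "longevity") the simulated
    study measured.
    """
    rng = np.random.default_rng(seed)
    v = geno.variants
    maf = v["maf"].to_numpy(dtype=float)
    if np.any(maf <= 0):
        raise ValueError("zero MAF: cannot form a summary-statistic SE")
    planted = np.zeros(len(v))
    emap = arch.effect_map(effect)
    if emap:
        planted = v["snp_id"].map(emap).fillna(0.0).to_numpy()
    se = 1.0 / np.sqrt(2.0 * arch.gwas_n * maf * (1.0 - maf))
    beta = planted + se * rng.standard_normal(len(v))
    z = beta / se
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
    out = pd.DataFrame({
        "snp_id": v["snp_id"],
        "chrom": v["chrom"],
        "pos": v["pos"],
        "effect_allele": v["counted_allele"],
        "other_allele": v["other_allele"],
        "beta": beta,
        "se": se,
        "p": p,
        "n": float(arch.gwas_n),
    })
    return out[SUMSTATS_COLUMNS]


def write_vcf(path, geno: GenotypeData) -> None:
    """Write hard-call genotypes as minimal VCFv4.2 text."""
    v = geno.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(geno.n_snps):
            row = v.iloc[j]
            calls = [gt_codes.get(x, "./.") if not np.isnan(x) else "./."
                     for x in geno.matrix[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.other_allele}"
                     f"\t{row.counted_allele}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def write_fixture_bundle(outdir, geno: GenotypeData, phenotype=None,
                         sumstats: pd.DataFrame | None = None,
                         sets: dict | None = None, groups: dict | None = None,
                         regions: pd.DataFrame | None = None,
                         or_column: bool = False) -> dict:
    """Write the simulated objects as the package's on-disk formats.

    VCF for genotypes, tab-separated sumstats (header SNP CHR BP A1 A2
    BETA|OR SE P N), two-column phenotype, per-SNP BED intervals for
    annotation sets with a set→group mapping, and a chrom/start/end region
    file. Everything round-trips through the package readers.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict = {}
    vcf_path = os.path.join(outdir, "genotypes.vcf")
    write_vcf(vcf_path, geno)
    paths["vcf"] = vcf_path
    if phenotype is not None:
        p = os.path.join(outdir, "phenotype.txt")
        pd.DataFrame({"iid": geno.samples,
                      "status": np.asarray(phenotype, dtype=int)}
                     ).to_csv(p, sep="\t", header=False, index=False)
        paths["phenotype"] = p
    if sumstats is not None:
        p = os.path.join(outdir, "sumstats.tsv")
        out = sumstats.rename(columns={
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2", "beta": "BETA",
            "se": "SE", "p": "P", "n": "N"})
        if or_column:
            out["OR"] = np.exp(out.pop("BETA"))
            out = out[["SNP", "CHR", "BP", "A1", "A2", "OR", "SE", "P", "N"]]
        out.to_csv(p, sep="\t", index=False)
        paths["sumstats"] = p
    if sets is not None:
        bed = os.path.join(outdir, "annotations.bed")
        pos_by_id = geno.variants.set_index("snp_id")[["chrom", "pos"]]
        with open(bed, "w") as fh:
            for name, ids in sets.items():
                for sid in ids:
                    if sid in pos_by_id.index:
                        chrom, pos = pos_by_id.loc[sid]
                        fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\n")
        paths["annotations"] = bed
        gmap = os.path.join(outdir, "set_groups.tsv")
        with open(gmap, "w") as fh:
            for name in sets:
                fh.write(f"{name}\t{(groups or {}).get(name, name)}\n")
        paths["set_groups"] = gmap
    if regions is not None:
        p = os.path.join(outdir, "regions.tsv")
        regions.to_csv(p, sep="\t", index=False,
                       columns=["chrom", "start", "end"])
        paths["regions"] = p
    return paths


# ---------------------------------------------------------------------------
# Ready-made study architectures
# ---------------------------------------------------------------------------

#: planted disease z-score bands for the significance-stratified trade-off
#: architecture: (z target, SNP count). Strong bands carry the deleterious
#: longevity effect, weak bands the protective one. Placement and counts
#: were chosen so each p-value bin's expected composition is dominated by
#: its own side of the 1e-5 boundary despite the unit-variance noise on
#: realized z-scores (see docs/methods.md).
STRONG_BANDS = ((6.4, 70), (6.0, 570), (5.35, 240))
WEAK_BANDS = ((4.0, 170), (3.4, 530), (2.6, 650), (2.25, 170))


def tradeoff_cohort(n_individuals: int = 4000, seed: int = 0,
                    strong_effect: float = -0.3, weak_effect: float = 0.15,
                    gwas_n: int = 100_000, n_null: int = 100,
                    strong_bands=STRONG_BANDS, weak_bands=WEAK_BANDS):
    """Cohort with the bidirectional significance-band trade-off planted.

    Disease-GWAS-strong SNPs (p spanning genome-wide significance down to
    1e-5) harm the longevity phenotype (per-allele log-odds
    ``strong_effect``); sub-significant SNPs (1e-5 < p <= 0.05) help
    (``weak_effect``). Returns (genotypes, phenotype, disease sumstats,
    architecture).
    """
    rng = np.random.default_rng(seed)
    n_strong = sum(c for _, c in strong_bands)
    n_weak = sum(c for _, c in weak_bands)
    m = n_strong + n_weak + n_null
    spec = LDBlockSpec(n_snps_per_block=1, n_blocks=m,
                       within_block_r=0.0, maf_range=(0.2, 0.4))
    geno = simulate_ld_genotypes(n_individuals, spec, seed=int(rng.integers(2**31)))
    ids = geno.variants["snp_id"].to_numpy()
    perm = rng.permutation(m)
    maf = geno.variants["maf"].to_numpy()
    med_se = 1.0 / np.sqrt(2.0 * gwas_n * np.median(maf) * (1 - np.median(maf)))

    strata, k = [], 0
    for z_mid, count in strong_bands:
        sel = ids[perm[k:k + count]]
        k += count
        strata.append(Stratum(list(sel), z_mid * med_se, strong_effect))
    for z_mid, count in weak_bands:
        sel = ids[perm[k:k + count]]
        k += count
        strata.append(Stratum(list(sel), z_mid * med_se, weak_effect))
    arch = PlantedArchitecture(strata=strata, gwas_n=gwas_n, prevalence=0.5)
    pheno = simulate_phenotype(geno, arch, seed=int(rng.integers(2**31)))
    ss = simulate_sumstats(geno, arch, seed=int(rng.integers(2**31)))
    return geno, pheno, ss, arch


def annotated_cohort(n_individuals: int = 4000, seed: int = 0,
                     n_per_set: int = 120, effect: float = 0.2,
                     disease_z: float = 4.0, gwas_n: int = 100_000,
                     n_null: int = 100):
    """Cohort with two annotation sets of opposite planted longevity effect.

    Set "setA" SNPs raise the chance of longevity (+``effect`` per risk
    allele), set "setB" SNPs lower it; both carry positive disease effects
    (z ≈ ``disease_z``) so the stratified score weights are informative.
    Returns (genotypes, phenotype, sumstats, sets, groups, architecture).
    """
    rng = np.random.default_rng(seed)
    m = 2 * n_per_set + n_null
    spec = LDBlockSpec(n_snps_per_block=1, n_blocks=m,
                       within_block_r=0.0, maf_range=(0.2, 0.4))
    geno = simulate_ld_genotypes(n_individuals, spec, seed=int(rng.integers(2**31)))
    ids = geno.variants["snp_id"].to_numpy()
    perm = rng.permutation(m)
    maf = geno.variants["maf"].to_numpy()
    med_se = 1.0 / np.sqrt(2.0 * gwas_n * np.median(maf) * (1 - np.median(maf)))
    set_a = list(ids[perm[:n_per_set]])
    set_b = list(ids[perm[n_per_set:2 * n_per_set]])
    arch = PlantedArchitecture(strata=[
        Stratum(set_a, disease_z * med_se, effect),
        Stratum(set_b, disease_z * med_se, -effect),
    ], gwas_n=gwas_n, prevalence=0.5)
    pheno = simulate_phenotype(geno, arch, seed=int(rng.integers(2**31)))
    ss = simulate_sumstats(geno, arch, seed=int(rng.integers(2**31)))
    sets = {"setA": set(set_a), "setB": set(set_b)}
    groups = {"setA": "groupA", "setB": "groupB"}
    return geno, pheno, ss, sets, groups, arch
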
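"""Synthetic cohort generator: calibration, determinism, round-trips."""

import numpy as np
import pytest
from scipy import stats as sps

from longprs import harmonize, target
from longprs.simulate import (LDBlockSpec, PlantedArchitecture, Stratum,
                              simulate_ld_genotypes, simulate_phenotype,
                              simulate_sumstats, write_fixture_bundle)
from longprs.stats import fit_logistic


def test_single_snp_allele_frequency_matches_maf():
    spec = LDBlockSpec(n_snps_per_block=1, n_blocks=1, within_block_r=0.0,
                       maf_range=(0.3, 0.3))
    geno = simulate_ld_genotypes(1000, spec, seed=4)
    freq = geno.matrix.mean() / 2.0
    assert abs(freq - 0.3) < 0.03


def test_adjacent_snps_in_block_are_correlated():
    spec = LDBlockSpec(n_snps_per_block=2, n_blocks=40, within_block_r=0.9,
                       maf_range=(0.2, 0.4))
    geno = simulate_ld_genotypes(10_000, spec, seed=5)
    r2s = []
    for b in range(40):
        g1, g2 = geno.matrix[:, 2 * b], geno.matrix[:, 2 * b + 1]
        r2s.append(np.corrcoef(g1, g2)[0, 1] ** 2)
    # dichotomizing the latent AR(1) at MAF 0.2-0.4 attenuates r = 0.9 to
    # genotype r^2 ~ 0.46; band frozen from a 20-replicate oracle
    assert 0.42 < np.mean(r2s) < 0.52


def test_cross_block_snps_are_uncorrelated():
    spec = LDBlockSpec(n_snps_per_block=1, n_blocks=20, within_block_r=0.0,
                       maf_range=(0.2, 0.4))
    geno = simulate_ld_genotypes(10_000, spec, seed=6)
    rs = []
    for a in range(0, 20, 2):
        rs.append(abs(np.corrcoef(geno.matrix[:, a],
                                  geno.matrix[:, a + 1])[0, 1]))
    assert np.mean(rs) < 0.05


def test_positions_increase_and_blocks_are_separated():
    spec = LDBlockSpec(n_snps_per_block=3, n_blocks=4, within_block_r=0.5,
                       maf_range=(0.2, 0.4))
    geno = simulate_ld_genotypes(10, spec, seed=0)
    pos = geno.variants["pos"].to_numpy()
    assert np.all(np.diff(pos) > 0)
    block_gaps = pos[3::3] - pos[2::3][:len(pos[3::3])]  # next block start - prev block end
    assert np.all(block_gaps > 500_000)


def test_generator_is_deterministic_in_seed():
    spec = LDBlockSpec(n_snps_per_block=2, n_blocks=3, maf_range=(0.2, 0.4))
    a = simulate_ld_genotypes(50, spec, seed=9)
    b = simulate_ld_genotypes(50, spec, seed=9)
    assert np.array_equal(a.matrix, b.matrix)
    assert a.variants.equals(b.variants)


@pytest.mark.parametrize("bad", [
    dict(n_snps_per_block=0),
    dict(maf_range=(0.0, 0.3)),
    dict(maf_range=(0.4, 0.2)),
    dict(n_snps_per_block=2, within_block_r=1.0),
])
def test_invalid_block_specs_rejected(bad):
    with pytest.raises(ValueError):
        LDBlockSpec(**bad)


def test_genotype_entries_are_hard_calls(small_cohort):
    geno, *_ = small_cohort
    assert set(np.unique(geno.matrix)) <= {0.0, 1.0, 2.0}


class TestPhenotype:
    def test_null_architecture_hits_prevalence(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=2,
                           maf_range=(0.2, 0.4))
        geno = simulate_ld_genotypes(10_000, spec, seed=1)
        arch = PlantedArchitecture(strata=[], gwas_n=1000, prevalence=0.5)
        y = simulate_phenotype(geno, arch, seed=2)
        assert abs(y.mean() - 0.5) < 0.02

    def test_planted_effect_recovered_by_logistic_refit(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=5,
                           maf_range=(0.3, 0.4))
        geno = simulate_ld_genotypes(4000, spec, seed=3)
        sid = geno.variants["snp_id"].iloc[0]
        arch = PlantedArchitecture(
            strata=[Stratum([sid], 0.1, 1.0)], gwas_n=1000)
        y = simulate_phenotype(geno, arch, seed=4)
        fit = fit_logistic(y, geno.dosages([sid])[:, 0])
        assert np.exp(fit.coef) > 1.0 and fit.p < 1e-4

    def test_degenerate_prevalence_rejected(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=1,
                           maf_range=(0.3, 0.3))
        geno = simulate_ld_genotypes(10, spec, seed=0)
        with pytest.raises(ValueError):
            simulate_phenotype(
                geno, PlantedArchitecture(prevalence=0.0), seed=0)

    def test_unknown_stratum_snp_rejected(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=1,
                           maf_range=(0.3, 0.3))
        geno = simulate_ld_genotypes(10, spec, seed=0)
        arch = PlantedArchitecture(strata=[Stratum(["nope"], 0.0, 0.1)])
        with pytest.raises(ValueError, match="nope"):
            simulate_phenotype(geno, arch, seed=0)

    def test_doubling_effect_does_not_reduce_mean_refit_or(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=1,
                           maf_range=(0.3, 0.3))
        ors = {0.3: [], 0.6: []}
        for rep in range(20):
            geno = simulate_ld_genotypes(2000, spec, seed=100 + rep)
            sid = geno.variants["snp_id"].iloc[0]
            for eff in ors:
                arch = PlantedArchitecture(
                    strata=[Stratum([sid], 0.0, eff)], gwas_n=1000)
                y = simulate_phenotype(geno, arch, seed=200 + rep)
                fit = fit_logistic(y, geno.dosages([sid])[:, 0])
                ors[eff].append(np.exp(fit.coef))
        assert np.mean(ors[0.6]) >= np.mean(ors[0.3])


class TestSumstats:
    def test_null_pvalues_are_uniform(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=1000,
                           maf_range=(0.2, 0.4))
        geno = simulate_ld_genotypes(200, spec, seed=7)
        arch = PlantedArchitecture(strata=[], gwas_n=100_000)
        ss = simulate_sumstats(geno, arch, seed=8)
        ks = sps.kstest(ss["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_p_is_two_sided_normal_tail_of_z(self, small_cohort):
        _, _, ss, _ = small_cohort
        z = ss["beta"] / ss["se"]
        np.testing.assert_allclose(
            ss["p"], np.clip(2 * sps.norm.sf(np.abs(z)),
                             np.nextafter(0, 1), 1), rtol=1e-12)
        # spot value: z = 1.96 corresponds to p just under 0.05
        assert 2 * sps.norm.sf(1.96) == pytest.approx(0.05, abs=2e-4)

    def test_larger_planted_effect_gives_smaller_p(self):
        spec = LDBlockSpec(n_snps_per_block=1, n_blocks=200,
                           maf_range=(0.3, 0.3))
        geno = simulate_ld_genotypes(200, spec, seed=9)
        ids = list(geno.variants["snp_id"])
        arch = PlantedArchitecture(
            strata=[Stratum(ids[:100], 0.4, 0.0),
                    Stratum(ids[100:], 0.02, 0.0)],
            gwas_n=50_000)
        ss = simulate_sumstats(geno, arch, seed=10).set_index("snp_id")
        assert (ss.loc[ids[:100], "p"].median()
                < ss.loc[ids[100:], "p"].median())

    def test_overlapping_strata_rejected(self):
        with pytest.raises(ValueError):
            PlantedArchitecture(strata=[Stratum(["a"], 0.1, 0.0),
                                        Stratum(["a"], 0.2, 0.0)])


class TestFixtureBundle:
    def test_vcf_round_trip_is_lossless(self, small_cohort, tmp_path):
        geno, pheno, ss, _ = small_cohort
        geno.matrix = geno.matrix.copy()
        geno.matrix[0, 0] = np.nan  # exercise missing-call encoding
        paths = write_fixture_bundle(tmp_path, geno, pheno, ss)
        back = target.read_genotypes(paths["vcf"])
        assert np.array_equal(geno.matrix, back.matrix, equal_nan=True)
        cols = ["snp_id", "chrom", "pos", "counted_allele", "other_allele"]
        assert back.variants[cols].equals(geno.variants[cols])
        y = target.read_phenotype(paths["phenotype"])
        assert np.array_equal(y.reindex(geno.samples).to_numpy(), pheno)

    def test_or_column_reader_recovers_beta(self, small_cohort, tmp_path):
        geno, pheno, ss, _ = small_cohort
        paths = write_fixture_bundle(tmp_path, geno, sumstats=ss,
                                     or_column=True)
        back = harmonize.read_sumstats(paths["sumstats"])
        np.testing.assert_allclose(back["beta"], ss["beta"], rtol=1e-12)

    def test_empty_annotation_set_round_trips(self, small_cohort, tmp_path):
        geno, *_ = small_cohort
        ids = set(geno.variants["snp_id"][:3])
        paths = write_fixture_bundle(tmp_path, geno,
                                     sets={"full": ids, "empty": set()},
                                     groups={"full": "g", "empty": "g"})
        from longprs.stratify import read_bed_sets, snps_in_sets
        bed, groups = read_bed_sets(paths["annotations"], paths["set_groups"])
        sets = snps_in_sets(geno.variants, bed, groups)
        assert sets.sets["full"] == ids
        assert "empty" not in sets.sets or sets.sets["empty"] == set()
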
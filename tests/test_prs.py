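"""Clumping, scoring, and the p-value threshold scan."""

import numpy as np
import pandas as pd
import pytest

from longprs.prs import (DEFAULT_LADDER, greedy_clump, pairwise_r2, score_prs,
                         threshold_scan)
from longprs.simulate import LDBlockSpec, simulate_ld_genotypes
from longprs.target import GenotypeData


class TestPairwiseR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0], float)
        assert pairwise_r2(g, g) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        g = np.array([0, 1, 2, 1, 0], float)
        assert pairwise_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        g1 = rng.binomial(2, 0.3, 10_000).astype(float)
        g2 = rng.binomial(2, 0.3, 10_000).astype(float)
        assert pairwise_r2(g1, g2) < 0.01

    def test_missing_entries_pairwise_deleted(self):
        g1 = np.array([0, 1, 2, np.nan, 0], float)
        g2 = np.array([0, 1, 2, 2, np.nan], float)
        assert pairwise_r2(g1, g2) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_r2(np.ones(5), np.arange(5, dtype=float))


def _geno_from(matrix, chrom, pos):
    m = np.asarray(matrix, float)
    variants = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m.shape[1])],
        "chrom": chrom, "pos": pos,
        "counted_allele": "A", "other_allele": "G",
        "maf": np.clip(m.mean(0) / 2, 0.01, 0.5)})
    return GenotypeData(samples=np.array([f"i{k}" for k in range(m.shape[0])]),
                        variants=variants, matrix=m)


def _ss_for(geno, p):
    v = geno.variants
    return pd.DataFrame({
        "snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": v["counted_allele"], "other_allele": v["other_allele"],
        "beta": 0.1, "se": 0.02, "p": p, "n": 1000.0})


def brute_clump(ss, geno, r2_threshold=0.1, window_bp=500_000):
    """Re-scanning oracle: recompute eligibility from scratch each round."""
    tab = ss[ss["snp_id"].isin(geno.variants["snp_id"])]
    tab = tab.sort_values(["p", "chrom", "pos"], kind="mergesort")
    remaining = list(tab.itertuples())
    index_snps, members = [], {}
    while remaining:
        best = min(remaining, key=lambda r: (r.p, r.chrom, r.pos))
        remaining = [r for r in remaining if r.snp_id != best.snp_id]
        index_snps.append(best.snp_id)
        members[best.snp_id] = []
        g_best = geno.dosages([best.snp_id])[:, 0]
        still = []
        for r in remaining:
            if (r.chrom == best.chrom
                    and abs(r.pos - best.pos) <= window_bp):
                try:
                    r2 = pairwise_r2(g_best, geno.dosages([r.snp_id])[:, 0])
                except ValueError:
                    r2 = 0.0
                if r2 > r2_threshold:
                    members[best.snp_id].append(r.snp_id)
                    continue
            still.append(r)
        remaining = still
    return index_snps, members


class TestGreedyClump:
    def test_single_snp_is_its_own_index(self):
        geno = _geno_from([[0], [1], [2], [1]], "1", [100])
        ss = _ss_for(geno, [1e-4])
        res = greedy_clump(ss, geno)
        assert res.index_snps == ["s0"] and res.members == {"s0": []}

    def test_correlated_neighbour_clumps_under_best_p(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]], float)
        geno = _geno_from(g, "1", [100, 10_100])
        ss = _ss_for(geno, [1e-8, 1e-4])
        res = greedy_clump(ss, geno)
        assert res.index_snps == ["s0"]
        assert res.members["s0"] == ["s1"]

    def test_window_limits_clumping(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]], float)
        geno = _geno_from(g, "1", [100, 600_100])  # beyond 500 kb
        ss = _ss_for(geno, [1e-8, 1e-4])
        res = greedy_clump(ss, geno)
        assert res.index_snps == ["s0", "s1"]

    def test_matches_rescanning_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            m = rng.integers(2, 13)
            n = 60
            block = rng.integers(1, m + 1)
            spec = LDBlockSpec(n_snps_per_block=block,
                               n_blocks=int(np.ceil(m / block)),
                               within_block_r=rng.uniform(0, 0.98),
                               maf_range=(0.2, 0.5))
            geno = simulate_ld_genotypes(n, spec, seed=int(rng.integers(2**31)))
            geno = geno.subset(list(geno.variants["snp_id"][:m]))
            ss = _ss_for(geno, rng.uniform(0, 1, m))
            try:
                res = greedy_clump(ss, geno)
            except ValueError:
                continue
            oracle_idx, oracle_members = brute_clump(ss, geno)
            assert res.index_snps == oracle_idx
            assert {k: sorted(v) for k, v in res.members.items()} == \
                {k: sorted(v) for k, v in oracle_members.items()}

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(22)
        spec = LDBlockSpec(n_snps_per_block=5, n_blocks=2,
                           within_block_r=0.8, maf_range=(0.2, 0.5))
        geno = simulate_ld_genotypes(80, spec, seed=7)
        ss = _ss_for(geno, rng.uniform(0, 1, geno.n_snps))
        a = greedy_clump(ss, geno)
        b = greedy_clump(ss.sample(frac=1, random_state=1), geno)
        assert a.index_snps == b.index_snps and a.members == b.members


class TestScorePrs:
    def test_direct_formula_single_snp(self):
        geno = _geno_from([[2]], "1", [100])
        ss = _ss_for(geno, [0.5])
        ss["beta"] = 0.5
        res = score_prs(geno, ss, ["s0"])
        assert res.scores[0] == pytest.approx(0.5)  # (0.5*2)/(2*1)

    def test_direct_formula_two_snps(self):
        geno = _geno_from([[1, 2]], "1", [100, 200])
        ss = _ss_for(geno, [0.5, 0.5])
        ss["beta"] = [0.1, -0.2]
        res = score_prs(geno, ss, ["s0", "s1"])
        assert res.scores[0] == pytest.approx((0.1 - 0.4) / 4)

    def test_missing_genotype_drops_from_numerator_and_mj(self):
        geno = _geno_from([[1, np.nan]], "1", [100, 200])
        ss = _ss_for(geno, [0.5, 0.5])
        ss["beta"] = [0.1, -0.2]
        res = score_prs(geno, ss, ["s0", "s1"])
        assert res.scores[0] == pytest.approx(0.05)  # (0.1*1)/(2*1)

    def test_all_missing_individual_gets_nan(self):
        geno = _geno_from([[np.nan], [1.0]], "1", [100])
        ss = _ss_for(geno, [0.5])
        res = score_prs(geno, ss, ["s0"])
        assert np.isnan(res.scores[0]) and np.isfinite(res.scores[1])

    def test_linear_in_beta(self, small_cohort):
        geno, _, ss, _ = small_cohort
        ids = list(ss["snp_id"][:10])
        base = score_prs(geno, ss, ids).scores
        ss2 = ss.copy()
        ss2["beta"] = 2 * ss2["beta"]
        np.testing.assert_allclose(score_prs(geno, ss2, ids).scores, 2 * base,
                                   rtol=1e-12)

    def test_snps_mode_is_constant_rescale(self, small_cohort):
        geno, _, ss, _ = small_cohort
        ids = list(ss["snp_id"][:10])
        a = score_prs(geno, ss, ids, mj_mode="alleles").scores
        b = score_prs(geno, ss, ids, mj_mode="snps").scores
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_empty_set_rejected(self, small_cohort):
        geno, _, ss, _ = small_cohort
        with pytest.raises(ValueError):
            score_prs(geno, ss, [])


class TestThresholdScan:
    def test_default_ladder_values(self):
        assert DEFAULT_LADDER == (5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3,
                                  5e-2, 5e-1, 1.0)

    def test_n_snps_nondecreasing_and_best_has_min_p(self, small_cohort):
        geno, pheno, ss, _ = small_cohort
        clump = greedy_clump(ss, geno)
        scan = threshold_scan(ss, geno, pheno, clump)
        assert (np.diff(scan["n_snps"]) >= 0).all()
        assert scan.loc[scan["best"], "p"].iloc[0] == scan["p"].min()

    def test_tied_best_p_takes_smaller_threshold(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        geno = _geno_from(g, "1", [100, 600_100])
        ss = _ss_for(geno, [1e-9, 1e-9])  # both below every cutoff
        y = rng.integers(0, 2, 200)
        clump = greedy_clump(ss, geno)
        scan = threshold_scan(ss, geno, y, clump)
        # identical SNP set at every threshold -> identical p; first row wins
        assert scan.loc[scan["best"], "threshold"].iloc[0] == 5e-8

    def test_members_never_enter_scores(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]], float)
        geno = _geno_from(g, "1", [100, 10_100])
        ss = _ss_for(geno, [1e-8, 1e-4])
        ss["beta"] = [0.3, 99.0]  # member beta must be irrelevant
        clump = greedy_clump(ss, geno)
        assert clump.members["s0"] == ["s1"]
        res = score_prs(geno, ss, clump.index_snps)
        np.testing.assert_allclose(res.scores, 0.3 * g[:, 0] / 2)

    def test_constant_phenotype_rejected(self, small_cohort):
        geno, _, ss, _ = small_cohort
        clump = greedy_clump(ss, geno)
        with pytest.raises(ValueError):
            threshold_scan(ss, geno, np.ones(geno.n_individuals), clump)
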
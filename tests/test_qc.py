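"""Quality-control cascade: exactness of the HWE test, filter behaviour,
report reconciliation and the genomic inflation diagnostic."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagwas.qc import (
    QCParams,
    filter_heterozygosity,
    filter_hwe,
    filter_missingness,
    filter_relatedness,
    genomic_inflation,
    hwe_exact_test,
    ld_thin,
    pca_ancestry_filter,
    pihat_matrix,
    run_qc,
)
from gagwas.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Exact-rational enumeration oracle for the HWE test."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    if na == 0 or na == 2 * n:
        return Fraction(1)
    weights = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        h1 = (na - h) // 2
        h2 = n - h1 - h
        weights[h] = math.comb(n, h) * math.comb(n - h, h1) * 2**h
    total = sum(weights.values())
    w_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)


class TestHwe:
    @pytest.mark.parametrize(
        "counts,expected",
        [((0, 2, 0), 1.0), ((1, 0, 1), 1 / 3), ((5, 0, 0), 1.0), ((0, 0, 9), 1.0)],
    )
    def test_small_tables(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_exact_rational_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            float(hwe_oracle(a, b, c)), abs=1e-10
        )

    def test_extreme_deviation_is_significant(self):
        # all heterozygous missing despite intermediate frequency
        assert hwe_exact_test(50, 0, 50) < 1e-6


class TestMissingness:
    def test_four_percent_snp_removed_at_three_percent(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (100, 50)).astype(np.int8)
        calls[:4, 0] = -1  # missing in 4 of 100 samples (4%)
        g = make_genotypes(calls)
        g2, rep = filter_missingness(g, QCParams())
        assert "s0" not in set(g2.snp_ids)
        assert g2.n_snps == 49 and g2.n_samples == 100

    def test_fully_observed_matrix_untouched(self, null_cohort):
        g, _ = null_cohort
        g2, rep = filter_missingness(g, QCParams())
        assert g2.n_samples == g.n_samples and g2.n_snps == g.n_snps

    def test_planted_missing_sample_removed(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (40, 50)).astype(np.int8)
        calls[7, :3] = -1  # 6% missing row
        g = make_genotypes(calls)
        g2, _ = filter_missingness(g, QCParams())
        assert set(g.sample_ids) - set(g2.sample_ids) == {"I7"}

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, (50, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = -1
        g = make_genotypes(calls)
        g1, _ = filter_missingness(g, QCParams())
        g2, rep = filter_missingness(g1, QCParams())
        assert g2.n_samples == g1.n_samples and g2.n_snps == g1.n_snps


class TestHeterozygosityAndRelatedness:
    def test_zero_sd_removes_none(self):
        calls = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (6, 5))[:, :5]
        g = make_genotypes(calls)
        g2, _ = filter_heterozygosity(g, QCParams())
        assert g2.n_samples == g.n_samples

    def test_duplicate_pair_loses_exactly_one_member_seeded(self):
        cfg = SimConfig(n_samples=40, n_chromosomes=4, blocks_per_chr=10,
                        snps_per_block=10, founder_haplotypes_per_block=64,
                        n_duplicates=1, seed=21)
        g = simulate_genotypes(cfg)
        ph = pihat_matrix(g)
        assert ph[0, g.n_samples - 1] > 0.9  # duplicate of sample 0
        removed = []
        for _ in range(2):
            g2, rep = filter_relatedness(g, QCParams(seed=77))
            gone = set(g.sample_ids) - set(g2.sample_ids)
            # exactly one member of the duplicate pair goes (other flagged
            # pairs, if any, are estimator noise at this SNP count)
            assert len(gone & {"S000000", "DUP0000"}) == 1
            removed.append(gone)
        assert removed[0] == removed[1]  # seed fixes the choice

    def test_unrelated_samples_have_low_pihat(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 0.5, 2000)
        calls = rng.binomial(2, f, size=(40, 2000)).astype(np.int8)
        g = make_genotypes(calls, chrom=["1"] * 2000,
                           bp=list(range(1, 2001)))
        ph = pihat_matrix(g)
        iu = np.triu_indices(40, 1)
        assert np.median(ph[iu]) < 0.05
        assert np.quantile(ph[iu], 0.95) < 0.15


class TestPca:
    def test_shifted_cluster_removed_and_only_it(self):
        cfg = SimConfig(n_samples=80, n_chromosomes=2, blocks_per_chr=8,
                        snps_per_block=8, founder_haplotypes_per_block=64,
                        shifted_cluster=(10, 0.35), seed=9)
        g = simulate_genotypes(cfg)
        ref = simulate_genotypes(
            SimConfig(n_samples=60, n_chromosomes=2, blocks_per_chr=8,
                      snps_per_block=8, founder_haplotypes_per_block=64, seed=9)
        )
        g2, rep = pca_ancestry_filter(g, ref, QCParams())
        gone = set(g.sample_ids) - set(g2.sample_ids)
        assert gone == {f"SHIFT{i:04d}" for i in range(10)}

    def test_absent_panel_skips_with_warning(self, null_cohort, caplog):
        g, _ = null_cohort
        with caplog.at_level("WARNING"):
            g2, rep = pca_ancestry_filter(g, None, QCParams())
        assert g2.n_samples == g.n_samples
        assert "skipped" in rep.stages[0].reason


class TestLambdaAndCascade:
    def test_lambda_definition_and_scale(self):
        chi2 = np.full(100, 0.4549)
        assert genomic_inflation(chi2) == pytest.approx(1.0, abs=1e-3)
        assert genomic_inflation(2 * chi2) == pytest.approx(2.0, abs=2e-3)

    def test_lambda_maf_filter(self):
        chi2 = np.concatenate([np.full(50, 0.4549), np.full(50, 50.0)])
        maf = np.concatenate([np.full(50, 0.3), np.full(50, 0.01)])
        assert genomic_inflation(chi2, maf=maf) == pytest.approx(1.0, abs=1e-3)

    def test_full_cascade_reconciles_counts(self):
        cfg = SimConfig(n_samples=60, n_chromosomes=2, blocks_per_chr=5,
                        snps_per_block=8, founder_haplotypes_per_block=16,
                        missing_rate=0.02, n_duplicates=2, seed=4)
        g = simulate_genotypes(cfg)
        g2, rep = run_qc(g, QCParams(seed=1))
        df = rep.to_frame()
        for _, row in df.iterrows():
            assert row.samples_in - row.n_removed_samples == row.samples_out
            assert row.snps_in - row.n_removed_snps == row.snps_out
        # stages chain: outputs feed the next stage
        for prev, nxt in zip(df.itertuples(), df.iloc[1:].itertuples()):
            assert prev.samples_out == nxt.samples_in
            assert prev.snps_out == nxt.snps_in

    def test_ld_thin_keeps_one_per_correlated_pair(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, (100, 1)).astype(np.int8)
        calls = np.hstack([base, base, rng.integers(0, 3, (100, 1)).astype(np.int8)])
        g = make_genotypes(calls)
        keep = ld_thin(g, 0.2, 50)
        assert keep.tolist() == [True, False, True]

    def test_hwe_filter_removes_planted_violation(self):
        rng = np.random.default_rng(0)
        f = 0.4
        hw = rng.binomial(2, f, size=(300, 1)).astype(np.int8)
        bad = np.where(rng.random((300, 1)) < 0.5, 0, 2).astype(np.int8)
        g = make_genotypes(np.hstack([hw, bad]))
        g2, _ = filter_hwe(g, QCParams())
        assert list(g2.snp_ids) == ["s0"]
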
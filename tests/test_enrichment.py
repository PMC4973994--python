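"""Interval preparation, hit counting, matched sampling and the permutation
enrichment test (with a small exhaustive oracle)."""

import math

import numpy as np
import pandas as pd
import pytest

from gagwas.clumping import Clump
from gagwas.datatypes import GeneSetCollection
from gagwas.enrichment import (
    EnrichmentParams,
    Interval,
    _sample_matched_batch,
    _SnpIndex,
    enrichment_test,
    interval_hits,
    prepare_intervals,
    sample_matched_interval,
)


def snp_map(n=40, spacing=10_000, chrom="1"):
    return pd.DataFrame({
        "snp": [f"s{i}" for i in range(n)],
        "chrom": chrom,
        "bp": 1 + np.arange(n) * spacing,
    })


def gene_map(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


PARAMS = EnrichmentParams(n_permutations=2_000, seed=5)


class TestPrepareIntervals:
    def test_geneless_interval_dropped(self):
        gm = gene_map([("g1", "1", 300_000, 310_000)])
        cl = [Clump("a", "1", 1_000, 1e-5, ["a"], (1_000, 5_000)),      # 295 kb away
              Clump("b", "1", 290_000, 1e-4, ["b"], (285_000, 295_000))]
        ivs = prepare_intervals(cl, gm, snp_map(), PARAMS)
        assert [iv.source for iv in ivs] == [("b",)]

    def test_overlapping_clumps_merge(self):
        gm = gene_map([("g1", "1", 1, 400_000)])
        cl = [Clump("a", "1", 10_000, 1e-6, ["a"], (10_000, 50_000)),
              Clump("b", "1", 40_000, 1e-5, ["b"], (40_000, 90_000)),
              Clump("c", "1", 200_000, 1e-4, ["c"], (200_000, 210_000))]
        ivs = prepare_intervals(cl, gm, snp_map(), PARAMS)
        assert len(ivs) == 2
        assert ivs[0].start == 10_000 and ivs[0].end == 90_000
        assert ivs[0].source == ("a", "b")
        # map SNPs (bp 1, 10001, ..., 390001) recounted over the merged span:
        # 10001..80001 inclusive -> 8
        assert ivs[0].n_snps == 8

    def test_disjoint_intervals_pass_through(self):
        gm = gene_map([("g1", "1", 1, 400_000)])
        cl = [Clump("a", "1", 10_000, 1e-6, ["a"], (10_000, 20_000)),
              Clump("b", "1", 200_000, 1e-5, ["b"], (200_000, 220_000))]
        assert len(prepare_intervals(cl, gm, snp_map(), PARAMS)) == 2

    def test_singleton_span_gets_flank(self):
        gm = gene_map([("g1", "1", 1, 400_000)])
        cl = [Clump("a", "1", 50_000, 1e-6, ["a"], (50_000, 50_000))]
        iv = prepare_intervals(cl, gm, snp_map(), PARAMS)[0]
        assert (iv.start, iv.end) == (49_000, 51_000)

    def test_top_k_limits_input(self):
        gm = gene_map([("g1", "1", 1, 400_000)])
        cl = [Clump(f"c{i}", "1", 10_000 + 30_000 * i, 1e-6 * (i + 1),
                    [f"c{i}"], (10_000 + 30_000 * i, 12_000 + 30_000 * i))
              for i in range(5)]
        p = EnrichmentParams(n_permutations=2_000, top_k_clumps=2, seed=1)
        assert len(prepare_intervals(cl, gm, snp_map(), p)) == 2


class TestIntervalHits:
    IV = [Interval("1", 30_000, 40_000, 2)]

    def test_gene_inside_interval_hits(self):
        t, gh, names = interval_hits(self.IV, ["g"], gene_map([("g", "1", 32_000, 33_000)]), PARAMS)
        assert (t, gh, names) == (1, 1, ["g"])

    def test_boundary_exactly_at_offset_hits(self):
        gm = gene_map([("g", "1", 1_000, 5_000)])  # ends 25,000 bp before start
        assert interval_hits(self.IV, ["g"], gm, PARAMS)[0] == 1

    def test_one_bp_beyond_offset_misses(self):
        gm = gene_map([("g", "1", 1_000, 4_999)])
        assert interval_hits(self.IV, ["g"], gm, PARAMS)[0] == 0

    def test_absent_genes_ignored(self):
        gm = gene_map([("g", "1", 32_000, 33_000)])
        t, gh, _ = interval_hits(self.IV, ["g", "phantom"], gm, PARAMS)
        assert (t, gh) == (1, 1)

    def test_offset_monotonicity(self):
        gm = gene_map([("g", "1", 70_000, 75_000), ("h", "1", 90_000, 95_000)])
        ts = []
        for off in (0, 25_000, 50_000, 60_000):
            p = EnrichmentParams(gene_offset=off, n_permutations=2_000, seed=1)
            ts.append(interval_hits(self.IV, ["g", "h"], gm, p)[0])
        assert ts == sorted(ts)


class TestMatchedSampling:
    def test_snp_count_within_band(self):
        sm = snp_map(60)
        tpl = Interval("1", 1, 90_001, 10)
        si = _SnpIndex(sm)
        cc, ss, ee = _sample_matched_batch(tpl, si, 3_000, PARAMS,
                                           np.random.default_rng(0))
        counts = np.array([si.count_in("1", s, e) for s, e in zip(ss, ee)])
        assert counts.min() >= math.ceil(0.9 * 10)
        assert counts.max() <= math.floor(1.1 * 10)

    def test_identical_seed_identical_sequence(self):
        sm = snp_map(60)
        tpl = Interval("1", 1, 50_001, 6)
        a = [sample_matched_interval(tpl, sm, PARAMS, np.random.default_rng(3))
             for _ in range(3)]
        b = [sample_matched_interval(tpl, sm, PARAMS, np.random.default_rng(3))
             for _ in range(3)]
        assert a == b

    def test_single_snp_template(self):
        tpl = Interval("1", 5_000, 5_000, 1)
        iv = sample_matched_interval(tpl, snp_map(30), PARAMS,
                                     np.random.default_rng(2))
        assert iv.n_snps == 1 and iv.start == iv.end

    def test_interval_stays_on_one_chromosome(self):
        sm = pd.concat([snp_map(10, chrom="1"), snp_map(10, chrom="2")],
                       ignore_index=True)
        sm["snp"] = [f"s{i}" for i in range(20)]
        si = _SnpIndex(sm)
        tpl = Interval("1", 1, 50_001, 6)
        cc, ss, ee = _sample_matched_batch(tpl, si, 500, PARAMS,
                                           np.random.default_rng(1))
        # all sampled intervals fit within a chromosome's span
        assert ((ee - ss) <= 90_001).all()


def exhaustive_hit_probability(template, sm, set_genes, gm, params):
    """Enumerate every admissible (anchor, m) placement; exact hit rate."""
    si = _SnpIndex(sm)
    m_lo = max(1, math.ceil(params.snp_count_match[0] * template.n_snps - 1e-9))
    m_hi = max(m_lo, math.floor(params.snp_count_match[1] * template.n_snps + 1e-9))
    admissible, hits = 0, 0
    for anchor in range(si.n_snps):
        for m in range(m_lo, m_hi + 1):
            last = anchor + m - 1
            if last >= si.n_snps or si.flat_chrom[last] != si.flat_chrom[anchor]:
                continue
            start, end = si.flat_pos[anchor], si.flat_pos[last]
            if template.n_snps > 1 and template.span > 1:
                ratio = (end - start + 1) / template.span
                if not (params.span_match[0] <= ratio <= params.span_match[1]):
                    continue
            admissible += 1
            chrom = si.chroms[si.flat_chrom[anchor]]
            hit = interval_hits([Interval(chrom, int(start), int(end), m)],
                                set_genes, gm, params)[0]
            hits += hit
    return hits / admissible


class TestEnrichmentTest:
    def test_permutation_p_matches_exhaustive_enumeration(self):
        sm = snp_map(18, spacing=10_000)
        gm = gene_map([("g1", "1", 5_000, 8_000), ("g2", "1", 120_000, 125_000)])
        sets = GeneSetCollection()
        sets.add("s", ["g1"])
        ivs = [Interval("1", 1, 20_001, 3), Interval("1", 100_001, 120_001, 3)]
        params = EnrichmentParams(n_permutations=20_000, seed=9)
        res = enrichment_test(ivs, sets, gm, sm, params)
        t_obs = int(res.loc[0, "T"])
        q = exhaustive_hit_probability(ivs[0], sm, ["g1"], gm, params)
        # both intervals share the template geometry here (3 SNPs each)
        q2 = exhaustive_hit_probability(ivs[1], sm, ["g1"], gm, params)
        probs = {0: (1 - q) * (1 - q2), 1: q * (1 - q2) + q2 * (1 - q), 2: q * q2}
        exact = sum(v for t, v in probs.items() if t >= t_obs)
        se = math.sqrt(exact * (1 - exact) / params.n_permutations)
        assert abs(res.loc[0, "p_empirical"] - exact) < 3 * se + 2 / params.n_permutations

    def test_p_lower_bound_and_saturated_set(self):
        sm = snp_map(20)
        gm = gene_map([("g", "1", 1, 400_000)])  # covers everything
        sets = GeneSetCollection()
        sets.add("everywhere", ["g"])
        ivs = [Interval("1", 10_000, 30_000, 3)]
        res = enrichment_test(ivs, sets, gm, sm,
                              EnrichmentParams(n_permutations=500, seed=2))
        assert res.loc[0, "p_empirical"] == pytest.approx(1.0)
        assert (res["p_empirical"] >= 1 / 501).all()

    def test_set_absent_from_map_reports_p_one(self, caplog):
        sm = snp_map(20)
        gm = gene_map([("g", "1", 10_000, 20_000)])
        sets = GeneSetCollection()
        sets.add("ghost", ["nope"])
        ivs = [Interval("1", 10_000, 30_000, 3)]
        with caplog.at_level("WARNING"):
            res = enrichment_test(ivs, sets, gm, sm,
                                  EnrichmentParams(n_permutations=500, seed=2))
        assert res.loc[0, "p_empirical"] == 1.0
        assert "no genes" in caplog.text

    def test_deterministic_under_seed(self):
        sm = snp_map(30)
        gm = gene_map([("g1", "1", 5_000, 9_000), ("g2", "1", 150_000, 160_000)])
        sets = GeneSetCollection()
        sets.add("a", ["g1"])
        sets.add("b", ["g2"])
        ivs = [Interval("1", 1, 30_001, 4)]
        p = EnrichmentParams(n_permutations=1_000, seed=4)
        r1 = enrichment_test(ivs, sets, gm, sm, p)
        r2 = enrichment_test(ivs, sets, gm, sm, p)
        pd.testing.assert_frame_equal(r1, r2)

    def test_corrected_p_bounds_uncorrected(self):
        sm = snp_map(30)
        gm = gene_map([("g1", "1", 5_000, 9_000), ("g2", "1", 150_000, 160_000)])
        sets = GeneSetCollection()
        sets.add("a", ["g1"])
        sets.add("b", ["g2"])
        ivs = [Interval("1", 1, 30_001, 4), Interval("1", 140_001, 170_001, 4)]
        p = EnrichmentParams(n_permutations=1_000, seed=4, corrected_p=True)
        res = enrichment_test(ivs, sets, gm, sm, p)
        assert (res["p_corrected"] >= res["p_empirical"] - 1e-12).all()
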
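"""LD r-squared (EM haplotype and genotype correlation) and greedy clumping."""

import numpy as np
import pandas as pd
import pytest

from gagwas.clumping import (
    Clump,
    ClumpParams,
    _genotype_tables,
    clump,
    em_haplotype_r2,
    genotype_correlation_r2,
    pairwise_r2,
    top_clumps,
)
from gagwas.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


def grid_search_r2(table, step=1e-4):
    """Exhaustive ML oracle: scan the one free haplotype frequency.

    The ML solution preserves the observed allele frequencies, leaving the
    double-heterozygote phase (equivalently f11) as the only free parameter.
    """
    table = np.asarray(table, float)
    n = table.sum()
    pa = (table[1, :].sum() + 2 * table[2, :].sum()) / (2 * n)
    pb = (table[:, 1].sum() + 2 * table[:, 2].sum()) / (2 * n)
    if min(pa, pb) <= 0 or max(pa, pb) >= 1:
        return np.nan
    f11 = np.arange(max(0.0, pa + pb - 1.0), min(pa, pb) + step, step)
    f10 = pa - f11
    f01 = pb - f11
    f00 = 1 - pa - pb + f11
    hap = [f00, f01, f10, f11]
    ll = np.zeros_like(f11)
    for i in range(3):
        for j in range(3):
            c = table[i, j]
            if c == 0:
                continue
            if i == 1 and j == 1:
                prob = 2 * f00 * f11 + 2 * f01 * f10
            else:
                prob = np.zeros_like(f11)
                for h1 in range(4):
                    for h2 in range(h1, 4):
                        if (h1 >> 1) + (h2 >> 1) == i and (h1 & 1) + (h2 & 1) == j:
                            prob = prob + (1 if h1 == h2 else 2) * hap[h1] * hap[h2]
            ll += c * np.log(np.maximum(prob, 1e-300))
    best = int(np.argmax(ll))
    d = f11[best] - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def random_table(rng):
    n = int(rng.integers(20, 150))
    fa, fb = rng.uniform(0.1, 0.9, 2)
    rho = rng.uniform(-0.9, 0.9)
    a = (rng.random(2 * n) < fa).astype(int)
    b = np.where(rng.random(2 * n) < abs(rho), a if rho > 0 else 1 - a,
                 (rng.random(2 * n) < fb).astype(int))
    da, db = a[::2] + a[1::2], b[::2] + b[1::2]
    tab = np.zeros((3, 3), int)
    np.add.at(tab, (da, db), 1)
    return tab


class TestR2:
    def test_em_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            tab = random_table(rng)
            em = em_haplotype_r2(tab[None])[0]
            grid = grid_search_r2(tab)
            if np.isnan(grid):
                assert np.isnan(em)
            else:
                assert em == pytest.approx(grid, abs=1e-3)

    def test_duplicated_column_gives_one(self):
        rng = np.random.default_rng(1)
        da = rng.integers(0, 3, 200)
        assert em_haplotype_r2(_genotype_tables(da, da[:, None]))[0] == pytest.approx(1.0)
        assert genotype_correlation_r2(da, da)[0] == pytest.approx(1.0)

    def test_monomorphic_is_nan(self):
        da = np.zeros(50, dtype=np.int8)
        db = np.array([0, 1, 2] * 17)[:50]
        assert np.isnan(em_haplotype_r2(_genotype_tables(da, db[:, None]))[0])

    def test_independent_blocks_have_near_zero_r2(self):
        # blocks separated by a recomb_prob=0.5 boundary decorrelate
        vals = []
        for seed in range(8):
            cfg = SimConfig(n_samples=800, n_chromosomes=1, blocks_per_chr=2,
                            snps_per_block=4, founder_haplotypes_per_block=32,
                            recomb_prob=0.5, seed=seed)
            g = simulate_genotypes(cfg)
            r2 = pairwise_r2(g.snp_ids[0], g.snp_ids[6], g,
                             method="genotype_correlation")
            if not np.isnan(r2):
                vals.append(r2)
        # mean within 3 SE of the small positive floor expected at n=800
        assert np.mean(vals) < 0.05

    def test_em_and_correlation_agree_without_missingness(self):
        rng = np.random.default_rng(5)
        tab = random_table(rng)
        # reconstruct a genotype sample from the table
        da = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], tab.flatten())
        db = np.repeat([0, 1, 2] * 3, tab.flatten())
        em = em_haplotype_r2(tab[None])[0]
        cor = genotype_correlation_r2(da, db[:, None])[0]
        assert em == pytest.approx(cor, abs=0.15)  # same scale, not identical


def brute_force_clumps(res, calls, p1=5e-4, p2=0.05, r2_min=0.25, kb=250.0):
    """Independent loop-based reference for the greedy assignment rules."""
    order = res.sort_values(["best_p", "chrom", "bp"], kind="mergesort")
    colof = {s: i for i, s in enumerate(res["snp"])}
    assigned, out = set(), []
    for _, row in order.iterrows():
        if row.best_p >= p1 or row.snp in assigned:
            continue
        members = [row.snp]
        for _, other in res.iterrows():
            if other.snp == row.snp or other.snp in assigned:
                continue
            if other.chrom != row.chrom or abs(other.bp - row.bp) >= kb * 1000:
                continue
            if other.best_p >= p2:
                continue
            a = calls[:, colof[row.snp]].astype(float)
            b = calls[:, colof[other.snp]].astype(float)
            ok = (a >= 0) & (b >= 0)
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 > r2_min:
                members.append(other.snp)
        assigned.update(members)
        bp = res.set_index("snp")["bp"]
        out.append((row.snp, sorted(members, key=lambda s: int(bp[s]))))
    return out


def random_instance(rng, m=30, n=60):
    chrom = np.sort(rng.choice(["1", "2"], m))
    bp = np.concatenate([
        np.sort(rng.choice(np.arange(1, 600_001, 997), (chrom == c).sum(),
                           replace=False))
        for c in ["1", "2"]
    ])
    calls = rng.integers(0, 3, (n, m)).astype(np.int8)
    for j in range(1, m):
        if rng.random() < 0.5 and chrom[j] == chrom[j - 1]:
            calls[:, j] = calls[:, j - 1]
    pvals = 10.0 ** rng.uniform(-6, 0, m)
    pvals[rng.random(m) < 0.2] = 4e-4  # exercise ties at the index threshold
    g = make_genotypes(calls, chrom=list(chrom), bp=list(bp))
    res = pd.DataFrame({"snp": g.snp_ids, "chrom": chrom, "bp": bp,
                        "best_p": pvals})
    return g, res


class TestClump:
    PARAMS = ClumpParams(r2_method="genotype_correlation")

    def test_no_index_below_threshold_gives_empty(self, tiny_genotypes):
        res = pd.DataFrame({"snp": ["s0", "s1"], "chrom": "1", "bp": [1, 2],
                            "best_p": [0.2, 0.9]})
        assert clump(res, tiny_genotypes, self.PARAMS) == []

    def test_member_beyond_window_excluded(self):
        calls = np.tile(np.array([[0], [1], [2]] * 20, dtype=np.int8), (1, 2))
        g = make_genotypes(calls, bp=[1, 260_001])
        res = pd.DataFrame({"snp": ["s0", "s1"], "chrom": "1",
                            "bp": [1, 260_001], "best_p": [1e-5, 0.01]})
        cl = clump(res, g, self.PARAMS)
        assert cl[0].members == ["s0"]
        # move inside the window: perfectly correlated member joins
        g2 = make_genotypes(calls, bp=[1, 240_001])
        res2 = res.assign(bp=[1, 240_001])
        assert clump(res2, g2, self.PARAMS)[0].members == ["s0", "s1"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g, res = random_instance(rng)
            got = [(c.index_snp, c.members) for c in clump(res, g, self.PARAMS)]
            assert got == brute_force_clumps(res, g.calls)

    def test_disjoint_members_and_recheckable_rules(self):
        rng = np.random.default_rng(9)
        g, res = random_instance(rng)
        cl = clump(res, g, self.PARAMS)
        seen = [s for c in cl for s in c.members]
        assert len(seen) == len(set(seen))
        pmap = res.set_index("snp")
        for c in cl:
            assert c.index_p < 5e-4
            assert c.span[0] <= c.index_bp <= c.span[1]
            for s in c.members:
                assert abs(pmap.loc[s, "bp"] - c.index_bp) < 250_000
                assert pmap.loc[s, "best_p"] < 0.05 or s == c.index_snp

    def test_input_order_invariance(self):
        rng = np.random.default_rng(13)
        g, res = random_instance(rng)
        a = [(c.index_snp, c.members) for c in clump(res, g, self.PARAMS)]
        shuffled = res.sample(frac=1, random_state=3)
        b = [(c.index_snp, c.members) for c in clump(shuffled, g, self.PARAMS)]
        assert a == b

    def test_top_clumps_selects_best_k(self):
        cl = [Clump("a", "1", 10, 1e-5), Clump("b", "1", 20, 1e-6),
              Clump("c", "2", 5, 2e-4)]
        assert [c.index_snp for c in top_clumps(cl, 2)] == ["b", "a"]
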
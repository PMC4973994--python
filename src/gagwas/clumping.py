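"""Greedy LD clumping of association results into independent loci.

Index variants are chosen greedily in ascending order of the per-SNP best
empirical p-value (ties by chromosome, then position) among SNPs below the
index threshold.  Every still-unassigned SNP on the same chromosome that
lies strictly within the window of the index, is correlated with it above
``r2_min`` and itself passes the member threshold joins the index's clump;
each SNP belongs to at most one clump (the first-processed index wins).

r-squared is computed among founders by default, either from
maximum-likelihood haplotype frequencies (EM over the 3x3 genotype table)
or as the squared Pearson correlation of dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import logger
from .datatypes import ConfigurationError, GenotypeMatrix

EM_MAX_ITER = 50
EM_TOL = 1e-10


@dataclass
class ClumpParams:
    p1: float = 5e-4          # index threshold
    p2: float = 0.05          # member threshold
    r2_min: float = 0.25
    kb_window: float = 250.0
    r2_method: str = "em_haplotype"
    founders_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_min <= 1.0:
            raise ConfigurationError("r2_min must be in [0, 1]")
        if self.kb_window <= 0:
            raise ConfigurationError("kb_window must be positive")
        if self.r2_method not in ("em_haplotype", "genotype_correlation"):
            raise ConfigurationError(f"unknown r2 method {self.r2_method!r}")


@dataclass
class Clump:
    """An index SNP with its member SNPs and genomic span (1-based incl.)."""

    index_snp: str
    chrom: str
    index_bp: int
    index_p: float
    members: list[str] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)

    @property
    def n_snps(self) -> int:
        return len(self.members)


def _genotype_tables(da: np.ndarray, dm: np.ndarray) -> np.ndarray:
    """3x3 genotype count tables for one anchor SNP vs m partner SNPs.

    ``da`` is (n,) and ``dm`` (n, m) of calls in {0,1,2,-1}; missing calls
    are pairwise-deleted.  Returns (m, 3, 3) counts.
    """
    m = dm.shape[1]
    tables = np.zeros((m, 3, 3), dtype=np.int64)
    valid = (da >= 0)[:, None] & (dm >= 0)
    for i in range(3):
        ai = (da == i)[:, None] & valid
        for j in range(3):
            tables[:, i, j] = (ai & (dm == j)).sum(axis=0)
    return tables


def em_haplotype_r2(tables: np.ndarray) -> np.ndarray:
    """ML haplotype-frequency r^2 for a batch of 3x3 genotype tables.

    EM resolves the double-heterozygote phase ambiguity; frequencies start
    at linkage equilibrium.  Returns r^2 per table (NaN for monomorphic
    input).  Iterates up to 50 rounds or frequency change < 1e-10.
    """
    tables = np.atleast_3d(np.asarray(tables, dtype=np.float64))
    if tables.ndim == 2:
        tables = tables[None]
    m = tables.shape[0]
    n = tables.sum(axis=(1, 2))
    # fixed haplotype contributions from phase-determined genotypes:
    # hap (x, y), x = allele at locus A (0/1), y at locus B
    c = np.zeros((m, 4))  # order: 00, 01, 10, 11
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = tables[:, i, j]
            # the two haplotypes of genotype (i, j): split i into x1+x2, j into y1+y2
            x1, x2 = (1, 1) if i == 2 else ((0, 1) if i == 1 else (0, 0))
            y1, y2 = (1, 1) if j == 2 else ((0, 1) if j == 1 else (0, 0))
            if i == 1:
                # het at A, hom at B: haplotypes (0, y) and (1, y)
                c[:, 0 + y1] += cnt
                c[:, 2 + y2] += cnt
            elif j == 1:
                c[:, 2 * x1 + 0] += cnt
                c[:, 2 * x2 + 1] += cnt
            else:
                c[:, 2 * x1 + y1] += 2 * cnt
    dh = tables[:, 1, 1]  # double heterozygotes
    total = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (c[:, 2] + c[:, 3] + dh) / total  # allele-1 freq at A
        p_b = (c[:, 1] + c[:, 3] + dh) / total
    mono = (p_a <= 0) | (p_a >= 1) | (p_b <= 0) | (p_b >= 1) | (n == 0)
    f = np.stack(
        [(1 - p_a) * (1 - p_b), (1 - p_a) * p_b, p_a * (1 - p_b), p_a * p_b], axis=1
    )
    live = ~mono
    for _ in range(EM_MAX_ITER):
        if not live.any():
            break
        fl = f[live]
        num = fl[:, 0] * fl[:, 3]
        den = num + fl[:, 1] * fl[:, 2]
        pi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        new = c[live].copy()
        new[:, 0] += dh[live] * pi
        new[:, 3] += dh[live] * pi
        new[:, 1] += dh[live] * (1 - pi)
        new[:, 2] += dh[live] * (1 - pi)
        new /= total[live][:, None]
        delta = np.abs(new - fl).max(axis=1)
        f[live] = new
        still = np.zeros_like(live)
        still[live] = delta >= EM_TOL
        live = still
    d_ld = f[:, 3] - p_a * p_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = d_ld * d_ld / (p_a * (1 - p_a) * p_b * (1 - p_b))
    r2 = np.clip(r2, 0.0, 1.0 + 1e-12)
    r2 = np.minimum(r2, 1.0)
    r2[mono] = np.nan
    return r2


def genotype_correlation_r2(da: np.ndarray, dm: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosages, pairwise-deleted."""
    da = np.asarray(da, dtype=np.float64)
    dm = np.asarray(dm, dtype=np.float64)
    if dm.ndim == 1:
        dm = dm[:, None]
    out = np.empty(dm.shape[1])
    for j in range(dm.shape[1]):
        ok = (da >= 0) & (dm[:, j] >= 0)
        a, b = da[ok], dm[ok, j]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            out[j] = np.nan
            continue
        r = np.corrcoef(a, b)[0, 1]
        out[j] = min(r * r, 1.0)
    return out


def pairwise_r2(
    snp_a: str,
    snp_b: str,
    g: GenotypeMatrix,
    method: str = "em_haplotype",
    founders_only: bool = True,
) -> float:
    """r^2 between two SNPs; NaN for monomorphic input (logged)."""
    idx = pd.Index(g.snp_map["snp"])
    ja, jb = idx.get_loc(snp_a), idx.get_loc(snp_b)
    sel = g.founders_mask() if founders_only else np.ones(g.n_samples, bool)
    da = g.calls[sel, ja]
    db = g.calls[sel, jb][:, None]
    if method == "em_haplotype":
        r2 = float(em_haplotype_r2(_genotype_tables(da, db))[0])
    else:
        r2 = float(genotype_correlation_r2(da, db)[0])
    if np.isnan(r2):
        logger.info("r2(%s, %s) undefined (monomorphic)", snp_a, snp_b)
    return r2


def clump(
    results: pd.DataFrame,
    g: GenotypeMatrix,
    params: Optional[ClumpParams] = None,
) -> list[Clump]:
    """Form clumps from a per-SNP results table (columns snp, chrom, bp, best_p).

    Output is ordered by ascending index p.  Empty input (or no SNP under
    the index threshold) yields an empty list.
    """
    params = params or ClumpParams()
    req = {"snp", "chrom", "bp", "best_p"}
    if not req.issubset(results.columns):
        raise ConfigurationError(f"results table needs columns {sorted(req)}")
    res = results[["snp", "chrom", "bp", "best_p"]].copy()
    res["chrom"] = res["chrom"].astype(str)
    snp_pos = pd.Index(g.snp_map["snp"])
    col = snp_pos.get_indexer(res["snp"])
    if (col < 0).any():
        missing = res["snp"][col < 0].tolist()[:5]
        raise ConfigurationError(f"results contain SNPs absent from genotypes: {missing}")
    res["colidx"] = col

    sel = g.founders_mask() if params.founders_only else np.ones(g.n_samples, bool)
    calls = g.calls[sel]

    window_bp = params.kb_window * 1_000.0
    cand = res[res["best_p"] < params.p1].sort_values(
        ["best_p", "chrom", "bp"], kind="mergesort"
    )
    member_pool = res[res["best_p"] < params.p2]
    assigned: set[str] = set()
    clumps: list[Clump] = []
    for row in cand.itertuples(index=False):
        if row.snp in assigned:
            continue
        near = member_pool[
            (member_pool["chrom"] == row.chrom)
            & (np.abs(member_pool["bp"] - row.bp) < window_bp)
            & ~member_pool["snp"].isin(assigned)
            & (member_pool["snp"] != row.snp)
        ]
        members = [row.snp]
        if len(near):
            da = calls[:, row.colidx]
            dm = calls[:, near["colidx"].to_numpy()]
            if params.r2_method == "em_haplotype":
                r2 = em_haplotype_r2(_genotype_tables(da, dm))
            else:
                r2 = genotype_correlation_r2(da, dm)
            keep = np.nan_to_num(r2, nan=-1.0) > params.r2_min
            members += near["snp"].to_numpy()[keep].tolist()
        assigned.update(members)
        bps = res.set_index("snp").loc[members, "bp"]
        clumps.append(
            Clump(
                index_snp=row.snp,
                chrom=row.chrom,
                index_bp=int(row.bp),
                index_p=float(row.best_p),
                members=sorted(members, key=lambda s: int(bps.loc[s])),
                span=(int(bps.min()), int(bps.max())),
            )
        )
    return clumps


def top_clumps(clumps: Sequence[Clump], k: int) -> list[Clump]:
    """The k best clumps by index p (ties by chromosome, then position)."""
    ordered = sorted(clumps, key=lambda c: (c.index_p, c.chrom, c.index_bp))
    return list(ordered[:k])


def clumps_to_frame(clumps: Sequence[Clump]) -> pd.DataFrame:
    rows = [
        (
            c.index_snp,
            c.chrom,
            c.index_bp,
            c.index_p,
            c.span[0],
            c.span[1],
            c.n_snps,
            ",".join(c.members),
        )
        for c in clumps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "index_snp", "chrom", "index_bp", "index_p",
            "span_start", "span_end", "n_snps", "members",
        ],
    )
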
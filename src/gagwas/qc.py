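"""Genotype and sample quality control, plus the genomic inflation diagnostic.

The cascade runs sample missingness -> SNP missingness -> heterozygosity ->
relatedness -> Hardy-Weinberg -> PCA ancestry (entity-level filters before
statistics that assume clean data).  Relatedness and PCA operate on an
LD-thinned SNP subset.  Every stage records removed entities and the before /
after counts in a :class:`QCReport`, so the filtering narrative can be
reconstructed from the report alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._utils import logger
from .datatypes import GenotypeMatrix, QCError

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class QCParams:
    missingness_threshold: float = 0.03
    het_sd_threshold: float = 3.0
    relatedness_pihat_threshold: float = 0.05
    hwe_p_threshold: float = 1e-6
    pca_n_components: int = 3
    pca_sd_threshold: float = 10.0
    lambda_maf_min: float = 0.06
    hwe_founders_only: bool = False
    thin_r2: float = 0.2
    thin_window: int = 50
    seed: int = 0


@dataclass
class StageReport:
    stage: str
    removed_samples: list[str] = field(default_factory=list)
    removed_snps: list[str] = field(default_factory=list)
    reason: str = ""
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0


@dataclass
class QCReport:
    stages: list[StageReport] = field(default_factory=list)
    genomic_inflation: Optional[float] = None
    seed: int = 0

    def add(self, g_in: GenotypeMatrix, g_out: GenotypeMatrix, stage: str,
            removed_samples=(), removed_snps=(), reason: str = "") -> None:
        rep = StageReport(
            stage=stage,
            removed_samples=list(removed_samples),
            removed_snps=list(removed_snps),
            reason=reason,
            n_samples_in=g_in.n_samples,
            n_samples_out=g_out.n_samples,
            n_snps_in=g_in.n_snps,
            n_snps_out=g_out.n_snps,
        )
        if rep.n_samples_in - len(rep.removed_samples) != rep.n_samples_out:
            raise QCError(f"stage {stage}: sample counts do not reconcile")
        if rep.n_snps_in - len(rep.removed_snps) != rep.n_snps_out:
            raise QCError(f"stage {stage}: SNP counts do not reconcile")
        self.stages.append(rep)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                s.stage, s.n_samples_in, s.n_samples_out, s.n_snps_in, s.n_snps_out,
                len(s.removed_samples), len(s.removed_snps),
                ";".join(s.removed_samples), ";".join(s.removed_snps), s.reason,
            )
            for s in self.stages
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "stage", "samples_in", "samples_out", "snps_in", "snps_out",
                "n_removed_samples", "n_removed_snps",
                "removed_samples", "removed_snps", "reason",
            ],
        )


# -- missingness -----------------------------------------------------------


def filter_missingness(
    g: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples then SNPs whose missing-call rate exceeds the threshold.

    Samples go first; SNP rates are then recomputed on the remaining samples.
    """
    report = QCReport(seed=params.seed)
    thr = params.missingness_threshold
    miss = g.calls == -1
    sample_rate = miss.mean(axis=1)
    drop_s = sample_rate > thr
    if drop_s.all():
        raise QCError("missingness filter removed every sample")
    g1 = g.subset_samples(~drop_s)
    report.add(g, g1, "sample_missingness",
               removed_samples=g.sample_ids[drop_s],
               reason=f"missing rate > {thr}")
    snp_rate = (g1.calls == -1).mean(axis=0)
    drop_v = snp_rate > thr
    g2 = g1.subset_snps(~drop_v)
    report.add(g1, g2, "snp_missingness",
               removed_snps=g1.snp_ids[drop_v],
               reason=f"missing rate > {thr}")
    return g2, report


# -- Hardy-Weinberg exact test ---------------------------------------------


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test probability.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    Monomorphic input returns 1.0.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    na = 2 * n_hom1 + n_het  # copies of allele 1
    if na == 0 or na == 2 * n:
        return 1.0
    hets = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    hom1 = (na - hets) // 2
    hom2 = n - hom1 - hets
    logp = (
        gammaln(n + 1)
        - gammaln(hom1 + 1)
        - gammaln(hets + 1)
        - gammaln(hom2 + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(na + 1) - gammaln(2 * n - na + 1))
    )
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def filter_hwe(g: GenotypeMatrix, params: QCParams) -> tuple[GenotypeMatrix, QCReport]:
    """Remove autosomal SNPs with exact HWE p below the threshold."""
    report = QCReport(seed=params.seed)
    sel = g.founders_mask() if params.hwe_founders_only else np.ones(g.n_samples, bool)
    calls = g.calls[sel]
    autos = ~g.is_x()
    drop = np.zeros(g.n_snps, dtype=bool)
    for j in np.flatnonzero(autos):
        col = calls[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            continue
        if hwe_exact_test(n2, n1, n0) < params.hwe_p_threshold:
            drop[j] = True
    g2 = g.subset_snps(~drop)
    report.add(g, g2, "hwe", removed_snps=g.snp_ids[drop],
               reason=f"exact HWE p < {params.hwe_p_threshold}")
    return g2, report


# -- heterozygosity --------------------------------------------------------


def filter_heterozygosity(
    g: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples whose autosomal het rate deviates > k SD from the group mean.

    Groups follow the ``genome`` sample column when present (mothers and
    children have different expected heterozygosity batches), else one group.
    """
    report = QCReport(seed=params.seed)
    autos = ~g.is_x()
    calls = g.calls[:, autos]
    obs = calls != -1
    nobs = obs.sum(axis=1)
    het = np.divide((calls == 1).sum(axis=1), nobs,
                    out=np.zeros(g.n_samples), where=nobs > 0)
    groups = (
        g.samples["genome"] if "genome" in g.samples.columns
        else pd.Series("all", index=g.samples.index)
    )
    drop = np.zeros(g.n_samples, dtype=bool)
    for _, idx in groups.groupby(groups).groups.items():
        pos = groups.index.get_indexer(idx)
        h = het[pos]
        sd = h.std()
        if sd == 0:
            continue
        drop[pos] = np.abs(h - h.mean()) > params.het_sd_threshold * sd
    if drop.all():
        raise QCError("heterozygosity filter removed every sample")
    g2 = g.subset_samples(~drop)
    report.add(g, g2, "heterozygosity", removed_samples=g.sample_ids[drop],
               reason=f"autosomal het rate beyond {params.het_sd_threshold} SD")
    return g2, report


# -- LD thinning (support for relatedness / PCA) ---------------------------


def ld_thin(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy window thinning: keep one SNP of every pair with r^2 > r2_max.

    Works in non-overlapping windows of ``window`` SNPs per chromosome;
    returns a boolean keep mask over SNPs.
    """
    keep = np.ones(g.n_snps, dtype=bool)
    d = g.calls.astype(float)
    d[g.calls == -1] = np.nan
    for _, grp in g.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for s in range(0, idx.size, window):
            w = idx[s : s + window]
            cols = d[:, w]
            mu = np.nanmean(cols, axis=0)
            filled = np.where(np.isnan(cols), mu, cols)
            sd = filled.std(axis=0)
            ok = sd > 0
            z = np.zeros_like(filled)
            z[:, ok] = (filled[:, ok] - mu[ok]) / sd[:, None].T[:, ok]
            r2 = (z.T @ z / len(filled)) ** 2
            kept_local: list[int] = []
            for jj in range(w.size):
                if not ok[jj]:
                    continue
                if all(r2[jj, kk] <= r2_max for kk in kept_local):
                    kept_local.append(jj)
                else:
                    keep[w[jj]] = False
            keep[w[~ok]] = False
    return keep


# -- relatedness -----------------------------------------------------------


def pihat_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments genome-wide IBD proportion (PI_HAT) per sample pair.

    Uses population-level conditional IBS probabilities given IBD state with
    allele frequencies estimated in the provided samples; IBS counts are
    pairwise-complete.  Returns an (n, n) symmetric matrix (diagonal 1).
    """
    calls = g.calls
    obs = calls != -1
    x = np.where(obs, calls, 0).sum(axis=0).astype(np.float64)  # a2 allele count
    t = 2.0 * obs.sum(axis=0)
    y = t - x
    informative = (t >= 4) & (x > 0) & (y > 0)
    calls = calls[:, informative]
    x, t, y = x[informative], t[informative], y[informative]
    valid = (calls != -1).astype(np.float64)
    a = [(calls == k).astype(np.float64) for k in (0, 1, 2)]
    ibs2 = a[0] @ a[0].T + a[1] @ a[1].T + a[2] @ a[2].T
    ibs0 = a[0] @ a[2].T + a[2] @ a[0].T
    nvalid = valid @ valid.T
    ibs1 = nvalid - ibs0 - ibs2
    # conditional IBS probabilities per SNP, from unbiased factorial moments
    # of the allele counts (plug-in sample frequencies overstate relatedness
    # at desk-scale SNP counts)
    perm2 = t * (t - 1)
    perm4 = perm2 * (t - 2) * (t - 3)
    pq = x * y / perm2
    p2q2 = x * (x - 1) * y * (y - 1) / perm4
    p3q = x * (x - 1) * (x - 2) * y / perm4
    pq3 = x * y * (y - 1) * (y - 2) / perm4
    e0_i0 = 2 * p2q2
    e1_i0 = 4 * p3q + 4 * pq3
    e2_i0 = 1.0 - e0_i0 - e1_i0
    e1_i1 = 2 * pq
    e2_i1 = 1.0 - e1_i1
    # pairwise expected sums over the SNPs both samples observe
    s0_i0 = valid @ (e0_i0[:, None] * valid.T)
    s1_i0 = valid @ (e1_i0[:, None] * valid.T)
    s2_i0 = valid @ (e2_i0[:, None] * valid.T)
    s1_i1 = valid @ (e1_i1[:, None] * valid.T)
    s2_i1 = valid @ (e2_i1[:, None] * valid.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(s0_i0 > 0, ibs0 / s0_i0, 0.0)
        p1 = np.where(s1_i1 > 0, (ibs1 - p0 * s1_i0) / s1_i1, 0.0)
        p2 = np.where(nvalid > 0, (ibs2 - p0 * s2_i0 - p1 * s2_i1) / nvalid, 0.0)
    p0, p1, p2 = (np.clip(x, 0.0, 1.0) for x in (p0, p1, p2))
    tot = p0 + p1 + p2
    tot[tot == 0] = 1.0
    p1, p2 = p1 / tot, p2 / tot
    pihat = p2 + 0.5 * p1
    np.fill_diagonal(pihat, 1.0)
    return pihat


def filter_relatedness(
    g: GenotypeMatrix, params: QCParams
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove one random member of every within-group pair above the PI_HAT cut.

    Pairs are assessed within each genome-type group (mother-mother or
    child-child) on LD-thinned SNPs; which member goes is fixed by the seed.
    Because the method-of-moments estimator's sampling noise scales with
    1/sqrt(SNP count), a pair is only flagged when its PI_HAT also exceeds a
    data-driven noise floor (median + 5 robust SDs of all pairwise values);
    at realistic SNP counts the floor sits far below any configured
    threshold and the threshold alone governs.
    """
    report = QCReport(seed=params.seed)
    keep_snps = ld_thin(g, params.thin_r2, params.thin_window)
    thin = g.subset_snps(keep_snps)
    groups = (
        g.samples["genome"] if "genome" in g.samples.columns
        else pd.Series("all", index=g.samples.index)
    )
    rng = np.random.default_rng(params.seed)
    removed = np.zeros(g.n_samples, dtype=bool)
    for _, idx in sorted(groups.groupby(groups).groups.items()):
        pos = groups.index.get_indexer(idx)
        if pos.size < 2:
            continue
        sub = thin.subset_samples(pos)
        ph = pihat_matrix(sub)
        iu, ju = np.triu_indices(pos.size, k=1)
        vals = ph[iu, ju]
        mad_sd = 1.4826 * np.median(np.abs(vals - np.median(vals)))
        floor = np.median(vals) + 5.0 * mad_sd
        cut = max(params.relatedness_pihat_threshold, floor)
        if floor > params.relatedness_pihat_threshold:
            logger.warning(
                "PI_HAT noise floor %.3f exceeds threshold %.3f "
                "(too few SNPs for the configured cut); using the floor",
                floor, params.relatedness_pihat_threshold,
            )
        order = np.argsort(-vals, kind="stable")
        for t in order:
            i, j = pos[iu[t]], pos[ju[t]]
            if vals[t] <= cut:
                break
            if removed[i] or removed[j]:
                continue
            removed[i if rng.random() < 0.5 else j] = True
    g2 = g.subset_samples(~removed)
    report.add(g, g2, "relatedness", removed_samples=g.sample_ids[removed],
               reason=f"PI_HAT > {params.relatedness_pihat_threshold}")
    return g2, report


# -- PCA ancestry ----------------------------------------------------------


def pca_ancestry_filter(
    g: GenotypeMatrix,
    reference_panel: Optional[GenotypeMatrix],
    params: QCParams,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples far from the reference cluster in PC space.

    Study and reference samples are merged (shared SNPs, LD-thinned),
    standardised per SNP by the reference allele frequency (mean 2p, scale
    sqrt(2p(1-p)); missing calls mean-imputed for the decomposition only) and
    decomposed together — fitting on the merged panel is what lets a
    divergent study cluster surface in the leading components.  Samples
    whose Euclidean distance from the reference centroid over the first
    ``pca_n_components`` PCs exceeds ``pca_sd_threshold`` times the SD of
    reference distances are removed.  Absent reference panel skips the
    stage with a warning.
    """
    from sklearn.decomposition import PCA

    report = QCReport(seed=params.seed)
    if reference_panel is None:
        logger.warning("no reference panel: PCA ancestry filter skipped")
        report.add(g, g, "pca_ancestry", reason="skipped: no reference panel")
        return g, report
    shared = [s for s in g.snp_ids if s in set(reference_panel.snp_ids)]
    keep_snps = ld_thin(g.subset_snps(shared), params.thin_r2, params.thin_window)
    shared = [s for s, k in zip(shared, keep_snps) if k]
    gs = g.subset_snps(shared)
    rs = reference_panel.subset_snps(shared)
    f = rs.freq_a2()
    f = np.clip(np.nan_to_num(f, nan=0.5), 0.01, 0.99)
    scale = np.sqrt(2 * f * (1 - f))

    def standardise(mat: GenotypeMatrix) -> np.ndarray:
        d = mat.calls.astype(float)
        d[mat.calls == -1] = np.nan
        z = (d - 2 * f) / scale
        return np.where(np.isnan(z), 0.0, z)

    zr = standardise(rs)
    zg = standardise(gs)
    merged = np.vstack([zr, zg])
    ncomp = min(params.pca_n_components, merged.shape[0] - 1, merged.shape[1])
    pca = PCA(n_components=ncomp, svd_solver="full", random_state=0)
    proj = pca.fit_transform(merged)
    pr, pg = proj[: zr.shape[0]], proj[zr.shape[0]:]
    centroid = pr.mean(axis=0)
    ref_d = np.linalg.norm(pr - centroid, axis=1)
    sd = ref_d.std()
    if sd == 0:
        logger.warning("degenerate reference panel (zero PC spread); none removed")
        report.add(g, g, "pca_ancestry", reason="degenerate reference spread")
        return g, report
    d = np.linalg.norm(pg - centroid, axis=1)
    drop = d > params.pca_sd_threshold * sd
    g2 = g.subset_samples(~drop)
    report.add(g, g2, "pca_ancestry", removed_samples=g.sample_ids[drop],
               reason=f"PC distance > {params.pca_sd_threshold} SD from reference")
    return g2, report


# -- genomic inflation -----------------------------------------------------


def genomic_inflation(chi2_stats, maf=None, params: Optional[QCParams] = None) -> float:
    """Genomic inflation factor: median chi-square over its 1-df null median.

    ``chi2_stats`` are per-SNP 1-df association chi-squares (additive model);
    SNPs at or below ``lambda_maf_min`` are excluded when ``maf`` is given.
    Reported to 3 decimals.
    """
    params = params or QCParams()
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if maf is not None:
        maf = np.asarray(maf, dtype=float)
        chi2_stats = chi2_stats[maf > params.lambda_maf_min]
    chi2_stats = chi2_stats[~np.isnan(chi2_stats)]
    if chi2_stats.size < 30:
        logger.warning("genomic inflation on only %d SNPs", chi2_stats.size)
    if chi2_stats.size == 0:
        raise QCError("no eligible SNPs for genomic inflation")
    return round(float(np.median(chi2_stats) / CHI2_MEDIAN_1DF), 3)


# -- full cascade ----------------------------------------------------------


def run_qc(
    g: GenotypeMatrix,
    params: Optional[QCParams] = None,
    reference_panel: Optional[GenotypeMatrix] = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """The full QC cascade; returns the filtered matrix and merged report."""
    params = params or QCParams()
    report = QCReport(seed=params.seed)
    g1, rep = filter_missingness(g, params)
    report.stages.extend(rep.stages)
    g2, rep = filter_heterozygosity(g1, params)
    report.stages.extend(rep.stages)
    g3, rep = filter_relatedness(g2, params)
    report.stages.extend(rep.stages)
    g4, rep = filter_hwe(g3, params)
    report.stages.extend(rep.stages)
    g5, rep = pca_ancestry_filter(g4, reference_panel, params)
    report.stages.extend(rep.stages)
    for s in report.stages:
        logger.info(
            "QC %s: -%d samples, -%d SNPs (%s)",
            s.stage, len(s.removed_samples), len(s.removed_snps), s.reason,
        )
    return g5, report
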
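"""Per-SNP association of a continuous phenotype under three genetic models.

Each SNP is tested under additive, recessive and dominant codings of the
minor (effect) allele with simple linear regression of gestational age on
the coded dosage; the test statistic is |t|.  Empirical p-values come from
label permutation of the phenotype vector: one permutation per replicate is
shared by all SNP x model tests still active in that replicate, exceedances
are counted with ties included, and the estimator is (R+1)/(N+1) — valid
(never anti-conservative) under exchangeability.

Adaptive early stopping prunes clearly non-significant tests: at pruning
checkpoints a two-sided normal-approximation interval at confidence
``1 - beta`` around R/N is computed and the test stops once the interval
excludes ``alpha`` from below.  The checkpoint schedule starts at
``min_perms`` and then advances by ``max(1, ceil(a + b*N))`` replicates with
``a = prune_interval_init`` and ``b = prune_interval_slope``.  Nothing is
declared significant early; every test stops at ``max_perms`` at the latest.
X-chromosome SNPs run the additive model only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._utils import logger
from .datatypes import ConfigurationError, GenotypeMatrix

MODELS = ("additive", "recessive", "dominant")
#: tie-break preference for equal empirical p-values across models
MODEL_PRIORITY = {"additive": 0, "dominant": 1, "recessive": 2}

_BLOCK = 256  # permutation replicates per vectorised block (fixed: results
# must not depend on internal batching)


@dataclass
class PermutationParams:
    """Adaptive permutation settings.

    Defaults follow genome-wide practice (``alpha = beta = 5e-8``,
    ``min_perms = 10``) with a desk-scale cap ``max_perms = 1e5``; the
    full-scale ``1e9`` cap is a configuration choice away.
    """

    alpha: float = 5e-8
    beta: float = 5e-8
    min_perms: int = 10
    max_perms: int = 100_000
    prune_interval_init: float = 1.0
    prune_interval_slope: float = 0.001
    adaptive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ConfigurationError("alpha and beta must be in (0, 1)")
        if self.min_perms < 1:
            raise ConfigurationError("min_perms must be >= 1")
        if self.max_perms < self.min_perms:
            raise ConfigurationError("max_perms must be >= min_perms")

    def checkpoints(self) -> np.ndarray:
        """Materialise the pruning checkpoint schedule up to max_perms."""
        out = []
        n = self.min_perms
        while n < self.max_perms:
            out.append(n)
            n += max(1, math.ceil(self.prune_interval_init + self.prune_interval_slope * n))
        return np.asarray(out, dtype=np.int64)


@dataclass
class AssociationResult:
    """Per SNP x model records plus the per-SNP combined (min-p) table."""

    per_model: pd.DataFrame
    per_snp: pd.DataFrame
    params: PermutationParams = field(repr=False, default_factory=PermutationParams)


def encode_genotype(calls, model: str):
    """Code minor-allele dosage under a genetic model; missing propagates.

    ``calls`` are minor-allele counts (0/1/2, NaN missing).  additive keeps
    the count; recessive is 1 for two copies; dominant is 1 for at least one.
    """
    d = np.asarray(calls, dtype=float)
    if model == "additive":
        return d.copy()
    if model == "recessive":
        out = (d == 2).astype(float)
    elif model == "dominant":
        out = (d >= 1).astype(float)
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    out[np.isnan(d)] = np.nan
    return out


def model_statistic(dosages, phenotype):
    """Simple linear regression of phenotype on dosage (pairwise deletion).

    Returns ``(beta, t_abs, p_asymptotic, groups)`` where ``groups`` maps
    dosage class (of the raw 0/1/2 coding passed in) to ``(count, mean)``.
    Degenerate input (zero dosage variance or fewer than 3 complete pairs)
    yields ``(nan, nan, nan, groups)``.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(y)
    d, y = d[ok], y[ok]
    groups = {}
    for val in np.unique(d):
        sel = d == val
        groups[float(val)] = (int(sel.sum()), float(y[sel].mean()))
    n = d.size
    if n < 3 or np.ptp(d) == 0:
        return math.nan, math.nan, math.nan, groups
    vx = d.var()
    vy = y.var()
    cov = ((d - d.mean()) * (y - y.mean())).mean()
    beta = cov / vx
    if vy == 0 or cov**2 >= vx * vy:
        r2 = 1.0 if vy > 0 else 0.0
    else:
        r2 = cov**2 / (vx * vy)
    if vy == 0:
        return 0.0, 0.0, 1.0, groups
    if r2 >= 1.0:
        return beta, math.inf, 0.0, groups
    t_abs = math.sqrt(r2 * (n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(t_abs, df=n - 2)
    return beta, t_abs, p, groups


def _batch_stats(x0, sx, sxx, nval, y_mat, miss=None, want_beta=False):
    """|t| for every test column against every phenotype column.

    ``x0`` is (n, k) dosage with missing set to 0; ``miss`` an optional
    (k, n) sparse missing-indicator used to correct the phenotype sums for
    pairwise deletion; ``y_mat`` is (n, B).
    """
    sxy = x0.T @ y_mat  # (k, B)
    ysum = y_mat.sum(axis=0)
    y2sum = (y_mat * y_mat).sum(axis=0)
    if miss is None:
        sy = np.broadcast_to(ysum, sxy.shape)
        syy = np.broadcast_to(y2sum, sxy.shape)
    else:
        sy = ysum[None, :] - miss @ y_mat
        syy = y2sum[None, :] - miss @ (y_mat * y_mat)
    n = nval[:, None].astype(float)
    cov = sxy - sx[:, None] * sy / n
    vx = (sxx - sx * sx / nval.astype(float))[:, None]
    vy = syy - sy * sy / n
    denom = vx * vy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = np.where(r2 < 1.0, r2 * (n - 2) / (1.0 - r2), np.inf)
    t_abs = np.sqrt(t2)
    if want_beta:
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(vx > 0, cov / vx, np.nan)
        return t_abs, beta
    return t_abs


def _prune_now(r, n, z, alpha):
    """True when the CI around R/N excludes alpha from below."""
    phat = r / n
    half = z * np.sqrt(phat * (1.0 - phat) / n)
    return (phat - half) > alpha


def adaptive_permutation(
    g: GenotypeMatrix,
    phenotype,
    models: Sequence[str] = MODELS,
    params: Optional[PermutationParams] = None,
) -> AssociationResult:
    """Run the three-model permutation GWAS on QC-passed genotypes.

    ``phenotype`` is aligned with ``g.samples`` (array or Series).  Returns
    per-model records (statistic, asymptotic p, exceedance count R,
    permutations N, empirical p, status) and the per-SNP combined table.
    Fully reproducible under ``params.seed``.
    """
    params = params or PermutationParams()
    for m in models:
        if m not in MODELS:
            raise ConfigurationError(f"unknown model {m!r}")
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ConfigurationError("phenotype length does not match sample count")
    if np.isnan(y).any():
        raise ConfigurationError("phenotype contains missing values")

    dosage, eff, ref = g.minor_dosage()
    is_x = g.is_x()
    snp_ids = g.snp_ids
    chroms = g.snp_map["chrom"].to_numpy()
    bps = g.snp_map["bp"].to_numpy()

    # assemble test columns (snp, model)
    test_snp: list[int] = []
    test_model: list[str] = []
    for m in models:
        for j in range(g.n_snps):
            if is_x[j] and m != "additive":
                continue
            test_snp.append(j)
            test_model.append(m)
    k = len(test_snp)
    x0 = np.empty((g.n_samples, k), dtype=np.float64)
    for c, (j, m) in enumerate(zip(test_snp, test_model)):
        x0[:, c] = encode_genotype(dosage[:, j], m)
    nan_mask = np.isnan(x0)
    nval = (~nan_mask).sum(axis=0).astype(np.int64)
    x0[nan_mask] = 0.0
    sx = x0.sum(axis=0)
    sxx = (x0 * x0).sum(axis=0)
    any_missing = nan_mask.any()
    miss_all = sp.csr_matrix(nan_mask.T.astype(np.float64)) if any_missing else None

    # degenerate: zero dosage variance or too few complete pairs
    with np.errstate(invalid="ignore"):
        varx = sxx - sx * sx / np.maximum(nval, 1)
    degenerate = (nval < 3) | (varx <= 0)

    t_obs, beta = _batch_stats(
        x0, sx, sxx, np.maximum(nval, 1), y[:, None], miss_all, want_beta=True
    )
    t_obs = t_obs[:, 0]
    beta = beta[:, 0]
    t_obs[degenerate] = np.nan
    with np.errstate(invalid="ignore"):
        p_asym = 2.0 * stats.t.sf(t_obs, df=np.maximum(nval - 2, 1))

    R = np.zeros(k, dtype=np.int64)
    N_final = np.zeros(k, dtype=np.int64)
    status = np.where(degenerate, "skipped-degenerate", "completed").astype(object)
    active = ~degenerate

    cps = params.checkpoints() if params.adaptive else np.empty(0, dtype=np.int64)
    z = stats.norm.ppf(1.0 - params.beta / 2.0)
    rng = np.random.default_rng(params.seed)
    n_done = 0
    while n_done < params.max_perms and active.any():
        b = int(min(_BLOCK, params.max_perms - n_done))
        u = rng.random((g.n_samples, b))
        order = np.argsort(u, axis=0, kind="stable")
        y_perm = y[order]
        act = np.flatnonzero(active)
        x_act = x0[:, act]
        miss_act = miss_all[act] if miss_all is not None else None
        t_perm = _batch_stats(
            x_act, sx[act], sxx[act], nval[act], y_perm, miss_act
        )
        exceed = (t_perm >= t_obs[act, None]).astype(np.int64)
        csum = np.cumsum(exceed, axis=1)
        in_block = cps[(cps > n_done) & (cps <= n_done + b)]
        pruned_here = np.zeros(act.size, dtype=bool)
        if in_block.size:
            off = in_block - n_done - 1
            r_cp = R[act, None] + csum[:, off]  # (k_act, n_cp)
            cond = _prune_now(r_cp, in_block[None, :].astype(float), z, params.alpha)
            hit = cond.any(axis=1)
            first = np.argmax(cond, axis=1)
            idx = np.flatnonzero(hit)
            rows = act[idx]
            N_final[rows] = in_block[first[idx]]
            R[rows] = r_cp[idx, first[idx]]
            status[rows] = "pruned"
            active[rows] = False
            pruned_here[idx] = True
        keep = ~pruned_here
        R[act[keep]] += csum[keep, -1]
        n_done += b
    N_final[active] = n_done
    if n_done >= params.max_perms:
        pass  # tests still active at the cap carry status "completed"

    emp_p = np.where(
        degenerate, np.nan, (R + 1.0) / (N_final + 1.0)
    )
    per_model = pd.DataFrame(
        {
            "snp": snp_ids[test_snp],
            "chrom": chroms[test_snp],
            "bp": bps[test_snp],
            "model": test_model,
            "beta": beta,
            "t_abs": t_obs,
            "p_asymptotic": p_asym,
            "R": R,
            "N": N_final,
            "p_empirical": emp_p,
            "status": status,
        }
    )

    per_snp = min_p_combine(per_model)
    # per-SNP genotype class counts and means (minor-allele dosage classes)
    grp = _group_summaries(dosage, y)
    per_snp = per_snp.merge(
        pd.DataFrame(
            {
                "snp": snp_ids,
                "effect_allele": eff,
                "ref_allele": ref,
                **grp,
            }
        ),
        on="snp",
        how="left",
    )
    return AssociationResult(per_model=per_model, per_snp=per_snp, params=params)


def _group_summaries(dosage: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Counts and phenotype means per genotypic class (EE, ER, RR)."""
    out = {}
    for label, val in (("EE", 2), ("ER", 1), ("RR", 0)):
        sel = dosage == val
        n = sel.sum(axis=0)
        s = np.where(sel, y[:, None], 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"n{label}"] = n
            out[f"m{label}"] = np.where(n > 0, s / n, np.nan)
    return out


def min_p_combine(per_model: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP best (most extreme) empirical p over non-skipped models.

    Ties break deterministically additive > dominant > recessive.  SNPs with
    every model skipped are excluded with a logged reason.
    """
    ok = per_model[per_model["status"] != "skipped-degenerate"].copy()
    dropped = set(per_model["snp"]) - set(ok["snp"])
    if dropped:
        logger.info("%d SNP(s) excluded: all models degenerate", len(dropped))
    ok["_prio"] = ok["model"].map(MODEL_PRIORITY)
    ok = ok.sort_values(["snp", "p_empirical", "_prio"], kind="mergesort")
    best = ok.groupby("snp", sort=False).head(1)
    best = best.rename(
        columns={"p_empirical": "best_p", "model": "best_model"}
    )[["snp", "chrom", "bp", "best_p", "best_model", "t_abs", "p_asymptotic", "R", "N"]]
    # restore map order
    order = {s: i for i, s in enumerate(dict.fromkeys(per_model["snp"]))}
    best = best.sort_values("snp", key=lambda s: s.map(order), kind="mergesort")
    return best.reset_index(drop=True)
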
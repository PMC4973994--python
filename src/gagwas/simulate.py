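"""Synthetic cohort, annotation and abstract-corpus generation.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable offline:

* **Genotypes** follow a haplotype-pool block model: each LD block has a small
  pool of founder haplotypes; an individual's two copies pick a pool member
  per block and re-draw it with probability ``recomb_prob`` at each block
  boundary.  Fewer founder haplotypes and lower recombination mean stronger
  within-block LD.
* **Phenotype** is gestational age in integer days: a baseline plus
  model-coded causal SNP effects plus Gaussian noise.  The cohort is then
  assembled by individual-level rejection sampling until two gestational-age
  windows (preterm and term) hold their configured counts, reproducing a
  case-oversampled bimodal design: selection acts on the phenotype, so
  genotype-phenotype association survives (extreme-phenotype sampling).
* **Annotation** tiles non-overlapping genes along the simulated chromosomes
  (each planted causal SNP lies inside a gene by construction) and draws one
  designated truth gene-set containing those causal genes, plus null
  candidate-analog and control-analog sets.
* **Corpus** abstracts embed gene symbols and keyword contexts, including
  every text-mining trap kind, with ground-truth labels emitted alongside.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed, logger
from .datatypes import (
    MISSING,
    ConfigurationError,
    GeneSetCollection,
    GenotypeMatrix,
    SimulationError,
)
from .mining import KeywordSpec, MiningFilters
from .mining_defaults import (
    DEFAULT_ACRONYM_BLACKLIST,
    DEFAULT_CONDITION_INDICATORS,
    DEFAULT_KEYWORDS,
    DEFAULT_NONHUMAN_INDICATORS,
)

MODELS = ("additive", "recessive", "dominant")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    ``causal_spec`` entries are ``(snp_index, model, effect_days)``; the
    effect applies per copy (additive) or per carrier class (recessive /
    dominant) of allele ``a2``, the allele simulated at the block MAF.
    ``sampling_ranges`` are closed day windows and ``range_counts`` the number
    of cohort members each must hold (defaults to a 40:60 preterm:term split).
    """

    n_samples: int = 500
    n_chromosomes: int = 5
    blocks_per_chr: int = 10
    snps_per_block: int = 10
    founder_haplotypes_per_block: int = 8
    maf_range: tuple[float, float] = (0.10, 0.50)
    recomb_prob: float = 0.50
    causal_spec: list[tuple[int, str, float]] = field(default_factory=list)
    noise_sd: float = 15.0
    baseline_ga: float = 270.0
    sampling_ranges: tuple[tuple[int, int], ...] = ((154, 258), (273, 286))
    range_counts: Optional[tuple[int, ...]] = None
    strata_props: tuple[float, float] = (0.616, 0.807)  # P(mother), P(labor)
    snp_spacing_bp: int = 5_000
    seed: int = 0
    # opt-in artifact injections for QC tests
    missing_rate: float = 0.0
    n_duplicates: int = 0
    shifted_cluster: Optional[tuple[int, float]] = None  # (n_samples, freq shift)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ConfigurationError("recomb_prob must be in [0, 1]")
        if min(
            self.n_samples,
            self.n_chromosomes,
            self.blocks_per_chr,
            self.snps_per_block,
            self.founder_haplotypes_per_block,
        ) < 1:
            raise ConfigurationError("all dimension counts must be >= 1")
        if self.range_counts is None:
            n_pre = int(round(0.4 * self.n_samples))
            self.range_counts = (n_pre, self.n_samples - n_pre)
        if len(self.range_counts) != len(self.sampling_ranges):
            raise ConfigurationError("one target count per sampling range required")
        if sum(self.range_counts) != self.n_samples:
            raise ConfigurationError("range target counts must sum to n_samples")
        for idx, model, eff in self.causal_spec:
            if model not in MODELS:
                raise ConfigurationError(f"unknown genetic model {model!r}")
            if not np.isfinite(eff):
                raise ConfigurationError("causal effect sizes must be finite")
            if not 0 <= idx < self.n_snps:
                raise ConfigurationError(f"causal SNP index {idx} out of range")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.blocks_per_chr * self.snps_per_block


class Population:
    """Founder haplotype pools plus the SNP map; draws cohort members.

    Constructed deterministically from the config seed so that repeated
    batches (rejection sampling) sample from one fixed population.
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        rng = np.random.default_rng(derive_seed(cfg.seed, "population"))
        k = cfg.founder_haplotypes_per_block
        spb = cfg.snps_per_block
        n_blocks = cfg.n_chromosomes * cfg.blocks_per_chr
        lo, hi = cfg.maf_range
        self.block_maf = rng.uniform(lo, hi, size=(n_blocks, spb))
        self.haplotypes = (
            rng.random((n_blocks, k, spb)) < self.block_maf[:, None, :]
        ).astype(np.int8)
        rows = []
        for c in range(cfg.n_chromosomes):
            chrom = str(c + 1)
            for j in range(cfg.blocks_per_chr * spb):
                bp = 1 + j * cfg.snp_spacing_bp
                rows.append((f"snp{chrom}_{j:05d}", chrom, bp, "A", "B"))
        self.snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "bp", "a1", "a2"])

    def draw_calls(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw genotype calls (copies of allele a2) for ``n`` individuals."""
        cfg = self.cfg
        k = cfg.founder_haplotypes_per_block
        spb = cfg.snps_per_block
        calls = np.empty((n, cfg.n_snps), dtype=np.int8)
        b = 0
        for _c in range(cfg.n_chromosomes):
            idx = rng.integers(0, k, size=(n, 2))
            for j in range(cfg.blocks_per_chr):
                if j > 0:
                    redraw = rng.random((n, 2)) < cfg.recomb_prob
                    fresh = rng.integers(0, k, size=(n, 2))
                    idx = np.where(redraw, fresh, idx)
                haps = self.haplotypes[b]  # (k, spb)
                block = haps[idx[:, 0]] + haps[idx[:, 1]]
                calls[:, b * spb : (b + 1) * spb] = block
                b += 1
        return calls


def _make_samples(ids: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(ids),
            "founder": True,
            "sex": rng.integers(1, 3, size=len(ids)),
        }
    )


def simulate_genotypes(cfg: SimConfig, n_samples: Optional[int] = None) -> GenotypeMatrix:
    """Generate a genotype matrix from the haplotype-pool block model.

    ``n_samples`` overrides ``cfg.n_samples`` (used internally by the
    rejection sampler).  Opt-in artifact injections (missingness, duplicate
    samples, a frequency-shifted cluster) are applied here when configured.
    """
    n = cfg.n_samples if n_samples is None else n_samples
    pop = Population(cfg)
    rng = np.random.default_rng(derive_seed(cfg.seed, "individuals"))
    calls = pop.draw_calls(n, rng)
    samples = _make_samples([f"S{i:06d}" for i in range(n)], rng)
    g = GenotypeMatrix(calls, pop.snp_map.copy(), samples)
    return inject_artifacts(g, cfg, np.random.default_rng(derive_seed(cfg.seed, "inject")))


def inject_artifacts(
    g: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Apply the opt-in QC violations: duplicates, shifted cluster, missingness."""
    calls, samples = g.calls, g.samples
    if cfg.n_duplicates:
        k = min(cfg.n_duplicates, len(samples))
        dup_calls = calls[:k].copy()
        dup_samples = samples.iloc[:k].copy()
        dup_samples["sample_id"] = [f"DUP{i:04d}" for i in range(k)]
        dup_samples["founder"] = False
        calls = np.vstack([calls, dup_calls])
        samples = pd.concat([samples, dup_samples], ignore_index=True)
    if cfg.shifted_cluster is not None:
        n_shift, shift = cfg.shifted_cluster
        f = GenotypeMatrix(calls, g.snp_map, samples).freq_a2()
        f_shift = np.clip(np.nan_to_num(f, nan=0.5) + shift, 0.02, 0.98)
        shift_calls = rng.binomial(2, f_shift, size=(n_shift, calls.shape[1])).astype(
            np.int8
        )
        shift_samples = pd.DataFrame(
            {
                "sample_id": [f"SHIFT{i:04d}" for i in range(n_shift)],
                "founder": True,
                "sex": rng.integers(1, 3, size=n_shift),
            }
        )
        calls = np.vstack([calls, shift_calls])
        samples = pd.concat([samples, shift_samples], ignore_index=True)
    if cfg.missing_rate > 0:
        calls = calls.copy()
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    return GenotypeMatrix(calls, g.snp_map.copy(), samples.reset_index(drop=True))


def _encode_raw(calls: np.ndarray, model: str) -> np.ndarray:
    """Model coding of raw a2 dosage for the phenotype model (missing -> 0)."""
    d = np.maximum(calls, 0).astype(np.float64)
    if model == "additive":
        return d
    if model == "recessive":
        return (d == 2).astype(np.float64)
    return (d >= 1).astype(np.float64)


def simulate_phenotype(
    g: GenotypeMatrix, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Latent gestational-age phenotype with delivery-onset / genome strata.

    This is the raw generative model (no range selection):
    ``GA = baseline + sum of model-coded causal effects + N(0, noise_sd)``,
    rounded to integer days.  Range-quota selection lives in
    :func:`simulate_cohort`.
    """
    if rng is None:
        rng = np.random.default_rng(derive_seed(cfg.seed, "phenotype"))
    ga = np.full(g.n_samples, float(cfg.baseline_ga))
    for idx, model, eff in cfg.causal_spec:
        ga += eff * _encode_raw(g.calls[:, idx], model)
    ga += rng.normal(0.0, cfg.noise_sd, size=g.n_samples)
    ga = np.rint(ga).astype(int)
    p_mother, p_labor = cfg.strata_props
    genome = np.where(rng.random(g.n_samples) < p_mother, "mother", "child")
    onset = np.where(rng.random(g.n_samples) < p_labor, "labor", "PROM")
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "ga_days": ga,
            "onset": onset,
            "genome": genome,
        }
    )


MAX_OVERSAMPLE = 100  # rejection-sampling retry cap, in multiples of n_samples


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the case-oversampled cohort by rejection sampling.

    Individuals are drawn from the population (genotype + latent phenotype)
    and kept while the gestational-age window containing them still needs
    members; generation stops when every window holds its configured count.
    Raises :class:`SimulationError` when ``MAX_OVERSAMPLE * n_samples``
    individuals were generated without filling the quotas.
    """
    pop = Population(cfg)
    rng = np.random.default_rng(derive_seed(cfg.seed, "individuals"))
    needed = list(cfg.range_counts)
    ranges = cfg.sampling_ranges
    kept_calls: list[np.ndarray] = []
    kept_pheno: list[pd.DataFrame] = []
    total = 0
    batch = max(256, cfg.n_samples)
    while sum(needed) > 0:
        if total >= MAX_OVERSAMPLE * cfg.n_samples:
            raise SimulationError(
                f"range targets unattained after {total} simulated individuals; "
                f"still needed per range: {needed}"
            )
        calls = pop.draw_calls(batch, rng)
        gb = GenotypeMatrix(
            calls, pop.snp_map, _make_samples([f"tmp{i}" for i in range(batch)], rng)
        )
        ph = simulate_phenotype(gb, cfg, rng)
        total += batch
        ga = ph["ga_days"].to_numpy()
        take = np.zeros(batch, dtype=bool)
        for r, (lo, hi) in enumerate(ranges):
            if needed[r] <= 0:
                continue
            in_range = np.flatnonzero((ga >= lo) & (ga <= hi) & ~take)
            chosen = in_range[: needed[r]]
            take[chosen] = True
            needed[r] -= len(chosen)
        if take.any():
            kept_calls.append(calls[take])
            kept_pheno.append(ph.loc[take])
    calls = np.vstack(kept_calls)[: cfg.n_samples]
    pheno = pd.concat(kept_pheno, ignore_index=True).iloc[: cfg.n_samples].copy()
    ids = [f"S{i:06d}" for i in range(cfg.n_samples)]
    pheno["sample_id"] = ids
    samples = _make_samples(ids, rng)
    samples["onset"] = pheno["onset"].to_numpy()
    samples["genome"] = pheno["genome"].to_numpy()
    g = GenotypeMatrix(calls, pop.snp_map.copy(), samples)
    g = inject_artifacts(g, cfg, np.random.default_rng(derive_seed(cfg.seed, "inject")))
    if g.n_samples > cfg.n_samples:
        extra = g.samples.iloc[cfg.n_samples :]
        extra_ph = _phenotype_for_extras(extra, pheno, cfg, rng)
        pheno = pd.concat([pheno, extra_ph], ignore_index=True)
    logger.info(
        "cohort assembled: %d kept of %d simulated individuals", cfg.n_samples, total
    )
    return g, pheno


def _phenotype_for_extras(
    extra: pd.DataFrame, pheno: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Phenotypes for injected samples (duplicates copy their source)."""
    rows = []
    by_pos = pheno.reset_index(drop=True)
    p_mother, p_labor = cfg.strata_props
    for sid in extra["sample_id"]:
        if sid.startswith("DUP"):
            src = by_pos.iloc[int(sid[3:])]
            rows.append((sid, int(src["ga_days"]), src["onset"], src["genome"]))
        else:
            lo, hi = cfg.sampling_ranges[
                int(rng.random() >= cfg.range_counts[0] / cfg.n_samples)
            ]
            rows.append(
                (
                    sid,
                    int(rng.integers(lo, hi + 1)),
                    "labor" if rng.random() < p_labor else "PROM",
                    "mother" if rng.random() < p_mother else "child",
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "ga_days", "onset", "genome"])


def auto_causal_spec(
    cfg: SimConfig,
    n_causal: int,
    frac_variance: float,
    model: str = "additive",
) -> list[tuple[int, str, float]]:
    """Plan causal SNPs each explaining ``frac_variance`` of latent variance.

    SNPs are spread over distinct chromosomes (middle of the middle block);
    the per-SNP effect solves ``beta^2 * var(coding) = frac * sigma_tot^2``
    with ``sigma_tot^2 = noise_sd^2 / (1 - n_causal * frac)``, using the
    founder-pool allele frequency for the coding variance under
    Hardy-Weinberg proportions.
    """
    if not 0 < n_causal * frac_variance < 1:
        raise ConfigurationError("total causal variance fraction must be in (0, 1)")
    pop = Population(cfg)
    spb = cfg.snps_per_block
    per_chr = cfg.blocks_per_chr * spb
    sigma2_tot = cfg.noise_sd**2 / (1.0 - n_causal * frac_variance)
    spec = []
    for i in range(n_causal):
        chrom = i % cfg.n_chromosomes
        block_in_chr = (cfg.blocks_per_chr // 2 + i // cfg.n_chromosomes) % cfg.blocks_per_chr
        snp_idx = chrom * per_chr + block_in_chr * spb + spb // 2
        block = chrom * cfg.blocks_per_chr + block_in_chr
        f = float(pop.haplotypes[block, :, snp_idx % spb].mean())
        f = min(max(f, 0.02), 0.98)
        if model == "additive":
            var = 2 * f * (1 - f)
        elif model == "recessive":
            q = f**2
            var = q * (1 - q)
        else:
            q = 1 - (1 - f) ** 2
            var = q * (1 - q)
        beta = float(np.sqrt(frac_variance * sigma2_tot / var))
        spec.append((snp_idx, model, -beta))
    return spec


# -- annotation and corpus -------------------------------------------------


@dataclass
class CorpusSpec:
    """Shape of the synthetic abstract corpus.

    ``n_true_abstracts`` abstracts are generated per (keyword, gene) pair —
    at least 2 so genes pass the more-than-one-abstract filter — and
    ``n_trap_abstracts`` per trap kind.  Every generated abstract carries its
    intended ground-truth classification in a ``label`` field.
    """

    n_true_abstracts: int = 2
    n_trap_abstracts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_abstracts < 2:
            raise ConfigurationError(
                "n_true_abstracts must be >= 2 (the >1-abstract filter)"
            )


TRAP_KINDS = (
    "nonhuman",
    "condition",
    "acronym_collision",
    "single_mention",
    "multi_keyword",
)


@dataclass
class SyntheticAnnotation:
    """Gene map, gene sets, corpus and mining config emitted together."""

    gene_map: pd.DataFrame
    gene_sets: GeneSetCollection
    truth_set_name: str
    keywords: list[KeywordSpec]
    filters: MiningFilters
    abstracts: list[dict]
    labels: pd.DataFrame


def simulate_annotation_and_corpus(
    cfg: SimConfig,
    corpus: Optional[CorpusSpec] = None,
    gene_length: int = 10_000,
    gene_gap: int = 2_500,
    truth_set_size: Optional[int] = None,
    null_set_size_range: Optional[tuple[int, int]] = None,
) -> SyntheticAnnotation:
    """Tile genes over the synthetic genome and build gene sets (+ corpus).

    The first candidate keyword's set is the designated truth set: it contains
    every gene overlapping a planted causal SNP.  When ``corpus`` is given, a
    labelled abstract corpus is generated whose exact mining result equals the
    emitted gene sets.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "annotation"))
    pop = Population(cfg)
    snp_map = pop.snp_map

    gene_rows: list[list] = []
    gidx = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        span_end = int(grp["bp"].max()) + cfg.snp_spacing_bp
        pos = 1
        while pos <= span_end:
            gene_rows.append([f"GX{gidx:04d}", chrom, pos, pos + gene_length - 1])
            gidx += 1
            pos += gene_length + gene_gap
    gene_map = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    max_genes = len(gene_map)
    if null_set_size_range is None:
        # null sets sized so a target interval lands near a set gene with
        # mid-range probability, giving null interval-hit counts wide
        # support (4-8% of genes)
        null_set_size_range = (
            max(3, min(round(0.04 * max_genes), max_genes - 4)),
            max(4, min(round(0.08 * max_genes), max_genes - 4)),
        )
    if truth_set_size is None:
        # small relative to the nulls: its null hit-probability stays low
        # while the planted causal genes drive the observed statistic
        truth_set_size = max(5, min(round(0.015 * max_genes), max_genes - 4))
    if truth_set_size > max_genes - 4 or null_set_size_range[1] > max_genes - 4:
        raise ConfigurationError(
            f"gene-set sizes exceed the {max_genes - 4} poolable genes the "
            f"genome span allows"
        )

    # guarantee every causal SNP sits inside a gene: extend the nearest
    # upstream gene over gap-dwelling causal positions
    causal_genes: list[str] = []
    for idx, _model, _eff in cfg.causal_spec:
        chrom = snp_map["chrom"].iloc[idx]
        bp = int(snp_map["bp"].iloc[idx])
        on_chr = gene_map[gene_map["chrom"] == chrom]
        inside = on_chr[(on_chr["start"] <= bp) & (on_chr["end"] >= bp)]
        if len(inside):
            causal_genes.append(inside["gene"].iloc[0])
            continue
        upstream = on_chr[on_chr["start"] <= bp]
        row = upstream.index[-1]
        gene_map.loc[row, "end"] = bp
        causal_genes.append(gene_map.loc[row, "gene"])
    causal_genes = list(dict.fromkeys(causal_genes))

    all_genes = gene_map["gene"].to_numpy()
    # reserve a few non-causal genes as dedicated trap symbols: they never
    # enter any set, so a failed corpus filter is visible as a spurious gene
    reserved = [g for g in all_genes[::-1] if g not in causal_genes][:4]
    poolable = np.array([g for g in all_genes if g not in reserved])
    keywords = list(DEFAULT_KEYWORDS)
    candidate_names = [k.name for k in keywords if k.klass.startswith(("pregnancy", "female", "fetal"))]
    truth_name = candidate_names[0]
    sets = GeneSetCollection()
    pad = [g for g in poolable if g not in causal_genes]
    extra = rng.choice(pad, size=max(0, truth_set_size - len(causal_genes)), replace=False)
    sets.add(truth_name, [*causal_genes, *extra], "designated truth set")
    lo, hi = null_set_size_range
    for kw in keywords:
        if kw.name == truth_name:
            continue
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(poolable, size=size, replace=False)
        sets.add(kw.name, members, f"{kw.klass} null-analog set")

    filters = MiningFilters(
        hgnc_symbols=frozenset(all_genes) | {"SPTB"},
        nonhuman_indicators=DEFAULT_NONHUMAN_INDICATORS,
        condition_indicators=DEFAULT_CONDITION_INDICATORS,
        acronym_blacklist=dict(DEFAULT_ACRONYM_BLACKLIST),
    )

    abstracts: list[dict] = []
    labels: list[dict] = []
    if corpus is not None:
        abstracts, labels = _build_corpus(
            sets, keywords, corpus, all_genes, rng
        )
    return SyntheticAnnotation(
        gene_map=gene_map,
        gene_sets=sets,
        truth_set_name=truth_name,
        keywords=keywords,
        filters=filters,
        abstracts=abstracts,
        labels=pd.DataFrame(labels),
    )


def _abstract(aid: int, title: str, text: str, label: dict) -> dict:
    return {
        "id": f"A{aid:06d}",
        "title": title,
        "abstract": text,
        "mesh_terms": [],
        "label": label,
    }


def _build_corpus(
    sets: GeneSetCollection,
    keywords: list[KeywordSpec],
    spec: CorpusSpec,
    all_genes: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict]]:
    by_name = {k.name: k for k in keywords}
    abstracts: list[dict] = []
    labels: list[dict] = []
    aid = 0

    def emit(title, text, label):
        nonlocal aid
        abstracts.append(_abstract(aid, title, text, label))
        labels.append({"id": f"A{aid:06d}", **label})
        aid += 1

    for name, genes in sets.sets.items():
        term = by_name[name].terms[0]
        for gene in genes:
            for rep in range(spec.n_true_abstracts):
                emit(
                    f"Genetic study of {term} biology ({rep + 1})",
                    f"We analysed the gene {gene} in {term} material donated by "
                    f"volunteers. Variation in {gene} reached significance.",
                    {"kind": "true", "keyword": name, "genes": [gene], "kept": True,
                     "drop_reason": ""},
                )

    # trap genes: symbols deliberately outside every truth set
    in_sets = set().union(*sets.sets.values()) if sets.sets else set()
    spare = [g for g in all_genes if g not in in_sets]
    if len(spare) < 4:
        raise ConfigurationError("need >= 4 genes outside all sets for trap abstracts")
    trap_gene = dict(zip(("nonhuman", "condition", "multi_keyword", "single_mention"), spare))
    non_exempt = [k for k in keywords if not k.exclusivity_exempt]
    kw_a, kw_b = non_exempt[0], non_exempt[1]

    for _rep in range(spec.n_trap_abstracts):
        g = trap_gene["nonhuman"]
        emit(
            f"Genetic study of {kw_a.terms[0]} biology in cattle",
            f"The gene {g} was analysed in bovine {kw_a.terms[0]} material.",
            {"kind": "trap_nonhuman", "keyword": kw_a.name, "genes": [g],
             "kept": False, "drop_reason": "nonhuman"},
        )
        g = trap_gene["condition"]
        emit(
            f"Genetic study of {kw_a.terms[0]} biology under listeriosis",
            f"The gene {g} was analysed in {kw_a.terms[0]} material from "
            f"listeriosis patients.",
            {"kind": "trap_condition", "keyword": kw_a.name, "genes": [g],
             "kept": False, "drop_reason": "condition"},
        )
        emit(
            "Genetic risk factors for Spontaneous Preterm Birth (SPTB)",
            "SPTB denotes spontaneous preterm birth here; no gene is meant. "
            "Candidate gene panels were screened.",
            {"kind": "trap_acronym", "keyword": "preterm", "genes": [],
             "kept": True, "drop_reason": "blacklisted mention only"},
        )
        g = trap_gene["multi_keyword"]
        emit(
            f"Genetic study across {kw_a.terms[0]} and {kw_b.terms[0]} tissue",
            f"The gene {g} was analysed in both {kw_a.terms[0]} and "
            f"{kw_b.terms[0]} material.",
            {"kind": "trap_multi_keyword", "keyword": "", "genes": [g],
             "kept": False, "drop_reason": "exclusivity"},
        )
    # single-mention trap: exactly one abstract in the whole corpus
    g = trap_gene["single_mention"]
    emit(
        f"Genetic study of {kw_a.terms[0]} biology, isolated report",
        f"A single report linked the gene {g} to {kw_a.terms[0]} material.",
        {"kind": "trap_single_mention", "keyword": kw_a.name, "genes": [g],
         "kept": True, "drop_reason": "below abstract-count threshold"},
    )
    order = rng.permutation(len(abstracts))
    return [abstracts[i] for i in order], [labels[i] for i in order]
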
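"""Orchestration of the six stratified analyses and report surfaces.

A run executes: synthetic cohort generation (or loading of user inputs) ->
QC -> per-stratum association (mother/child x labor/PROM/all) -> clumping ->
enrichment against mined + control gene-sets -> overlap report and
Manhattan-plot data tables.  Every stage seed derives deterministically from
the global seed plus stage/stratum labels, outputs are stamped with the
config hash, and re-running the same config reproduces all tables
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed, logger
from .association import AssociationResult, PermutationParams, adaptive_permutation
from .clumping import Clump, ClumpParams, clump, clumps_to_frame
from .datatypes import ConfigurationError
from .enrichment import EnrichmentParams, enrichment_test, prepare_intervals
from .fileio import (
    read_gene_map,
    read_gmt,
    read_pedmap,
    read_phenotype,
    write_gene_map_bed,
    write_gmt,
    write_pedmap,
    write_phenotype,
    write_table,
)
from .mining import build_gene_sets
from .qc import QCParams, genomic_inflation, run_qc
from .simulate import CorpusSpec, SimConfig, simulate_annotation_and_corpus, simulate_cohort

GENOMES = ("mother", "child")
ONSETS = ("labor", "PROM", "all")
ALL_STRATA = tuple((g, o) for g in GENOMES for o in ONSETS)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "gagwas_run"
    # either simulate (sim is not None) or load from paths
    sim: Optional[SimConfig] = field(default_factory=SimConfig)
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    pheno_path: Optional[str] = None
    gene_map_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    qc: QCParams = field(default_factory=QCParams)
    perm: PermutationParams = field(default_factory=PermutationParams)
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    enrich: EnrichmentParams = field(default_factory=EnrichmentParams)
    strata: tuple = ALL_STRATA
    top_k_overlap: int = 1_000
    mine_corpus: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if kwargs.get("sim") is not None:
            sim = dict(kwargs["sim"])
            for key in ("maf_range", "strata_props", "sampling_ranges", "range_counts",
                        "shifted_cluster"):
                if sim.get(key) is not None:
                    val = sim[key]
                    sim[key] = tuple(
                        tuple(v) if isinstance(v, (list, tuple)) else v for v in val
                    )
            if sim.get("causal_spec"):
                sim["causal_spec"] = [tuple(t) for t in sim["causal_spec"]]
            kwargs["sim"] = SimConfig(**sim)
        for name, klass in (("qc", QCParams), ("perm", PermutationParams),
                            ("clump_params", ClumpParams)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = klass(**kwargs[name])
        if isinstance(kwargs.get("enrich"), dict):
            en = dict(kwargs["enrich"])
            for key in ("snp_count_match", "span_match"):
                if key in en:
                    en[key] = tuple(en[key])
            kwargs["enrich"] = EnrichmentParams(**en)
        if "strata" in kwargs:
            kwargs["strata"] = tuple(tuple(s) for s in kwargs["strata"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def stratify_samples(pheno: pd.DataFrame, stratum: tuple[str, str]) -> list[str]:
    """Sample ids of one (genome, onset) stratum; onset "all" = labor + PROM."""
    genome, onset = stratum
    if genome not in GENOMES or onset not in ONSETS:
        raise ConfigurationError(f"unknown stratum {stratum!r}")
    sel = pheno["genome"] == genome
    if onset != "all":
        sel &= pheno["onset"] == onset
    ids = pheno.loc[sel, "sample_id"].tolist()
    logger.info("stratum %s/%s: %d samples", genome, onset, len(ids))
    return ids


def overlap_report(
    ranked_lists: dict[str, Sequence[str]], k: int
) -> pd.DataFrame:
    """Venn-region counts among the three onset strata of one genome type.

    ``ranked_lists`` maps onset label -> ranked SNP ids; the top ``k`` of
    each list feed exact set intersections.  Lists shorter than ``k`` are
    used in full (logged).
    """
    tops = {}
    for name, lst in ranked_lists.items():
        if len(lst) < k:
            logger.info("overlap list %r has only %d < %d SNPs", name, len(lst), k)
        tops[name] = set(lst[:k])
    names = sorted(tops)
    rows = []
    for mask in range(1, 2 ** len(names)):
        inc = [names[i] for i in range(len(names)) if mask >> i & 1]
        exc = [n for n in names if n not in inc]
        region = set.intersection(*(tops[n] for n in inc))
        for n in exc:
            region -= tops[n]
        rows.append(("&".join(inc), len(region)))
    return pd.DataFrame(rows, columns=["region", "n_snps"])


@dataclass
class StratumResult:
    stratum: tuple[str, str]
    association: AssociationResult
    clumps: list[Clump]
    enrichment: Optional[pd.DataFrame]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the in-memory report bundle.

    Writes, under ``config.out_dir``: inputs (when simulated), per-stratum
    association/clump/enrichment/Manhattan tables, the QC report, overlap
    report and a JSON run manifest.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    bundle = _run_stages(config, out)
    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "outputs": {
            name: hashlib.sha256(open(os.path.join(out, name), "rb").read()).hexdigest()
            for name in sorted(os.listdir(out))
            if name != "manifest.json" and os.path.isfile(os.path.join(out, name))
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "sim"))
        g, pheno = simulate_cohort(sim)
        corpus_spec = CorpusSpec() if config.mine_corpus else None
        ann = simulate_annotation_and_corpus(sim, corpus=corpus_spec)
        gene_map, gene_sets = ann.gene_map, ann.gene_sets
        if config.mine_corpus:
            gene_sets, _ = build_gene_sets(ann.abstracts, ann.keywords, ann.filters)
        return g, pheno, gene_map, gene_sets, ann
    for name in ("ped_path", "map_path", "pheno_path", "gene_map_path",
                 "gene_sets_path"):
        if getattr(config, name) is None:
            raise ConfigurationError(f"{name} required when sim is disabled")
    g = read_pedmap(config.ped_path, config.map_path)
    pheno = read_phenotype(config.pheno_path)
    g.samples = g.samples.merge(pheno, on="sample_id", how="left")
    g.samples["founder"] = True
    return (
        g,
        pheno,
        read_gene_map(config.gene_map_path),
        read_gmt(config.gene_sets_path),
        None,
    )


def _run_stages(config: RunConfig, out: str) -> dict:
    g, pheno, gene_map, gene_sets, ann = _load_inputs(config)
    if config.sim is not None:
        write_pedmap(g, os.path.join(out, "input.ped"), os.path.join(out, "input.map"))
        write_phenotype(pheno, os.path.join(out, "phenotype.tsv"))
        write_gene_map_bed(gene_map, os.path.join(out, "genes.bed"))
        write_gmt(gene_sets, os.path.join(out, "gene_sets.gmt"))

    qc_params = dataclasses.replace(config.qc, seed=derive_seed(config.seed, "qc"))
    g_qc, qc_report = run_qc(g, qc_params)
    write_table(qc_report.to_frame(), os.path.join(out, "qc_report.tsv"))

    pheno_idx = pheno.set_index("sample_id")
    results: dict[tuple[str, str], StratumResult] = {}
    ranked: dict[str, dict[str, list[str]]] = {gnm: {} for gnm in GENOMES}
    lam = None
    for genome, onset in config.strata:
        tag = f"{genome}_{onset}"
        ids = stratify_samples(pheno, (genome, onset))
        ids = [i for i in ids if i in set(g_qc.sample_ids)]
        if not ids:
            logger.warning("stratum %s empty after QC; skipped", tag)
            continue
        g_s = g_qc.subset_samples(ids)
        y = pheno_idx.loc[ids, "ga_days"].to_numpy(dtype=float)
        perm = dataclasses.replace(
            config.perm, seed=derive_seed(config.seed, "assoc", genome, onset)
        )
        assoc = adaptive_permutation(g_s, y, params=perm)
        write_table(assoc.per_snp, os.path.join(out, f"assoc_{tag}.tsv"))
        if lam is None and genome == "mother" and onset == "labor":
            add = assoc.per_model[assoc.per_model["model"] == "additive"]
            maf = g_s.freq_a2()
            maf = np.minimum(maf, 1 - maf)
            chi2 = add["t_abs"].to_numpy() ** 2
            lam = genomic_inflation(chi2, maf=maf, params=qc_params)
        cl = clump(assoc.per_snp, g_s, config.clump_params)
        write_table(clumps_to_frame(cl), os.path.join(out, f"clumps_{tag}.tsv"))
        enr = None
        if cl:
            en_params = dataclasses.replace(
                config.enrich, seed=derive_seed(config.seed, "enrich", genome, onset)
            )
            intervals = prepare_intervals(cl, gene_map, g_s.snp_map, en_params)
            if intervals:
                enr = enrichment_test(
                    intervals, gene_sets, gene_map, g_s.snp_map, en_params
                )
                write_table(enr, os.path.join(out, f"enrichment_{tag}.tsv"))
        manhattan = assoc.per_snp[["snp", "chrom", "bp", "best_p"]].copy()
        manhattan["neg_log10_p"] = -np.log10(manhattan.pop("best_p"))
        in_clump = {s for c in cl for s in c.members}
        manhattan["in_clump"] = manhattan["snp"].isin(in_clump)
        write_table(manhattan, os.path.join(out, f"manhattan_{tag}.tsv"))
        order = assoc.per_snp.sort_values(
            ["best_p", "chrom", "bp"], kind="mergesort"
        )["snp"].tolist()
        ranked[genome][onset] = order
        results[(genome, onset)] = StratumResult((genome, onset), assoc, cl, enr)

    overlaps = {}
    for genome in GENOMES:
        if len(ranked[genome]) >= 2:
            rep = overlap_report(ranked[genome], config.top_k_overlap)
            overlaps[genome] = rep
            write_table(rep, os.path.join(out, f"overlap_{genome}.tsv"))
    return {
        "genotypes": g_qc,
        "phenotype": pheno,
        "gene_map": gene_map,
        "gene_sets": gene_sets,
        "annotation": ann,
        "qc_report": qc_report,
        "genomic_inflation": lam,
        "strata": results,
        "overlap": overlaps,
    }
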
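"""Core containers and exceptions shared across the pipeline.

The central object is :class:`GenotypeMatrix`: a samples x SNPs matrix of
diploid allele counts together with a SNP map (chromosome, 1-based physical
position, alleles) and per-sample metadata.  Genotype calls count copies of
allele ``a2`` and use ``-1`` for missing.  Gene coordinates are carried in a
plain DataFrame (:func:`validate_gene_map`) in the internal 1-based inclusive
coordinate system; BED input is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: chromosome labels treated as the X chromosome (additive-only association)
X_CHROMS = frozenset({"X", "23", "chrX"})

SNP_MAP_COLUMNS = ("snp", "chrom", "bp", "a1", "a2")
GENE_MAP_COLUMNS = ("gene", "chrom", "start", "end")


class GagwasError(Exception):
    """Base class for package errors."""


class ConfigurationError(GagwasError):
    """Inconsistent or invalid configuration."""


class SimulationError(GagwasError):
    """Simulation could not satisfy its constraints (e.g. range targets)."""


class ParseError(GagwasError):
    """Malformed input file."""


class QCError(GagwasError):
    """Quality control produced an unusable dataset."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with SNP map and sample metadata.

    Parameters
    ----------
    calls
        ``(n_samples, n_snps)`` integer array; entries in ``{0, 1, 2}`` count
        copies of allele ``a2``, ``-1`` marks a missing call.
    snp_map
        DataFrame with columns ``snp, chrom, bp, a1, a2``; ``bp`` is 1-based
        and strictly increasing within each chromosome.
    samples
        DataFrame with at least a unique ``sample_id`` column; optional
        columns include ``founder`` (bool), ``sex``, ``onset``, ``genome``.
    """

    calls: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ConfigurationError("calls must be a 2-D samples x SNPs array")
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.snp_map["chrom"] = self.snp_map["chrom"].astype(str)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, p = self.calls.shape
        if len(self.samples) != n:
            raise ConfigurationError(
                f"sample table has {len(self.samples)} rows for {n} genotype rows"
            )
        if len(self.snp_map) != p:
            raise ConfigurationError(
                f"SNP map has {len(self.snp_map)} rows for {p} genotype columns"
            )
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ConfigurationError(f"SNP map lacks columns {missing_cols}")
        if "sample_id" not in self.samples.columns:
            raise ConfigurationError("sample table lacks a sample_id column")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ConfigurationError("genotype calls outside {-1, 0, 1, 2}")
        if self.snp_map["snp"].duplicated().any():
            dups = self.snp_map.loc[self.snp_map["snp"].duplicated(), "snp"]
            raise ConfigurationError(f"duplicate SNP ids: {sorted(set(dups))[:5]}")
        if self.samples["sample_id"].duplicated().any():
            raise ConfigurationError("duplicate sample ids")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ConfigurationError(
                    f"bp positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic shape ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp"].to_numpy()

    def is_x(self) -> np.ndarray:
        """Boolean per-SNP vector: True for X-chromosome SNPs."""
        return self.snp_map["chrom"].isin(X_CHROMS).to_numpy()

    # -- allele bookkeeping ----------------------------------------------
    def freq_a2(self) -> np.ndarray:
        """Per-SNP frequency of allele ``a2`` among non-missing calls.

        Monomorphic-by-missingness columns (no observed calls) yield NaN.
        """
        c = self.calls
        obs = c != MISSING
        nobs = obs.sum(axis=0)
        tot = np.where(obs, c, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nobs > 0, tot / (2.0 * nobs), np.nan)

    def minor_dosage(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dosage of the minor (effect) allele, with effect/reference alleles.

        Returns ``(dosage, effect_allele, reference_allele)`` where dosage is
        float with NaN for missing calls.  The minor allele is determined from
        the sample frequency; at exactly 0.5 the lexicographically greater
        allele token is used as the effect allele (a fixed, arbitrary but
        deterministic tie-break).
        """
        f = self.freq_a2()
        a1 = self.snp_map["a1"].to_numpy(dtype=object)
        a2 = self.snp_map["a2"].to_numpy(dtype=object)
        tie = np.isclose(f, 0.5)
        # flip when a2 is the major allele, or on ties when a1 > a2
        flip = (f > 0.5) & ~tie
        flip |= tie & (a1 > a2)
        d = self.calls.astype(np.float64)
        d[self.calls == MISSING] = np.nan
        d[:, flip] = 2.0 - d[:, flip]
        eff = np.where(flip, a1, a2)
        ref = np.where(flip, a2, a1)
        return d, eff, ref

    def canonicalize(self) -> "GenotypeMatrix":
        """Return a copy where ``a2`` is the minor allele for every SNP.

        Ties at frequency 0.5 keep the lexicographically greater token as
        ``a2`` so the representation is unique; this is the form emitted by
        the PED/MAP reader.
        """
        f = self.freq_a2()
        a1 = self.snp_map["a1"].to_numpy(dtype=object)
        a2 = self.snp_map["a2"].to_numpy(dtype=object)
        tie = np.isclose(f, 0.5)
        flip = (f > 0.5) & ~tie
        flip |= tie & (a1 > a2)
        calls = self.calls.copy()
        m = calls[:, flip] == MISSING
        calls[:, flip] = 2 - calls[:, flip]
        calls[:, flip] = np.where(m, MISSING, calls[:, flip])
        snp_map = self.snp_map.copy()
        snp_map.loc[flip, ["a1", "a2"]] = snp_map.loc[flip, ["a2", "a1"]].to_numpy()
        return GenotypeMatrix(calls, snp_map, self.samples.copy())

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, keep: Sequence | np.ndarray) -> "GenotypeMatrix":
        """Subset rows; ``keep`` is a boolean mask, index array or id list."""
        idx = _as_row_index(keep, self.samples["sample_id"])
        return GenotypeMatrix(
            self.calls[idx], self.snp_map.copy(), self.samples.iloc[idx].copy()
        )

    def subset_snps(self, keep: Sequence | np.ndarray) -> "GenotypeMatrix":
        idx = _as_row_index(keep, self.snp_map["snp"])
        return GenotypeMatrix(
            self.calls[:, idx], self.snp_map.iloc[idx].copy(), self.samples.copy()
        )

    def founders_mask(self) -> np.ndarray:
        if "founder" in self.samples.columns:
            return self.samples["founder"].to_numpy(dtype=bool)
        return np.ones(self.n_samples, dtype=bool)


def _as_row_index(keep, ids: pd.Series) -> np.ndarray:
    keep = np.asarray(keep)
    if keep.dtype == bool:
        if keep.shape[0] != len(ids):
            raise ConfigurationError("boolean mask length mismatch")
        return np.flatnonzero(keep)
    if np.issubdtype(keep.dtype, np.integer):
        return keep
    pos = pd.Index(ids).get_indexer(keep)
    if (pos < 0).any():
        missing = np.asarray(keep)[pos < 0]
        raise ConfigurationError(f"unknown ids: {list(missing[:5])}")
    return pos


def validate_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table (sample_id, ga_days, onset, genome)."""
    for col in ("sample_id", "ga_days", "onset", "genome"):
        if col not in pheno.columns:
            raise ConfigurationError(f"phenotype table lacks column {col!r}")
    if pheno["sample_id"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in phenotype table")
    if pheno[["onset", "genome"]].isna().any().any():
        raise ConfigurationError("missing onset/genome labels")
    bad_onset = set(pheno["onset"]) - {"labor", "PROM"}
    if bad_onset:
        raise ConfigurationError(f"unknown onset labels {bad_onset}")
    bad_genome = set(pheno["genome"]) - {"mother", "child"}
    if bad_genome:
        raise ConfigurationError(f"unknown genome labels {bad_genome}")
    return pheno


def validate_gene_map(gene_map: pd.DataFrame) -> pd.DataFrame:
    """Check a gene coordinate table (1-based inclusive spans)."""
    for col in GENE_MAP_COLUMNS:
        if col not in gene_map.columns:
            raise ConfigurationError(f"gene map lacks column {col!r}")
    if gene_map["gene"].duplicated().any():
        raise ConfigurationError("duplicate gene names in gene map")
    if (gene_map["end"] < gene_map["start"]).any():
        raise ConfigurationError("gene end < start")
    if (gene_map["start"] < 1).any():
        raise ConfigurationError("gene start < 1 (coordinates are 1-based)")
    gene_map = gene_map.copy()
    gene_map["chrom"] = gene_map["chrom"].astype(str)
    return gene_map


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (GMT semantics): name -> ordered symbol list."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, symbols: Iterable[str], description: str = "") -> None:
        seen: dict[str, None] = {}
        for s in symbols:
            seen.setdefault(s, None)
        self.sets[name] = list(seen)
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: sorted(v) for k, v in self.sets.items()} == {
            k: sorted(v) for k, v in other.sets.items()
        }
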
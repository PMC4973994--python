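"""Readers and writers for the text formats the pipeline exchanges.

Formats
-------
* PLINK text PED/MAP (missing genotype ``0 0``; MAP bp is 1-based).
* Phenotype TSV: ``sample_id  ga_days  onset  genome``.
* Gene map: BED (0-based half-open, name in column 4) or TSV with a header
  (1-based inclusive).  Internally all coordinates are 1-based inclusive.
* GMT gene-set collections (name, description, tab-separated symbols).
* Abstract corpus as JSON-lines with ``id``, ``title``, ``abstract`` and
  optional ``mesh_terms`` / ``label`` fields.
* VCF is supported read-only as an alternate genotype source.

Every writer is paired with a reader and round-trips losslessly; the PED/MAP
reader recovers allele assignment with the canonical minor-allele rule (see
:meth:`gagwas.datatypes.GenotypeMatrix.canonicalize`).
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import numpy as np
import pandas as pd

from ._utils import logger
from .datatypes import (
    MISSING,
    GeneSetCollection,
    GenotypeMatrix,
    ParseError,
    validate_gene_map,
    validate_phenotype,
)

PED_MISSING_ALLELE = "0"

# -- coordinate conversions (BED <-> internal 1-based inclusive) -----------


def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED span to 1-based inclusive."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span to 0-based half-open BED."""
    return start - 1, end


# -- PED / MAP -------------------------------------------------------------


def write_pedmap(g: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    snp_map = g.snp_map
    with open(map_path, "w") as fh:
        for row in snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.bp}\n")
    a1 = snp_map["a1"].to_numpy(dtype=object)
    a2 = snp_map["a2"].to_numpy(dtype=object)
    # per-SNP lookup: call value -> two allele tokens
    lookup = np.empty((len(snp_map), 4), dtype=object)
    for i in range(len(snp_map)):
        het = sorted((a1[i], a2[i]))  # PED carries no phase: canonical order
        lookup[i, 0] = f"{a1[i]} {a1[i]}"
        lookup[i, 1] = f"{het[0]} {het[1]}"
        lookup[i, 2] = f"{a2[i]} {a2[i]}"
    lookup[:, 3] = f"{PED_MISSING_ALLELE} {PED_MISSING_ALLELE}"
    sex_col = g.samples["sex"] if "sex" in g.samples.columns else None
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            sex = str(sex_col.iloc[i]) if sex_col is not None else "0"
            calls = g.calls[i]
            toks = [lookup[j, c if c != MISSING else 3] for j, c in enumerate(calls)]
            fh.write(f"{sid} {sid} 0 0 {sex} -9 " + " ".join(toks) + "\n")


def read_pedmap(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a canonical :class:`GenotypeMatrix`."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) == 4:
                chrom, snp, _cm, bp = parts
            elif len(parts) == 3:
                chrom, snp, bp = parts
            else:
                raise ParseError(f"{map_path}:{lineno}: expected 3 or 4 columns")
            rows.append((snp, chrom, int(bp)))
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "bp"])
    if snp_map["snp"].duplicated().any():
        dup = snp_map.loc[snp_map["snp"].duplicated(), "snp"].iloc[0]
        raise ParseError(f"{map_path}: duplicate SNP id {dup!r}")
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        if np.any(np.diff(grp["bp"].to_numpy()) <= 0):
            raise ParseError(
                f"{map_path}: bp not strictly increasing on chromosome {chrom}"
            )
    p = len(snp_map)

    sample_ids: list[str] = []
    sexes: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * p:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * p} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            sexes.append(parts[4])
            allele_rows.append(np.array(parts[6:], dtype=object))
    n = len(sample_ids)
    calls = np.full((n, p), MISSING, dtype=np.int8)
    a1_out = np.empty(p, dtype=object)
    a2_out = np.empty(p, dtype=object)
    if n:
        alle = np.stack(allele_rows)  # (n, 2p)
        first = alle[:, 0::2]
        second = alle[:, 1::2]
        for j in range(p):
            f, s = first[:, j], second[:, j]
            miss = (f == PED_MISSING_ALLELE) | (s == PED_MISSING_ALLELE)
            if np.any((f == PED_MISSING_ALLELE) != (s == PED_MISSING_ALLELE)):
                bad = int(np.flatnonzero(
                    (f == PED_MISSING_ALLELE) != (s == PED_MISSING_ALLELE))[0])
                raise ParseError(
                    f"{ped_path}: half-missing genotype for SNP "
                    f"{snp_map['snp'].iloc[j]!r}, sample {sample_ids[bad]!r}"
                )
            observed = sorted(set(f[~miss]) | set(s[~miss]))
            if len(observed) > 2:
                raise ParseError(
                    f"{ped_path}: >2 alleles for SNP {snp_map['snp'].iloc[j]!r}"
                )
            if not observed:
                a1_out[j], a2_out[j] = PED_MISSING_ALLELE, PED_MISSING_ALLELE
                continue
            if len(observed) == 1:
                # monomorphic: the absent allele is unknowable from PED
                a1_out[j], a2_out[j] = observed[0], PED_MISSING_ALLELE
                calls[~miss, j] = 0
                continue
            x, y = observed
            dosage_y = (f == y).astype(np.int8) + (s == y).astype(np.int8)
            freq_y = dosage_y[~miss].mean() / 2.0
            # canonical rule: a2 = minor allele; lexicographically greater on ties
            if freq_y < 0.5 or (freq_y == 0.5 and y > x):
                a1_out[j], a2_out[j] = x, y
                calls[~miss, j] = dosage_y[~miss]
            else:
                a1_out[j], a2_out[j] = y, x
                calls[~miss, j] = 2 - dosage_y[~miss]
    snp_map["a1"] = a1_out
    snp_map["a2"] = a2_out
    samples = pd.DataFrame({"sample_id": sample_ids, "sex": sexes})
    return GenotypeMatrix(calls, snp_map[["snp", "chrom", "bp", "a1", "a2"]], samples)


# -- VCF (read-only alternate genotype source) -----------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a (plain-text) VCF via pysam."""
    import pysam

    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    rows, calls = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        row = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, s in enumerate(sample_ids):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            row[i] = sum(gt)
        snp = rec.id or f"{rec.chrom}:{rec.pos}"
        rows.append((snp, str(rec.chrom), rec.pos, ref, alt))
        calls.append(row)
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "bp", "a1", "a2"])
    calls_arr = (
        np.stack(calls, axis=1) if calls else np.empty((len(sample_ids), 0), np.int8)
    )
    samples = pd.DataFrame({"sample_id": sample_ids})
    return GenotypeMatrix(calls_arr, snp_map, samples)


# -- phenotype TSV ---------------------------------------------------------


def write_phenotype(pheno: pd.DataFrame, path: str) -> None:
    validate_phenotype(pheno)
    pheno[["sample_id", "ga_days", "onset", "genome"]].to_csv(
        path, sep="\t", index=False
    )


def read_phenotype(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_phenotype(pheno)


# -- GMT -------------------------------------------------------------------


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, symbols in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *symbols]) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    out = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
            name, desc, *symbols = parts
            symbols = [s for s in symbols if s]
            uniq: dict[str, None] = {}
            for s in symbols:
                if s in uniq:
                    logger.warning("GMT set %r: duplicate symbol %r dropped", name, s)
                uniq.setdefault(s, None)
            if not uniq:
                logger.warning("GMT set %r is empty; retained as size-0 set", name)
            out.add(name, uniq, desc)
    return out


# -- gene map (BED or TSV) -------------------------------------------------


def write_gene_map_bed(gene_map: pd.DataFrame, path: str) -> None:
    gene_map = validate_gene_map(gene_map)
    with open(path, "w") as fh:
        for row in gene_map.itertuples(index=False):
            start0, end0 = internal_to_bed(int(row.start), int(row.end))
            fh.write(f"{row.chrom}\t{start0}\t{end0}\t{row.gene}\n")


def read_gene_map(path: str) -> pd.DataFrame:
    """Read gene coordinates from BED (no header) or TSV (with header).

    A file whose first line starts with the ``gene`` header is treated as a
    1-based inclusive TSV; anything else as 4-column BED.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0].strip().lower() == "gene":
        df = pd.read_csv(path, sep="\t")
        return validate_gene_map(df[["gene", "chrom", "start", "end"]])
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            chrom, s, e, name = parts[0], int(parts[1]), int(parts[2]), parts[3].strip()
            start, end = bed_to_internal(s, e)
            rows.append((name, chrom, start, end))
    return validate_gene_map(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


# -- abstract corpus (JSON lines) ------------------------------------------


def write_corpus(abstracts: Iterable[dict], path: str) -> None:
    with open(path, "w") as fh:
        for rec in abstracts:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_corpus(path: str) -> list[dict]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            for col in ("id", "title", "abstract"):
                if col not in rec:
                    rid = rec.get("id", f"line {lineno}")
                    raise ParseError(f"{path}: record {rid}: missing field {col!r}")
            rec.setdefault("mesh_terms", [])
            out.append(rec)
    return out


# -- generic result tables -------------------------------------------------


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with stable float formatting."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
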
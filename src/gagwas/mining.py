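"""Keyword-specific gene-set construction from an abstract corpus.

The procedure mirrors a date-bounded literature snapshot workflow: an
abstract enters a keyword's pool when it contains a keyword term AND a
genetics term, and contains neither non-human subject indicators nor medical
condition indicators.  Gene symbols are recognised by cross-referencing
capitalised tokens against an HGNC-style symbol list, with an acronym
blacklist suppressing symbols that double as domain acronyms (e.g. SPTB next
to "spontaneous preterm birth").  Genes mentioned in more than one pooled
abstract form the keyword's gene set; a non-exempt keyword's pool excludes
abstracts that also match another non-exempt keyword (exclusivity filter).

No network access is involved: the corpus is a local list of records with
``title``, ``abstract`` and optional ``mesh_terms``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._utils import logger
from .datatypes import GeneSetCollection

# tokens keep internal hyphens ("toll-like" is one token)
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class KeywordSpec:
    """A mining keyword: name, term variants, class, exclusivity exemption."""

    name: str
    terms: tuple[str, ...]
    klass: str = "pregnancy-condition"
    exclusivity_exempt: bool = False

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"keyword {self.name!r} has an empty term list")


@dataclass
class MiningFilters:
    """Vocabulary filters applied while pooling abstracts and mining symbols.

    All matching is case-insensitive except gene-symbol matching (see
    :func:`extract_gene_mentions`).
    """

    hgnc_symbols: frozenset[str]
    genetic_terms: frozenset[str] = frozenset(
        {"gene", "genes", "genomic", "genetic", "gwas"}
    )
    nonhuman_indicators: frozenset[str] = frozenset()
    condition_indicators: frozenset[str] = frozenset()
    disease_suffixes: tuple[str, ...] = ("osis", "itis", "emia", "oma")
    acronym_blacklist: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    min_abstracts_per_gene: int = 2

    def __post_init__(self) -> None:
        self.hgnc_symbols = frozenset(self.hgnc_symbols)
        self._hgnc_upper = {s.upper(): s for s in self.hgnc_symbols}


def build_condition_blacklist(
    vocabulary_terms: Iterable[str],
    suffixes: Iterable[str] = ("osis", "itis", "emia", "oma"),
    allowlist: Iterable[str] = (),
    min_length: int = 5,
) -> frozenset[str]:
    """Mine condition-indicator words from free-text vocabulary descriptions.

    Returns the deduplicated lowercase words of length >= ``min_length``
    ending in one of the disease ``suffixes``, minus the ``allowlist`` (words
    like "diagnosis" that carry a suffix without naming a condition).
    """
    suffixes = tuple(s.lstrip("-").lower() for s in suffixes)
    allow = {w.lower() for w in allowlist}
    out: set[str] = set()
    n_terms = 0
    for term in vocabulary_terms:
        n_terms += 1
        for tok in tokenize(term.lower()):
            if len(tok) >= min_length and tok.endswith(suffixes) and tok not in allow:
                out.add(tok)
    if n_terms == 0:
        logger.warning("empty vocabulary: condition blacklist is empty")
    return frozenset(out)


def _abstract_text(abstract: Mapping) -> str:
    return f"{abstract.get('title', '')} {abstract.get('abstract', '')}"


def match_abstract(
    abstract: Mapping, keyword: KeywordSpec, filters: MiningFilters
) -> tuple[bool, str]:
    """Decide whether an abstract enters a keyword's pool.

    Returns ``(True, "")`` on a match, else ``(False, reason)`` where the
    reason names the first failed clause: ``no-keyword``, ``not-genetic``,
    ``nonhuman`` or ``condition``.
    """
    text = _abstract_text(abstract)
    toks = {t.lower() for t in tokenize(text)}
    mesh = {t.lower() for m in abstract.get("mesh_terms", ()) for t in tokenize(m)}
    if not toks.intersection(t.lower() for t in keyword.terms):
        return False, "no-keyword"
    if not (toks | mesh) & filters.genetic_terms:
        return False, "not-genetic"
    hit = toks & filters.nonhuman_indicators
    if hit:
        return False, "nonhuman"
    hit = toks & filters.condition_indicators
    if hit:
        return False, "condition"
    return True, ""


def extract_gene_mentions(abstract: Mapping, filters: MiningFilters) -> set[str]:
    """Gene symbols mentioned in an abstract.

    A token is a mention when it equals a known symbol case-sensitively, or
    when it is all-uppercase (length >= 2) and equals a symbol
    case-insensitively.  Blacklisted symbols are suppressed when any of
    their forbidden context phrases co-occurs in the abstract.
    """
    text = _abstract_text(abstract)
    lowered = text.lower()
    found: set[str] = set()
    for tok in tokenize(text):
        if tok in filters.hgnc_symbols:
            found.add(tok)
        elif len(tok) >= 2 and tok.isupper():
            sym = filters._hgnc_upper.get(tok)
            if sym is not None:
                found.add(sym)
    for sym in list(found):
        phrases = filters.acronym_blacklist.get(sym)
        if phrases and any(p.lower() in lowered for p in phrases):
            found.discard(sym)
    return found


def build_gene_sets(
    corpus: Iterable[Mapping],
    keywords: Iterable[KeywordSpec],
    filters: MiningFilters,
    evidence: bool = True,
) -> tuple[GeneSetCollection, Optional[pd.DataFrame]]:
    """Build one gene set per keyword from a local abstract corpus.

    For every keyword the matched abstracts are pooled; an abstract leaves a
    non-exempt keyword's pool when it also matches at least one other
    non-exempt keyword.  Genes appearing in more than
    ``min_abstracts_per_gene - 1`` pooled abstracts form the set.  Returns the
    collection plus a per-(keyword, gene) evidence table of abstract ids.
    """
    keywords = list(keywords)
    corpus = list(corpus)
    non_exempt = [k for k in keywords if not k.exclusivity_exempt]
    # abstract x keyword match matrix
    matches: dict[str, set[int]] = {k.name: set() for k in keywords}
    for i, rec in enumerate(corpus):
        for k in keywords:
            ok, _ = match_abstract(rec, k, filters)
            if ok:
                matches[k.name].add(i)
    n_nonexempt_matches = [0] * len(corpus)
    for k in non_exempt:
        for i in matches[k.name]:
            n_nonexempt_matches[i] += 1

    mentions_cache: dict[int, set[str]] = {}

    def mentions(i: int) -> set[str]:
        if i not in mentions_cache:
            mentions_cache[i] = extract_gene_mentions(corpus[i], filters)
        return mentions_cache[i]

    collection = GeneSetCollection()
    rows = []
    for k in keywords:
        pool = sorted(matches[k.name])
        if not k.exclusivity_exempt:
            pool = [i for i in pool if n_nonexempt_matches[i] <= 1]
        if not pool:
            logger.warning("keyword %r matched no abstracts; empty set", k.name)
            collection.add(k.name, [], f"{k.klass}; 0 abstracts")
            continue
        counts: dict[str, list[str]] = {}
        for i in pool:
            for g in sorted(mentions(i)):
                counts.setdefault(g, []).append(str(corpus[i].get("id", i)))
        kept = sorted(
            g for g, ids in counts.items() if len(ids) >= filters.min_abstracts_per_gene
        )
        collection.add(k.name, kept, f"{k.klass}; {len(pool)} abstracts")
        if evidence:
            for g in kept:
                rows.append((k.name, g, len(counts[g]), ",".join(counts[g])))
    ev = (
        pd.DataFrame(rows, columns=["keyword", "gene", "n_abstracts", "abstract_ids"])
        if evidence
        else None
    )
    return collection, ev
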
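"""Resolve a search term to a set of PMIDs via a pluggable backend.

The shipped backend is a local inverted index over a small document-term
corpus (TSV of PMID, term rows), so the whole pipeline runs offline.  A
thin adapter for the NCBI E-utilities E-search API implements the same
protocol for live use; it is never exercised by default code paths.

Query semantics: include terms are intersected (logical AND) and the
union of exclude-term postings is subtracted.  Matching is exact on
normalized (lowercased, stripped) strings; retrieval semantics such as
MeSH expansion are delegated to the backend and not emulated locally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from drugmine.rif_store import RifFormatError, _open_text

logger = logging.getLogger(__name__)


def normalize_term(term: str) -> str:
    return term.strip().lower()


@dataclass(frozen=True)
class TermQuery:
    """A search query: AND-combined include terms plus optional exclusions."""

    include_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "include_terms", tuple(normalize_term(t) for t in self.include_terms)
        )
        object.__setattr__(
            self, "exclude_terms", tuple(normalize_term(t) for t in self.exclude_terms)
        )
        if not self.include_terms:
            raise ValueError("include_terms must have at least one element")


class SearchBackend(Protocol):
    """Anything that maps a normalized term to a set of PMIDs."""

    def pmids(self, term: str) -> frozenset[int]: ...


@dataclass(frozen=True)
class CorpusIndex:
    """Inverted index term -> {PMID} over a local corpus."""

    postings: dict[str, frozenset[int]] = field(default_factory=dict)

    def pmids(self, term: str) -> frozenset[int]:
        return self.postings.get(normalize_term(term), frozenset())

    @property
    def terms(self) -> list[str]:
        return sorted(self.postings)

    @classmethod
    def from_pairs(cls, pairs) -> "CorpusIndex":
        acc: dict[str, set[int]] = {}
        for pmid, term in pairs:
            pmid = int(pmid)
            if pmid <= 0:
                raise ValueError(f"non-positive PMID {pmid} in corpus pair")
            acc.setdefault(normalize_term(str(term)), set()).add(pmid)
        return cls(postings={t: frozenset(s) for t, s in acc.items()})


def read_corpus(path: str | Path) -> CorpusIndex:
    """Read a corpus TSV (columns PMID, term; optional header) into an index."""
    pairs: list[tuple[int, str]] = []
    with _open_text(path) as fh:
        first_data_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RifFormatError(
                    f"{path}: line {lineno}: expected >= 2 tab-separated fields"
                )
            pmid_s, term = fields[0].strip(), fields[1]
            if not first_data_seen:
                first_data_seen = True
                if not pmid_s.isdigit():
                    continue  # header
            if not pmid_s.isdigit():
                raise RifFormatError(
                    f"{path}: line {lineno}: PMID {pmid_s!r} is not a positive integer"
                )
            if not term.strip():
                raise RifFormatError(f"{path}: line {lineno}: empty term")
            pairs.append((int(pmid_s), term))
    return CorpusIndex.from_pairs(pairs)


def write_corpus(index: CorpusIndex, path: str | Path, header: bool = True) -> None:
    """Write a corpus index back to TSV in sorted (term, PMID) order."""
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("PMID\tterm\n")
        for term in index.terms:
            for pmid in sorted(index.postings[term]):
                fh.write(f"{pmid}\t{term}\n")


def query_pmids(query: TermQuery, index: SearchBackend) -> frozenset[int]:
    """Evaluate a :class:`TermQuery` against a backend.

    Returns the intersection of include-term postings minus the union of
    exclude-term postings.  Unknown terms contribute empty postings.
    """
    result: frozenset[int] | None = None
    for term in query.include_terms:
        postings = index.pmids(term)
        result = postings if result is None else result & postings
    assert result is not None  # include_terms is nonempty by construction
    for term in query.exclude_terms:
        result = result - index.pmids(term)
    return result


class ESearchBackend:
    """Live PubMed E-search adapter implementing :class:`SearchBackend`.

    Uses only the standard library; intended for interactive use, not for
    tests or default pipelines (which stay offline on :class:`CorpusIndex`).
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

    def __init__(self, retmax: int = 100_000, timeout: float = 30.0) -> None:
        self.retmax = retmax
        self.timeout = timeout

    def pmids(self, term: str) -> frozenset[int]:  # pragma: no cover - network
        import json
        import urllib.parse
        import urllib.request

        params = urllib.parse.urlencode(
            {"db": "pubmed", "term": term, "retmode": "json", "retmax": self.retmax}
        )
        with urllib.request.urlopen(f"{self.BASE}?{params}", timeout=self.timeout) as r:
            payload = json.load(r)
        return frozenset(int(p) for p in payload["esearchresult"]["idlist"])
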
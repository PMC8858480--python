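"""Drug -> PMID association tables ("RIF" tables, References Into Function).

A RIF table maps each small-molecule name to the set of PubMed identifiers
(PMIDs) of publications mentioning it.  Published tables of this shape are
distributed as two-column TSV files (one drug-PMID pair per row), curated
either from structure-resolved cross-references or from name-based PubMed
searches.  Drugs are kept only if they are associated with at least two
distinct PMIDs (configurable), which suppresses one-off mentions.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class RifFormatError(ValueError):
    """Raised for malformed association input (bad PMID, empty name, bad line)."""


def normalize_name(name: str) -> str:
    """Normalize a drug name: strip surrounding whitespace, lowercase."""
    return name.strip().lower()


@dataclass(frozen=True)
class RifTable:
    """Immutable drug -> {PMID} association map.

    ``entries`` maps normalized drug names to frozensets of positive-integer
    PMIDs.  Instances are normally built with :func:`build_rif`, which
    enforces the minimum-PMID filter and name normalization.
    """

    entries: dict[str, frozenset[int]]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug: str) -> bool:
        return normalize_name(drug) in self.entries

    def __getitem__(self, drug: str) -> frozenset[int]:
        return self.entries[normalize_name(drug)]

    @property
    def drugs(self) -> list[str]:
        """Drug names in ascending lexicographic order."""
        return sorted(self.entries)

    def total(self, drug: str) -> int:
        """Total number of publications mentioning ``drug``."""
        return len(self[drug])

    def pairs(self) -> Iterator[tuple[str, int]]:
        """Iterate (drug, PMID) pairs in deterministic sorted order."""
        for drug in self.drugs:
            for pmid in sorted(self.entries[drug]):
                yield drug, pmid


@dataclass(frozen=True)
class DrugMasterList:
    """Master list of small molecules with optional InChIKey identifiers.

    Each record is ``(drug_name, inchikey)`` where the InChIKey, when
    present, must match the 27-character ``XXXXXXXXXXXXXX-XXXXXXXXXX-X``
    block pattern.
    """

    records: list[tuple[str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, key in self.records:
            if not name or not name.strip():
                raise ValueError("drug_name must be nonempty in master list")
            if key is not None and not _INCHIKEY_RE.match(key):
                raise ValueError(f"malformed InChIKey for {name!r}: {key!r}")

    def __len__(self) -> int:
        return len(self.records)


def _validate_pmid(pmid: object, row: object) -> int:
    # bool is an int subclass; reject it explicitly
    if isinstance(pmid, bool) or not isinstance(pmid, (int, np.integer)):
        raise RifFormatError(f"non-integer PMID {pmid!r} in row {row!r}")
    pmid = int(pmid)
    if pmid <= 0:
        raise RifFormatError(f"non-positive PMID {pmid} in row {row!r}")
    return pmid


def build_rif(pairs: Iterable[tuple[str, int]], min_pmids: int = 2) -> RifTable:
    """Build a :class:`RifTable` from (drug_name, PMID) pairs.

    Duplicate pairs are collapsed, names normalized, and only drugs with at
    least ``min_pmids`` distinct PMIDs are retained.

    Parameters
    ----------
    pairs:
        Iterable of ``(drug_name, PMID)`` tuples.
    min_pmids:
        Minimum number of distinct PMIDs a drug needs to be kept
        (default 2, the convention of the published association tables).

    Raises
    ------
    RifFormatError
        On a non-integer or non-positive PMID, or an empty drug name; the
        error names the offending row.
    ValueError
        If ``min_pmids < 1``.
    """
    if min_pmids < 1:
        raise ValueError(f"min_pmids must be >= 1, got {min_pmids}")
    acc: dict[str, set[int]] = {}
    for row in pairs:
        name, pmid = row
        norm = normalize_name(str(name))
        if not norm:
            raise RifFormatError(f"empty drug name in row {row!r}")
        pmid = _validate_pmid(pmid, row)
        acc.setdefault(norm, set()).add(pmid)
    entries = {
        drug: frozenset(pmids)
        for drug, pmids in acc.items()
        if len(pmids) >= min_pmids
    }
    return RifTable(entries=entries)


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8")  # type: ignore[return-value]


def read_rif(path: str | Path, min_pmids: int = 1) -> RifTable:
    """Read a RIF TSV file (columns drug_name, PMID; optional header).

    A header row is auto-detected: if the second field of the first
    non-blank line is not a decimal integer, the line is treated as a
    header and skipped.  Extra columns beyond the first two are ignored.
    Gzip compression is handled transparently for ``.gz`` paths.

    ``min_pmids`` defaults to 1 so that reading back a written table is an
    identity on the stored pair set; pass 2 to re-apply the publication
    filter.
    """
    pairs: list[tuple[str, int]] = []
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
            name, pmid_s = fields[0], fields[1].strip()
            if not first_data_seen:
                first_data_seen = True
                if not pmid_s.isdigit():
                    continue  # header row
            if not pmid_s.isdigit():
                raise RifFormatError(
                    f"{path}: line {lineno}: PMID {pmid_s!r} is not a positive integer"
                )
            if not name.strip():
                raise RifFormatError(f"{path}: line {lineno}: empty drug name")
            pairs.append((name, int(pmid_s)))
    return build_rif(pairs, min_pmids=min_pmids)


def write_rif(table: RifTable, path: str | Path, header: bool = True) -> None:
    """Write a :class:`RifTable` as a two-column TSV (``.gz`` supported).

    Rows are emitted in sorted (drug, PMID) order so identical tables
    serialize byte-identically.  PMIDs are written as plain decimal strings.
    """
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("drug\tPMID\n")
        for drug, pmid in table.pairs():
            fh.write(f"{drug}\t{pmid}\n")
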
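"""Core term-drug association scoring.

For a search term resolved to a set of PMIDs, every drug in the RIF table
sharing at least one PMID with the term gets a row with

* ``count``    — number of shared PMIDs,
* ``fraction`` — count divided by the drug's total publication count
  (how specific the term is to the drug),
* ``score``    — count * fraction = count**2 / total, the ranking key that
  balances raw co-mention frequency against specificity.

The top-k drugs under a chosen key form the "unweighted drug set" that
seeds the similarity-based augmentation step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from drugmine.rif_store import RifTable, normalize_name

logger = logging.getLogger(__name__)

RANK_KEYS = ("score", "count", "fraction")

#: Size bounds for drug sets built via the default ranked-cutoff path.
K_MIN, K_MAX = 20, 200

ASSOCIATION_COLUMNS = ["drug", "count", "fraction", "score"]


@dataclass(frozen=True)
class DrugSet:
    """An unordered, unweighted set of drug names.

    ``members`` are normalized names.  Sets built from an association table
    via :func:`top_drug_set` are a prefix of the ranking; user-submitted
    sets (see :func:`drugmine.augmentation.read_drug_set`) may be any size
    >= 2.
    """

    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(normalize_name(m) for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, drug: str) -> bool:
        return normalize_name(drug) in self.members


def rank_score(count: int, total: int) -> tuple[float, float]:
    """Return ``(fraction, score)`` for a drug's term overlap.

    ``fraction = count / total`` and ``score = count * fraction``
    (equivalently ``count**2 / total``).

    Raises
    ------
    ValueError
        If ``total == 0`` or ``count`` is outside ``[1, total]``.
    """
    if total == 0:
        raise ValueError("total publication count must be positive")
    if not 1 <= count <= total:
        raise ValueError(f"count must satisfy 1 <= count <= total, got {count}/{total}")
    fraction = count / total
    return fraction, count * fraction


def associate(term_pmids: frozenset[int] | set[int], rif: RifTable) -> pd.DataFrame:
    """Cross-reference term PMIDs with a RIF table.

    Returns a DataFrame with columns ``drug, count, fraction, score``
    containing one row per drug whose PMID set intersects ``term_pmids``,
    sorted by score descending (ties: count descending, then drug name
    ascending).  An empty ``term_pmids`` yields an empty table with a
    logged warning, not an error.
    """
    if len(rif) == 0:
        raise ValueError("RIF table is empty")
    if not term_pmids:
        logger.warning("term query returned no PMIDs; association table is empty")
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    term_pmids = frozenset(term_pmids)
    rows = []
    for drug in rif.drugs:
        pmids = rif.entries[drug]
        count = len(term_pmids & pmids)
        if count == 0:
            continue
        fraction, score = rank_score(count, len(pmids))
        rows.append((drug, count, fraction, score))
    table = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    return _sort_association(table, "score")


def _sort_association(table: pd.DataFrame, key: str) -> pd.DataFrame:
    secondary = "count" if key != "count" else "score"
    return table.sort_values(
        [key, secondary, "drug"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def top_drug_set(table: pd.DataFrame, k: int, rank_by: str = "score") -> DrugSet:
    """Take the top ``min(k, len(table))`` drugs under the chosen ranking key.

    ``rank_by`` is one of ``score`` (default), ``count`` or ``fraction``.
    Ties are broken deterministically (secondary key descending, then drug
    name ascending).  Short tables return all rows with a logged warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if rank_by not in RANK_KEYS:
        raise ValueError(f"rank_by must be one of {RANK_KEYS}, got {rank_by!r}")
    if k > len(table):
        logger.warning(
            "requested k=%d exceeds table size %d; returning all drugs", k, len(table)
        )
    ranked = _sort_association(table, rank_by)
    return DrugSet(members=frozenset(ranked["drug"].head(k)))


def scatter_data(table: pd.DataFrame) -> pd.DataFrame:
    """Per-drug (x=count, y=fraction) export backing the search scatter plot."""
    return table[["drug", "count", "fraction"]].rename(
        columns={"count": "x", "fraction": "y"}
    )


def write_association(table: pd.DataFrame, path) -> None:
    """Export an association table as TSV, floats at 6 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
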
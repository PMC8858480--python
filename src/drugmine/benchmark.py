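"""Benchmarking the augmentation step against shuffled-matrix nulls.

For each term in an annotation library, the pipeline builds the
unweighted drug set from the literature (query -> associate -> top-k) and
asks how well a similarity matrix ranks those seed drugs above everything
else, scored leave-one-out.  The positives are the literature-derived
seed set itself — the annotation library contributes only the term list.
Per-term AUROC and average precision are compared against the same
computation on label-shuffled copies of the matrix (the null), pooled
across shuffles, with a two-sided Mann-Whitney U test.

AUROC here is the Mann-Whitney probability that a random positive
outscores a random negative with ties counted 1/2; average precision is
the mean of precision evaluated at each positive's rank (tied scores
share the precision at the bottom of their tie group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from drugmine.association import DrugSet, associate, top_drug_set
from drugmine.augmentation import augment
from drugmine.literature_search import CorpusIndex, TermQuery, query_pmids
from drugmine.rif_store import RifTable, normalize_name, _open_text
from drugmine.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


class GmtFormatError(ValueError):
    """Raised for malformed GMT library files."""


@dataclass(frozen=True)
class TermAnnotationLibrary:
    """GMT-style term -> drug-set library; supplies the benchmark term list."""

    name: str
    terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, drugs in self.terms.items():
            if not drugs:
                raise ValueError(f"term {term!r} has no annotated drugs")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_list(self) -> list[str]:
        return sorted(self.terms)


def read_gmt(path: str | Path, name: str | None = None) -> TermAnnotationLibrary:
    """Parse a GMT file (term, description, tab-separated member names)."""
    terms: dict[str, frozenset[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno}: expected term, description and "
                    f">= 1 member (got {len(fields)} fields)"
                )
            term = fields[0].strip()
            members = frozenset(
                normalize_name(m) for m in fields[2:] if m.strip()
            )
            if not term or not members:
                raise GmtFormatError(
                    f"{path}: line {lineno}: empty term or member list"
                )
            terms[term] = members
    return TermAnnotationLibrary(name=name or str(Path(path).stem), terms=terms)


def write_gmt(library: TermAnnotationLibrary, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term in library.term_list:
            members = "\t".join(sorted(library.terms[term]))
            fh.write(f"{term}\t{library.name}\t{members}\n")


def _split_scores(
    scores: Mapping[str, float], positives
) -> tuple[np.ndarray, np.ndarray]:
    positives = {normalize_name(p) for p in positives}
    unknown = positives - set(scores)
    if unknown:
        raise ValueError(f"positives not present among scored drugs: {sorted(unknown)}")
    y = np.array([d in positives for d in scores], dtype=bool)
    s = np.array([scores[d] for d in scores], dtype=float)
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative")
    return y, s


def auroc(scores: Mapping[str, float], positives) -> float:
    """Area under the ROC curve for the given drug -> score ranking.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, ties counted 1/2.
    """
    from sklearn.metrics import roc_auc_score

    y, s = _split_scores(scores, positives)
    return float(roc_auc_score(y, s))


def average_precision(scores: Mapping[str, float], positives) -> float:
    """Average precision: mean over positives of precision at that rank."""
    from sklearn.metrics import average_precision_score

    y, s = _split_scores(scores, positives)
    return float(average_precision_score(y, s))


def evaluate_term(
    seed: DrugSet, matrix: SimilarityMatrix
) -> tuple[float, float, int]:
    """Score all matrix drugs leave-one-out against the seed set.

    Returns ``(auroc, avg_precision, n_positives)`` where the positives
    are the seed drugs matched in the matrix.
    """
    table = augment(seed, matrix, top_n=len(matrix), mode="loo")
    scores = dict(zip(table["drug"], table["mean_similarity"]))
    positives = {d for d in seed if d in set(matrix.labels)}
    return (
        auroc(scores, positives),
        average_precision(scores, positives),
        len(positives),
    )


def shuffled_matrix(matrix: SimilarityMatrix, seed: int) -> SimilarityMatrix:
    """Shuffle drug identities against the value grid (the benchmark null).

    One uniformly random permutation is applied jointly to rows and
    columns, which is equivalent to relabeling the drugs; symmetry and the
    value multiset are preserved exactly.  Deterministic per ``seed``.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(matrix))
    values = matrix.values[np.ix_(perm, perm)]
    return SimilarityMatrix(labels=matrix.labels, values=values, kind=matrix.kind)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_of_x, p_two_sided)``.

    ``U = #{(i,j): x_i > y_j} + 1/2 #ties``.  The exact null distribution
    is used when ``len(x) + len(y) <= 16`` and there are no ties; otherwise
    the normal approximation with continuity and tie correction.  A pooled
    sample that is entirely constant returns ``(n1*n2/2, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 16 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-term metrics, pooled shuffle-null metrics, and the U tests."""

    per_term: pd.DataFrame  # columns: term, auroc, avg_precision, n_positives
    null_per_term: pd.DataFrame  # columns: term, shuffle, auroc, avg_precision
    u_auroc: float
    p_auroc: float
    u_ap: float
    p_ap: float
    skipped: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_terms": int(len(self.per_term)),
            "n_skipped": len(self.skipped),
            "skipped": dict(sorted(self.skipped.items())),
            "mean_auroc": float(self.per_term["auroc"].mean()),
            "mean_avg_precision": float(self.per_term["avg_precision"].mean()),
            "null_mean_auroc": float(self.null_per_term["auroc"].mean()),
            "null_mean_avg_precision": float(
                self.null_per_term["avg_precision"].mean()
            ),
            "u_auroc": self.u_auroc,
            "p_auroc": self.p_auroc,
            "u_ap": self.u_ap,
            "p_ap": self.p_ap,
        }

    def violin_data(self) -> pd.DataFrame:
        """Long-format (term, metric, value, source) table for violin plots."""
        real = self.per_term.melt(
            id_vars=["term"],
            value_vars=["auroc", "avg_precision"],
            var_name="metric",
            value_name="value",
        )
        real["source"] = "real"
        null = self.null_per_term.melt(
            id_vars=["term"],
            value_vars=["auroc", "avg_precision"],
            var_name="metric",
            value_name="value",
        )
        null["source"] = "shuffled"
        return pd.concat([real, null], ignore_index=True)


def run_benchmark(
    library: TermAnnotationLibrary,
    rif: RifTable,
    corpus: CorpusIndex,
    matrix: SimilarityMatrix,
    k: int = 20,
    n_shuffles: int = 10,
    seed: int = 0,
    rank_by: str = "score",
) -> BenchmarkResult:
    """Run the full benchmark over every term of an annotation library.

    Per term: query the corpus for the term's PMIDs, build the association
    table, take the top-``k`` unweighted drug set, and evaluate it on the
    real matrix and on each of ``n_shuffles`` label-shuffled copies (the
    same shuffled copies are reused across terms; null values are pooled).
    Terms whose query returns no PMIDs, whose association table is empty,
    or whose seed matches fewer than 2 matrix drugs are skipped and
    reported in ``BenchmarkResult.skipped``.
    """
    if len(library) == 0:
        raise ValueError("annotation library is empty")
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    shuffle_seeds = np.random.SeedSequence(seed).generate_state(n_shuffles) % (2**31)
    nulls = [shuffled_matrix(matrix, int(s)) for s in shuffle_seeds]
    label_set = set(matrix.labels)

    real_rows, null_rows = [], []
    skipped: dict[str, str] = {}
    for term in library.term_list:
        pmids = query_pmids(TermQuery((term,)), corpus)
        if not pmids:
            skipped[term] = "no PMIDs for term"
            continue
        table = associate(pmids, rif)
        if len(table) == 0:
            skipped[term] = "no drugs share PMIDs with term"
            continue
        drug_set = top_drug_set(table, k, rank_by=rank_by)
        n_matched = len({d for d in drug_set if d in label_set})
        if n_matched < 2:
            skipped[term] = "fewer than 2 seed drugs matched in matrix"
            continue
        if n_matched >= len(matrix):
            skipped[term] = "seed covers every matrix drug (no negatives)"
            continue
        a, ap, n_pos = evaluate_term(drug_set, matrix)
        real_rows.append((term, a, ap, n_pos))
        for i, null in enumerate(nulls):
            a0, ap0, _ = evaluate_term(drug_set, null)
            null_rows.append((term, i, a0, ap0))

    per_term = pd.DataFrame(
        real_rows, columns=["term", "auroc", "avg_precision", "n_positives"]
    )
    null_per_term = pd.DataFrame(
        null_rows, columns=["term", "shuffle", "auroc", "avg_precision"]
    )
    if len(per_term) == 0:
        raise ValueError(
            f"all {len(library)} terms were skipped: {skipped}"
        )
    u_auroc, p_auroc = mann_whitney_u(per_term["auroc"], null_per_term["auroc"])
    u_ap, p_ap = mann_whitney_u(
        per_term["avg_precision"], null_per_term["avg_precision"]
    )
    return BenchmarkResult(
        per_term=per_term,
        null_per_term=null_per_term,
        u_auroc=u_auroc,
        p_auroc=p_auroc,
        u_ap=u_ap,
        p_ap=p_ap,
        skipped=skipped,
    )
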
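"""Drug-drug similarity ("prediction") matrices.

Two constructions:

* literature co-mentions — pairwise absolute counts of shared PMIDs
  between drugs, from a RIF table; the diagonal holds each drug's total
  publication count (never used in augmentation scoring, where the self
  term is excluded);
* expression-signature similarity — pairwise cosine similarity between
  drug-induced gene-expression signatures supplied as a drug x gene
  matrix.  Signatures are used as given (any z-scoring or fold-change
  preprocessing is the caller's responsibility); zero-norm rows are
  dropped with a warning.

Both matrices are symmetric, label-aligned, and serialized as labeled
TSV (optionally gzipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from drugmine.rif_store import RifTable, normalize_name

logger = logging.getLogger(__name__)

KINDS = ("comention", "cosine")


class MatrixFormatError(ValueError):
    """Raised for malformed similarity-matrix files."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square labeled symmetric drug-drug similarity matrix.

    ``labels`` is the ordered drug-name list; ``values`` is the aligned
    square ndarray; ``kind`` is ``"comention"`` (non-negative integer
    shared-PMID counts) or ``"cosine"`` (values in [-1, 1], unit diagonal).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be square, got shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in similarity matrix")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, drugs) -> np.ndarray:
        """Positions of the given drug names (normalized); KeyError if absent."""
        pos = {d: i for i, d in enumerate(self.labels)}
        return np.array([pos[normalize_name(d)] for d in drugs], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def astype(self, dtype) -> "SimilarityMatrix":
        """Return a copy with values cast to ``dtype`` (e.g. float32 storage)."""
        return SimilarityMatrix(self.labels, self.values.astype(dtype), self.kind)


def comention_matrix(rif: RifTable) -> SimilarityMatrix:
    """Pairwise shared-PMID counts between all drugs of a RIF table.

    ``M[i, j] = |PMIDs(i) & PMIDs(j)|``; the diagonal is each drug's total
    PMID count.  Labels are the drugs in ascending lexicographic order.
    """
    if len(rif) == 0:
        raise ValueError("RIF table is empty")
    drugs = rif.drugs
    all_pmids = sorted({p for d in drugs for p in rif.entries[d]})
    pmid_pos = {p: i for i, p in enumerate(all_pmids)}
    rows, cols = [], []
    for i, d in enumerate(drugs):
        for p in rif.entries[d]:
            rows.append(i)
            cols.append(pmid_pos[p])
    indicator = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(drugs), len(all_pmids)),
    )
    counts = (indicator @ indicator.T).toarray()
    return SimilarityMatrix(labels=tuple(drugs), values=counts, kind="comention")


def cosine_matrix(signatures: pd.DataFrame, dtype=np.float64) -> SimilarityMatrix:
    """Pairwise cosine similarity between drug signature rows.

    ``signatures`` is a drug x feature DataFrame.  Rows with zero norm are
    dropped with a logged warning (cosine is undefined for them).  The
    result is exactly symmetric with unit diagonal; labels follow ascending
    lexicographic order of the retained drugs.
    """
    from sklearn.metrics.pairwise import cosine_similarity

    sig = signatures.copy()
    sig.index = [normalize_name(str(d)) for d in sig.index]
    if sig.index.has_duplicates:
        raise ValueError("duplicate drug labels in signature matrix")
    norms = np.linalg.norm(sig.values.astype(float), axis=1)
    zero = norms == 0
    if zero.any():
        dropped = list(sig.index[zero])
        logger.warning("dropping %d zero-norm signatures: %s", len(dropped), dropped)
        sig = sig.loc[~zero]
    if len(sig) == 0:
        raise ValueError("no nonzero signatures to compare")
    sig = sig.sort_index()
    values = cosine_similarity(sig.values.astype(float))
    values = (values + values.T) / 2.0  # force exact symmetry
    np.clip(values, -1.0, 1.0, out=values)
    return SimilarityMatrix(
        labels=tuple(sig.index), values=values.astype(dtype), kind="cosine"
    )


def _infer_kind(values: np.ndarray) -> str:
    if np.all(values >= 0) and np.allclose(values, np.round(values)):
        return "comention"
    return "cosine"


def read_matrix(path, kind: str | None = None) -> SimilarityMatrix:
    """Read a labeled square TSV matrix (header row and first column = labels).

    ``kind`` may be given explicitly; otherwise it is inferred (all
    non-negative integers -> ``comention``, else ``cosine``).  ``.gz``
    paths are decompressed transparently.  Raises
    :class:`MatrixFormatError` on non-square data or a row/column label
    mismatch (naming the first mismatch).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    row_labels = [str(x) for x in frame.index]
    col_labels = [str(x) for x in frame.columns]
    if len(row_labels) != len(col_labels):
        raise MatrixFormatError(
            f"{path}: matrix is not square ({len(row_labels)} rows x "
            f"{len(col_labels)} columns)"
        )
    for i, (r, c) in enumerate(zip(row_labels, col_labels)):
        if r != c:
            raise MatrixFormatError(
                f"{path}: row/column label mismatch at position {i}: "
                f"{r!r} != {c!r}"
            )
    values = frame.to_numpy(dtype=float)
    if kind is None:
        kind = _infer_kind(values)
    if kind == "comention":
        values = values.astype(np.int64)
    return SimilarityMatrix(labels=tuple(row_labels), values=values, kind=kind)


def write_matrix(matrix: SimilarityMatrix, path) -> None:
    """Write a similarity matrix as labeled TSV (``.gz`` supported).

    Co-mention counts are written as integers; cosine values at full
    ``repr`` precision so round-trips preserve them exactly.
    """
    frame = matrix.to_frame()
    if matrix.kind == "comention":
        frame = frame.astype(np.int64)
        frame.to_csv(path, sep="\t")
    else:
        frame.to_csv(path, sep="\t", float_format="%.17g")


def read_signatures(path) -> pd.DataFrame:
    """Read a drug x feature signature matrix from labeled TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = [str(x) for x in frame.index]
    return frame


def write_signatures(signatures: pd.DataFrame, path) -> None:
    signatures.to_csv(path, sep="\t", float_format="%.17g")
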
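"""Drug-set augmentation: rank candidates by mean similarity to a seed set.

Given an unweighted seed drug set and a drug-drug similarity matrix, each
candidate drug is scored by the mean of its similarities to the seed
members found in the matrix.  Two modes:

* ``predict`` — score only non-seed drugs (the user-facing augmentation
  table excludes the seed itself);
* ``loo``     — score every drug; for seed members the self-similarity
  term is excluded (leave-one-out), so the diagonal never inflates a seed
  member's score.  This is the scoring used for benchmarking.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from drugmine.association import DrugSet
from drugmine.rif_store import normalize_name
from drugmine.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["drug", "mean_similarity"]


def augment(
    seed: DrugSet | frozenset[str] | set[str],
    matrix: SimilarityMatrix,
    top_n: int = 20,
    mode: str = "predict",
) -> pd.DataFrame:
    """Rank drugs by average similarity to the seed set.

    Returns a DataFrame with columns ``drug, mean_similarity`` holding the
    ``top_n`` highest-scoring drugs, sorted by score descending with ties
    broken by drug name ascending.

    Seed drugs absent from the matrix are dropped with a warning; fewer
    than two matched seed drugs is an error reporting the unmatched names.
    In ``predict`` mode the output never contains a seed member and the
    divisor is the matched-seed count m; in ``loo`` mode all labels are
    scored and seed members use divisor m - 1 (self term excluded).
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if mode not in ("predict", "loo"):
        raise ValueError(f"mode must be 'predict' or 'loo', got {mode!r}")
    seed_names = sorted({normalize_name(d) for d in seed})
    label_set = set(matrix.labels)
    matched = [d for d in seed_names if d in label_set]
    unmatched = [d for d in seed_names if d not in label_set]
    if unmatched:
        logger.warning(
            "%d seed drugs absent from the similarity matrix: %s",
            len(unmatched),
            unmatched,
        )
    if len(matched) < 2:
        raise ValueError(
            "fewer than 2 seed drugs found in the similarity matrix; "
            f"unmatched: {unmatched}"
        )
    m = len(matched)
    seed_idx = matrix.index_of(matched)
    values = matrix.values.astype(float)
    row_sums = values[:, seed_idx].sum(axis=1)
    labels = np.array(matrix.labels)
    is_seed = np.isin(labels, matched)

    if mode == "predict":
        scores = row_sums[~is_seed] / m
        out_labels = labels[~is_seed]
    else:
        scores = row_sums.copy()
        diag = values[seed_idx, seed_idx]
        scores[seed_idx] -= diag  # remove the self term for seed members
        divisors = np.where(is_seed, m - 1, m)
        scores = scores / divisors
        out_labels = labels

    table = pd.DataFrame({"drug": out_labels, "mean_similarity": scores})
    table = table.sort_values(
        ["mean_similarity", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(top_n).reset_index(drop=True)


def read_drug_set(path: str | Path) -> DrugSet:
    """Read a user-submitted drug set: one name per line, ``#`` comments.

    Names are normalized and deduplicated; fewer than 2 usable names is a
    usage error.
    """
    members: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                members.add(normalize_name(line))
    if len(members) < 2:
        raise ValueError(
            f"{path}: a drug set needs at least 2 distinct names, got {len(members)}"
        )
    return DrugSet(members=frozenset(members))


def write_prediction(table: pd.DataFrame, path, matrix_kind: str) -> None:
    """Export a prediction table as TSV with a matrix-kind provenance column."""
    out = table.copy()
    out["matrix_kind"] = matrix_kind
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
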
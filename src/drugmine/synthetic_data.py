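"""Seeded generators for planted-structure test worlds.

The generator emulates the statistical structure the scorer exploits:
each publication (PMID) is about exactly one term; the term's planted
drugs are mentioned in such publications with elevated probability
``p_planted`` while every drug has a baseline mention probability
``p_background``.  Drug-induced expression signatures mirror the same
planting: planted co-term drugs share a cluster centroid, so the
literature co-mention and signature-similarity channels are correlated
but not identical.  Everything is deterministic per ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from drugmine.benchmark import TermAnnotationLibrary
from drugmine.literature_search import CorpusIndex
from drugmine.rif_store import RifTable, build_rif

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedWorldConfig:
    """Parameters of the planted world.

    ``p_planted`` is the probability that a publication about a term
    mentions any given planted drug of that term; ``p_background`` the
    baseline mention probability for every drug in every publication.
    ``p_planted == p_background`` gives a null world with no signal.
    Planted sets are disjoint across terms, so
    ``n_terms * drugs_per_term <= n_drugs`` is required.
    """

    n_drugs: int = 200
    n_terms: int = 20
    n_pmids: int = 5000
    p_planted: float = 0.3
    p_background: float = 0.01
    drugs_per_term: int = 10
    n_genes: int = 50
    cluster_noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_background <= self.p_planted <= 1):
            raise ValueError(
                "need 0 <= p_background <= p_planted <= 1, got "
                f"p_background={self.p_background}, p_planted={self.p_planted}"
            )
        if self.drugs_per_term > self.n_drugs:
            raise ValueError("drugs_per_term cannot exceed n_drugs")
        if self.n_terms * self.drugs_per_term > self.n_drugs:
            raise ValueError(
                "planted sets are disjoint: need n_terms * drugs_per_term "
                f"<= n_drugs ({self.n_terms} * {self.drugs_per_term} > {self.n_drugs})"
            )
        for name in ("n_drugs", "n_terms", "n_pmids", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cluster_noise_sd < 0:
            raise ValueError("cluster_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: term -> planted drug set, drug -> cluster id."""

    planted: dict[str, frozenset[str]]
    cluster: dict[str, int]


@dataclass(frozen=True)
class World:
    """A complete synthetic test world."""

    corpus: CorpusIndex
    rif: RifTable
    signatures: pd.DataFrame
    library: TermAnnotationLibrary
    truth: GroundTruth
    config: PlantedWorldConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _drug_name(i: int, width: int) -> str:
    return f"drug_{i:0{width}d}"


def _term_name(i: int, width: int) -> str:
    return f"term_{i:0{width}d}"


def generate_world(config: PlantedWorldConfig) -> World:
    """Generate a corpus, RIF table, signatures, library and ground truth.

    Each PMID is assigned one term uniformly at random; mentions are drawn
    as described in the module docstring; the RIF table applies the
    standard >= 2 distinct PMIDs filter; signatures are cluster centroid +
    isotropic Gaussian noise, where each term's planted drugs form one
    cluster and every unplanted drug is its own singleton cluster.
    """
    rng = np.random.default_rng(config.rng_seed)
    dw = max(3, len(str(config.n_drugs - 1)))
    tw = max(2, len(str(config.n_terms - 1)))
    drugs = [_drug_name(i, dw) for i in range(config.n_drugs)]
    terms = [_term_name(i, tw) for i in range(config.n_terms)]

    # disjoint planted sets: a random permutation carved into consecutive blocks
    perm = rng.permutation(config.n_drugs)
    planted: dict[str, frozenset[str]] = {}
    cluster: dict[str, int] = {}
    for t, term in enumerate(terms):
        block = perm[t * config.drugs_per_term : (t + 1) * config.drugs_per_term]
        planted[term] = frozenset(drugs[i] for i in block)
        for i in block:
            cluster[drugs[i]] = t
    next_cluster = config.n_terms
    for d in drugs:
        if d not in cluster:
            cluster[d] = next_cluster
            next_cluster += 1

    # one term per publication; planted mentions on top of background ones
    pmids = np.arange(1, config.n_pmids + 1)
    term_of_pmid = rng.integers(config.n_terms, size=config.n_pmids)
    planted_mask = np.zeros((config.n_terms, config.n_drugs), dtype=bool)
    for t, term in enumerate(terms):
        planted_mask[t, [drugs.index(d) for d in planted[term]]] = True
    background = rng.random((config.n_pmids, config.n_drugs)) < config.p_background
    extra = config.p_planted - config.p_background
    planted_hits = (
        rng.random((config.n_pmids, config.n_drugs)) < (extra / (1 - config.p_background))
        if config.p_background < 1
        else np.zeros((config.n_pmids, config.n_drugs), dtype=bool)
    )
    # union gives overall mention probability exactly p_planted for planted drugs
    mention = background | (planted_hits & ~background & planted_mask[term_of_pmid])

    pmid_idx, drug_idx = np.nonzero(mention)
    pairs = [(drugs[d], int(pmids[p])) for p, d in zip(pmid_idx, drug_idx)]
    rif = build_rif(pairs, min_pmids=2)

    corpus = CorpusIndex.from_pairs(
        (int(pmids[p]), terms[t]) for p, t in enumerate(term_of_pmid)
    )

    centroids = rng.normal(size=(next_cluster, config.n_genes))
    noise = rng.normal(
        scale=config.cluster_noise_sd, size=(config.n_drugs, config.n_genes)
    ) if config.cluster_noise_sd > 0 else np.zeros((config.n_drugs, config.n_genes))
    sig_values = np.array([centroids[cluster[d]] for d in drugs]) + noise
    signatures = pd.DataFrame(
        sig_values, index=drugs, columns=[f"gene_{g:03d}" for g in range(config.n_genes)]
    )

    library = TermAnnotationLibrary(name="planted", terms=dict(planted))
    truth = GroundTruth(planted=planted, cluster=cluster)
    return World(
        corpus=corpus,
        rif=rif,
        signatures=signatures,
        library=library,
        truth=truth,
        config=config,
    )


def recovery_rate(
    table: pd.DataFrame, truth: GroundTruth, term: str, k: int
) -> float:
    """Fraction of a term's planted drugs recovered in the top-k ranks.

    ``|top-k drugs & planted(term)| / min(k, |planted(term)|)``; the table
    is an association table sorted by score.
    """
    if term not in truth.planted:
        raise ValueError(f"unknown term {term!r}")
    top = set(table["drug"].head(k))
    planted = truth.planted[term]
    return len(top & planted) / min(k, len(planted))
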
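# Methods

## Association scoring

A RIF table maps each drug name to the set of PMIDs mentioning it; drugs
with fewer than two distinct PMIDs are dropped (`min_pmids=2` by default,
configurable) to suppress one-off mentions. Names are normalized by
lowercasing and trimming, which prevents spurious duplicates while
preserving exact-name keying; no synonym resolution is attempted.

For a term resolved to PMID set *T* and a drug *d* with PMID set *D*:

* count *c* = |T ∩ D|, total *t* = |D|,
* fraction = *c/t*, score = *c·(c/t)* = *c²/t*.

Rows with *c* = 0 are omitted. Tables are sorted by score descending with
deterministic tie-breaking (secondary key descending, then drug name
ascending), so outputs are identical across runs and platforms. The
unweighted drug set is the top-*k* prefix under a user-selectable key
(score by default; count and fraction are exposed because the ranking key
is a legitimate modelling choice — fraction favors niche compounds, count
favors heavily studied ones). On the default term-query path *k* is
bounded to [20, 200]; user-submitted sets bypass the bound (any size ≥ 2).

Term queries intersect the postings of all include terms and subtract the
union of exclude-term postings. Matching is exact on normalized strings;
we deliberately do not emulate PubMed's query expansion, so the local
corpus backend defines retrieval semantics precisely and reproducibly.

## Similarity matrices and augmentation

Two square, symmetric, label-aligned drug–drug matrices:

* **co-mention**: M[i,j] = |PMIDs(i) ∩ PMIDs(j)| (non-negative integers).
  The diagonal stores each drug's total publication count; it is inert in
  scoring because the self term is always excluded.
* **cosine**: cosine similarity between drug signature rows of a
  drug × gene matrix. Signatures are used as given — any z-scoring or
  fold-change preprocessing is the caller's responsibility, and the
  method is agnostic to signature semantics. Zero-norm rows are dropped
  with a warning. The computed matrix is symmetrized exactly
  ((M + Mᵀ)/2) and clipped to [−1, 1] to remove floating-point residue.

Matrices are dense float64 by default with a float32 storage option
(`SimilarityMatrix.astype`); at the scale this package targets in tests
(≤ a few hundred drugs) memory is irrelevant, but a ~20k-drug matrix is
~3 GB in float64, hence the option. Labels are ordered lexicographically
at construction; file readers preserve file order.

Augmentation scores every candidate drug by the mean of its similarities
to the seed drugs present in the matrix. Two modes:

* `predict` — only non-seed drugs are scored and returned (associated and
  predicted compounds are separate tables; the seed never appears in its
  own augmentation output);
* `loo` — every drug is scored; seed members exclude their self term
  (divisor m − 1 instead of m). This is the benchmarking mode: including
  the diagonal would trivially inflate every seed member's score and any
  AUROC computed from it.

Seed drugs missing from the matrix are dropped with a warning, and the
divisor is the matched count; fewer than two matched seeds is an error.

## Benchmarking

For each term of an annotation library (GMT format), the pipeline builds
the unweighted drug set from the literature and asks how well a
similarity matrix ranks those seed drugs above all other drugs, scored
leave-one-out. **The positives are the literature-derived seed set
itself** — the annotation library contributes only the term list. This
mirrors the upstream evaluation design this package reproduces; it
measures internal consistency of a similarity channel with the
literature ranking, not recovery of independently curated annotations.

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted ½. Average precision is the mean over
positives of precision at that positive's rank; tied scores share the
precision at the bottom of their tie group (the threshold convention).
Both are computed with scikit-learn and cross-checked in the test suite
against brute-force pair-counting and rank-walking oracles to 1e-9.

The null distribution comes from re-evaluating every term on
label-shuffled copies of the matrix: one uniformly random permutation
applied jointly to rows and columns (equivalent to relabeling the drugs),
which preserves symmetry and the exact value multiset. Ten shuffles by
default, pooled across terms. Shuffling rows and columns independently
would destroy the matrix's validity as a similarity structure, so the
joint permutation is the documented choice.

Real and pooled-null metric distributions are compared with a two-sided
Mann–Whitney U test: exact enumeration when n₁+n₂ ≤ 16 with no ties,
otherwise the normal approximation with continuity and tie correction
(scipy). A fully constant pooled sample returns U = n₁n₂/2, p = 1.
Terms whose query returns no PMIDs, whose association table is empty, or
whose seed matches fewer than two (or all) matrix drugs are skipped,
counted, and reported rather than silently dropped.

### Selection circularity of the co-mention benchmark

The seed set is selected from the same corpus co-occurrences that build
the co-mention matrix, so even in a world with no planted signal the
seed drugs are mutually more similar than chance (they were chosen for
sharing the term's PMIDs, and those shared PMIDs are entries of the
matrix). The co-mention benchmark is therefore anti-conservative by
construction: in signal-free simulations its real AUROC sits near
0.55–0.62 rather than 0.5. This is a property of the evaluation design,
not an implementation artifact. Type-I error control is consequently
demonstrated on the signature-similarity matrix, which shares no data
with seed selection; that is also the matrix for which the U statistics
are the meaningful novelty test, since the co-mention channel partially
restates its own input.

## Synthetic worlds

The generator plants the statistical structure the scorer exploits. Each
of `n_pmids` publications is about exactly one term (uniform); every drug
is mentioned with background probability `p_background`; each term's
`drugs_per_term` planted drugs are additionally mentioned in that term's
publications so their overall mention probability is exactly `p_planted`.
Planted sets are disjoint across terms (requiring
`n_terms · drugs_per_term ≤ n_drugs`), giving each drug a well-defined
cluster. Signatures are cluster centroid + isotropic Gaussian noise
(`cluster_noise_sd`, default 0.5 against unit-variance centroids), with
unplanted drugs as singleton clusters — so the literature and signature
channels are correlated but not identical, and tests can observe the two
augmentation channels ranking differently.

Defaults (200 drugs, 20 terms, 5000 PMIDs, 10 drugs per term,
`p_planted` = 0.3, `p_background` = 0.01, seed 0) are the study
conditions for all headline simulations: at these rates a planted drug
accrues ≈ 75 term-specific mentions against ≈ 50 background mentions,
strong but not degenerate signal. One-term-per-document keeps the model
simple; multi-topic documents, realistic language statistics, and
realistic L1000 signature distributions are deliberately out of scope,
so passing tests demonstrate correctness of the machinery and
calibration of the null — not performance on real literature.

`p_planted = p_background` gives a signal-free null world (the config
validator allows equality precisely for this case).

## Numerical and design notes

* Scores are plain float64; association TSV exports round to 6
  significant digits for display, cosine matrix files use 17 so
  round-trips are bit-exact (reads use round-trip float parsing).
* All randomness flows through `numpy.random.default_rng` seeds;
  benchmark shuffle seeds derive from a `SeedSequence`, making every
  pipeline bit-reproducible for fixed inputs and seed.
* Exit codes: 0 success (an empty query result is a success with empty
  outputs), 2 usage error, 1 runtime failure.
* The CLI subcommands are thin wrappers over the library; run manifests
  record version, parameters and input checksums for auditability.

## Known limitations

* Name-keyed matching only; no InChIKey resolution, synonym handling or
  MeSH harmonization, so distinct names for one compound are distinct
  drugs.
* The local corpus backend is exact-match; results with a live PubMed
  backend will differ wherever PubMed's query expansion matters.
* Benchmark AUROCs inherit the selection circularity described above for
  the co-mention matrix; compare channels, not absolute values.
* The acceptance simulations use hundreds of drugs, not the tens of
  thousands of a full literature corpus; the dense-matrix code path is
  sized accordingly.
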
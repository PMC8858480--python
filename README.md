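# drugmine

Rank small molecules against any biomedical search term from the
literature, and expand the resulting drug set with similar compounds.

`drugmine` is an offline, testable implementation of literature
co-mention drug ranking and drug-set augmentation for drug-discovery
triage. Given a term (a disease, phenotype, pathway, side effect, ...),
it:

1. resolves the term to a set of publication identifiers (PMIDs) through a
   pluggable search backend (a local corpus index ships with the package;
   a thin PubMed E-search adapter exists for live use);
2. cross-references those PMIDs with a **RIF table** (drug → PMIDs of
   publications mentioning it) and scores every drug sharing at least one
   publication with the term:

   * `count` — number of shared PMIDs,
   * `fraction = count / total` — share of the drug's literature that
     co-mentions the term (specificity),
   * `score = count × fraction = count² / total` — the ranking key,
     balancing frequency against specificity;
3. takes the top-*k* drugs as an **unweighted drug set** (k ∈ [20, 200]
   on the default path) and ranks all remaining drugs by their **average
   similarity** to that seed set under one of two drug–drug similarity
   matrices: pairwise shared-PMID co-mention counts, or pairwise cosine
   similarity of drug-induced gene-expression signatures;
4. benchmarks any such matrix with per-term AUROC and average precision
   of the seed drugs under leave-one-out scoring, compared against
   label-shuffled copies of the matrix with a two-sided Mann–Whitney U
   test.

A seeded synthetic-data generator (`drugmine.synthetic_data`) plants
term–drug co-occurrence structure and clustered signatures so every stage
is testable without downloads.

## Worked example

```python
from drugmine import build_rif, associate, top_drug_set

rif = build_rif([("aspirin", 1), ("aspirin", 2), ("aspirin", 3), ("aspirin", 4),
                 ("heparin", 3), ("heparin", 4)])
table = associate({1, 2, 3}, rif)          # PMIDs returned for the term
print(table.to_string(index=False))
print(sorted(top_drug_set(table, k=1).members))
```

prints

```
   drug  count  fraction  score
aspirin      3      0.75   2.25
heparin      1      0.50   0.50
['aspirin']
```

Aspirin shares 3 of the term's PMIDs and 75% of its own literature
co-mentions the term, so its score is 3 × 0.75 = 2.25; heparin shares one
publication (50% of its literature) and scores 0.5. The size-1 unweighted
drug set is therefore `{aspirin}`.

The same pipeline is available from the shell:

```bash
drugmine synthesize --out-dir world --seed 0        # synthetic test world
drugmine build-matrix --kind comention --rif world/rif.tsv --out world/com.tsv
drugmine query --rif world/rif.tsv --corpus world/corpus.tsv \
    --term term_00 --comention-matrix world/com.tsv --k 20 --out-dir out
drugmine benchmark --library world/library.gmt --rif world/rif.tsv \
    --corpus world/corpus.tsv --matrix world/com.tsv --k 10 --out-dir bench
```

`query` writes the ranked association table, the unweighted drug set, the
augmentation tables, scatter-plot data (count vs fraction), and a run
manifest; `benchmark` writes per-term metrics, violin-plot data and a
JSON summary with the U statistics and p-values.

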
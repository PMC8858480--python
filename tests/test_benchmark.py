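import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    auroc_pair_counting,
    average_precision_by_rank,
    mann_whitney_enumeration,
)

from drugmine.association import DrugSet
from drugmine.benchmark import (
    GmtFormatError,
    TermAnnotationLibrary,
    auroc,
    average_precision,
    evaluate_term,
    mann_whitney_u,
    read_gmt,
    run_benchmark,
    shuffled_matrix,
    write_gmt,
)
from drugmine.literature_search import CorpusIndex
from drugmine.rif_store import build_rif
from drugmine.similarity import SimilarityMatrix, comention_matrix


def scores_of(values, names=None):
    names = names or [f"d{i}" for i in range(len(values))]
    return dict(zip(names, map(float, values)))


class TestAuroc:
    def test_perfect_separation(self):
        s = scores_of([0.9, 0.8, 0.2, 0.1])
        assert auroc(s, {"d0", "d1"}) == 1.0

    def test_inverted_separation(self):
        s = scores_of([0.9, 0.8, 0.2, 0.1])
        assert auroc(s, {"d2", "d3"}) == 0.0

    def test_hand_pair_count(self):
        s = scores_of([0.9, 0.4, 0.6, 0.1])
        assert auroc(s, {"d0", "d1"}) == 0.75

    def test_all_ties_give_half(self):
        s = scores_of([0.3, 0.3, 0.3, 0.3])
        assert auroc(s, {"d0", "d2"}) == 0.5

    def test_degenerate_labels_rejected(self):
        s = scores_of([1.0, 0.0])
        with pytest.raises(ValueError):
            auroc(s, {"d0", "d1"})
        with pytest.raises(ValueError):
            auroc(s, set())


class TestAveragePrecision:
    def test_all_positives_on_top(self):
        s = scores_of([0.9, 0.8, 0.2, 0.1])
        assert average_precision(s, {"d0", "d1"}) == 1.0

    def test_pos_neg_pos_pattern(self):
        s = scores_of([0.9, 0.5, 0.3])
        assert average_precision(s, {"d0", "d2"}) == pytest.approx((1 + 2 / 3) / 2)

    def test_single_positive_ranked_last(self):
        s = scores_of([0.9, 0.8, 0.7, 0.1])
        assert average_precision(s, {"d3"}) == pytest.approx(1 / 4)


@given(st.integers(0, 10_000))
def test_metrics_match_definition_oracles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 50))
    scores = np.round(rng.normal(size=n), int(rng.integers(0, 3)))  # induce ties
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
    s = scores_of(scores)
    pos = {f"d{i}" for i in np.nonzero(labels)[0]}
    assert auroc(s, pos) == pytest.approx(auroc_pair_counting(scores, labels), abs=1e-9)
    assert average_precision(s, pos) == pytest.approx(
        average_precision_by_rank(scores, labels), abs=1e-9
    )


@given(st.integers(0, 10_000))
def test_auroc_complement_under_negation(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 30))
    scores = rng.permutation(n).astype(float)  # tie-free
    pos = {f"d{i}" for i in rng.choice(n, size=int(rng.integers(1, n)), replace=False)}
    assert auroc(scores_of(scores), pos) + auroc(scores_of(-scores), pos) == pytest.approx(1.0)


class TestMannWhitney:
    def test_hand_example(self):
        u, p = mann_whitney_u([3, 4], [1, 2])
        assert u == 4 and p == pytest.approx(1 / 3)

    def test_identical_samples_give_half_u(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n1*n2/2

    def test_constant_pooled_sample(self):
        u, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (u, p) == (3.0, 1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(st.integers(0, 5000))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        pooled = rng.permutation(n1 + n2).astype(float)
        x, y = pooled[:n1], pooled[n1:]
        u_ref, p_ref = mann_whitney_enumeration(x, y)
        u, p = mann_whitney_u(x, y)
        assert u == u_ref
        assert p == pytest.approx(p_ref, abs=1e-12)

    @settings(max_examples=25)
    @given(st.integers(0, 5000))
    def test_large_sample_p_close_to_asymptotic_reference(self, seed):
        import scipy.stats

        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        u, p = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestShuffledMatrix:
    def test_value_multiset_and_symmetry_preserved(self, planted_world):
        m = comention_matrix(planted_world.rif)
        sh = shuffled_matrix(m, seed=3)
        assert sh.labels == m.labels
        assert (sh.values == sh.values.T).all()
        assert np.array_equal(np.sort(sh.values, axis=None), np.sort(m.values, axis=None))

    def test_deterministic_per_seed(self, planted_world):
        m = comention_matrix(planted_world.rif)
        assert (shuffled_matrix(m, 5).values == shuffled_matrix(m, 5).values).all()

    def test_different_seeds_give_different_assignments(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10, 10))
        v = (v + v.T) / 2
        m = SimilarityMatrix(tuple(f"d{i}" for i in range(10)), v, "cosine")
        distinct = {shuffled_matrix(m, s).values.tobytes() for s in range(100)}
        assert len(distinct) > 90


class TestEvaluateTerm:
    def block_matrix(self):
        labels = tuple("abcdef")
        v = np.full((6, 6), 0.1)
        v[:3, :3] = 0.9
        v[3:, 3:] = 0.9
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(labels, v, "cosine")

    def test_block_structure_gives_perfect_auroc(self):
        a, ap, n_pos = evaluate_term(DrugSet(frozenset("abc")), self.block_matrix())
        assert (a, ap, n_pos) == (1.0, 1.0, 3)

    def test_constant_matrix_gives_half(self):
        v = np.full((5, 5), 0.7)
        m = SimilarityMatrix(tuple("abcde"), v, "cosine")
        a, ap, _ = evaluate_term(DrugSet(frozenset("ab")), m)
        assert a == 0.5

    def test_agrees_with_brute_force_pair_counting(self):
        from oracles import auroc_pair_counting

        rng = np.random.default_rng(11)
        v = rng.normal(size=(4, 4))
        v = (v + v.T) / 2
        labels = tuple("abcd")
        m = SimilarityMatrix(labels, v, "cosine")
        seed = DrugSet(frozenset("ab"))
        a, _, _ = evaluate_term(seed, m)
        scores = []
        for i, d in enumerate(labels):
            js = [j for j, s in enumerate(labels) if s in "ab" and j != i]
            scores.append(np.mean([v[i, j] for j in js]))
        labels_bool = np.array([d in "ab" for d in labels])
        assert a == pytest.approx(auroc_pair_counting(np.array(scores), labels_bool))


class TestGmt:
    def test_round_trip(self, tmp_path):
        lib = TermAnnotationLibrary(
            "demo", {"t1": frozenset({"a", "b"}), "t2": frozenset({"c"})}
        )
        path = tmp_path / "lib.gmt"
        write_gmt(lib, path)
        back = read_gmt(path)
        assert back.terms == lib.terms

    def test_malformed_line_error_names_line(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("t1\tdesc\ta\tb\nt2_only_two_fields\tdesc\n")
        with pytest.raises(GmtFormatError, match="line 2"):
            read_gmt(path)

    def test_empty_term_set_rejected(self):
        with pytest.raises(ValueError):
            TermAnnotationLibrary("demo", {"t": frozenset()})


class TestRunBenchmark:
    def test_planted_world_beats_null(self, planted_world):
        m = comention_matrix(planted_world.rif)
        res = run_benchmark(
            planted_world.library, planted_world.rif, planted_world.corpus, m,
            k=10, n_shuffles=5, seed=7,
        )
        assert res.per_term["auroc"].mean() > res.null_per_term["auroc"].mean()
        assert res.p_auroc < 0.05

    def test_skip_report_lists_orphan_terms(self, tiny_rif):
        corpus = CorpusIndex.from_pairs(
            [(1, "good"), (2, "good"), (3, "good"), (99, "orphan")]
        )
        library = TermAnnotationLibrary(
            "demo", {"good": frozenset({"a"}), "orphan": frozenset({"a"})}
        )
        rif = build_rif(
            [("a", 1), ("a", 2), ("b", 2), ("b", 3), ("c", 1), ("c", 3),
             ("d", 50), ("d", 51), ("e", 50), ("e", 52)]
        )
        m = comention_matrix(rif)
        res = run_benchmark(library, rif, corpus, m, k=20, n_shuffles=2, seed=0)
        assert list(res.per_term["term"]) == ["good"]
        assert set(res.skipped) == {"orphan"}

    def test_bit_reproducible_for_fixed_seed(self, planted_world):
        m = comention_matrix(planted_world.rif)
        args = (planted_world.library, planted_world.rif, planted_world.corpus, m)
        r1 = run_benchmark(*args, k=10, n_shuffles=2, seed=42)
        r2 = run_benchmark(*args, k=10, n_shuffles=2, seed=42)
        assert r1.per_term.equals(r2.per_term)
        assert r1.null_per_term.equals(r2.null_per_term)
        assert (r1.u_auroc, r1.p_auroc) == (r2.u_auroc, r2.p_auroc)

    def test_empty_library_rejected(self, planted_world):
        m = comention_matrix(planted_world.rif)
        with pytest.raises(ValueError):
            run_benchmark(
                TermAnnotationLibrary("e", {}), planted_world.rif,
                planted_world.corpus, m, seed=0,
            )

    def test_violin_data_long_format(self, planted_world):
        m = comention_matrix(planted_world.rif)
        res = run_benchmark(
            planted_world.library, planted_world.rif, planted_world.corpus, m,
            k=10, n_shuffles=2, seed=1,
        )
        vd = res.violin_data()
        assert set(vd.columns) == {"term", "metric", "value", "source"}
        assert set(vd["source"]) == {"real", "shuffled"}
        n_terms = len(res.per_term)
        assert len(vd) == 2 * n_terms + 2 * len(res.null_per_term)
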
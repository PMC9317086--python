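import networkx as nx
import numpy as np
import pytest

from complexwise import svcc
from complexwise.core import ComplexSet, ProteinComplex, ValidationError
from complexwise.features import extract_features
from conftest import unit_weights


class StubScorer:
    """Duck-typed scorer mapping member sets to fixed or computed scores."""

    def __init__(self, fn):
        self.fn = fn

    def prob_sets(self, sets):
        return np.array([self.fn(frozenset(s)) for s in sets])

    def prob(self, members):
        return float(self.fn(frozenset(members)))


def table_scorer(table, default=0.1):
    return StubScorer(lambda m: table.get(m, default))


def cx(*members, p=None):
    return ProteinComplex(frozenset(members), probability=p)


class TestSampleNegatives:
    def test_size_multiset_matches_positives(self, bench):
        pos = ComplexSet([c for c in bench["truth"][:6]])
        neg = svcc.sample_negatives(bench["net"], pos, seed=3)
        assert sorted(len(c) for c in neg) == sorted(len(c) for c in pos)

    def test_deterministic_under_seed(self, bench):
        pos = ComplexSet(list(bench["truth"]))
        a = svcc.sample_negatives(bench["net"], pos, seed=5)
        b = svcc.sample_negatives(bench["net"], pos, seed=5)
        assert [c.members for c in a] == [c.members for c in b]

    def test_never_duplicates_a_positive(self, bench):
        pos = ComplexSet(list(bench["truth"]))
        neg = svcc.sample_negatives(bench["net"], pos, seed=7)
        forbidden = {c.members for c in pos}
        assert all(c.members not in forbidden for c in neg)

    def test_exhaustion_raises(self, four_clique):
        pos = ComplexSet([cx("a", "b", "c", "d")])
        with pytest.raises(ValidationError):
            svcc.sample_negatives(four_clique, pos, seed=0, max_tries=20)

    def test_impossible_size(self, triangle):
        pos = ComplexSet([cx("a", "b", "c", "d")])
        with pytest.raises(ValidationError):
            svcc.sample_negatives(triangle, pos, seed=0)


class TestTrainingSet:
    def test_shapes_and_labels(self, bench):
        pos = ComplexSet(list(bench["truth"][:2]))
        neg = svcc.sample_negatives(bench["net"], pos, seed=1)
        ts = svcc.build_training_set(pos, neg, bench["net"], bench["wnet"])
        assert ts.features.shape == (4, 16)
        assert ts.labels.tolist() == [1, 1, 0, 0]

    def test_rows_equal_standalone_extraction(self, bench):
        pos = ComplexSet(list(bench["truth"][:2]))
        neg = svcc.sample_negatives(bench["net"], pos, seed=1)
        ts = svcc.build_training_set(pos, neg, bench["net"], bench["wnet"])
        for row, ref in zip(ts.features, ts.complex_refs):
            assert np.allclose(
                row, extract_features(ref.members, bench["net"], bench["wnet"])
            )

    def test_both_classes_required(self, bench):
        pos = ComplexSet(list(bench["truth"][:2]))
        with pytest.raises(ValidationError):
            svcc.build_training_set(
                pos, ComplexSet([]), bench["net"], bench["wnet"]
            )


@pytest.fixture(scope="module")
def trained():
    """Stage-1 scorer: 20 planted-clique positives vs random negatives."""
    from complexwise import synthetic, weighting

    cfg = synthetic.SynthConfig(n_complexes=28, p_in=1.0, seed=6)
    net, truth, ann = synthetic.generate(cfg)
    wnet = weighting.weight_network(net, ann)
    pos = ComplexSet(list(truth[:20]))
    neg = svcc.sample_negatives(net, pos, seed=2)
    ts = svcc.build_training_set(pos, neg, net, wnet)
    holdout_pos = ComplexSet(list(truth[20:]))
    holdout_neg = svcc.sample_negatives(net, holdout_pos, seed=9)
    scorer = svcc.train_stage1(ts, net, wnet, seed=4)
    return scorer, holdout_pos, holdout_neg


class TestStage1Classifier:
    def test_holdout_separates_dense_from_sparse(self, trained):
        scorer, hpos, hneg = trained
        probs = scorer.prob_sets(
            [c.members for c in hpos] + [c.members for c in hneg]
        )
        preds = (probs > 0.5).astype(int)
        truth = np.array([1] * len(hpos) + [0] * len(hneg))
        assert (preds == truth).mean() > 0.9

    def test_probabilities_bounded(self, trained):
        scorer, hpos, _ = trained
        probs = scorer.prob_sets([c.members for c in hpos])
        assert np.all((probs >= 0) & (probs <= 1))

    def test_refit_same_seed_identical(self, bench):
        pos = ComplexSet(list(bench["truth"][:8]))
        neg = svcc.sample_negatives(bench["net"], pos, seed=2)
        ts = svcc.build_training_set(pos, neg, bench["net"], bench["wnet"])
        q = [c.members for c in bench["truth"][8:12]]
        p1 = svcc.train_stage1(ts, bench["net"], bench["wnet"], seed=4).prob_sets(q)
        p2 = svcc.train_stage1(ts, bench["net"], bench["wnet"], seed=4).prob_sets(q)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, bench):
        pos = ComplexSet(list(bench["truth"][:4]))
        with pytest.raises(ValidationError):
            svcc.TrainingSet(
                np.zeros((4, 16)), np.ones(4), list(pos)
            )


class TestCliqueSeeding:
    def test_triangle_with_pendant(self, triangle):
        g = triangle.copy()
        g.add_edge("c", "d")
        cs = svcc.enumerate_initial_subgraphs(g)
        assert [c.members for c in cs] == [frozenset("abc")]

    def test_maximality(self, four_clique):
        cs = svcc.enumerate_initial_subgraphs(four_clique)
        assert [c.members for c in cs] == [frozenset("abcd")]

    def test_triangle_free_graph_empty(self):
        assert len(svcc.enumerate_initial_subgraphs(nx.cycle_graph(6))) == 0


class TestSelection:
    def test_overlap_count_rule(self):
        scorer = table_scorer({frozenset("abcd"): 0.9, frozenset("abc"): 0.8})
        out = svcc.select_subgraphs(
            ComplexSet([cx("a", "b", "c", "d"), cx("a", "b", "c")]),
            scorer, alpha=2,
        )
        assert [c.members for c in out] == [frozenset("abcd")]

    def test_exactly_alpha_shared_is_kept(self):
        scorer = table_scorer({frozenset("abcd"): 0.9, frozenset("abe"): 0.8})
        out = svcc.select_subgraphs(
            ComplexSet([cx("a", "b", "c", "d"), cx("a", "b", "e")]),
            scorer, alpha=2,
        )
        assert len(out) == 2

    def test_disjoint_all_kept(self):
        scorer = table_scorer({}, default=0.5)
        out = svcc.select_subgraphs(
            ComplexSet([cx("a", "b", "c"), cx("d", "e", "f")]), scorer, alpha=2
        )
        assert len(out) == 2

    def test_pass_through_limit_huge_alpha(self, bench):
        seeds = svcc.enumerate_initial_subgraphs(bench["wnet"])
        scorer = StubScorer(lambda m: min(1.0, len(m) / 10))
        out = svcc.select_subgraphs(seeds, scorer, alpha=10**6)
        assert len(out) == len(seeds)


class TestExpansion:
    def test_modularity_guided_growth(self, triangle):
        host = triangle.copy()
        for m in "abc":
            host.add_edge(m, "d")
        w = unit_weights(host)
        from complexwise.features import modularity

        scorer = StubScorer(lambda m: modularity(m, w))
        out = svcc.expand_subgraph(cx("a", "b", "c"), host, scorer)
        assert out.members == frozenset("abcd")
        assert out.probability == 1.0

    def test_no_neighbors_unchanged(self, triangle):
        scorer = StubScorer(lambda m: 0.5)
        out = svcc.expand_subgraph(cx("a", "b", "c"), triangle, scorer)
        assert out.members == frozenset("abc")

    def test_constant_scorer_never_expands(self, four_clique):
        g = four_clique.copy()
        g.add_edge("d", "e")
        scorer = StubScorer(lambda m: 0.5)
        out = svcc.expand_subgraph(cx("a", "b", "c", "d"), g, scorer)
        assert out.members == frozenset("abcd")


class TestFiltration:
    def test_sub_threshold_overlap_removed(self):
        scorer = table_scorer(
            {frozenset("abcd"): 0.9, frozenset("abce"): 0.8}
        )
        out = svcc.filter_candidates(
            ComplexSet([cx("a", "b", "c", "d"), cx("a", "b", "c", "e")]),
            scorer, beta=0.8,
        )
        assert [c.members for c in out] == [frozenset("abcd")]

    def test_identical_candidates_collapse(self):
        scorer = table_scorer({frozenset("abc"): 0.7})
        out = svcc.filter_candidates(
            ComplexSet([cx("a", "b", "c"), cx("a", "b", "c")]), scorer
        )
        assert [c.members for c in out] == [frozenset("abc")]

    def test_disjoint_retained(self):
        scorer = table_scorer({}, default=0.5)
        out = svcc.filter_candidates(
            ComplexSet([cx("a", "b", "c"), cx("d", "e", "f")]), scorer
        )
        assert len(out) == 2

    def test_high_overlap_merges_and_rescores(self):
        scores = {
            frozenset("abcde"): 0.9,
            frozenset("abcdx"): 0.8,
            frozenset("abcdex"): 0.95,
        }
        scorer = table_scorer(scores)
        out = svcc.filter_candidates(
            ComplexSet([cx(*"abcde"), cx(*"abcdx")]), scorer, beta=2 / 3
        )
        assert [c.members for c in out] == [frozenset("abcdex")]
        assert out[0].probability == 0.95

    def test_aggressive_merge_limit_small_beta(self):
        scorer = StubScorer(lambda m: min(1.0, len(m) / 10))
        cands = ComplexSet(
            [cx("a", "b", "c"), cx("c", "d", "e"), cx("e", "f", "g")]
        )
        out = svcc.filter_candidates(cands, scorer, beta=1e-9)
        # every overlapping chain collapses into one union complex
        assert len(out) == 1
        assert out[0].members == frozenset("abcdefg")


class TestRunSvcc:
    def test_planted_cliques_recovered_with_density_stub(self):
        from complexwise import synthetic
        from complexwise.evaluation import neighborhood_affinity
        from complexwise.features import weighted_density

        cfg = synthetic.SynthConfig(
            n_background_nodes=60, p_background=0.02, n_complexes=5,
            size_min=5, size_max=5, p_in=1.0, seed=3,
        )
        net, truth, _ = synthetic.generate(cfg)
        w = unit_weights(net)
        scorer = StubScorer(lambda m: min(1.0, weighted_density(m, w)))
        out = svcc.run_svcc(net, scorer, svcc.SvccConfig())
        recovered = sum(
            any(neighborhood_affinity(t, p) > 0.25 for p in out)
            for t in truth
        )
        assert recovered >= 4

    def test_empty_network(self):
        scorer = StubScorer(lambda m: 0.5)
        assert len(svcc.run_svcc(nx.Graph(), scorer)) == 0

    def test_all_outputs_at_least_three_members(self, bench):
        scorer = StubScorer(
            lambda m: min(1.0, 0.1 * len(m))
        )
        out = svcc.run_svcc(bench["wnet"], scorer)
        assert out and all(len(c) >= 3 for c in out)
        nodes = set(bench["wnet"].nodes)
        assert all(c.members <= nodes for c in out)
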
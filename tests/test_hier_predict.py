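"""Top-down traversal: worked examples, oracle equivalence, monotonicity."""

import numpy as np
import pytest

from tehier.hier_predict import (
    THRESHOLD_GRID,
    predict_topdown,
    summarize_attention,
    threshold_sweep,
    PredictionPath,
)
from tehier.hierarchy import load_taxonomy

from .conftest import brute_force_topdown


class MockClassifier:
    """Fixed-probability stand-in for a trained node classifier."""

    def __init__(self, child_labels, probs, alphas=(0.5, 0.5)):
        self.child_labels = list(child_labels)
        self.probs = np.asarray(probs, dtype=float)
        self.alphas = alphas

    def predict_proba(self, feature_pair):
        return self.probs, self.alphas


def mock_classifiers(tax, probs_by_node, alphas=(0.5, 0.5)):
    return {
        node: MockClassifier(tax.children[node], probs, alphas)
        for node, probs in probs_by_node.items()
    }


@pytest.fixture
def fig2_style_classifiers(default_tax):
    """Confident down to LTR, where the max child probability is 0.57."""
    def confident(node, child):
        kids = default_tax.children[node]
        p = np.full(len(kids), 0.05 / max(len(kids) - 1, 1))
        p[kids.index(child)] = 0.95
        p /= p.sum()
        return p

    probs = {
        "TE": confident("TE", "ClassI"),
        "ClassI": confident("ClassI", "LTR"),
        "LTR": np.array([0.57, 0.20, 0.13, 0.10]),  # max 0.57 < 0.60
        "ERV": confident("ERV", "ERV1"),
        "ClassII": confident("ClassII", "TIR"),
        "TIR": confident("TIR", "hAT"),
        "nonLTR": confident("nonLTR", "LINE"),
        "LINE": confident("LINE", "L1"),
        "SINE": confident("SINE", "ID"),
    }
    return mock_classifiers(default_tax, probs)


class TestWorkedExamples:
    def test_stops_at_ltr_below_threshold(self, default_tax, fig2_style_classifiers):
        """A 0.57 max at the LTR node is below 0.60, so the path ends at LTR."""
        path = predict_topdown(None, fig2_style_classifiers, default_tax,
                               threshold=0.60)
        assert path.labels == ["TE", "ClassI", "LTR"]
        assert not path.stopped_at_leaf
        assert path.confidences == pytest.approx([0.95, 0.95])

    def test_reaches_leaf_hat_when_confident(self, default_tax):
        probs = {}
        for node in default_tax.parent_nodes():
            kids = default_tax.children[node]
            target = {"TE": "ClassII", "ClassII": "TIR", "TIR": "hAT"}.get(node, kids[0])
            p = np.full(len(kids), 0.40 / (len(kids) - 1))
            p[kids.index(target)] = 0.60
            probs[node] = p
        classifiers = mock_classifiers(default_tax, probs)
        path = predict_topdown(None, classifiers, default_tax, threshold=0.60)
        assert path.labels == ["TE", "ClassII", "TIR", "hAT"]
        assert path.stopped_at_leaf

    def test_unreachable_threshold_stops_at_root(self, default_tax, fig2_style_classifiers):
        path = predict_topdown(None, fig2_style_classifiers, default_tax,
                               threshold=0.999)
        assert path.labels == ["TE"]
        assert path.confidences == []

    def test_missing_classifier_flags_path(self, default_tax, fig2_style_classifiers):
        del fig2_style_classifiers["ClassI"]
        path = predict_topdown(None, fig2_style_classifiers, default_tax,
                               threshold=0.60)
        assert path.labels == ["TE", "ClassI"]
        assert path.model_missing

    def test_invalid_threshold_refused(self, default_tax, fig2_style_classifiers):
        with pytest.raises(ValueError):
            predict_topdown(None, fig2_style_classifiers, default_tax, threshold=0.0)


def random_tree_and_probs(rng, n_nodes=12):
    labels = [f"n{i}" for i in range(n_nodes)]
    children: dict[str, list[str]] = {}
    for i in range(1, n_nodes):
        parent = labels[int(rng.integers(0, i))]
        children.setdefault(parent, []).append(labels[i])
    tax = load_taxonomy({"children": children, "root": labels[0]})
    probs_by_node = {}
    for node in tax.parent_nodes():
        k = len(tax.children[node])
        p = rng.dirichlet(np.ones(k))
        probs_by_node[node] = p
    return tax, probs_by_node


class TestTraversalOracle:
    def test_matches_brute_force_on_random_tables(self):
        """200 random trees/probability tables x the full threshold grid."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            tax, probs_by_node = random_tree_and_probs(rng)
            classifiers = mock_classifiers(tax, probs_by_node)
            child_order = {n: tax.children[n] for n in probs_by_node}
            prev_len = None
            for t in THRESHOLD_GRID:
                got = predict_topdown(None, classifiers, tax, threshold=t)
                want = brute_force_topdown(probs_by_node, child_order, tax, t)
                assert got.labels == want
                if prev_len is not None:
                    assert len(got.labels) <= prev_len
                prev_len = len(got.labels)

    def test_sweep_equals_pointwise_prediction(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tax, probs_by_node = random_tree_and_probs(rng)
            classifiers = mock_classifiers(tax, probs_by_node)
            sweep = threshold_sweep([None], classifiers, tax, THRESHOLD_GRID)
            for t in THRESHOLD_GRID:
                point = predict_topdown(None, classifiers, tax, threshold=t)
                assert sweep[t][0].labels == point.labels
                assert sweep[t][0].confidences == point.confidences

    def test_paths_weakly_shorten_with_threshold(self):
        rng = np.random.default_rng(8)
        tax, probs_by_node = random_tree_and_probs(rng, n_nodes=20)
        classifiers = mock_classifiers(tax, probs_by_node)
        sweep = threshold_sweep([None] * 3, classifiers, tax, THRESHOLD_GRID)
        for i in range(3):
            lengths = [len(sweep[t][i].labels) for t in THRESHOLD_GRID]
            assert lengths == sorted(lengths, reverse=True)
            # higher-threshold path is a prefix of the lower-threshold path
            for t1, t2 in zip(THRESHOLD_GRID, THRESHOLD_GRID[1:]):
                p1, p2 = sweep[t1][i].labels, sweep[t2][i].labels
                assert p1[: len(p2)] == p2

    def test_grid_validation(self, default_tax, fig2_style_classifiers):
        with pytest.raises(ValueError):
            threshold_sweep([None], fig2_style_classifiers, default_tax, [])
        with pytest.raises(ValueError):
            threshold_sweep([None], fig2_style_classifiers, default_tax, [0.9, 0.5])

    def test_grid_has_ten_sets(self, default_tax, fig2_style_classifiers):
        sweep = threshold_sweep([None], fig2_style_classifiers, default_tax,
                                THRESHOLD_GRID)
        assert len(sweep) == 10


class TestAttentionSummary:
    def _path(self, trace):
        labels = ["TE"] + ["x"] * len(trace)
        return PredictionPath(labels=labels, confidences=[0.9] * len(trace),
                              attention_trace=trace)

    def test_all_balanced(self):
        paths = [self._path([(0.5, 0.5)]) for _ in range(4)]
        df = summarize_attention(paths)
        assert df.loc[0, "equal"] == 1.0

    def test_mixed_dominance(self):
        paths = [self._path([(0.7, 0.3)]), self._path([(0.2, 0.8)])]
        df = summarize_attention(paths)
        assert df.loc[0, "cnn_dominant"] == 0.5
        assert df.loc[0, "rnn_dominant"] == 0.5

    def test_fractions_partition(self):
        rng = np.random.default_rng(10)
        paths = []
        for _ in range(50):
            a = float(rng.random())
            paths.append(self._path([(a, 1 - a)]))
        groups = rng.choice(["g1", "g2"], size=50).tolist()
        df = summarize_attention(paths, grouping=groups)
        for _, row in df.iterrows():
            assert row["cnn_dominant"] + row["rnn_dominant"] + row["equal"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_trace_counts_as_equal(self):
        df = summarize_attention([PredictionPath(labels=["TE"])])
        assert df.loc[0, "equal"] == 1.0
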
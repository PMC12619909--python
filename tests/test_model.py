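"""Node classifier: construction, attention fusion, training, prediction."""

import numpy as np
import pytest

from tehier.features import featurize
from tehier.model import (
    ModelConfig,
    NodeClassifier,
    attention_fuse,
    build_node_classifier,
    crossvalidate,
)


def tiny_config(branch="both", k=3, L=15):
    return ModelConfig(k=k, L=L, conv_channels=(4, 6), gru_units=(6, 4),
                       dense_units=12, learning_rate=5e-3, branch=branch)


def toy_two_class_data(n_per_class=10, k=3, L=15, seed=0):
    """Classes separated by a planted terminal motif — separable by design."""
    rng = np.random.default_rng(seed)
    kmers, onehots, labels = [], [], []
    for label, motif in (("a", "ACGTACGTAC"), ("b", "TTGGCCAATT")):
        for _ in range(n_per_class):
            body = "".join(rng.choice(list("ACGT"), size=80))
            seq = motif + body + motif
            fp = featurize(seq, k=k, L=L)
            kmers.append(fp.kmer)
            onehots.append(fp.onehot)
            labels.append(label)
    return np.stack(kmers), np.stack(onehots), labels


class TestConstruction:
    def test_output_dimension_matches_children(self):
        m = NodeClassifier("TIR", [f"c{i}" for i in range(7)], tiny_config(), seed=1)
        assert m.params["out_W"].data.shape[1] == 7

    def test_single_child_refused(self):
        with pytest.raises(ValueError, match=">= 2 child"):
            NodeClassifier("X", ["only"], tiny_config())

    def test_same_seed_identical_parameters(self):
        a = NodeClassifier("p", ["x", "y"], tiny_config(), seed=42)
        b = NodeClassifier("p", ["x", "y"], tiny_config(), seed=42)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name].data, b.params[name].data)

    def test_different_seed_differs(self):
        a = NodeClassifier("p", ["x", "y"], tiny_config(), seed=1)
        b = NodeClassifier("p", ["x", "y"], tiny_config(), seed=2)
        assert any(
            not np.array_equal(a.params[n].data, b.params[n].data) for n in a.params
        )

    def test_global_dense_parameter_count(self):
        """Dense weight count = flattened conv length x units (+ bias)."""
        cfg = tiny_config()
        m = NodeClassifier("p", ["x", "y"], cfg, seed=0)
        length = 4**cfg.k
        for _ in cfg.conv_channels:
            length //= cfg.pool_width
        flat = length * cfg.conv_channels[-1]
        assert m.params["g_dense_W"].data.shape == (flat, cfg.dense_units)
        assert m.params["g_dense_b"].data.size == cfg.dense_units

    def test_build_wrapper_sets_dims(self):
        m = build_node_classifier("LTR", ["Copia", "Gypsy"], k=3, L=15, seed=3,
                                  config=tiny_config())
        assert m.config.k == 3 and m.config.L == 15


class TestAttentionFuse:
    def test_identical_inputs_balanced(self):
        h = np.arange(8.0)
        w = np.linspace(-1, 1, 8)
        ctx, (ac, ar) = attention_fuse(h, h, w)
        assert ac == pytest.approx(0.5) and ar == pytest.approx(0.5)
        np.testing.assert_allclose(ctx, h)

    def test_weights_sum_to_one_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            hc, hr = rng.standard_normal((2, 16))
            w = rng.standard_normal(16)
            _, (ac, ar) = attention_fuse(hc, hr, w)
            assert ac + ar == pytest.approx(1.0, abs=1e-6)
            assert 0 < ac < 1

    def test_two_dim_hand_arithmetic(self):
        hc = np.array([1.0, 0.0])
        hr = np.array([0.0, 1.0])
        w = np.array([2.0, -1.0])
        e_c, e_r = np.tanh(2.0), np.tanh(-1.0)
        a_c = np.exp(e_c) / (np.exp(e_c) + np.exp(e_r))
        ctx, (ac, ar) = attention_fuse(hc, hr, w)
        assert ac == pytest.approx(a_c, abs=1e-9)
        np.testing.assert_allclose(ctx, a_c * hc + (1 - a_c) * hr, atol=1e-9)

    def test_context_is_convex_combination(self):
        rng = np.random.default_rng(2)
        hc, hr = rng.standard_normal((2, 32))
        ctx, _ = attention_fuse(hc, hr, rng.standard_normal(32))
        lo = np.minimum(hc, hr)
        hi = np.maximum(hc, hr)
        assert ((ctx >= lo - 1e-12) & (ctx <= hi + 1e-12)).all()

    def test_non_finite_refused(self):
        h = np.ones(4)
        bad = np.array([1.0, np.nan, 0.0, 0.0])
        with pytest.raises(ValueError, match="non-finite"):
            attention_fuse(h, bad, np.ones(4))


class TestPredictProba:
    def test_probabilities_sum_to_one(self):
        m = NodeClassifier("p", ["x", "y", "z"], tiny_config(), seed=5)
        km, oh, _ = toy_two_class_data(3)
        probs, alphas = m.predict_proba((km, oh))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(alphas.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_output_layer_gives_uniform(self):
        m = NodeClassifier("p", ["x", "y", "z"], tiny_config(), seed=6)
        m.params["out_W"].data[:] = 0
        m.params["out_b"].data[:] = 0
        km, oh, _ = toy_two_class_data(1)
        probs, _ = m.predict_proba((km[:1], oh[:1]))
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)

    def test_dimension_mismatch_refused(self):
        m = NodeClassifier("p", ["x", "y"], tiny_config(), seed=7)
        with pytest.raises(ValueError, match="expected"):
            m.predict_proba((np.zeros((1, 10)), np.zeros((1, 30, 4))))

    def test_attention_weights_trivial_for_single_branch(self):
        km, oh, _ = toy_two_class_data(2)
        mg = NodeClassifier("p", ["x", "y"], tiny_config("global"), seed=1)
        _, alphas = mg.predict_proba((km, oh))
        np.testing.assert_array_equal(alphas, np.tile([1.0, 0.0], (4, 1)))

    def test_permutation_of_output_head_permutes_probs(self):
        m = NodeClassifier("p", ["x", "y", "z"], tiny_config(), seed=8)
        km, oh, _ = toy_two_class_data(1)
        probs, _ = m.predict_proba((km[:1], oh[:1]))
        perm = [2, 0, 1]
        m2 = NodeClassifier("p", ["z", "x", "y"], tiny_config(), seed=8)
        for name in m.params:
            m2.params[name].data = m.params[name].data.copy()
        m2.params["out_W"].data = m.params["out_W"].data[:, perm]
        m2.params["out_b"].data = m.params["out_b"].data[perm]
        probs2, _ = m2.predict_proba((km[:1], oh[:1]))
        np.testing.assert_allclose(probs2[0], probs[0][perm], atol=1e-12)


class TestTraining:
    def test_epochs_zero_is_identity(self):
        m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=9)
        before = {n: t.data.copy() for n, t in m.params.items()}
        km, oh, y = toy_two_class_data(2)
        log = m.fit(km, oh, y, epochs=0)
        assert log == []
        for n in before:
            np.testing.assert_array_equal(m.params[n].data, before[n])

    def test_missing_child_class_refused(self):
        m = NodeClassifier("p", ["a", "b", "c"], tiny_config(), seed=10)
        km, oh, y = toy_two_class_data(2)
        with pytest.raises(ValueError, match="'c'"):
            m.fit(km, oh, y, epochs=1)

    def test_foreign_label_refused(self):
        m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=10)
        km, oh, y = toy_two_class_data(2)
        y[-1] = "z"
        with pytest.raises(ValueError, match="not children"):
            m.fit(km, oh, y, epochs=1)

    def test_separable_toy_overfits(self):
        """A planted-motif two-class toy reaches training accuracy 1.0."""
        km, oh, y = toy_two_class_data(10)
        m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=11)
        log = m.fit(km, oh, y, epochs=30, batch_size=8, seed=11, patience=None)
        assert max(e["accuracy"] for e in log) == 1.0
        # an overfit model reproduces the label of a training duplicate
        probs, _ = m.predict_proba((km[:1], oh[:1]))
        assert m.child_labels[int(probs.argmax())] == y[0]

    def test_loss_descends_from_initialization(self):
        km, oh, y = toy_two_class_data(10)
        m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=12)
        init_loss, _ = m.evaluate_loss(km, oh, y)
        log = m.fit(km, oh, y, epochs=3, batch_size=8, seed=12, patience=None)
        assert log[-1]["loss"] <= init_loss + 0.05

    def test_fixed_seed_reproducible_trajectory(self):
        km, oh, y = toy_two_class_data(5)
        logs = []
        for _ in range(2):
            m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=13)
            logs.append(m.fit(km, oh, y, epochs=3, batch_size=8, seed=13,
                              patience=None))
        assert logs[0] == logs[1]

    def test_validation_early_stopping(self):
        km, oh, y = toy_two_class_data(10)
        m = NodeClassifier("p", ["a", "b"], tiny_config(), seed=14)
        log = m.fit(km, oh, y, epochs=50, batch_size=8, seed=14,
                    validation=(km, oh, y), patience=2)
        assert len(log) <= 50
        assert "val_loss" in log[0]


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        km, oh, y = toy_two_class_data(5)
        m = NodeClassifier("LTR", ["a", "b"], tiny_config(), seed=15)
        m.fit(km, oh, y, epochs=2, batch_size=8, seed=15, patience=None)
        m.save(str(tmp_path / "node"))
        back = NodeClassifier.load(str(tmp_path / "node"))
        assert back.parent_label == "LTR"
        assert back.child_labels == ["a", "b"]
        for n in m.params:
            np.testing.assert_array_equal(back.params[n].data, m.params[n].data)
        p1, _ = m.predict_proba((km, oh))
        p2, _ = back.predict_proba((km, oh))
        np.testing.assert_array_equal(p1, p2)


class TestCrossValidation:
    def test_stratified_folds_partition(self):
        km, oh, y = toy_two_class_data(25)   # 25 per class, 5 folds of 10
        reports = crossvalidate(km, oh, y, ["a", "b"], folds=5, seed=1,
                                config=tiny_config(), epochs=1, batch_size=16)
        assert len(reports) == 5
        all_val = np.concatenate([r["val_idx"] for r in reports])
        assert sorted(all_val.tolist()) == list(range(50))
        for r in reports:
            labels = np.asarray(y)[r["val_idx"]]
            assert (labels == "a").sum() == 5 and (labels == "b").sum() == 5

    def test_same_seed_same_folds(self):
        km, oh, y = toy_two_class_data(15)
        r1 = crossvalidate(km, oh, y, ["a", "b"], folds=3, seed=2,
                           config=tiny_config(), epochs=0)
        r2 = crossvalidate(km, oh, y, ["a", "b"], folds=3, seed=2,
                           config=tiny_config(), epochs=0)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a["val_idx"], b["val_idx"])

    def test_thin_class_refused(self):
        km, oh, y = toy_two_class_data(3)
        with pytest.raises(ValueError, match="fewer than 5"):
            crossvalidate(km, oh, y, ["a", "b"], folds=5)


class TestClassRecovery:
    """Ablation logic on controlled synthetic contrasts (seed-averaged)."""

    def test_local_branch_wins_on_terminal_signal(self, contrast_results):
        local = np.mean([r["local"] for r in contrast_results["terminal"]])
        glob = np.mean([r["global"] for r in contrast_results["terminal"]])
        assert local > glob

    def test_global_branch_wins_on_composition_signal(self, contrast_results):
        local = np.mean([r["local"] for r in contrast_results["composition"]])
        glob = np.mean([r["global"] for r in contrast_results["composition"]])
        assert glob > local

    def test_fused_tracks_better_branch(self, contrast_results):
        for kind in ("terminal", "composition"):
            fused = np.mean([r["both"] for r in contrast_results[kind]])
            best = max(
                np.mean([r["local"] for r in contrast_results[kind]]),
                np.mean([r["global"] for r in contrast_results[kind]]),
            )
            assert fused >= best - 0.05
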
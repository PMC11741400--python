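import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr
from sklearn.metrics import f1_score

from kinetraits import models

from _oracles import fusion_grid_oracle


def _blocks(rng, n=30, L=5):
    return {
        "kineme": rng.random((n, L, 16)),
        "au": (rng.random((n, L, 17)) > 0.5).astype(float),
        "speech": rng.normal(0, 1, (n, L, 23)),
    }


def _speech_labels(blocks, task="classification"):
    signal = blocks["speech"][:, :, 0].mean(axis=1)
    if task == "classification":
        return (signal > np.median(signal)).astype(float)
    target = 0.5 + 0.3 * np.tanh(signal)
    return target


class TestModelConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            models.ModelConfig(task="ranking")
        with pytest.raises(ValueError):
            models.ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            models.ModelConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            models.ModelConfig(hidden=0)


class TestTrainUnimodal:
    def test_classification_outputs_in_unit_interval(self, rng):
        blocks = _blocks(rng)
        y = _speech_labels(blocks)
        config = models.ModelConfig(
            task="classification", hidden=6, epochs=5, batch_size=16, seed=0
        )
        model, _ = models.train_unimodal(blocks["speech"], y, config)
        preds = model.predict(blocks["speech"])
        assert (preds >= 0).all() and (preds <= 1).all()

    def test_overfits_separable_data(self, rng):
        n, L = 20, 4
        x = np.zeros((n, L, 5))
        y = np.array([0.0, 1.0] * (n // 2))
        x[y == 1, :, 0] = 1.0  # trivially separable
        config = models.ModelConfig(
            task="classification", hidden=8, dropout=0.0, epochs=60,
            batch_size=10, patience=60, seed=1,
        )
        model, _ = models.train_unimodal(x, y, config)
        f1 = f1_score(y, (model.predict(x) > 0.5).astype(int))
        assert f1 >= 0.95

    def test_determinism_same_seed(self, rng):
        blocks = _blocks(rng)
        y = _speech_labels(blocks, "regression")
        config = models.ModelConfig(
            task="regression", hidden=6, epochs=5, batch_size=16, seed=3
        )
        val = (blocks["speech"][:10], y[:10])
        _, a = models.train_unimodal(blocks["speech"][10:], y[10:], config, val)
        _, b = models.train_unimodal(blocks["speech"][10:], y[10:], config, val)
        assert a == b

    def test_single_class_labels_error(self, rng):
        blocks = _blocks(rng, n=8)
        config = models.ModelConfig(task="classification", epochs=1)
        with pytest.raises(ValueError, match="single class"):
            models.train_unimodal(blocks["speech"], np.ones(8), config)

    def test_mixed_sequence_lengths_error(self, rng):
        config = models.ModelConfig(epochs=1)
        ragged = [rng.random((4, 6, 23)), rng.random((4, 5, 23))]
        with pytest.raises(ValueError, match="sequence length"):
            models.train_feature_fusion(ragged, np.zeros(4), config)


class TestFeatureFusion:
    def test_trimodal_scalar_prediction(self, rng):
        blocks = _blocks(rng, n=12)
        y = _speech_labels(blocks, "regression")
        config = models.ModelConfig(task="regression", hidden=5, epochs=2, seed=0)
        model, _ = models.train_feature_fusion(blocks, y, config)
        preds = model.predict(blocks)
        assert preds.shape == (12,)

    def test_single_modality_reduces_to_unimodal_architecture(self, rng):
        blocks = _blocks(rng, n=10)
        config = models.ModelConfig(task="regression", hidden=5, epochs=1, seed=0)
        model, _ = models.train_feature_fusion([blocks["speech"]], np.full(10, 0.5), config)
        unimodal, _ = models.train_unimodal(blocks["speech"], np.full(10, 0.5), config)
        assert {k.split(".")[-1] for k in model.params} == {
            k.split(".")[-1] for k in unimodal.params
        }
        assert model.params["head.W"].data.shape == unimodal.params["head.W"].data.shape

    def test_zeroing_signal_modality_degrades_pcc(self, rng):
        # labels depend only on speech; zeroing speech must hurt (5 seeds)
        deltas = []
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            blocks = _blocks(r, n=80, L=5)
            sig = blocks["speech"][:, :, :3].mean(axis=(1, 2))
            y = 0.5 + 0.4 * np.tanh(3 * sig)
            train = {k: v[:60] for k, v in blocks.items()}
            test = {k: v[60:] for k, v in blocks.items()}
            config = models.ModelConfig(
                task="regression", hidden=8, dropout=0.0, epochs=60,
                batch_size=20, patience=60, seed=seed,
            )
            model, _ = models.train_feature_fusion(train, y[:60], config)
            intact = pearsonr(model.predict(test), y[60:])[0]
            ablated_blocks = dict(test)
            ablated_blocks["speech"] = np.zeros_like(test["speech"])
            ablated = pearsonr(model.predict(ablated_blocks), y[60:])[0]
            if np.isnan(ablated):
                ablated = 0.0
            deltas.append(intact - ablated)
        assert np.mean(deltas) > 0.2


class TestAttentionFusion:
    def test_rows_sum_to_one(self, rng):
        blocks = _blocks(rng, n=10)
        config = models.ModelConfig(task="regression", hidden=5, epochs=2, seed=0)
        model, _ = models.train_attention_fusion(blocks, np.full(10, 0.5), config)
        attention = model.attention(blocks)
        np.testing.assert_allclose(attention.sum(axis=2), 1.0, atol=1e-6)
        assert (attention >= 0).all()

    def test_equal_logits_give_uniform_weights(self, rng):
        blocks = _blocks(rng, n=4)
        config = models.ModelConfig(task="regression", hidden=5, epochs=1, seed=0)
        model = models.AttentionFusionLSTM([16, 17, 23], config)
        model.params["att_out.W"].data[:] = 0.0
        model.params["att_out.b"].data[:] = 0.0
        attention = model.attention(blocks)
        np.testing.assert_allclose(attention, 1.0 / 3.0, atol=1e-12)

    def test_fewer_than_three_modalities_error(self, rng):
        config = models.ModelConfig(epochs=1)
        with pytest.raises(ValueError, match="3 modalities"):
            models.train_attention_fusion(
                [np.random.random((4, 3, 5))] * 2, np.full(4, 0.5), config
            )

    def test_scale_invariance_of_one_modality(self, rng):
        blocks = _blocks(rng, n=8)
        config = models.ModelConfig(task="regression", hidden=5, epochs=2, seed=2)
        model, _ = models.train_attention_fusion(blocks, np.full(8, 0.5), config)
        base = model.predict(blocks)
        scaled = dict(blocks)
        scaled["speech"] = blocks["speech"] * 3.7
        np.testing.assert_allclose(model.predict(scaled), base, atol=1e-4)
        np.testing.assert_allclose(
            model.attention(scaled), model.attention(blocks), atol=1e-4
        )

    def test_signal_modality_receives_highest_weight(self):
        # only speech carries label signal (consistent per-sample mean
        # shifts); grand mean over 5 seeds must favor speech
        means = []
        for seed in range(5):
            r = np.random.default_rng(200 + seed)
            n, L = 80, 5
            mu = r.normal(0, 1, (n, 1, 23))
            blocks = {
                "kineme": r.random((n, L, 16)),
                "au": (r.random((n, L, 17)) > 0.5).astype(float),
                "speech": mu + 0.2 * r.normal(0, 1, (n, L, 23)),
            }
            y = 0.5 + 0.45 * np.tanh(mu[:, 0, :4].mean(axis=1) * 3)
            config = models.ModelConfig(
                task="regression", hidden=8, dropout=0.0, epochs=120,
                batch_size=20, patience=120, seed=seed,
            )
            model, _ = models.train_attention_fusion(blocks, y, config)
            means.append(model.attention(blocks).mean(axis=(0, 1)))
        grand = np.mean(means, axis=0)
        assert grand.argmax() == list(models.MODALITY_ORDER).index("speech")

    def test_traces_api(self, rng):
        blocks = _blocks(rng, n=3)
        config = models.ModelConfig(task="regression", hidden=4, epochs=1, seed=0)
        model, _ = models.train_attention_fusion(blocks, np.full(3, 0.5), config)
        traces = model.traces(blocks, ["a", "b", "c"])
        assert [t.video_id for t in traces] == ["a", "b", "c"]
        assert traces[0].weights.shape == (5, 3)

    def test_trace_csv_export(self, rng, tmp_path):
        import pandas as pd

        blocks = _blocks(rng, n=2)
        config = models.ModelConfig(task="regression", hidden=4, epochs=1, seed=0)
        model, _ = models.train_attention_fusion(blocks, np.full(2, 0.5), config)
        traces = model.traces(blocks, ["a", "b"])
        models.write_attention_traces(tmp_path / "tr.csv", traces)
        df = pd.read_csv(tmp_path / "tr.csv")
        assert list(df.columns) == [
            "video_id", "window_start_s", "w_kineme", "w_au", "w_speech"
        ]
        assert len(df) == 10  # 2 videos x 5 windows
        sums = df[["w_kineme", "w_au", "w_speech"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        blocks = _blocks(rng, n=6)
        config = models.ModelConfig(task="regression", hidden=4, epochs=2, seed=0)
        model, _ = models.train_attention_fusion(blocks, np.full(6, 0.5), config)
        model.save(tmp_path / "model.npz")
        assert (tmp_path / "model.json").exists()
        clone = models.AttentionFusionLSTM([16, 17, 23], config)
        clone.load_weights(tmp_path / "model.npz")
        np.testing.assert_allclose(clone.predict(blocks), model.predict(blocks))


class TestDecisionFuse:
    def test_alpha_one_returns_first_stream(self):
        p1, p2 = np.array([0.1, 0.9]), np.array([0.5, 0.5])
        np.testing.assert_array_equal(
            models.decision_fuse([p1, p2], [1.0, 0.0]), p1
        )

    def test_hand_arithmetic(self):
        fused = models.decision_fuse(
            [np.array([0.2]), np.array([0.6])], [0.5, 0.5]
        )
        assert fused[0] == pytest.approx(0.4)

    def test_trimodal_uniform(self):
        fused = models.decision_fuse(
            [np.array([0.0]), np.array([0.3]), np.array([0.9])],
            [1 / 3, 1 / 3, 1 / 3],
        )
        assert fused[0] == pytest.approx(0.4)

    def test_weight_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            models.decision_fuse([np.zeros(2), np.zeros(2)], [0.5, 0.6])
        with pytest.raises(ValueError, match="non-negative"):
            models.decision_fuse([np.zeros(2), np.zeros(2)], [1.5, -0.5])

    @given(
        bump=st.floats(0.0, 1.0),
        alpha=st.sampled_from([0.0, 0.25, 0.5, 1.0]),
        index=st.integers(0, 3),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotonicity(self, bump, alpha, index):
        rng = np.random.default_rng(7)
        streams = rng.random((2, 4))
        base = models.decision_fuse(streams, [alpha, 1 - alpha])
        raised = streams.copy()
        raised[0, index] += bump
        fused = models.decision_fuse(raised, [alpha, 1 - alpha])
        assert (fused >= base - 1e-12).all()


class TestFitFusionWeights:
    def test_perfect_stream_gets_corner_weight(self, rng):
        labels = rng.random(40)
        streams = np.stack([labels, rng.random(40)])
        result = models.fit_fusion_weights(streams, labels, "regression")
        np.testing.assert_allclose(result.weights, [1.0, 0.0])
        assert result.score >= fusion_grid_oracle(streams, labels) - 1e-9

    def test_symmetric_streams_tie_break_uniform(self, rng):
        p = rng.random(20)
        labels = rng.random(20)
        result = models.fit_fusion_weights(np.stack([p, p]), labels, "regression")
        np.testing.assert_allclose(result.weights, [0.5, 0.5])

    def test_grid_membership_and_simplex(self, rng):
        for _ in range(5):
            streams = rng.random((3, 25))
            labels = rng.random(25)
            result = models.fit_fusion_weights(streams, labels, "regression")
            assert result.weights.sum() == pytest.approx(1.0)
            assert (result.weights >= 0).all()
            steps = result.weights / 0.05
            np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_never_below_unimodal_corners(self, rng):
        streams = rng.random((3, 30))
        labels = rng.random(30)
        result = models.fit_fusion_weights(streams, labels, "regression")
        for corner in np.eye(3):
            corner_score = models._fusion_metric(
                corner @ streams, labels, "regression"
            )
            assert result.score >= corner_score - 1e-12

    def test_classification_uses_f1(self):
        labels = np.array([0, 0, 1, 1, 1, 0], dtype=float)
        streams = np.stack([labels, 1 - labels])
        result = models.fit_fusion_weights(streams, labels, "classification")
        assert result.metric == "f1_macro"
        # every alpha > 0.5 classifies perfectly; the tie-break picks the
        # most uniform maximizer on the grid
        np.testing.assert_allclose(result.weights, [0.55, 0.45])
        assert result.score == pytest.approx(1.0)

    def test_constant_labels_error(self):
        with pytest.raises(ValueError, match="constant"):
            models.fit_fusion_weights(
                np.random.random((2, 10)), np.ones(10), "regression"
            )

    def test_trimodal_grid_has_231_points(self):
        assert len(models._simplex_grid(3)) == 231
        assert len(models._simplex_grid(2)) == 21
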
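"""Recurrent trait predictors and fusion strategies.

A single-hidden-layer LSTM per modality feeds a one-neuron head (sigmoid for
classification, linear for regression). Feature fusion concatenates the
per-modality LSTM outputs; attention fusion computes per-window softmax
weights over the three modalities and additively fuses their
layer-normalized representations; decision fusion convexly combines
unimodal score streams with weights grid-searched at step 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import f1_score

from kinetraits.nn.autodiff import Tensor, concat, layer_norm_raw, softmax
from kinetraits.nn.layers import (
    dense,
    init_dense,
    init_layer_norm,
    init_lstm,
    layer_norm,
    lstm_forward,
)
from kinetraits.nn.training import bce_with_logits_loss, fit, mae_loss

MODALITY_ORDER = ("kineme", "au", "speech")

ATTENTION_FC_UNITS = 12
GRID_STEP = 0.05


@dataclass
class ModelConfig:
    """Training hyperparameters."""

    task: str = "regression"  # 'regression' | 'classification'
    hidden: int = 20
    dropout: float = 0.2
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 0.01
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AttentionTrace:
    """Per-window modality importance weights for one video."""

    video_id: str
    weights: np.ndarray  # L x 3, rows sum to 1
    modalities: tuple[str, ...] = MODALITY_ORDER

    def __post_init__(self) -> None:
        rows = self.weights.sum(axis=1)
        if np.any(self.weights < -1e-9) or np.any(np.abs(rows - 1) > 1e-6):
            raise ValueError("attention rows must be non-negative and sum to 1")


@dataclass
class FusionWeights:
    """Convex decision-fusion weights on the 0.05 grid."""

    weights: np.ndarray
    metric: str
    score: float


def _as_blocks(blocks) -> list[np.ndarray]:  # noqa: ANN001
    if isinstance(blocks, dict):
        blocks = [blocks[m] for m in MODALITY_ORDER if m in blocks]
    elif isinstance(blocks, np.ndarray) and blocks.ndim == 3:
        blocks = [blocks]
    out = [np.asarray(b, dtype=float) for b in blocks]
    lengths = {b.shape[1] for b in out}
    if len(lengths) > 1:
        raise ValueError(f"modality blocks disagree on sequence length: {lengths}")
    sizes = {b.shape[0] for b in out}
    if len(sizes) > 1:
        raise ValueError(f"modality blocks disagree on sample count: {sizes}")
    return out


def _check_labels(y: np.ndarray, task: str) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if task == "classification":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("classification labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
    return y


def _seq_tensors(x: np.ndarray) -> list[Tensor]:
    return [Tensor(x[:, t, :]) for t in range(x.shape[1])]


class _BaseModel:
    """Shared fit/predict plumbing for the LSTM predictors."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)

    # subclasses implement _forward(blocks, train) -> Tensor (B, 1)

    def _dropout(self, h: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout
        if not train or rate == 0:
            return h
        mask = (self._rng.random(h.data.shape) >= rate) / (1 - rate)
        return h * Tensor(mask)

    def _head_output(self, h: Tensor) -> Tensor:
        return dense(self.params, h, "head")

    def _loss(self, out: Tensor, y: np.ndarray) -> Tensor:
        if self.config.task == "classification":
            return bce_with_logits_loss(out, y.reshape(-1, 1))
        return mae_loss(out, y.reshape(-1, 1))

    def fit(
        self,
        blocks: list[np.ndarray],
        y: np.ndarray,
        validation: tuple | None = None,
    ) -> float:
        y = _check_labels(y, self.config.task)
        config = self.config

        def forward_loss(indices: np.ndarray, train: bool) -> Tensor:
            batch = [b[indices] for b in blocks]
            return self._loss(self._forward(batch, train), y[indices])

        val_loss = None
        if validation is not None:
            val_blocks = _as_blocks(validation[0])
            val_y = np.asarray(validation[1], dtype=float).ravel()

            def val_loss() -> float:
                return float(self._loss(self._forward(val_blocks, False), val_y).data)

        return fit(
            self.params,
            forward_loss,
            n_train=len(y),
            val_loss=val_loss,
            lr=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            patience=config.patience,
            rng=self._rng,
        )

    def predict(self, blocks) -> np.ndarray:  # noqa: ANN001
        out = self._forward(_as_blocks(blocks), False)
        scores = out.data.ravel()
        if self.config.task == "classification":
            scores = 1.0 / (1.0 + np.exp(-scores))
        return scores

    def save(self, path) -> None:  # noqa: ANN001
        """Write weights (npz) plus a portable JSON sidecar describing the
        architecture and training config."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez(path, **{k: p.data for k, p in self.params.items()})
        sidecar = {
            "architecture": type(self).__name__,
            "config": asdict(self.config),
            "parameters": {k: list(p.data.shape) for k, p in self.params.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def load_weights(self, path) -> None:  # noqa: ANN001
        data = np.load(path)
        for key, p in self.params.items():
            p.data = data[key]


class UnimodalLSTM(_BaseModel):
    """Single LSTM layer + one-neuron head (Fig 3's unimodal path)."""

    def __init__(self, input_dim: int, config: ModelConfig) -> None:
        super().__init__(config)
        self.params.update(init_lstm(self._rng, input_dim, config.hidden, "lstm"))
        self.params.update(init_dense(self._rng, config.hidden, 1, "head"))

    def _forward(self, blocks: list[np.ndarray], train: bool) -> Tensor:
        h = lstm_forward(self.params, _seq_tensors(blocks[0]), self.config.hidden)
        return self._head_output(self._dropout(h, train))


class FeatureFusionLSTM(_BaseModel):
    """One LSTM per modality, outputs concatenated, one-neuron head."""

    def __init__(self, input_dims: list[int], config: ModelConfig) -> None:
        super().__init__(config)
        self.n_modalities = len(input_dims)
        for m, dim in enumerate(input_dims):
            self.params.update(init_lstm(self._rng, dim, config.hidden, f"lstm{m}"))
        self.params.update(
            init_dense(self._rng, config.hidden * len(input_dims), 1, "head")
        )

    def _forward(self, blocks: list[np.ndarray], train: bool) -> Tensor:
        states = [
            lstm_forward(
                self.params, _seq_tensors(block), self.config.hidden, f"lstm{m}"
            )
            for m, block in enumerate(blocks)
        ]
        merged = concat(states, axis=1) if len(states) > 1 else states[0]
        return self._head_output(self._dropout(merged, train))


class AttentionFusionLSTM(_BaseModel):
    """Additive soft-attention trimodal fusion.

    Per window, the three LSTM states are concatenated, passed through a
    12-unit tanh layer and a 3-way softmax; each modality state is
    layer-normalized, scaled by its weight and summed. The head reads the
    fused state of the final window. Raw input windows get a parameter-free
    layer normalization, which makes predictions exactly invariant to a
    uniform positive rescaling of any one modality's block.
    """

    def __init__(self, input_dims: list[int], config: ModelConfig) -> None:
        super().__init__(config)
        if len(input_dims) != 3:
            raise ValueError("attention fusion requires exactly 3 modalities")
        for m, dim in enumerate(input_dims):
            self.params.update(init_lstm(self._rng, dim, config.hidden, f"lstm{m}"))
            self.params.update(init_layer_norm(config.hidden, f"ln{m}"))
        self.params.update(
            init_dense(self._rng, 3 * config.hidden, ATTENTION_FC_UNITS, "att_fc")
        )
        self.params.update(init_dense(self._rng, ATTENTION_FC_UNITS, 3, "att_out"))
        self.params.update(init_dense(self._rng, config.hidden, 1, "head"))

    def _forward_with_attention(
        self, blocks: list[np.ndarray], train: bool
    ) -> tuple[Tensor, np.ndarray]:
        hidden = self.config.hidden
        sequences = []
        for m, block in enumerate(blocks):
            x_seq = [layer_norm_raw(t) for t in _seq_tensors(block)]
            sequences.append(
                lstm_forward(self.params, x_seq, hidden, f"lstm{m}", True)
            )
        L = len(sequences[0])
        attention = np.empty((blocks[0].shape[0], L, 3))
        fused = None
        for t in range(L):
            states = [sequences[m][t] for m in range(3)]
            u = dense(self.params, concat(states, axis=1), "att_fc").tanh()
            weights = softmax(dense(self.params, u, "att_out"))
            attention[:, t, :] = weights.data
            normalized = [
                layer_norm(self.params, states[m], f"ln{m}") for m in range(3)
            ]
            fused = sum(
                (weights.cols(m, m + 1) * normalized[m] for m in range(3)),
                start=Tensor(np.zeros_like(normalized[0].data)),
            )
        out = self._head_output(self._dropout(fused, train))
        return out, attention

    def _forward(self, blocks: list[np.ndarray], train: bool) -> Tensor:
        return self._forward_with_attention(blocks, train)[0]

    def attention(self, blocks) -> np.ndarray:  # noqa: ANN001
        """Per-window modality weights, shape (N, L, 3)."""
        _, attention = self._forward_with_attention(_as_blocks(blocks), False)
        return attention

    def traces(self, blocks, video_ids: list[str]) -> list[AttentionTrace]:  # noqa: ANN001
        weights = self.attention(blocks)
        return [
            AttentionTrace(video_id=vid, weights=weights[i])
            for i, vid in enumerate(video_ids)
        ]


def train_unimodal(
    block: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    validation: tuple | None = None,
) -> tuple[UnimodalLSTM, float]:
    """Train a unimodal LSTM; returns (model, best monitored loss)."""
    blocks = _as_blocks([block])
    model = UnimodalLSTM(blocks[0].shape[2], config)
    score = model.fit(blocks, y, validation)
    return model, score


def train_feature_fusion(
    blocks,  # noqa: ANN001
    y: np.ndarray,
    config: ModelConfig,
    validation: tuple | None = None,
) -> tuple[FeatureFusionLSTM, float]:
    """Train a feature-fusion LSTM over 1-3 modality blocks."""
    blocks = _as_blocks(blocks)
    model = FeatureFusionLSTM([b.shape[2] for b in blocks], config)
    score = model.fit(blocks, y, validation)
    return model, score


def train_attention_fusion(
    blocks,  # noqa: ANN001
    y: np.ndarray,
    config: ModelConfig,
    validation: tuple | None = None,
) -> tuple[AttentionFusionLSTM, float]:
    """Train the trimodal additive-attention model."""
    blocks = _as_blocks(blocks)
    if len(blocks) != 3:
        raise ValueError("attention fusion requires exactly 3 modalities")
    model = AttentionFusionLSTM([b.shape[2] for b in blocks], config)
    score = model.fit(blocks, y, validation)
    return model, score


def write_attention_traces(path, traces, times=None) -> None:  # noqa: ANN001
    """Export traces as CSV (video_id, window_start_s, w_kineme, w_au,
    w_speech)."""
    import pandas as pd

    rows = []
    for trace in traces:
        starts = (
            times[trace.video_id]
            if times is not None
            else np.arange(len(trace.weights), dtype=float)
        )
        for t, row in zip(starts, trace.weights):
            rows.append(
                {
                    "video_id": trace.video_id,
                    "window_start_s": float(t),
                    "w_kineme": row[0],
                    "w_au": row[1],
                    "w_speech": row[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def decision_fuse(streams, weights) -> np.ndarray:  # noqa: ANN001
    """Element-wise convex combination of score streams."""
    streams = np.atleast_2d(np.asarray(streams, dtype=float))
    weights = np.asarray(weights, dtype=float).ravel()
    if len(weights) != streams.shape[0]:
        raise ValueError("one weight per stream required")
    if np.any(weights < -1e-9):
        raise ValueError("fusion weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"fusion weights must sum to 1, got {weights.sum()}")
    return weights @ streams


def _simplex_grid(m: int, step: float = GRID_STEP) -> np.ndarray:
    """All non-negative weight vectors on the step lattice summing to 1."""
    n_steps = int(round(1.0 / step))
    points = [
        combo
        for combo in product(range(n_steps + 1), repeat=m)
        if sum(combo) == n_steps
    ]
    return np.asarray(points, dtype=float) * step


def _fusion_metric(fused: np.ndarray, labels: np.ndarray, task: str) -> float:
    if task == "classification":
        return float(f1_score(labels, (fused > 0.5).astype(int), average="macro"))
    return float(pearsonr(fused, labels)[0])


def fit_fusion_weights(
    streams,  # noqa: ANN001
    labels: np.ndarray,
    task: str = "regression",
    step: float = GRID_STEP,
) -> FusionWeights:
    """Exhaustive grid search for decision-fusion weights on the simplex.

    Maximizes macro F1 (classification) or PCC (regression); ties break
    toward the more uniform weight vector, then lexicographically.
    """
    streams = np.atleast_2d(np.asarray(streams, dtype=float))
    labels = np.asarray(labels, dtype=float).ravel()
    if streams.shape[0] < 2:
        raise ValueError("need at least 2 score streams to fuse")
    if streams.shape[1] != len(labels):
        raise ValueError("streams and labels disagree on length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant; fusion metric is undefined")
    grid = _simplex_grid(streams.shape[0], step)
    best: tuple | None = None
    for weights in grid:
        fused = weights @ streams
        metric = _fusion_metric(fused, labels, task)
        key = (-round(metric, 12), round(float(np.var(weights)), 12), tuple(weights))
        if best is None or key < best[0]:
            best = (key, weights, metric)
    metric_name = "f1_macro" if task == "classification" else "pcc"
    return FusionWeights(weights=best[1], metric=metric_name, score=best[2])
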
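"""Prediction settings and evaluation protocols.

Covers median dichotomization, thin-slice chunking on the window grid,
chunk-to-video aggregation, the metric set (classification accuracy +
macro F1; regression accuracy = 1 - MAE + PCC) and the two validation
protocols (fixed manifest splits and repeated k-fold over videos).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import accuracy_score, f1_score

from kinetraits._grid import DEFAULT_HOP_S, DEFAULT_WINDOW_S
from kinetraits.encoding import SegmentEncoding, zscore_block
from kinetraits.models import (
    MODALITY_ORDER,
    ModelConfig,
    decision_fuse,
    fit_fusion_weights,
    train_attention_fusion,
    train_feature_fusion,
    train_unimodal,
)

logger = logging.getLogger(__name__)

UNIMODAL_MODELS = ("kineme", "au", "speech")
MODEL_NAMES = UNIMODAL_MODELS + ("ff", "af", "df")


def dichotomize_median(
    scores: np.ndarray, train_scores: np.ndarray | None = None
) -> np.ndarray:
    """Binary labels: 1 iff score strictly exceeds the training median.

    Scores exactly at the median go to the negative class, which reproduces
    the mildly imbalanced class shares the median split induces.
    """
    scores = np.asarray(scores, dtype=float)
    if train_scores is None:
        train_scores = scores
    train_scores = np.asarray(train_scores, dtype=float)
    if len(train_scores) < 2:
        raise ValueError("need at least 2 scores to dichotomize")
    if np.ptp(train_scores) == 0:
        raise ValueError("all training scores are equal; median split undefined")
    return (scores > np.median(train_scores)).astype(int)


def make_slices(
    encoding: SegmentEncoding,
    slice_s: float,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> list[SegmentEncoding]:
    """Cut a video into contiguous non-overlapping chunks of ``slice_s``
    seconds on the window grid; a trailing remainder is dropped. Each chunk
    inherits the source video's label downstream."""
    if slice_s < window_s:
        raise ValueError(
            f"slice_s={slice_s} shorter than one {window_s} s window"
        )
    windows_per_chunk = floor((slice_s - window_s) / hop_s) + 1
    chunks: list[SegmentEncoding] = []
    i = 0
    while True:
        start_t = i * slice_s
        mask = (encoding.times >= start_t - 1e-9) & (
            encoding.times + window_s <= start_t + slice_s + 1e-9
        )
        idx = np.flatnonzero(mask)[:windows_per_chunk]
        if len(idx) < windows_per_chunk:
            break
        chunks.append(
            SegmentEncoding(
                video_id=f"{encoding.video_id}#chunk{i}",
                times=encoding.times[idx],
                kineme=encoding.kineme[idx],
                au=encoding.au[idx],
                speech=encoding.speech[idx],
            )
        )
        i += 1
    return chunks


def aggregate_video(chunk_predictions: np.ndarray, task: str) -> float:
    """Majority label (ties to the positive class) or mean value."""
    preds = np.asarray(chunk_predictions, dtype=float).ravel()
    if preds.size == 0:
        raise ValueError("no chunk predictions to aggregate")
    if task == "classification":
        positive = (preds > 0.5).sum()
        negative = preds.size - positive
        if positive == negative:
            logger.info("tied majority vote; resolving to the positive class")
            return 1.0
        return float(positive > negative)
    return float(preds.mean())


def compute_metrics(
    predictions: np.ndarray, truths: np.ndarray, task: str
) -> dict[str, float]:
    """Metric set per task. Undefined PCC (constant vector) is reported as
    NaN, never coerced to 0."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths disagree on length")
    if len(truths) < 2:
        raise ValueError("need at least 2 samples to compute metrics")
    if task == "classification":
        hard = (predictions > 0.5).astype(int)
        return {
            "acc": float(accuracy_score(truths.astype(int), hard)),
            "f1": float(f1_score(truths.astype(int), hard, average="macro")),
        }
    mae = float(np.mean(np.abs(predictions - truths)))
    if np.ptp(predictions) == 0 or np.ptp(truths) == 0:
        pcc = float("nan")
    else:
        pcc = float(pearsonr(predictions, truths)[0])
    return {"acc": 1.0 - mae, "pcc": pcc}


@dataclass
class EvaluationReport:
    """Per-run metric records plus mean +/- sd summaries."""

    records: pd.DataFrame
    task: str
    level: str
    slice_s: float | None

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.records.columns if c in ("acc", "f1", "pcc")]
        grouped = self.records.groupby("model")[metrics]
        out = grouped.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()

    def to_csv(self, path) -> None:  # noqa: ANN001
        self.records.to_csv(path, index=False)


@dataclass
class _RunData:
    """Chunked arrays for one train/val/test split."""

    blocks: dict[str, dict[str, np.ndarray]]  # role -> modality -> (n, L, D)
    targets: dict[str, np.ndarray]  # role -> per-chunk target
    chunk_video: dict[str, np.ndarray]  # role -> per-chunk source-video index
    video_targets: dict[str, np.ndarray]  # role -> per-video target


def _chunk_arrays(
    encodings: list[SegmentEncoding],
    indices: np.ndarray,
    slice_s: float | None,
) -> tuple[dict[str, list[np.ndarray]], np.ndarray]:
    blocks: dict[str, list[np.ndarray]] = {m: [] for m in MODALITY_ORDER}
    owner = []
    for vi in indices:
        enc = encodings[vi]
        chunks = make_slices(enc, slice_s) if slice_s is not None else [enc]
        for chunk in chunks:
            for m in MODALITY_ORDER:
                blocks[m].append(chunk.blocks()[m])
            owner.append(vi)
    if not owner:
        raise ValueError("no chunks produced; videos shorter than slice_s?")
    return blocks, np.asarray(owner)


def _prepare_run(
    encodings: list[SegmentEncoding],
    scores: np.ndarray,
    roles: dict[str, np.ndarray],
    task: str,
    slice_s: float | None,
) -> _RunData:
    # leakage guard: a video's chunks never span a train/test boundary
    all_idx = np.concatenate(list(roles.values()))
    assert len(all_idx) == len(set(all_idx.tolist())), "video appears in two roles"

    targets_by_video = scores.copy()
    if task == "classification":
        targets_by_video = dichotomize_median(
            scores, scores[roles["train"]]
        ).astype(float)

    blocks: dict[str, dict[str, np.ndarray]] = {}
    targets: dict[str, np.ndarray] = {}
    chunk_video: dict[str, np.ndarray] = {}
    raw_speech: dict[str, list[np.ndarray]] = {}
    for role, indices in roles.items():
        role_blocks, owner = _chunk_arrays(encodings, indices, slice_s)
        raw_speech[role] = role_blocks["speech"]
        blocks[role] = {
            "kineme": np.stack(role_blocks["kineme"]),
            "au": np.stack(role_blocks["au"]),
        }
        targets[role] = targets_by_video[owner]
        chunk_video[role] = owner
    # z-score speech on training chunks only
    _, stats = zscore_block(raw_speech["train"])
    for role in roles:
        normalized, _ = zscore_block(raw_speech[role], stats)
        blocks[role]["speech"] = np.stack(normalized)
    video_targets = {role: targets_by_video[idx] for role, idx in roles.items()}
    return _RunData(
        blocks=blocks,
        targets=targets,
        chunk_video=chunk_video,
        video_targets=video_targets,
    )


def _train_predict(
    data: _RunData, model_name: str, config: ModelConfig
) -> np.ndarray:
    """Train one model spec and return per-test-chunk predictions."""
    train, val, test = data.blocks["train"], data.blocks["val"], data.blocks["test"]
    y_train, y_val = data.targets["train"], data.targets["val"]
    if model_name in UNIMODAL_MODELS:
        model, _ = train_unimodal(
            train[model_name], y_train, config, (val[model_name], y_val)
        )
        return model.predict(test[model_name])
    if model_name == "ff":
        model, _ = train_feature_fusion(train, y_train, config, (val, y_val))
        return model.predict(test)
    if model_name == "af":
        model, _ = train_attention_fusion(train, y_train, config, (val, y_val))
        return model.predict(test)
    if model_name == "df":
        val_streams, test_streams = [], []
        for modality in UNIMODAL_MODELS:
            model, _ = train_unimodal(
                train[modality], y_train, config, (val[modality], y_val)
            )
            val_streams.append(model.predict(val[modality]))
            test_streams.append(model.predict(test[modality]))
        weights = fit_fusion_weights(np.stack(val_streams), y_val, config.task)
        return decision_fuse(np.stack(test_streams), weights.weights)
    raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def _score_run(
    data: _RunData, predictions: np.ndarray, task: str, level: str
) -> dict[str, float]:
    if level == "chunk":
        return compute_metrics(predictions, data.targets["test"], task)
    owners = data.chunk_video["test"]
    video_ids = np.unique(owners)
    video_preds = np.asarray(
        [aggregate_video(predictions[owners == v], task) for v in video_ids]
    )
    truth_by_video = {}
    for v, t in zip(owners, data.targets["test"]):
        truth_by_video[v] = t
    truths = np.asarray([truth_by_video[v] for v in video_ids])
    return compute_metrics(video_preds, truths, task)


def _kfold_indices(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[f::n_folds] for f in range(n_folds)]


def run_protocol(
    encodings: list[SegmentEncoding],
    scores: np.ndarray,
    config: ModelConfig,
    models: tuple[str, ...] = ("speech",),
    protocol: str = "repeated-k-fold",
    splits: list[str] | None = None,
    n_folds: int = 10,
    n_repeats: int = 5,
    slice_s: float | None = None,
    level: str = "video",
    val_fraction: float = 0.25,
    seed: int = 0,
) -> EvaluationReport:
    """Run a full evaluation protocol over one trait.

    ``fixed-split`` uses the provided per-video split tags; ``repeated-k-fold``
    partitions videos (never chunks) into ``n_folds`` folds, repeated
    ``n_repeats`` times with distinct seeds, reporting one record per
    model x run. A validation subset is carved from each training set for
    early stopping and decision-fusion weight fitting.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != len(encodings):
        raise ValueError("scores and encodings disagree on length")
    rng = np.random.default_rng(seed)
    role_sets: list[dict[str, np.ndarray]] = []
    if protocol == "fixed-split":
        if splits is None:
            raise ValueError("fixed-split protocol requires split tags")
        tags = np.asarray(splits)
        roles = {
            "train": np.flatnonzero(tags == "train"),
            "val": np.flatnonzero(tags == "val"),
            "test": np.flatnonzero(tags == "test"),
        }
        if len(roles["val"]) == 0:
            train = roles["train"]
            n_val = max(1, int(round(val_fraction * len(train))))
            shuffled = rng.permutation(train)
            roles["val"] = shuffled[:n_val]
            roles["train"] = shuffled[n_val:]
        role_sets.append(roles)
    elif protocol == "repeated-k-fold":
        if n_folds > len(encodings):
            raise ValueError("fold count exceeds video count")
        for repeat in range(n_repeats):
            fold_rng = np.random.default_rng(seed + 1000 * repeat)
            folds = _kfold_indices(len(encodings), n_folds, fold_rng)
            for f in range(n_folds):
                test = folds[f]
                rest = np.concatenate([folds[j] for j in range(n_folds) if j != f])
                n_val = max(1, int(round(val_fraction * len(rest))))
                shuffled = fold_rng.permutation(rest)
                role_sets.append(
                    {
                        "train": shuffled[n_val:],
                        "val": shuffled[:n_val],
                        "test": test,
                    }
                )
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    records = []
    for run_id, roles in enumerate(role_sets):
        data = _prepare_run(encodings, scores, roles, config.task, slice_s)
        for model_name in models:
            run_config = ModelConfig(
                **{**config.__dict__, "seed": config.seed + 7919 * run_id}
            )
            predictions = _train_predict(data, model_name, run_config)
            metrics = _score_run(data, predictions, config.task, level)
            records.append({"run": run_id, "model": model_name, **metrics})
    return EvaluationReport(
        records=pd.DataFrame(records), task=config.task, level=level, slice_s=slice_s
    )
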
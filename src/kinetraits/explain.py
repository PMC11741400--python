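"""Explanation surfaces: percentile-dominant behavioral patterns and
per-modality attention contributions.

High/low groups are the top and bottom 10-percentile videos per trait; the
most frequent four kinemes and five dominant AUs summarize each group.
Attention traces are averaged windows -> videos -> runs, with a standard
error over runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import ceil
from pathlib import Path

import numpy as np

from kinetraits.encoding import SegmentEncoding
from kinetraits.models import MODALITY_ORDER, AttentionTrace

TOP_KINEMES = 4
TOP_AUS = 5


@dataclass
class TraitExplanation:
    """Ranked dominant kinemes and AUs for one trait group."""

    trait: str
    group: str  # 'high' | 'low'
    kinemes: list[tuple[int, float]]  # (label, proportion), <= 4, non-increasing
    aus: list[tuple[int, float]]  # (AU index 1..17, proportion), <= 5
    group_size: int


@dataclass
class ModalityContribution:
    """Mean attention weight per modality with standard error over runs."""

    trait: str
    means: dict[str, float]
    standard_errors: dict[str, float]
    n_runs: int


def percentile_groups(
    scores: np.ndarray,
    video_ids: list[str] | None = None,
    pct: float = 10.0,
) -> tuple[list[str], list[str]]:
    """(high ids, low ids): the top and bottom ``pct``-percentile videos.

    Group size is ceil(pct% * n); boundary ties resolve by stable
    score-then-id ordering.
    """
    if not 0 < pct <= 50:
        raise ValueError("pct must lie in (0, 50]")
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if video_ids is None:
        video_ids = [str(i) for i in range(n)]
    if len(video_ids) != n:
        raise ValueError("scores and video_ids disagree on length")
    size = ceil(pct / 100.0 * n)
    order = sorted(range(n), key=lambda i: (scores[i], video_ids[i]))
    low = [video_ids[i] for i in order[:size]]
    high = [video_ids[i] for i in reversed(order[-size:])]
    return high, low


def dominant_patterns(
    trait: str,
    group: str,
    encodings: list[SegmentEncoding],
) -> TraitExplanation:
    """Most frequent kinemes and dominant AUs over all windows of a group.

    Frequencies are per-group window proportions; ties rank the lower
    index first.
    """
    if not encodings:
        raise ValueError("empty group")
    kineme_counts = sum(enc.kineme.sum(axis=0) for enc in encodings)
    au_counts = sum(enc.au.sum(axis=0) for enc in encodings)
    total_windows = sum(enc.n_windows for enc in encodings)

    def top(counts: np.ndarray, limit: int) -> list[tuple[int, float]]:
        order = sorted(range(len(counts)), key=lambda j: (-counts[j], j))
        ranked = [
            (j + 1, float(counts[j]) / total_windows)
            for j in order
            if counts[j] > 0
        ]
        return ranked[:limit]

    return TraitExplanation(
        trait=trait,
        group=group,
        kinemes=top(np.asarray(kineme_counts, dtype=float), TOP_KINEMES),
        aus=top(np.asarray(au_counts, dtype=float), TOP_AUS),
        group_size=len(encodings),
    )


def explain_trait(
    trait: str,
    scores: np.ndarray,
    encodings: list[SegmentEncoding],
    pct: float = 10.0,
) -> tuple[TraitExplanation, TraitExplanation]:
    """(high-group, low-group) explanations for one trait."""
    ids = [enc.video_id for enc in encodings]
    by_id = {enc.video_id: enc for enc in encodings}
    high, low = percentile_groups(scores, ids, pct)
    return (
        dominant_patterns(trait, "high", [by_id[v] for v in high]),
        dominant_patterns(trait, "low", [by_id[v] for v in low]),
    )


def summarize_attention(
    trait: str,
    traces_per_run: list[list[AttentionTrace]],
) -> ModalityContribution:
    """Aggregate attention weights over windows, then videos, then runs.

    ``traces_per_run`` holds one list of per-video traces per training run;
    the standard error is computed over the run means.
    """
    if len(traces_per_run) < 2:
        raise ValueError("need >= 2 runs to estimate a standard error")
    run_means = []
    for traces in traces_per_run:
        if not traces:
            raise ValueError("a run contains no traces")
        video_means = np.stack([t.weights.mean(axis=0) for t in traces])
        if video_means.shape[1] != len(MODALITY_ORDER):
            raise ValueError("inconsistent trace shapes")
        run_means.append(video_means.mean(axis=0))
    run_means = np.stack(run_means)  # n_runs x 3
    mean = run_means.mean(axis=0)
    se = run_means.std(axis=0, ddof=1) / np.sqrt(len(run_means))
    return ModalityContribution(
        trait=trait,
        means=dict(zip(MODALITY_ORDER, mean.tolist())),
        standard_errors=dict(zip(MODALITY_ORDER, se.tolist())),
        n_runs=len(run_means),
    )


def write_explanations(
    path: str | Path,
    explanations: list[TraitExplanation],
    contributions: list[ModalityContribution] | None = None,
) -> None:
    """Dump explanation report as JSON."""
    payload = {
        "explanations": [asdict(e) for e in explanations],
        "contributions": [asdict(c) for c in contributions or []],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
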
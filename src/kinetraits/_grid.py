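"""Shared sliding-window grid arithmetic.

Every modality is encoded on the same grid of fixed-length windows with a
fixed hop, so all grid math lives here and is converted from seconds to
frames exactly once.
"""

from __future__ import annotations

import numpy as np

DEFAULT_WINDOW_S = 2.0
DEFAULT_HOP_S = 1.0


def window_frames(window_s: float, frame_rate: float) -> int:
    """Window length in frames (rounded to nearest frame, at least 1)."""
    return max(1, int(round(window_s * frame_rate)))


def n_windows(n_frames: int, win: int, hop: int) -> int:
    """Number of complete windows of length ``win`` with hop ``hop``."""
    if n_frames < win:
        return 0
    return (n_frames - win) // hop + 1


def window_starts(n_frames: int, win: int, hop: int) -> np.ndarray:
    """Start indices (frames) of every complete window."""
    count = n_windows(n_frames, win, hop)
    return np.arange(count) * hop


def window_times(n_frames: int, win: int, hop: int, frame_rate: float) -> np.ndarray:
    """Start times (seconds) of every complete window."""
    return window_starts(n_frames, win, hop) / float(frame_rate)
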
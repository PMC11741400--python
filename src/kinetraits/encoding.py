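"""Per-window feature blocks for the three behavioral modalities.

All blocks live on a shared grid of 2 s windows with a 1 s hop: an L x k
one-hot kineme block, an L x 17 binary dominant-AU block, and an L x 23
z-scored speech block (per-window means of F0, voicing probability, ZCR and
20 MFCCs extracted over 93 ms frames with a 70 ms hop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

from kinetraits._grid import (
    DEFAULT_HOP_S,
    DEFAULT_WINDOW_S,
    n_windows,
    window_frames,
)
from kinetraits.io import AUSeries

#: Fixed LLD channel order: F0, voicing probability, ZCR, then 20 MFCCs.
LLD_COLUMNS: tuple[str, ...] = ("F0", "voicing", "zcr") + tuple(
    f"mfcc_{i:02d}" for i in range(1, 21)
)

N_LLD = len(LLD_COLUMNS)  # 23
N_MFCC = 20

LLD_WINDOW_S = 0.093
LLD_HOP_S = 0.070  # 93 ms window with 23 ms overlap

_F0_MIN_HZ = 60.0
_F0_MAX_HZ = 500.0
_VOICING_THRESHOLD = 0.3


@dataclass
class SegmentEncoding:
    """The three aligned per-window feature blocks of one video."""

    video_id: str
    times: np.ndarray  # window start times, seconds
    kineme: np.ndarray  # L x k one-hot
    au: np.ndarray  # L x 17 binary
    speech: np.ndarray  # L x 23 real

    def __post_init__(self) -> None:
        L = len(self.times)
        for name in ("kineme", "au", "speech"):
            block = getattr(self, name)
            if block.shape[0] != L:
                raise ValueError(
                    f"{name} block has {block.shape[0]} windows, expected {L}"
                )

    @property
    def n_windows(self) -> int:
        return len(self.times)

    def blocks(self) -> dict[str, np.ndarray]:
        return {"kineme": self.kineme, "au": self.au, "speech": self.speech}


def one_hot_kinemes(labels: np.ndarray, k: int) -> np.ndarray:
    """One-hot encode kineme labels (1..k) into an L x k binary block."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > k):
        bad = labels[(labels < 1) | (labels > k)]
        raise ValueError(f"kineme labels out of range 1..{k}: {np.unique(bad)}")
    block = np.zeros((len(labels), k))
    block[np.arange(len(labels)), labels - 1] = 1.0
    return block


def dominant_aus(
    aus: AUSeries,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> np.ndarray:
    """Binary L x 17 block marking AUs whose window mean strictly exceeds
    their whole-video mean (a per-person adaptive baseline); constant
    channels are never dominant."""
    win = window_frames(window_s, aus.frame_rate)
    hop = window_frames(hop_s, aus.frame_rate)
    count = n_windows(aus.n_frames, win, hop)
    if count < 1:
        raise ValueError(
            f"video {aus.video_id!r} shorter than one {window_s} s window"
        )
    video_mean = aus.intensities.mean(axis=0)
    block = np.zeros((count, aus.intensities.shape[1]))
    for t in range(count):
        start = t * hop
        window_mean = aus.intensities[start : start + win].mean(axis=0)
        block[t] = (window_mean > video_mean).astype(float)
    return block


def _frame_signal(waveform: np.ndarray, win: int, hop: int) -> np.ndarray:
    count = n_windows(len(waveform), win, hop)
    if count < 1:
        raise ValueError("waveform shorter than one analysis window")
    idx = np.arange(win)[None, :] + hop * np.arange(count)[:, None]
    return waveform[idx]


def _mel_filterbank(sr: int, n_fft: int, n_mels: int = 40) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sr / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sr).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for b in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, b] = (b - lo) / (ctr - lo)
        for b in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, b] = (hi - b) / (hi - ctr)
    return fb


def _zcr(frames: np.ndarray) -> np.ndarray:
    signs = np.sign(frames)
    signs[signs == 0] = 1
    changes = np.abs(np.diff(signs, axis=1)) > 0
    return changes.mean(axis=1)


def _f0_voicing(frames: np.ndarray, sr: int) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation F0 in a 60-500 Hz band; unvoiced frames report 0."""
    win = frames.shape[1]
    lag_min = max(2, int(np.floor(sr / _F0_MAX_HZ)))
    lag_max = min(win - 1, int(np.ceil(sr / _F0_MIN_HZ)))
    n_fft = 1
    while n_fft < 2 * win:
        n_fft *= 2
    spec = np.fft.rfft(frames, n=n_fft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=n_fft, axis=1)[:, :win]
    f0 = np.zeros(len(frames))
    voicing = np.zeros(len(frames))
    energy = acf[:, 0]
    ok = energy > 1e-12
    if lag_max > lag_min and ok.any():
        band = acf[:, lag_min : lag_max + 1]
        peak_lag = band.argmax(axis=1) + lag_min
        peak_val = band.max(axis=1)
        v = np.clip(np.where(ok, peak_val / np.maximum(energy, 1e-12), 0.0), 0.0, 1.0)
        voicing = np.where(ok, v, 0.0)
        f0_candidate = sr / peak_lag
        voiced = ok & (voicing >= _VOICING_THRESHOLD)
        f0 = np.where(voiced, f0_candidate, 0.0)
    return f0, voicing


def _mfcc(frames: np.ndarray, sr: int, n_mfcc: int = N_MFCC) -> np.ndarray:
    win = frames.shape[1]
    n_fft = 1
    while n_fft < win:
        n_fft *= 2
    windowed = frames * np.hanning(win)[None, :]
    power = np.abs(rfft(windowed, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(sr, n_fft)
    logmel = np.log(np.maximum(power @ fb.T, 1e-10))
    return dct(logmel, type=2, axis=1, norm="ortho")[:, :n_mfcc]


def extract_llds(
    waveform: np.ndarray,
    sample_rate: int,
    window_s: float = LLD_WINDOW_S,
    hop_s: float = LLD_HOP_S,
) -> pd.DataFrame:
    """Frame-level LLD table: F0, voicing probability, ZCR and 20 MFCCs
    over 93 ms sliding windows with a 70 ms hop (23 ms overlap).

    The ``time`` column holds each analysis frame's center time.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8 kHz")
    win = window_frames(window_s, sample_rate)
    hop = window_frames(hop_s, sample_rate)
    frames = _frame_signal(waveform, win, hop)
    f0, voicing = _f0_voicing(frames, sample_rate)
    zcr = _zcr(frames)
    mfcc = _mfcc(frames, sample_rate)
    table = pd.DataFrame(
        np.column_stack([f0, voicing, zcr, mfcc]), columns=list(LLD_COLUMNS)
    )
    times = (np.arange(len(frames)) * hop + win / 2) / sample_rate
    table.insert(0, "time", times)
    return table


def speech_segment_features(
    lld: pd.DataFrame,
    duration_s: float | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> np.ndarray:
    """Per-window mean of each LLD column, concatenated in fixed order
    (F0, voicing, ZCR, MFCC 1..20), giving an L x 23 block."""
    missing = [c for c in LLD_COLUMNS if c not in lld.columns]
    if missing:
        raise ValueError(f"LLD table missing columns: {missing}")
    times = (
        lld["time"].to_numpy(dtype=float)
        if "time" in lld.columns
        else (np.arange(len(lld)) * LLD_HOP_S + LLD_WINDOW_S / 2)
    )
    values = lld.loc[:, list(LLD_COLUMNS)].to_numpy(dtype=float)
    if duration_s is None:
        duration_s = float(times[-1]) + LLD_WINDOW_S / 2
    count = int(np.floor((duration_s - window_s) / hop_s)) + 1
    if count < 1:
        raise ValueError(f"LLD stream shorter than one {window_s} s window")
    block = np.empty((count, N_LLD))
    for t in range(count):
        start = t * hop_s
        mask = (times >= start) & (times < start + window_s)
        if not mask.any():
            raise ValueError(f"no LLD frames fall inside window at {start:.2f} s")
        block[t] = values[mask].mean(axis=0)
    return block


@dataclass
class ZScoreStats:
    """Per-dimension mean and standard deviation fit on training windows."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_block(
    blocks: list[np.ndarray],
    stats: ZScoreStats | None = None,
) -> tuple[list[np.ndarray], ZScoreStats]:
    """Z-score a list of L x D blocks.

    With ``stats=None`` the per-dimension mean/sd (population sd) are fit on
    all windows pooled over the given blocks; otherwise the supplied
    training statistics are applied unchanged. Zero-variance dimensions keep
    sd = 1 with a warning.
    """
    if stats is None:
        pooled = np.concatenate(blocks, axis=0)
        if pooled.shape[0] < 2:
            raise ValueError("need at least 2 training windows to fit z-scoring")
        mean = pooled.mean(axis=0)
        sd = pooled.std(axis=0)  # population sd
        flat = sd <= 0
        if flat.any():
            warnings.warn(
                f"zero-variance dimensions {np.flatnonzero(flat).tolist()}; "
                "sd set to 1",
                stacklevel=2,
            )
            sd = np.where(flat, 1.0, sd)
        stats = ZScoreStats(mean=mean, sd=sd)
    normalized = [(b - stats.mean) / stats.sd for b in blocks]
    return normalized, stats


def align_blocks(
    video_id: str,
    times: np.ndarray,
    kineme: np.ndarray,
    au: np.ndarray,
    speech: np.ndarray,
) -> SegmentEncoding:
    """Truncate the three blocks to the shortest shared window count."""
    L = min(len(kineme), len(au), len(speech), len(times))
    if L < 1:
        raise ValueError(f"video {video_id!r} yields no complete windows")
    return SegmentEncoding(
        video_id=video_id,
        times=np.asarray(times[:L], dtype=float),
        kineme=kineme[:L],
        au=au[:L],
        speech=speech[:L],
    )


def save_encodings(directory: str | Path, encodings: list[SegmentEncoding]) -> Path:
    """Serialize encodings (one archive per video + a sidecar index CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for enc in encodings:
        path = directory / f"{enc.video_id}_encoding.npz"
        np.savez_compressed(
            path, times=enc.times, kineme=enc.kineme, au=enc.au, speech=enc.speech
        )
        rows.append({"video_id": enc.video_id, "L": enc.n_windows, "path": path.name})
    index = directory / "encodings.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_encodings(index_path: str | Path) -> list[SegmentEncoding]:
    index_path = Path(index_path)
    index = pd.read_csv(index_path)
    out = []
    for _, row in index.iterrows():
        data = np.load(index_path.parent / row["path"])
        out.append(
            SegmentEncoding(
                video_id=str(row["video_id"]),
                times=data["times"],
                kineme=data["kineme"],
                au=data["au"],
                speech=data["speech"],
            )
        )
    return out
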
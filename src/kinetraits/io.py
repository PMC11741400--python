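"""Readers and writers for per-frame pose/AU tables (OpenFace CSV dialect),
WAV audio, LLD tables and the dataset manifest.

Coordinate and unit conventions are owned here: angles are radians in memory
(``pose_Rx``/``pose_Ry``/``pose_Rz`` map to pitch/yaw/roll), AU intensities
live on the 0-5 scale, and trait scores are min-max standardized to [0, 1]
with statistics fit on the training split only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: The 17 AU intensity channels emitted by the upstream pose/AU estimator.
#: AU28 (lip suck) is presence-only upstream and is tolerated but ignored.
AU_CHANNELS: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)

_POSE_COLUMN_SETS = (
    ("pose_Rx", "pose_Ry", "pose_Rz"),
    ("pitch", "yaw", "roll"),
)

DEFAULT_FRAME_RATE = 30.0


class FormatError(ValueError):
    """A table does not match the expected dialect."""


@dataclass
class PoseSeries:
    """Per-frame head-pose Euler angles (radians) for one video."""

    video_id: str
    frame_rate: float
    angles: np.ndarray  # T x 3, columns (pitch, yaw, roll)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError("angles must be a T x 3 matrix")
        if self.angles.shape[0] < 1:
            raise ValueError("angle series must contain at least one frame")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class AUSeries:
    """Per-frame AU intensities (0-5 scale) for one video."""

    video_id: str
    frame_rate: float
    intensities: np.ndarray  # T x 17
    channels: tuple[str, ...] = AU_CHANNELS

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(self.channels):
            raise ValueError(
                f"intensities must be T x {len(self.channels)}, "
                f"got {self.intensities.shape}"
            )
        if np.any(self.intensities < 0) or np.any(self.intensities > 5):
            raise ValueError("intensities must lie in [0, 5]")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]


@dataclass
class TraitAnnotations:
    """Per-video continuous trait scores standardized to [0, 1]."""

    video_ids: list[str]
    traits: list[str]
    scores: np.ndarray  # n_videos x n_traits, in [0, 1]
    splits: list[str] = field(default_factory=list)

    def trait_scores(self, trait: str) -> np.ndarray:
        return self.scores[:, self.traits.index(trait)]

    def split_mask(self, split: str) -> np.ndarray:
        return np.asarray([s == split for s in self.splits], dtype=bool)


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    # OpenFace writes headers with a leading space (" pose_Rx").
    return df.rename(columns=lambda c: str(c).strip())


def _interpolate_unreliable(values: np.ndarray, reliable: np.ndarray) -> np.ndarray:
    """Linearly interpolate rows flagged unreliable; edge rows copy the
    nearest reliable value (np.interp semantics)."""
    if reliable.all():
        return values
    if not reliable.any():
        raise FormatError("no reliable frames to interpolate from")
    idx = np.arange(len(values))
    out = values.copy()
    for j in range(values.shape[1]):
        out[~reliable, j] = np.interp(idx[~reliable], idx[reliable], values[reliable, j])
    return out


def _reliability_mask(df: pd.DataFrame, confidence_min: float) -> np.ndarray:
    mask = np.ones(len(df), dtype=bool)
    if "success" in df.columns:
        mask &= df["success"].to_numpy(dtype=float) > 0
    if "confidence" in df.columns:
        mask &= df["confidence"].to_numpy(dtype=float) >= confidence_min
    return mask


def read_pose_table(
    path: str | Path,
    video_id: str | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    angle_unit: str = "radians",
    confidence_min: float = 0.5,
) -> PoseSeries:
    """Read a per-frame head-pose table in the OpenFace output dialect.

    Accepts either ``pose_Rx/pose_Ry/pose_Rz`` (the upstream convention,
    radians) or ``pitch/yaw/roll`` columns. ``angle_unit='degrees'``
    converts on read. Rows flagged failed by ``success``/``confidence``
    columns are linearly interpolated from neighbours.
    """
    df = _normalize_columns(pd.read_csv(path))
    if df.empty:
        raise FormatError(f"empty pose table: {path}")
    cols = None
    for candidate in _POSE_COLUMN_SETS:
        if all(c in df.columns for c in candidate):
            cols = candidate
            break
    if cols is None:
        expected = " or ".join("/".join(c) for c in _POSE_COLUMN_SETS)
        raise FormatError(f"missing rotation columns in {path}; expected {expected}")
    if "frame" in df.columns:
        df = df.sort_values("frame", kind="stable")
    angles = df.loc[:, list(cols)].to_numpy(dtype=float)
    angles = _interpolate_unreliable(angles, _reliability_mask(df, confidence_min))
    if angle_unit == "degrees":
        angles = np.deg2rad(angles)
    elif angle_unit != "radians":
        raise ValueError(f"unknown angle unit: {angle_unit!r}")
    vid = video_id if video_id is not None else Path(path).stem
    return PoseSeries(video_id=vid, frame_rate=frame_rate, angles=angles)


def read_au_table(
    path: str | Path,
    video_id: str | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    confidence_min: float = 0.5,
) -> AUSeries:
    """Read a per-frame AU intensity table (``AU??_r`` columns, 0-5 scale).

    Presence (``AU??_c``) columns are optional and ignored. Out-of-range
    intensities are clipped to [0, 5] with a warning.
    """
    df = _normalize_columns(pd.read_csv(path))
    if df.empty:
        raise FormatError(f"empty AU table: {path}")
    wanted = [f"{au}_r" for au in AU_CHANNELS]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise FormatError(f"missing AU intensity columns in {path}: {missing}")
    if "frame" in df.columns:
        df = df.sort_values("frame", kind="stable")
    intensities = df.loc[:, wanted].to_numpy(dtype=float)
    intensities = _interpolate_unreliable(
        intensities, _reliability_mask(df, confidence_min)
    )
    if np.any(intensities < 0) or np.any(intensities > 5):
        warnings.warn(
            f"AU intensities outside [0, 5] in {path}; clipping", stacklevel=2
        )
        intensities = np.clip(intensities, 0.0, 5.0)
    vid = video_id if video_id is not None else Path(path).stem
    return AUSeries(video_id=vid, frame_rate=frame_rate, intensities=intensities)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as a float64 mono waveform in [-1, 1].

    Stereo input is downmixed by channel averaging.
    """
    sample_rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, int(sample_rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, sample_rate, np.clip(waveform, -1, 1).astype(np.float32))


def read_lld_table(path: str | Path) -> pd.DataFrame:
    """Read a frame-level LLD table written by the synthetic generator or
    by :func:`kinetraits.encoding.extract_llds`."""
    df = _normalize_columns(pd.read_csv(path))
    if df.empty:
        raise FormatError(f"empty LLD table: {path}")
    return df


_RESERVED_MANIFEST_COLUMNS = {
    "video_id", "pose_path", "au_path", "audio_path", "lld_path",
    "split", "frame_rate", "angle_unit",
}


@dataclass
class Manifest:
    """Parsed dataset manifest: annotations plus per-video file map."""

    annotations: TraitAnnotations
    files: pd.DataFrame  # indexed by video_id; path/meta columns
    root: Path

    def path(self, video_id: str, kind: str) -> Path | None:
        col = f"{kind}_path"
        if col not in self.files.columns:
            return None
        value = self.files.loc[video_id, col]
        if pd.isna(value) or value == "":
            return None
        p = Path(str(value))
        return p if p.is_absolute() else self.root / p

    def frame_rate(self, video_id: str) -> float:
        if "frame_rate" in self.files.columns:
            value = self.files.loc[video_id, "frame_rate"]
            if not pd.isna(value):
                return float(value)
        return DEFAULT_FRAME_RATE

    def angle_unit(self, video_id: str) -> str:
        if "angle_unit" in self.files.columns:
            value = self.files.loc[video_id, "angle_unit"]
            if not pd.isna(value) and value != "":
                return str(value)
        return "radians"


def read_manifest(
    path: str | Path,
    trait_columns: list[str] | None = None,
    standardize: bool = True,
) -> Manifest:
    """Read a dataset manifest CSV.

    Columns: ``video_id``, modality path columns (``pose_path``,
    ``au_path``, ``audio_path`` and/or ``lld_path``), optional ``split``,
    ``frame_rate``, ``angle_unit``; every remaining column is a trait.
    Trait scores are min-max standardized to [0, 1] using statistics from
    the training split (rows with ``split == 'train'``, or all rows when no
    split column is present).
    """
    path = Path(path)
    df = _normalize_columns(pd.read_csv(path))
    if "video_id" not in df.columns:
        raise FormatError("manifest must contain a video_id column")
    df["video_id"] = df["video_id"].astype(str)
    if df["video_id"].duplicated().any():
        dupes = df.loc[df["video_id"].duplicated(), "video_id"].tolist()
        raise ValueError(f"duplicate video_id values in manifest: {dupes}")
    if len(df) < 2:
        raise ValueError(
            "manifest must list at least 2 videos (score standardization "
            "is degenerate for a single video)"
        )
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c not in _RESERVED_MANIFEST_COLUMNS]
    if not trait_columns:
        raise FormatError("manifest has no trait columns")
    scores = df.loc[:, trait_columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("manifest trait scores must be finite")
    splits = (
        df["split"].astype(str).tolist() if "split" in df.columns else ["train"] * len(df)
    )
    if standardize:
        train = np.asarray([s == "train" for s in splits], dtype=bool)
        if not train.any():
            train = np.ones(len(df), dtype=bool)
        lo = scores[train].min(axis=0)
        hi = scores[train].max(axis=0)
        span = hi - lo
        if np.any(span <= 0):
            flat = [t for t, s in zip(trait_columns, span) if s <= 0]
            raise ValueError(f"constant trait scores on training split: {flat}")
        scores = (scores - lo) / span
    annotations = TraitAnnotations(
        video_ids=df["video_id"].tolist(),
        traits=list(trait_columns),
        scores=scores,
        splits=splits,
    )
    file_cols = [c for c in df.columns if c in _RESERVED_MANIFEST_COLUMNS]
    files = df.loc[:, file_cols].set_index("video_id")
    return Manifest(annotations=annotations, files=files, root=path.parent)


def write_pose_table(path: str | Path, angles: np.ndarray) -> None:
    """Write angles (radians) in the OpenFace dialect."""
    angles = np.asarray(angles, dtype=float)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(angles)),
            "success": np.ones(len(angles), dtype=int),
            "confidence": np.ones(len(angles)),
            "pose_Rx": angles[:, 0],
            "pose_Ry": angles[:, 1],
            "pose_Rz": angles[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def write_au_table(path: str | Path, intensities: np.ndarray) -> None:
    """Write AU intensities (0-5) in the OpenFace dialect."""
    intensities = np.asarray(intensities, dtype=float)
    data: dict[str, np.ndarray] = {
        "frame": np.arange(len(intensities)),
        "success": np.ones(len(intensities), dtype=int),
    }
    for j, au in enumerate(AU_CHANNELS):
        data[f"{au}_r"] = intensities[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")
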
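"""Synthetic multimodal behavioral corpora with known ground truth.

Each video's head motion is a concatenation of window-length sinusoidal
motion prototypes (distinct frequency/phase per prototype and axis), its AU
intensities and speech LLD streams are drawn around per-video channel means,
and its trait scores follow a known logistic-linear model on the behavioral
summary features (prototype usage frequencies, AU channel means, LLD channel
means). Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kinetraits import io
from kinetraits._grid import DEFAULT_WINDOW_S, window_frames
from kinetraits.encoding import LLD_COLUMNS, LLD_HOP_S, LLD_WINDOW_S, N_LLD

_LLD_WINDOW_S = LLD_WINDOW_S
_LLD_HOP_S = LLD_HOP_S

# Fixed theoretical centering/scale constants for the trait link, per
# summary-feature group, so a video's score depends only on its own features.
_AU_MEAN_LO, _AU_MEAN_HI = 1.0, 4.0
_LOGIT_GAIN = 2.0


@dataclass
class NoiseSpec:
    """Standard deviations for each noise source."""

    angle: float = 0.02
    au: float = 0.3
    lld: float = 0.3
    label: float = 0.02

    def __post_init__(self) -> None:
        for name in ("angle", "au", "lld", "label"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise_sd.{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SynthConfig:
    """Configuration of a synthetic corpus."""

    n_videos: int = 20
    duration_s: float = 16.0
    frame_rate: float = 30.0
    n_prototypes: int = 4
    au_channels: int = 17
    trait_weights: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    window_s: float = DEFAULT_WINDOW_S
    audio_mode: str = "lld"  # 'lld' emits LLD tables, 'wav' emits waveforms
    audio_sample_rate: int = 16000

    def __post_init__(self) -> None:
        if self.n_videos < 2:
            raise ValueError("n_videos must be >= 2")
        if self.duration_s < 4:
            raise ValueError("duration_s must be >= 4")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_prototypes < 1:
            raise ValueError("n_prototypes must be >= 1")
        if self.audio_mode not in ("lld", "wav"):
            raise ValueError("audio_mode must be 'lld' or 'wav'")
        if self.duration_s < self.window_s:
            raise ValueError(
                f"duration_s={self.duration_s} too short to hold one window; "
                f"minimum duration is {self.window_s} s"
            )
        if not self.trait_weights:
            self.trait_weights = {"trait1": default_trait_weights(self)}
        for name, w in self.trait_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.feature_dim,):
                raise ValueError(
                    f"trait_weights[{name!r}] must have length "
                    f"{self.feature_dim} (= n_prototypes + au_channels + {N_LLD})"
                )
            self.trait_weights[name] = w

    @property
    def feature_dim(self) -> int:
        return self.n_prototypes + self.au_channels + N_LLD

    @property
    def traits(self) -> list[str]:
        return list(self.trait_weights)

    @property
    def proto_len(self) -> int:
        """Prototype (= window) length in frames."""
        return window_frames(self.window_s, self.frame_rate)


def default_trait_weights(config: SynthConfig, rng_seed: int = 1234) -> np.ndarray:
    """A weight vector spreading signal over all three modalities."""
    rng = np.random.default_rng(rng_seed)
    w = np.zeros(config.feature_dim)
    w[: config.n_prototypes] = rng.normal(0, 1, config.n_prototypes)
    w[config.n_prototypes : config.n_prototypes + config.au_channels] = rng.normal(
        0, 1, config.au_channels
    )
    w[config.n_prototypes + config.au_channels :] = rng.normal(0, 1, N_LLD)
    return w


def modality_weights(
    config: SynthConfig,
    kineme: float = 1.0,
    au: float = 1.0,
    speech: float = 1.0,
    rng_seed: int = 1234,
) -> np.ndarray:
    """Scale the default weight vector per modality block (0 silences one)."""
    w = default_trait_weights(config, rng_seed)
    p, a = config.n_prototypes, config.au_channels
    w[:p] *= kineme
    w[p : p + a] *= au
    w[p + a :] *= speech
    return w


@dataclass
class SynthVideo:
    """One generated video with its ground truth."""

    video_id: str
    pose: io.PoseSeries
    au: io.AUSeries
    lld: pd.DataFrame  # time + 23 LLD channels
    waveform: np.ndarray | None  # only in audio_mode='wav'
    true_labels: np.ndarray  # 1..n_prototypes, one per generation-grid window
    summary: np.ndarray  # prototype freqs + AU means + LLD means


@dataclass
class SynthCorpus:
    """A generated corpus: videos, trait scores, generating prototypes."""

    config: SynthConfig
    videos: list[SynthVideo]
    scores: pd.DataFrame  # index video_id, one column per trait
    prototypes: np.ndarray  # n_prototypes x proto_len x 3 (radians)

    @property
    def video_ids(self) -> list[str]:
        return [v.video_id for v in self.videos]

    def pose_series(self) -> list[io.PoseSeries]:
        return [v.pose for v in self.videos]


def _make_prototypes(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Window-length sinusoidal motifs, distinct per prototype and axis."""
    ell = config.proto_len
    t = np.arange(ell) / max(ell - 1, 1)
    protos = np.empty((config.n_prototypes, ell, 3))
    for p in range(config.n_prototypes):
        for axis in range(3):
            # integer cycle counts keep prototypes clearly distinct
            freq = 1 + (p + axis) % 3 + rng.integers(0, 2)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.1, 0.3)
            protos[p, :, axis] = amp * np.sin(2 * np.pi * freq * t + phase)
    return protos


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _standardize_summary(config: SynthConfig, summary: np.ndarray) -> np.ndarray:
    """Affine per-group standardization with fixed theoretical constants."""
    p, a = config.n_prototypes, config.au_channels
    z = summary.copy()
    z[:p] = (z[:p] - 1.0 / p) * 3.0
    au_mid = (_AU_MEAN_LO + _AU_MEAN_HI) / 2
    au_sd = (_AU_MEAN_HI - _AU_MEAN_LO) / np.sqrt(12)
    z[p : p + a] = (z[p : p + a] - au_mid) / au_sd
    lld = z[p + a :]
    lld_mid = np.array([175.0, 0.65, 0.175] + [0.0] * 20)
    lld_sd = np.array([150.0 / np.sqrt(12), 0.5 / np.sqrt(12), 0.25 / np.sqrt(12)] + [2.0] * 20)
    z[p + a :] = (lld - lld_mid) / lld_sd
    return z


def trait_score(config: SynthConfig, weights: np.ndarray, summary: np.ndarray) -> float:
    """Noiseless logistic-linear trait score for one video's summary."""
    z = _standardize_summary(config, summary)
    norm = float(np.linalg.norm(weights))
    if norm == 0:
        return 0.5
    return float(_logistic(_LOGIT_GAIN * float(weights @ z) / norm))


def _lld_frame_times(duration_s: float) -> np.ndarray:
    n = int(np.floor((duration_s - _LLD_WINDOW_S) / _LLD_HOP_S)) + 1
    return np.arange(max(n, 1)) * _LLD_HOP_S + _LLD_WINDOW_S / 2


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a full corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ell = config.proto_len
    total_frames = int(round(config.duration_s * config.frame_rate))
    n_blocks = total_frames // ell
    if n_blocks < 1:
        raise ValueError(
            f"duration_s={config.duration_s} too short to hold one window; "
            f"minimum duration is {config.window_s} s"
        )
    prototypes = _make_prototypes(config, rng)
    noise = config.noise_sd
    videos: list[SynthVideo] = []
    score_rows: dict[str, list[float]] = {t: [] for t in config.traits}
    for v in range(config.n_videos):
        vid = f"video{v:04d}"
        usage = rng.dirichlet(np.full(config.n_prototypes, 1.0))
        labels = rng.choice(config.n_prototypes, size=n_blocks, p=usage) + 1
        angles = np.concatenate([prototypes[lab - 1] for lab in labels], axis=0)
        if len(angles) < total_frames:  # pad a truncated final block
            pad = prototypes[labels[-1] - 1][: total_frames - len(angles)]
            angles = np.concatenate([angles, pad], axis=0)
        angles = angles + rng.normal(0, noise.angle, angles.shape)
        pose = io.PoseSeries(video_id=vid, frame_rate=config.frame_rate, angles=angles)

        au_means = rng.uniform(_AU_MEAN_LO, _AU_MEAN_HI, config.au_channels)
        au_raw = au_means[None, :] + rng.normal(
            0, noise.au, (total_frames, config.au_channels)
        )
        au = io.AUSeries(
            video_id=vid,
            frame_rate=config.frame_rate,
            intensities=np.clip(au_raw, 0, 5),
            channels=io.AU_CHANNELS[: config.au_channels]
            if config.au_channels == 17
            else tuple(f"AU{i:02d}" for i in range(1, config.au_channels + 1)),
        )

        lld_means = np.concatenate(
            [
                [rng.uniform(100.0, 250.0)],  # F0
                [rng.uniform(0.4, 0.9)],  # voicing
                [rng.uniform(0.05, 0.3)],  # zcr
                rng.normal(0, 2.0, 20),  # mfccs
            ]
        )
        times = _lld_frame_times(config.duration_s)
        lld_vals = lld_means[None, :] + rng.normal(0, noise.lld, (len(times), N_LLD))
        lld = pd.DataFrame(lld_vals, columns=list(LLD_COLUMNS))
        lld.insert(0, "time", times)

        waveform = None
        if config.audio_mode == "wav":
            sr = config.audio_sample_rate
            t = np.arange(int(config.duration_s * sr)) / sr
            f0 = float(np.clip(lld_means[0], 80, 300))
            waveform = 0.3 * np.sin(2 * np.pi * f0 * t)
            waveform = waveform + rng.normal(0, 0.01 * (noise.lld > 0), len(t))

        freqs = np.bincount(labels - 1, minlength=config.n_prototypes) / n_blocks
        summary = np.concatenate([freqs, au_means, lld_means])
        for trait, w in config.trait_weights.items():
            s = trait_score(config, w, summary)
            s = float(np.clip(s + rng.normal(0, noise.label), 0, 1))
            score_rows[trait].append(s)
        videos.append(
            SynthVideo(
                video_id=vid,
                pose=pose,
                au=au,
                lld=lld,
                waveform=waveform,
                true_labels=labels,
                summary=summary,
            )
        )
    scores = pd.DataFrame(score_rows, index=[v.video_id for v in videos])
    return SynthCorpus(config=config, videos=videos, scores=scores, prototypes=prototypes)


def encode_corpus(
    corpus: SynthCorpus,
    vocab,  # noqa: ANN001  (KinemeVocabulary)
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float | None = None,
):
    """Encode every video of an in-memory corpus on the shared window grid.

    Returns a list of SegmentEncoding. The kineme grid comes from the
    vocabulary's (ell, hop); the AU and speech grids use ``window_s`` and
    ``hop_s`` (default: the vocabulary's hop in seconds). Speech blocks are
    raw per-window LLD means -- z-scoring happens at protocol time.
    """
    from kinetraits import encoding as enc
    from kinetraits.kineme import assign_kinemes

    hop_s = vocab.hop / corpus.config.frame_rate if hop_s is None else hop_s
    out = []
    for video in corpus.videos:
        seq = assign_kinemes(video.pose, vocab)
        kin = enc.one_hot_kinemes(seq.labels, vocab.k)
        au = enc.dominant_aus(video.au, window_s, hop_s)
        speech = enc.speech_segment_features(
            video.lld, corpus.config.duration_s, window_s, hop_s
        )
        out.append(enc.align_blocks(video.video_id, seq.times, kin, au, speech))
    return out


def assign_splits(
    n: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> list[str]:
    """Deterministic train/val/test split tags by index."""
    n_train = max(int(round(fractions[0] * n)), 1)
    n_val = max(int(round(fractions[1] * n)), 1)
    tags = ["train"] * n_train + ["val"] * n_val
    tags += ["test"] * (n - len(tags))
    return tags[:n]


def write_corpus(corpus: SynthCorpus, directory: str | Path) -> Path:
    """Write the corpus in the formats the manifest reader consumes.

    Returns the manifest path. Pose/AU tables use the OpenFace dialect;
    audio is an LLD CSV or a WAV file depending on ``config.audio_mode``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = corpus.config
    splits = assign_splits(config.n_videos)
    rows = []
    for v, video in enumerate(corpus.videos):
        vid = video.video_id
        pose_path = f"{vid}_pose.csv"
        au_path = f"{vid}_au.csv"
        io.write_pose_table(directory / pose_path, video.pose.angles)
        io.write_au_table(directory / au_path, video.au.intensities)
        row: dict[str, object] = {
            "video_id": vid,
            "pose_path": pose_path,
            "au_path": au_path,
            "frame_rate": config.frame_rate,
            "split": splits[v],
        }
        if config.audio_mode == "wav":
            audio_path = f"{vid}.wav"
            io.write_wav(
                directory / audio_path, video.waveform, config.audio_sample_rate
            )
            row["audio_path"] = audio_path
        else:
            lld_path = f"{vid}_lld.csv"
            video.lld.to_csv(directory / lld_path, index=False, float_format="%.9f")
            row["lld_path"] = lld_path
        for trait in config.traits:
            row[trait] = corpus.scores.loc[vid, trait]
        rows.append(row)
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, float_format="%.9f")
    return manifest_path
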
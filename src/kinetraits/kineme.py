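"""Kineme vocabulary learning and sequence assignment.

Pooled head-motion windows (concatenated pitch/yaw/roll, shifted to be
non-negative) are factorized with multiplicative-update NMF; a Gaussian
mixture over the coefficient columns yields k component means whose
back-projection B @ C* gives the kineme matrix. New windows are projected
onto the basis with non-negative least squares and labeled by maximum
posterior under the stored mixture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.mixture import GaussianMixture

from kinetraits._grid import window_frames, window_starts, window_times
from kinetraits.io import PoseSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP = 0.5
DEFAULT_K = 16
DEFAULT_RANK = 24
NMF_MAX_ITER = 500
NMF_TOL = 1e-4


@dataclass
class SegmentMatrix:
    """Pooled non-negative window matrix H (3*ell x S)."""

    matrix: np.ndarray
    ell: int
    hop: int
    offset: float
    video_ids: list[str]
    counts: list[int]  # per-video segment counts, aligned with video_ids

    @property
    def n_segments(self) -> int:
        return self.matrix.shape[1]


@dataclass
class KinemeVocabulary:
    """Learned basis, coefficient mixture and kineme matrix."""

    basis: np.ndarray  # 3*ell x r, non-negative
    mixture_weights: np.ndarray  # k
    mixture_means: np.ndarray  # k x r
    mixture_covariances: np.ndarray  # k x r x r
    kinemes: np.ndarray  # H* = B @ C*, 3*ell x k
    ell: int
    hop: int
    offset: float
    rank: int
    k: int
    seed: int
    format_version: int = 1

    def _gmm(self) -> GaussianMixture:
        gmm = GaussianMixture(n_components=self.k, covariance_type="full")
        gmm.weights_ = self.mixture_weights
        gmm.means_ = self.mixture_means
        gmm.covariances_ = self.mixture_covariances
        gmm.precisions_cholesky_ = _precisions_cholesky(self.mixture_covariances)
        return gmm

    def posterior(self, coeffs: np.ndarray) -> np.ndarray:
        """Posterior over the k components for coefficient rows (n x r)."""
        coeffs = np.atleast_2d(coeffs)
        return self._gmm().predict_proba(coeffs)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            basis=self.basis,
            mixture_weights=self.mixture_weights,
            mixture_means=self.mixture_means,
            mixture_covariances=self.mixture_covariances,
            kinemes=self.kinemes,
            meta=np.array(
                [self.ell, self.hop, self.offset, self.rank, self.k, self.seed,
                 self.format_version]
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "KinemeVocabulary":
        data = np.load(path)
        meta = data["meta"]
        return cls(
            basis=data["basis"],
            mixture_weights=data["mixture_weights"],
            mixture_means=data["mixture_means"],
            mixture_covariances=data["mixture_covariances"],
            kinemes=data["kinemes"],
            ell=int(meta[0]),
            hop=int(meta[1]),
            offset=float(meta[2]),
            rank=int(meta[3]),
            k=int(meta[4]),
            seed=int(meta[5]),
            format_version=int(meta[6]),
        )


@dataclass
class KinemeSequence:
    """Per-window kineme labels (1..k) for one video."""

    video_id: str
    labels: np.ndarray  # int, 1..k
    times: np.ndarray  # window start times in seconds

    def __len__(self) -> int:
        return len(self.labels)


def _precisions_cholesky(covariances: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    chols = np.empty_like(covariances)
    eye = np.eye(covariances.shape[-1])
    for i, cov in enumerate(covariances):
        chol = np.linalg.cholesky(cov)
        chols[i] = solve_triangular(chol, eye, lower=True).T
    return chols


def _segment_video(angles: np.ndarray, ell: int, hop: int) -> np.ndarray:
    """Columns of concatenated pitch/yaw/roll windows (3*ell x s)."""
    starts = window_starts(len(angles), ell, hop)
    cols = np.empty((3 * ell, len(starts)))
    for j, s in enumerate(starts):
        win = angles[s : s + ell]
        cols[:, j] = np.concatenate([win[:, 0], win[:, 1], win[:, 2]])
    return cols


def segment_params(
    frame_rate: float, window_s: float = DEFAULT_WINDOW_S,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> tuple[int, int]:
    """(ell, hop) in frames for a window length and overlap fraction."""
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    ell = window_frames(window_s, frame_rate)
    hop = max(1, int(round(ell * (1 - overlap_fraction))))
    return ell, hop


def build_segment_matrix(
    series: list[PoseSeries],
    window_s: float = DEFAULT_WINDOW_S,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> SegmentMatrix:
    """Pool overlapping windows from all videos into one non-negative matrix.

    A uniform offset of -(global minimum) is added so every entry is >= 0;
    videos shorter than one window are skipped with a warning.
    """
    if not series:
        raise ValueError("no pose series given")
    frame_rate = series[0].frame_rate
    ell, hop = segment_params(frame_rate, window_s, overlap_fraction)
    blocks, ids, counts = [], [], []
    for ps in series:
        if ps.frame_rate != frame_rate:
            raise ValueError("all series must share one frame rate")
        if ps.n_frames < ell:
            warnings.warn(
                f"video {ps.video_id!r} shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        cols = _segment_video(ps.angles, ell, hop)
        blocks.append(cols)
        ids.append(ps.video_id)
        counts.append(cols.shape[1])
    if not blocks:
        raise ValueError("every video is shorter than one window")
    matrix = np.concatenate(blocks, axis=1)
    offset = float(max(0.0, -matrix.min()))
    return SegmentMatrix(
        matrix=matrix + offset, ell=ell, hop=hop, offset=offset,
        video_ids=ids, counts=counts,
    )


def learn_vocabulary(
    segments: SegmentMatrix,
    rank: int = DEFAULT_RANK,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> KinemeVocabulary:
    """Learn the kineme vocabulary from a pooled segment matrix.

    NMF (multiplicative updates, 500-iteration cap, 1e-4 relative
    tolerance, seeded random init) yields B and C; a full-covariance
    Gaussian mixture with k-means init is fit on the columns of C; the k
    component means C* back-project to kinemes H* = B @ C*.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > segments.n_segments:
        raise ValueError(
            f"k={k} exceeds the number of segments ({segments.n_segments})"
        )
    if rank < k:
        logger.warning("rank r=%d < k=%d; r >= k is recommended", rank, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMF convergence warning handled below
        model = NMF(
            n_components=rank,
            solver="mu",
            beta_loss="frobenius",
            init="random",
            max_iter=NMF_MAX_ITER,
            tol=NMF_TOL,
            random_state=seed,
        )
        basis_t = model.fit_transform(segments.matrix.T)  # S x r
    if model.n_iter_ >= NMF_MAX_ITER:
        warnings.warn(
            f"NMF did not converge in {NMF_MAX_ITER} iterations "
            f"(final residual {model.reconstruction_err_:.4g})",
            stacklevel=2,
        )
    # sklearn factorizes X ~ W @ H with X = segments.T, so W holds the
    # per-segment coefficients and H.T is the 3*ell x r basis.
    coeffs = basis_t  # S x r
    basis = model.components_.T  # 3*ell x r
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        init_params="kmeans",
        n_init=1,
        reg_covar=1e-6,
        random_state=seed,
    ).fit(coeffs)
    kinemes = basis @ gmm.means_.T  # 3*ell x k
    return KinemeVocabulary(
        basis=basis,
        mixture_weights=gmm.weights_,
        mixture_means=gmm.means_,
        mixture_covariances=gmm.covariances_,
        kinemes=kinemes,
        ell=segments.ell,
        hop=segments.hop,
        offset=segments.offset,
        rank=rank,
        k=k,
        seed=seed,
    )


def project_segment(h: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Non-negative least-squares projection of one window onto the basis.

    Solves argmin_{c >= 0} ||h - B c||^2.
    """
    h = np.asarray(h, dtype=float).ravel()
    if h.shape[0] != basis.shape[0]:
        raise ValueError(
            f"segment length {h.shape[0]} != basis rows {basis.shape[0]}"
        )
    coeffs, _ = nnls(basis, h)
    return coeffs


def assign_kinemes(series: PoseSeries, vocab: KinemeVocabulary) -> KinemeSequence:
    """Label every window of a video with its maximum-posterior kineme.

    Windows use the vocabulary's stored (ell, hop, offset); ties in the
    posterior break toward the lowest component index.
    """
    ell, hop = vocab.ell, vocab.hop
    if series.n_frames < ell:
        raise ValueError(
            f"video {series.video_id!r} shorter than one window ({ell} frames)"
        )
    cols = _segment_video(series.angles, ell, hop) + vocab.offset
    coeffs = np.stack(
        [project_segment(cols[:, j], vocab.basis) for j in range(cols.shape[1])]
    )
    posterior = vocab.posterior(coeffs)
    labels = posterior.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    times = window_times(series.n_frames, ell, hop, series.frame_rate)
    return KinemeSequence(video_id=series.video_id, labels=labels, times=times)


def write_sequences(path: str | Path, sequences: list[KinemeSequence]) -> None:
    """Write kineme sequences as CSV (video_id, window_start_s, label)."""
    import pandas as pd

    rows = [
        {"video_id": s.video_id, "window_start_s": t, "label": int(lab)}
        for s in sequences
        for t, lab in zip(s.times, s.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
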
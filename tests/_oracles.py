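"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def nnls_grid_search_2d(
    basis: np.ndarray,
    target: np.ndarray,
    upper: float = 10.0,
    step: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Exhaustive 2-D grid search for min_{c in grid} ||target - B c||^2.

    The grid is {0, step, ..., upper}^2. For each c1 the objective is a
    convex quadratic in c2, so the best on-grid c2 is one of the two grid
    neighbours of the clipped continuous minimizer; checking both per c1
    yields exactly the exhaustive-grid minimum without 1e8 evaluations.
    """
    b1, b2 = basis[:, 0], basis[:, 1]
    q11, q22, q12 = b1 @ b1, b2 @ b2, b1 @ b2
    t1, t2 = b1 @ target, b2 @ target
    const = target @ target
    c1_grid = np.arange(0.0, upper + step / 2, step)

    def objective(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
        return (
            const
            + q11 * c1**2
            + q22 * c2**2
            + 2 * q12 * c1 * c2
            - 2 * t1 * c1
            - 2 * t2 * c2
        )

    # continuous minimizer in c2 for every c1, clipped to the box
    c2_star = np.clip((t2 - q12 * c1_grid) / q22, 0.0, upper)
    lo = np.clip(np.floor(c2_star / step) * step, 0.0, upper)
    hi = np.clip(lo + step, 0.0, upper)
    f_lo = objective(c1_grid, lo)
    f_hi = objective(c1_grid, hi)
    f_best = np.minimum(f_lo, f_hi)
    i = int(f_best.argmin())
    c2_best = lo[i] if f_lo[i] <= f_hi[i] else hi[i]
    return np.array([c1_grid[i], c2_best]), float(f_best[i])


def autocorrelation_f0(frame: np.ndarray, sample_rate: int) -> float:
    """Plain time-domain autocorrelation pitch estimate for one frame."""
    frame = frame - frame.mean()
    n = len(frame)
    acf = np.array([frame[: n - lag] @ frame[lag:] for lag in range(n)])
    lag_min = int(np.floor(sample_rate / 500.0))
    lag_max = int(np.ceil(sample_rate / 60.0))
    lag = lag_min + int(acf[lag_min : lag_max + 1].argmax())
    return sample_rate / lag


def fusion_grid_oracle(
    streams: np.ndarray, labels: np.ndarray, step: float = 0.05
) -> float:
    """Best achievable PCC over the full bimodal alpha grid."""
    from scipy.stats import pearsonr

    best = -np.inf
    for alpha in np.arange(0.0, 1.0 + step / 2, step):
        fused = alpha * streams[0] + (1 - alpha) * streams[1]
        if np.ptp(fused) > 0:
            best = max(best, pearsonr(fused, labels)[0])
    return best
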
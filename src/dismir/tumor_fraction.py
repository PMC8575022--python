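"""Tumor-fraction estimation from per-read d-scores.

Treating each read's d-score d_i as the probability that the read is
tumor-derived and assuming reads independent, the posterior of a sample with
tumor-read fraction r is

    P(r) = prod_i [ r * d_i + (1 - r) * (1 - d_i) ]

The estimate r-hat is the maximizer of P over a grid on [0, 1] with step
0.001.  The product underflows for realistic read counts, so the search runs
on the log-posterior with d-scores clipped away from {0, 1}; the log of an
affine function is concave, hence the log-posterior (a sum of such terms) is
concave in r and the grid argmax is well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TumorFractionEstimate",
    "log_posterior",
    "estimate_tumor_fraction",
    "cohort_auc",
    "DEFAULT_CLIP",
]

DEFAULT_CLIP = 1e-6


@dataclass(frozen=True)
class TumorFractionEstimate:
    """Grid maximizer r_hat plus the full log-posterior curve."""

    r_hat: float
    log_posterior: np.ndarray
    grid_step: float
    n_reads: int


def _clipped(dscores, clip: float) -> np.ndarray:
    d = np.asarray(dscores, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one d-score")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("d-scores must lie in [0, 1]")
    return np.clip(d, clip, 1.0 - clip)


def log_posterior(dscores, r: float, clip: float = DEFAULT_CLIP) -> float:
    """Sum_i log[r*d_i + (1-r)*(1-d_i)] with d clipped to [clip, 1-clip]."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    d = _clipped(dscores, clip)
    return float(np.sum(np.log(r * d + (1.0 - r) * (1.0 - d))))


def estimate_tumor_fraction(
    dscores,
    grid_step: float = 0.001,
    clip: float = DEFAULT_CLIP,
) -> TumorFractionEstimate:
    """Maximize the log-posterior over the grid {0, step, 2*step, ..., 1}.

    Ties resolve to the smallest maximizing grid point (the conservative,
    lowest-risk call; relevant only for flat curves, e.g. all d = 0.5).
    """
    d = _clipped(dscores, clip)
    n_points = int(np.floor(1.0 / grid_step)) + 1
    grid = np.minimum(np.arange(n_points) * grid_step, 1.0)
    # terms: (n_points, n_reads); chunk the grid if the matrix would be large
    curve = np.empty(n_points)
    chunk = max(1, int(5e7 // max(d.size, 1)))
    for lo in range(0, n_points, chunk):
        g = grid[lo:lo + chunk, None]
        curve[lo:lo + chunk] = np.log(g * d + (1.0 - g) * (1.0 - d)).sum(axis=1)
    best = int(np.argmax(curve))  # first index on exact ties
    return TumorFractionEstimate(
        r_hat=float(grid[best]),
        log_posterior=curve,
        grid_step=grid_step,
        n_reads=int(d.size),
    )


def cohort_auc(cancer_scores, healthy_scores) -> float:
    """Rank AUC for separating cancer from healthy sample scores.

    Equals the Mann-Whitney U statistic of the cancer scores over the
    healthy ones divided by n_cancer * n_healthy (ties at half weight).
    """
    x = np.asarray(cancer_scores, dtype=float)
    y = np.asarray(healthy_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be non-empty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u / (x.size * y.size))
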
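"""Palshikar-style peak detection baseline (S1/S2/S3 spike functions).

Each point receives a "peakiness" score built from signed differences
against its k nearest neighbours on each side (windows truncated at the
signal edges):

    S1: average of (y_t - max over each side's differences), i.e.
        y_t minus the mean of the two one-sided window minima;
    S2: average over the two sides of the mean signed difference
        between y_t and the side's neighbours;
    S3: average over the two sides of the difference between y_t and
        the side's neighbour mean.

(As described, S2 and S3 are algebraically identical; both are kept for
interface fidelity.)  Detection then applies a *global* threshold — keep
points with positive score, compute the mean m and standard deviation s
of those scores, retain points with score - m > h*s — and finally prunes
retained points closer than k to each other, keeping the larger score.

Scores are computed with O(N) rolling windows (pandas), so the baseline
runs in seconds even on multi-minute audio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import Signal

__all__ = ["PeakConfig", "peak_scores", "detect_peaks", "segments_from_peaks"]

_VARIANTS = ("S1", "S2", "S3")


@dataclass(frozen=True)
class PeakConfig:
    """Baseline settings: spike-function variant, threshold h (in standard
    deviations of the positive scores), window half-width k (samples),
    evaluation stride, and optionally rectification (score |y| instead
    of y)."""

    variant: str = "S1"
    h: float = 3.0
    k: int = 500
    resolution: int = 1
    rectify: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if not self.h > 0:
            raise ValueError(f"h must be positive, got {self.h}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")


def _one_sided_stats(x: np.ndarray, k: int):
    """Trailing/leading window extrema and means, truncated at the edges.

    Returns (left_min, left_mean, right_min, right_mean) where the left
    window of t is x[t-k : t] and the right window is x[t+1 : t+k+1];
    entries with an empty window are NaN (only t=0 / t=N-1).
    """
    s = pd.Series(x)
    trail_min = s.rolling(k, min_periods=1).min().to_numpy()
    trail_mean = s.rolling(k, min_periods=1).mean().to_numpy()
    rev = pd.Series(x[::-1])
    lead_min = rev.rolling(k, min_periods=1).min().to_numpy()[::-1]
    lead_mean = rev.rolling(k, min_periods=1).mean().to_numpy()[::-1]

    nan = np.full(1, np.nan)
    left_min = np.concatenate([nan, trail_min[:-1]])
    left_mean = np.concatenate([nan, trail_mean[:-1]])
    right_min = np.concatenate([lead_min[1:], nan])
    right_mean = np.concatenate([lead_mean[1:], nan])
    return left_min, left_mean, right_min, right_mean


def peak_scores(
    signal: Signal | np.ndarray,
    variant: str = "S1",
    k: int = 500,
    resolution: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-function scores at every evaluation point.

    Returns ``(points, scores)`` where ``points`` are the multiples of
    ``resolution`` in [0, N).  Edge windows are truncated; at the two
    boundary points only the available side contributes.
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=np.float64)
    n = x.size
    if k >= n:
        raise ValueError(f"window k={k} must be smaller than the signal length {n}")
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")

    left_min, left_mean, right_min, right_mean = _one_sided_stats(x, k)
    if variant == "S1":
        side_l = x - left_min  # max of (y_t - neighbour) = y_t - window min
        side_r = x - right_min
    else:  # S2 and S3: both reduce to y_t minus the side's neighbour mean
        side_l = x - left_mean
        side_r = x - right_mean
    with np.errstate(invalid="ignore"):
        scores_full = np.nanmean(np.column_stack([side_l, side_r]), axis=1)

    points = np.arange(0, n, resolution, dtype=np.int64)
    return points, scores_full[points]


def detect_peaks(signal: Signal | np.ndarray, config: PeakConfig) -> np.ndarray:
    """Detect peaks: score, global mean + h*std threshold, prune within k.

    Returns sorted absolute sample indices of the retained peaks.
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=np.float64)
    if config.rectify:
        x = np.abs(x)
    points, scores = peak_scores(x, config.variant, config.k, config.resolution)

    positive = scores > 0
    if not np.any(positive):
        return np.empty(0, dtype=np.int64)
    kept = scores[positive]
    m = float(np.mean(kept))
    s = float(np.std(kept))
    retained = positive & (scores - m > config.h * s)
    idx = points[retained]
    val = scores[retained]
    if idx.size == 0:
        return np.empty(0, dtype=np.int64)

    # left-to-right prune: among points closer than k, keep the larger score
    keep_idx = [0]
    for i in range(1, idx.size):
        last = keep_idx[-1]
        if idx[i] - idx[last] < config.k:
            if val[i] > val[last]:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
    return idx[np.asarray(keep_idx)]


def segments_from_peaks(peaks, n: int, fs: float = 1.0):
    """Wrap detected peaks as a :class:`~seqseg.segmenter.SegmentationResult`.

    Each peak is a changepoint (segments = peaks + 1); the evidence
    column is NaN since the baseline carries no e-values.
    """
    from .segmenter import SegmentationResult

    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and (np.any(peaks <= 0) or np.any(peaks >= n)):
        raise ValueError(f"peaks must lie strictly inside (0, {n})")
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be sorted and unique")
    return SegmentationResult(
        changepoints=peaks,
        evidences=np.full(peaks.size, np.nan),
        n=n,
        fs=fs,
        n_tests=0,
        config=None,
        method="palshikar",
    )
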
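"""Marginal posterior of a single variance changepoint.

Model: a zero-mean signal y_1..y_N with Var(y_t) = sigma0^2 for t <= tbar
and Var(y_t) = delta * sigma0^2 for t > tbar.  Marginalising the
likelihood analytically over delta (improper uniform prior on (0, inf))
and sigma0 (Jeffreys prior 1/sigma0) leaves a discrete posterior kernel
over the candidate cut t (number of samples on the left):

    log k(t) = log pi(t) + lnGamma((t+2)/2) + lnGamma((N-t-2)/2)
               - ((t+2)/2)   * ln S_left(t)
               - ((N-t-2)/2) * ln S_right(t)

with S_left / S_right the segment sums of squares.  Both integrals
converge iff 1 <= t <= N-3 and both sums are positive.  The kernel is
exactly invariant (after normalisation) under amplitude scaling
y -> c*y, since the two exponents add to N/2 independent of t.

Everything is computed from prefix sums of squared amplitudes
(:class:`SquareSums`), in log space, with `scipy.special.gammaln`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import DegenerateSegmentError, EmptySignalError, NoCandidateError
from .signals import Signal

__all__ = [
    "SquareSums",
    "GridConfig",
    "ChangepointPosterior",
    "square_sums",
    "log_changepoint_kernel",
    "map_changepoint",
]


@dataclass(frozen=True)
class SquareSums:
    """Prefix sums of squared amplitudes: the sufficient statistics.

    ``prefix[t] = sum_{u < t} y_u**2`` with ``prefix[0] == 0`` and
    ``len(prefix) == N + 1``.
    """

    prefix: np.ndarray

    @property
    def n(self) -> int:
        return self.prefix.size - 1

    @property
    def total(self) -> float:
        return float(self.prefix[-1])

    def left(self, t):
        """Sum of squares over the left segment [0, t)."""
        return self.prefix[t]

    def right(self, t):
        """Sum of squares over the right segment [t, N)."""
        return self.prefix[-1] - self.prefix[t]


def square_sums(signal: Signal | Sequence[float] | np.ndarray) -> SquareSums:
    """One-pass prefix sums of squared amplitudes."""
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise EmptySignalError("cannot build square sums of an empty signal")
    prefix = np.empty(x.size + 1)
    prefix[0] = 0.0
    np.cumsum(np.square(x), out=prefix[1:])
    return SquareSums(prefix)


@dataclass(frozen=True)
class GridConfig:
    """Candidate-cut grid: stride ``resolution`` (r) in samples, and edge
    margin ``tmin`` keeping at least that many samples on each side of any
    candidate.  The margin suppresses the spurious posterior peaks that
    small one-sided samples produce near the interval ends."""

    resolution: int = 1
    tmin: int = 5

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        if self.tmin < 3:
            raise ValueError(f"tmin must be >= 3, got {self.tmin}")

    def support(self, n: int) -> tuple[int, int]:
        """Inclusive bounds [lo, hi] of the valid candidate support."""
        return max(self.tmin, 1), n - max(self.tmin, 3)

    def grid(self, n: int) -> np.ndarray:
        """Multiples of ``resolution`` intersected with the valid support."""
        lo, hi = self.support(n)
        r = self.resolution
        first = max(r * int(np.ceil(lo / r)), r)
        return np.arange(first, hi + 1, r, dtype=np.int64)


@dataclass(frozen=True)
class ChangepointPosterior:
    """Discrete posterior over candidate cuts, kept in log space."""

    grid: np.ndarray
    log_kernel: np.ndarray
    log_norm: float
    map_index: int

    @property
    def probabilities(self) -> np.ndarray:
        """Normalised posterior over the grid (sums to one)."""
        return np.exp(self.log_kernel - self.log_norm)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"index": self.grid, "probability": self.probabilities})


def log_changepoint_kernel(ss: SquareSums, t, log_prior_t=0.0):
    """Log posterior kernel at candidate cut(s) ``t``.

    ``t`` is the number of samples on the left: left segment [0, t),
    right [t, N).  Accepts a scalar or array of candidates; requires
    1 <= t <= N-3 and positive sums of squares on both sides.
    """
    t_arr = np.asarray(t, dtype=np.int64)
    n = ss.n
    if np.any(t_arr < 1) or np.any(t_arr > n - 3):
        raise DegenerateSegmentError(
            f"candidate cut outside the convergence region [1, {n - 3}]"
        )
    s_left = ss.left(t_arr)
    s_right = ss.right(t_arr)
    if np.any(s_left <= 0) or np.any(s_right <= 0):
        raise DegenerateSegmentError("zero sum of squares on one side of the cut")
    a = (t_arr + 2) / 2.0
    b = (n - t_arr - 2) / 2.0
    out = log_prior_t + gammaln(a) + gammaln(b) - a * np.log(s_left) - b * np.log(s_right)
    return out if t_arr.ndim else float(out)


def map_changepoint(
    ss: SquareSums,
    grid_config: GridConfig = GridConfig(),
    log_prior: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ChangepointPosterior:
    """Evaluate the kernel on the resolution grid and locate the MAP cut.

    The prior over t defaults to uniform on the valid support;
    ``log_prior`` may supply any vectorised log-prior.  Ties are broken
    deterministically toward the smallest index.
    """
    grid = grid_config.grid(ss.n)
    if grid.size == 0:
        raise NoCandidateError(
            f"no candidate cut for n={ss.n} with tmin={grid_config.tmin}, "
            f"resolution={grid_config.resolution}"
        )
    lp = 0.0 if log_prior is None else np.asarray(log_prior(grid), dtype=np.float64)
    log_kernel = log_changepoint_kernel(ss, grid, lp)
    map_index = int(grid[int(np.argmax(log_kernel))])  # argmax -> first max: smallest index
    return ChangepointPosterior(
        grid=grid,
        log_kernel=np.asarray(log_kernel, dtype=np.float64),
        log_norm=float(logsumexp(log_kernel)),
        map_index=map_index,
    )
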
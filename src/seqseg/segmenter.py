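"""Sequential Bayesian signal segmentation.

The driver recursively splits a signal at the MAP variance changepoint
and keeps each split only while the Full Bayesian Significance Test
rejects variance equality of the two halves:

    seg(y, nmin):
        if len(y) < nmin: return []
        t = MAP changepoint of y (on the resolution grid)
        if ev(H0: equal variances of y[:t], y[t:]) >= alpha: return []
        return seg(y[:t], nmin) ++ [t] ++ (t + seg(y[t:], nmin))

The public surface follows the statsmodels convention: build a
:class:`SequentialSegmenter` from the data, call :meth:`~SequentialSegmenter.fit`,
and inspect the returned :class:`SegmentationResult` (changepoints, the
e-value that licensed each split, ``summary()``, ``to_frame()``,
``plot()``).  Functional wrappers :func:`segment` and
:func:`variance_equal_test` expose the same computation.

Randomness discipline: ``fit(seed)`` builds a master ``SeedSequence``
which spawns one child stream per FBST call, in depth-first order
(current segment, then left half, then right half), so runs are exactly
reproducible and independent of platform scheduling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .changepoint import ChangepointPosterior, GridConfig, SquareSums, map_changepoint, square_sums
from .exceptions import DegenerateDataError, NoCandidateError
from .fbst import FBSTConfig, FBSTResult, SegmentStats, evidence
from .signals import Signal

__all__ = [
    "SeqSegConfig",
    "SequentialSegmenter",
    "SegmentationResult",
    "segment",
    "variance_equal_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeqSegConfig:
    """Configuration of the sequential segmentation driver.

    nmin        minimum segment length (samples) still considered splittable
    beta        Laplace prior scale of the variance ratio (the calibration
                knob; small values favour "no change")
    alpha       evidence threshold: split while ev(H0) < alpha
    resolution  stride r of the MAP candidate grid (samples)
    tmin        edge margin of the candidate grid
    mcmc        FBST sampler settings (its beta is kept in sync with `beta`)
    seed        master seed for the per-test RNG streams
    demean      subtract the global sample mean before segmenting
    """

    nmin: int = 1000
    beta: float = 3e-5
    alpha: float = 0.01
    resolution: int = 1
    tmin: int | None = None
    mcmc: FBSTConfig | None = None
    seed: int | None = None
    demean: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tmin is None:
            # default edge margin: half the smallest detectable event, so a
            # split never creates a segment shorter than nmin/2 and the
            # spurious small-sample peaks of the cut posterior near the
            # interval ends are excluded from the MAP search
            object.__setattr__(self, "tmin", max(5, self.nmin // 2))
        if self.nmin < 2 * self.tmin:
            raise ValueError(f"need nmin >= 2*tmin, got nmin={self.nmin}, tmin={self.tmin}")
        mcmc = self.mcmc or FBSTConfig(beta=self.beta)
        if mcmc.beta != self.beta:
            mcmc = replace(mcmc, beta=self.beta)
        object.__setattr__(self, "mcmc", mcmc)

    @property
    def grid(self) -> GridConfig:
        return GridConfig(resolution=self.resolution, tmin=self.tmin)


@dataclass(frozen=True)
class SegmentationResult:
    """Changepoints found in a signal, with the evidence per split.

    ``changepoints`` are strictly increasing absolute sample indices;
    ``evidences`` holds the FBST e-value that licensed each split,
    aligned with the sorted changepoints (NaN for methods that carry no
    evidence, e.g. the peak-detection baseline).  The implied segments
    tile [0, N) exactly.
    """

    changepoints: np.ndarray
    evidences: np.ndarray
    n: int
    fs: float = 1.0
    n_tests: int = 0
    config: SeqSegConfig | None = None
    method: str = "seqseg"

    def __post_init__(self) -> None:
        cp = np.asarray(self.changepoints, dtype=np.int64)
        ev = np.asarray(self.evidences, dtype=np.float64)
        object.__setattr__(self, "changepoints", cp)
        object.__setattr__(self, "evidences", ev)
        if cp.size:
            if np.any(np.diff(cp) <= 0):
                raise ValueError("changepoints must be strictly increasing")
            if cp[0] <= 0 or cp[-1] >= self.n:
                raise ValueError(f"changepoints must lie strictly inside (0, {self.n})")
        if ev.size != cp.size:
            raise ValueError("evidences must align with changepoints")

    @property
    def n_segments(self) -> int:
        return self.changepoints.size + 1

    @property
    def segments(self) -> list[tuple[int, int]]:
        edges = [0, *self.changepoints.tolist(), self.n]
        return list(zip(edges[:-1], edges[1:]))

    @property
    def changepoint_seconds(self) -> np.ndarray:
        return self.changepoints / self.fs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "changepoint_index": self.changepoints,
                "changepoint_seconds": self.changepoint_seconds,
                "ev_h0": self.evidences,
            }
        )

    def to_dict(self) -> dict:
        cfg = None
        if self.config is not None:
            cfg = {
                "nmin": self.config.nmin,
                "beta": self.config.beta,
                "alpha": self.config.alpha,
                "resolution": self.config.resolution,
                "tmin": self.config.tmin,
                "seed": self.config.seed,
                "mcmc_n_samples": self.config.mcmc.n_samples,
                "mcmc_n_burn": self.config.mcmc.n_burn,
            }
        return {
            "method": self.method,
            "n": self.n,
            "fs": self.fs,
            "n_segments": self.n_segments,
            "n_tests": self.n_tests,
            "changepoints": self.changepoints.tolist(),
            "changepoint_seconds": self.changepoint_seconds.tolist(),
            "evidences": [None if math.isnan(e) else e for e in self.evidences.tolist()],
            "config": cfg,
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None

    def summary(self) -> str:
        lines = [
            f"Sequential segmentation results ({self.method})",
            f"  samples: {self.n}   fs: {self.fs:g} Hz   duration: {self.n / self.fs:.3f} s",
            f"  segments: {self.n_segments}   tests run: {self.n_tests}",
        ]
        if self.config is not None:
            c = self.config
            lines.append(
                f"  beta={c.beta:g}  alpha={c.alpha:g}  nmin={c.nmin}  "
                f"r={c.resolution}  tmin={c.tmin}  seed={c.seed}"
            )
        if self.changepoints.size:
            lines.append(f"  {'changepoint':>12}  {'seconds':>10}  {'ev(H0)':>8}")
            for cp, sec, ev in zip(self.changepoints, self.changepoint_seconds, self.evidences):
                ev_s = f"{ev:.4f}" if not math.isnan(ev) else "-"
                lines.append(f"  {cp:>12d}  {sec:>10.3f}  {ev_s:>8}")
        else:
            lines.append("  no changepoints detected")
        return "\n".join(lines)

    def plot(self, signal: Signal | None = None, ax=None):
        """Waveform with changepoint overlays (cosmetic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        if signal is not None:
            t = np.arange(signal.n_samples) / signal.fs
            ax.plot(t, signal.samples, lw=0.3, color="steelblue")
        for sec in self.changepoint_seconds:
            ax.axvline(sec, color="black", ls="--", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("amplitude")
        return ax


class SequentialSegmenter:
    """Model object: a signal plus the segmentation settings.

    Parameters mirror :class:`SeqSegConfig`; ``nmin`` defaults to one
    second of samples (``round(fs)``) when the signal carries a real
    sampling rate, and to 1000 samples otherwise.

    Examples
    --------
    >>> sig = generate_piecewise_gaussian(PiecewiseSpec((500,), (1.0, 3.0), 1000, seed=0))
    >>> res = SequentialSegmenter(sig, beta=1.0, nmin=100).fit(seed=1)
    >>> res.n_segments
    2
    """

    def __init__(
        self,
        signal: Signal | np.ndarray,
        *,
        nmin: int | None = None,
        beta: float = 3e-5,
        alpha: float = 0.01,
        resolution: int = 1,
        tmin: int | None = None,
        n_samples: int = 10_000,
        n_burn: int = 10_000,
        demean: bool = False,
        fs: float | None = None,
    ) -> None:
        if not isinstance(signal, Signal):
            signal = Signal(np.asarray(signal, dtype=np.float64), fs=fs or 1.0)
        elif fs is not None:
            signal = Signal(signal.samples, fs=fs)
        self.signal = signal
        if nmin is None:
            nmin = int(round(signal.fs)) if signal.fs > 1 else 1000
        self.config = SeqSegConfig(
            nmin=nmin,
            beta=beta,
            alpha=alpha,
            resolution=resolution,
            tmin=tmin,
            mcmc=FBSTConfig(beta=beta, n_samples=n_samples, n_burn=n_burn),
            demean=demean,
        )

    @classmethod
    def from_wav(cls, path, **kwargs) -> "SequentialSegmenter":
        from .signals import read_wav

        return cls(read_wav(path), **kwargs)

    def fit(self, seed: int | None = None) -> SegmentationResult:
        """Run the recursive segmentation; returns a :class:`SegmentationResult`."""
        cfg = replace(self.config, seed=seed)
        x = self.signal.samples
        if cfg.demean and x.size:
            x = x - x.mean()
        seedseq = np.random.SeedSequence(seed)
        state = _DriverState(prefix=None, cfg=cfg, seedseq=seedseq)
        found: list[tuple[int, float]] = []
        if x.size:
            state.prefix = square_sums(x).prefix
            _seg_recurse(0, x.size, state, found)
        found.sort(key=lambda pair: pair[0])
        return SegmentationResult(
            changepoints=np.array([c for c, _ in found], dtype=np.int64),
            evidences=np.array([e for _, e in found], dtype=np.float64),
            n=x.size,
            fs=self.signal.fs,
            n_tests=state.n_tests,
            config=cfg,
        )


@dataclass
class _DriverState:
    prefix: np.ndarray | None
    cfg: SeqSegConfig
    seedseq: np.random.SeedSequence
    n_tests: int = 0


def _seg_recurse(lo: int, hi: int, state: _DriverState, out: list) -> None:
    cfg = state.cfg
    n = hi - lo
    if n < cfg.nmin:
        return
    local = SquareSums(state.prefix[lo : hi + 1] - state.prefix[lo])
    try:
        posterior = map_changepoint(local, cfg.grid)
    except NoCandidateError:
        return
    t = posterior.map_index
    left = SegmentStats(n=t, ss=float(local.left(t)))
    right = SegmentStats(n=n - t, ss=float(local.right(t)))
    split, result = _run_test(left, right, state)
    if not split:
        return
    _seg_recurse(lo, lo + t, state, out)
    out.append((lo + t, result.ev_h0))
    _seg_recurse(lo + t, hi, state, out)


def _run_test(left: SegmentStats, right: SegmentStats, state: _DriverState):
    cfg = state.cfg
    rng = np.random.default_rng(state.seedseq.spawn(1)[0])
    state.n_tests += 1
    if left.ss <= 0 or right.ss <= 0:
        logger.warning(
            "degenerate half (zero sum of squares, n=%d/%d); treating variances as equal",
            left.n,
            right.n,
        )
        sup = float("nan")
        result = FBSTResult(
            ev_h0=1.0,
            sup_h0_logdens=sup,
            sigma0_star=float("nan"),
            acceptance_rates=(0.0, 0.0),
            samples_summary={},
            config=cfg.mcmc,
            degenerate=True,
        )
        return False, result
    result = evidence(left, right, cfg.mcmc, rng=rng)
    return result.ev_h0 < cfg.alpha, result


def segment(signal: Signal | np.ndarray, config: SeqSegConfig | None = None) -> SegmentationResult:
    """Functional wrapper: segment ``signal`` under ``config``."""
    config = config or SeqSegConfig()
    model = SequentialSegmenter(
        signal,
        nmin=config.nmin,
        beta=config.beta,
        alpha=config.alpha,
        resolution=config.resolution,
        tmin=config.tmin,
        n_samples=config.mcmc.n_samples,
        n_burn=config.mcmc.n_burn,
        demean=config.demean,
    )
    return model.fit(seed=config.seed)


def variance_equal_test(
    left_signal,
    right_signal,
    config: SeqSegConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[bool, FBSTResult]:
    """FBST of variance equality between two adjacent signals.

    Returns ``(split, result)`` where ``split`` is True when the
    evidence favouring equal variances falls below ``config.alpha``
    (i.e. the variances are judged different).  Degenerate halves (zero
    energy) are reported as "equal" with a degenerate-marked result.
    """
    config = config or SeqSegConfig()
    xl = left_signal.samples if isinstance(left_signal, Signal) else np.asarray(left_signal)
    xr = right_signal.samples if isinstance(right_signal, Signal) else np.asarray(right_signal)
    if xl.size == 0 or xr.size == 0:
        raise ValueError("both halves must be nonempty")
    left = SegmentStats.from_samples(xl)
    right = SegmentStats.from_samples(xr)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    try:
        result = evidence(left, right, config.mcmc, rng=rng)
    except DegenerateDataError:
        result = FBSTResult(
            ev_h0=1.0,
            sup_h0_logdens=float("nan"),
            sigma0_star=float("nan"),
            acceptance_rates=(0.0, 0.0),
            samples_summary={},
            config=config.mcmc,
            degenerate=True,
        )
        return False, result
    return result.ev_h0 < config.alpha, result
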
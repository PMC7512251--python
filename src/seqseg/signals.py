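"""Signal container, WAV input/output and synthetic piecewise-variance signals.

The segmentation machinery operates on a single-channel, discretely sampled,
zero-mean signal.  :class:`Signal` is a thin immutable wrapper around a float
array plus its sampling rate.  :func:`generate_piecewise_gaussian` draws the
kind of test signal used throughout the benchmark study: independent
zero-mean Gaussian samples whose standard deviation is piecewise constant,
switching at known sample indices.  WAV files are read through
``scipy.io.wavfile`` and normalised to amplitudes in [-1, 1]; the
segmentation statistics are amplitude-scale invariant, so the normalisation
is harmless.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .exceptions import InvalidSpecError, SeqSegError

__all__ = [
    "Signal",
    "PiecewiseSpec",
    "generate_piecewise_gaussian",
    "read_wav",
    "write_wav",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signal:
    """A single-channel sampled signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitudes (dimensionless).
    fs : float
        Sampling rate in Hz.  Defaults to 1.0, in which case sample
        indices and "seconds" coincide.
    """

    samples: np.ndarray
    fs: float = 1.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64).ravel()
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    # alias matching the usual N notation
    @property
    def N(self) -> int:  # noqa: N802
        return self.samples.size

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PiecewiseSpec:
    """Specification of a piecewise-variance zero-mean Gaussian signal.

    ``boundaries`` are strictly increasing sample indices in (0, n);
    boundary ``b`` means samples with 0-based index < b belong to the
    segment on its left (half-open ``[start, b)`` convention).
    ``sigmas`` holds one standard deviation per segment, so
    ``len(sigmas) == len(boundaries) + 1``.
    """

    boundaries: tuple[int, ...]
    sigmas: tuple[float, ...]
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", tuple(int(b) for b in self.boundaries))
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        if self.n < 0:
            raise InvalidSpecError(f"signal length must be >= 0, got {self.n}")
        if len(self.sigmas) != len(self.boundaries) + 1:
            raise InvalidSpecError(
                f"need len(sigmas) == len(boundaries) + 1, got "
                f"{len(self.sigmas)} sigmas for {len(self.boundaries)} boundaries"
            )
        if any(s <= 0 for s in self.sigmas):
            raise InvalidSpecError(f"all sigmas must be positive, got {self.sigmas}")
        bounds = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise InvalidSpecError(f"boundaries must be strictly increasing, got {bounds}")
        if bounds and (bounds[0] <= 0 or bounds[-1] >= self.n):
            raise InvalidSpecError(f"boundaries must lie strictly inside (0, {self.n})")

    @property
    def segment_slices(self) -> list[slice]:
        edges = (0, *self.boundaries, self.n)
        return [slice(a, b) for a, b in zip(edges, edges[1:])]


def generate_piecewise_gaussian(spec: PiecewiseSpec, fs: float = 1.0) -> Signal:
    """Draw a zero-mean Gaussian signal with piecewise-constant variance.

    Samples within segment ``i`` are independent ``N(0, sigmas[i]**2)``
    draws; the same ``(spec, seed)`` always yields the same array.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    sigma = np.empty(spec.n)
    for sl, s in zip(spec.segment_slices, spec.sigmas):
        sigma[sl] = s
    return Signal(z * sigma, fs=fs)


def benchmark_spec(seed: int | None = None) -> PiecewiseSpec:
    """The five-segment benchmark profile: 20,000 samples with variances
    1, 1.1, 1, 1.5, 1 switching at samples 5000, 10,000, 12,000, 15,000."""
    return PiecewiseSpec(
        boundaries=(5000, 10000, 12000, 15000),
        sigmas=(1.0, np.sqrt(1.1), 1.0, np.sqrt(1.5), 1.0),
        n=20000,
        seed=seed,
    )


_INT_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31}


def read_wav(path: str | os.PathLike) -> Signal:
    """Read a WAV file as a mono, [-1, 1]-normalised :class:`Signal`.

    Multichannel input is averaged to mono after normalisation; the
    sampling rate is taken from the header.
    """
    try:
        fs, data = wavfile.read(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise SeqSegError(f"cannot read WAV file {os.fspath(path)!r}: {exc}") from exc
    if data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_SCALE:
        x = data.astype(np.float64) / _INT_SCALE[data.dtype]
    else:  # float32 / float64 files are already in [-1, 1] by convention
        x = data.astype(np.float64)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return Signal(x, fs=float(fs))


def write_wav(signal: Signal, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a :class:`Signal` to a mono WAV file.

    Amplitudes outside [-1, 1] are clipped (with a logged warning);
    ``bit_depth`` 16 writes PCM int16, 32 writes IEEE float32.
    """
    x = np.asarray(signal.samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples to WAV")
    if x.size and np.max(np.abs(x), initial=0.0) > 1.0:
        logger.warning(
            "write_wav: clipping %d samples outside [-1, 1] in %s",
            int(np.sum(np.abs(x) > 1.0)),
            os.fspath(path),
        )
        x = np.clip(x, -1.0, 1.0)
    try:
        if bit_depth == 16:
            wavfile.write(os.fspath(path), int(round(signal.fs)), np.round(x * 32767.0).astype(np.int16))
        elif bit_depth == 32:
            wavfile.write(os.fspath(path), int(round(signal.fs)), x.astype(np.float32))
        else:
            raise ValueError(f"unsupported bit depth {bit_depth}; use 16 or 32")
    except OSError as exc:
        raise SeqSegError(f"cannot write WAV file {os.fspath(path)!r}: {exc}") from exc
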
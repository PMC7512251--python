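"""Shared fixtures.

The ten-seed benchmark study (the heaviest computation in the suite) is
session-scoped so the recovery, robustness and reproduction tests all
reuse the same runs.
"""

from __future__ import annotations

import pytest

from seqseg.benchmark import run_baseline_benchmark, run_seqseg_benchmark

BENCH_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def table1_seqseg_results():
    """Sequential segmentation on ten fresh benchmark realisations,
    quoted beta 1, alpha 0.01, full 10k+10k MCMC."""
    return [run_seqseg_benchmark(seed, beta_quoted=1.0, alpha=0.01) for seed in BENCH_SEEDS]


@pytest.fixture(scope="session")
def table1_baseline_results():
    """Palshikar S1 (h=3, k=500) on the same ten benchmark realisations."""
    return [run_baseline_benchmark(seed, variant="S1", h=3.0, k=500) for seed in BENCH_SEEDS]
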
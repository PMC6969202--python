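"""Shared fixtures and independent oracles.

The oracles deliberately take different computational paths from the package:
sample entropy by full broadcast template comparison, shortest paths by a
textbook Floyd-Warshall triple loop, chi-square by the direct
sum((O-E)^2/E) formula.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from boldvar.signal_metrics import RoiTimeSeries


# ---------------------------------------------------------------- oracles


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy by explicit all-pairs template comparison.

    Templates of lengths m and m+1 are materialized with a sliding window and
    compared pairwise by broadcasting; both counts run over the common
    n - m start positions.  Returns NaN when no matches exist.
    """
    x = np.asarray(x, dtype=float)
    tol = r * np.std(x, ddof=1)
    n = x.size
    tm1 = sliding_window_view(x, m + 1)        # (n - m) x (m + 1)
    tm = tm1[:, :m]                            # same start positions, length m
    def pair_count(t):
        d = np.abs(t[:, None, :] - t[None, :, :]).max(axis=2)
        iu = np.triu_indices(t.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= tol))
    b = pair_count(tm)
    a = pair_count(tm1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def floyd_warshall_oracle(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path by the textbook triple loop (inf = no edge)."""
    n = lengths.shape[0]
    d = lengths.astype(float).copy()
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = d[i, k] + d[k, j]
                if via < d[i, j]:
                    d[i, j] = via
    return d


def ge_bruteforce(weights: np.ndarray) -> float:
    """Global efficiency via the Floyd-Warshall oracle on 1/weight lengths."""
    w = 0.5 * (weights + weights.T)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    d = floyd_warshall_oracle(lengths)
    r = w.shape[0]
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (r * (r - 1)))


def ar1_series(rng: np.random.Generator, phi: float, n: int,
               burn: int = 50) -> np.ndarray:
    """Stationary-start AR(1) realization with standard-normal innovations."""
    from scipy.signal import lfilter

    eps = rng.standard_normal(n + burn)
    x = lfilter([1.0], [1.0, -phi], eps)
    return x[burn:]


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_series(rng):
    """One subject, 3 ROIs, 60 time points of lag-correlated noise."""
    data = np.cumsum(rng.standard_normal((61, 3)), axis=0)
    data = np.diff(data, axis=0) + 0.5 * data[:-1]
    return RoiTimeSeries(
        subject_id="s01", roi_labels=("roiA", "roiB", "roiC"),
        data=data, group="g1",
    )
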
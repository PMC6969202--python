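"""Per-ROI variability and complexity metrics for BOLD time series.

Variability is measured by the mean square successive difference (MSSD), the
average of squared amplitude changes between consecutive time points; unlike
the ordinary variance it is insensitive to slow drifts in the mean.
Complexity is measured by sample entropy (SampEn): the negative log of the
conditional probability that two sub-sequences ("templates") of length ``m``
that match within a tolerance ``r`` times the signal's standard deviation
also match at length ``m + 1``.  SampEn is low for both white noise and
strongly periodic signals and high for signals with rich temporal structure.

All metrics are computed on z-normalized series (mean 0, sample SD 1 with the
``n - 1`` divisor), so the entropy tolerance ``r * SD`` reduces to ``r``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Value returned by :func:`sample_entropy` when no template pairs match at
#: length m or m+1 and the conditional probability is undefined.
ENTROPY_FAILURE = float("nan")


@dataclass(frozen=True)
class RoiTimeSeries:
    """A single subject's ROI-by-time BOLD data.

    Parameters
    ----------
    subject_id
        Opaque subject label.
    roi_labels
        Ordered region names, one per column of ``data``.
    data
        T x R array of BOLD amplitudes (arbitrary units), T >= 3.
    group
        Categorical group label (e.g. ``"ASD"`` / ``"TD"``).
    """

    subject_id: str
    roi_labels: tuple[str, ...]
    data: np.ndarray = field(repr=False)
    group: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("data must be a 2-D T x R array")
        if arr.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"data has {arr.shape[1]} columns but {len(self.roi_labels)} "
                "ROI labels were given"
            )
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data contains non-finite values")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy parameters: pattern length ``m`` and tolerance factor ``r``.

    ``m`` is the number of samples in a template; ``r`` is the match tolerance
    expressed as a fraction of the series' standard deviation (unitless).
    """

    m: int
    r: float

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"m must be an integer >= 1, got {self.m!r}")
        if not (0 < self.r < 1):
            raise ValueError(f"r must lie in (0, 1), got {self.r!r}")


def znormalize(series: RoiTimeSeries) -> RoiTimeSeries:
    """Z-normalize each ROI column to mean 0 and sample SD 1 (ddof=1).

    Raises
    ------
    ValueError
        If any column is constant (zero variance), naming the ROI.
    """
    data = series.data
    mu = data.mean(axis=0)
    sigma = data.std(axis=0, ddof=1)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        names = ", ".join(series.roi_labels[i] for i in bad)
        raise ValueError(f"cannot z-normalize constant ROI column(s): {names}")
    return replace(series, data=(data - mu) / sigma)


def mssd(x: np.ndarray) -> float:
    """Mean square successive difference of a single series.

    delta^2 = sum_{i=1}^{n-1} (x_{i+1} - x_i)^2 / (n - 1), where n is the
    series length; the divisor is the number of time points minus one, which
    equals the number of successive differences.  Zero iff the series is
    constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError(f"MSSD needs at least 3 time points, got {n}")
    d = np.diff(x)
    return float(d @ d / (n - 1))


def sd(x: np.ndarray) -> float:
    """Sample standard deviation (ddof=1) of a single series."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"SD needs at least 2 time points, got {x.size}")
    return float(np.std(x, ddof=1))


def is_entropy_failure(value: float) -> bool:
    """True if ``value`` is the sample-entropy estimation-failure marker."""
    return math.isnan(value)


def _template_maxdist(x: np.ndarray, max_m: int) -> list[np.ndarray]:
    """Chebyshev distances between all template pairs for lengths 1..max_m.

    Returns a list ``D`` where ``D[m-1]`` is the condensed upper-triangular
    vector of max-norm distances between templates of length ``m`` starting at
    positions ``0..n-max_m`` (a common template count for every length, the
    convention of the canonical SampEn implementation: with ``max_m = m + 1``
    both the length-m and length-(m+1) counts run over ``n - m`` templates).
    """
    n = x.size
    n_templates = n - max_m + 1
    if n_templates < 2:
        raise ValueError("series too short for the requested pattern length")
    iu, ju = np.triu_indices(n_templates, k=1)
    d = np.abs(x[iu] - x[ju])
    out = [d.copy()]
    for k in range(1, max_m):
        np.maximum(d, np.abs(x[iu + k] - x[ju + k]), out=d)
        out.append(d.copy())
    return out


def sample_entropy(x: np.ndarray, params: EntropyParams) -> float:
    """Sample entropy of a single series.

    Counts template pairs (i < j, self-matches excluded) whose Chebyshev
    distance is within ``r * SD(x)`` at lengths ``m`` (count B) and ``m + 1``
    (count A), over the common set of ``n - m - 1`` template start positions,
    and returns ``-ln(A / B)``.

    Returns the :data:`ENTROPY_FAILURE` marker (NaN) when A or B is zero —
    an estimation failure due to an absence of pattern matches — so that
    calibration can count failures instead of aborting.

    A constant series returns exactly 0: every template pair matches at any
    length (A = B), so -ln(A/B) = 0.

    Raises
    ------
    ValueError
        If the series is shorter than ``m + 2``.
    """
    x = np.asarray(x, dtype=float).ravel()
    m, r = params.m, params.r
    if x.size < m + 2:
        raise ValueError(
            f"sample entropy with m={m} needs at least {m + 2} points, got {x.size}"
        )
    sigma = np.std(x, ddof=1)
    tol = r * sigma
    dists = _template_maxdist(x, m + 1)
    b = int(np.count_nonzero(dists[m - 1] <= tol))
    a = int(np.count_nonzero(dists[m] <= tol))
    if a == 0 or b == 0:
        return ENTROPY_FAILURE
    return float(-math.log(a / b))


def sample_entropy_grid(
    x: np.ndarray, m_values: list[int], r_values: list[float]
) -> np.ndarray:
    """Sample entropy of one series over a full (m, r) parameter grid.

    Computes the pairwise template distances once per pattern length and
    resolves all tolerances by a single sort, which makes dense calibration
    grids cheap.  Returns an array of shape ``(len(m_values), len(r_values))``
    with NaN marking estimation failures.  Agrees exactly with per-cell
    :func:`sample_entropy` calls.
    """
    x = np.asarray(x, dtype=float).ravel()
    m_values = [int(m) for m in m_values]
    r_arr = np.asarray(r_values, dtype=float)
    sigma = np.std(x, ddof=1)
    out = np.full((len(m_values), r_arr.size), np.nan)
    for mi, m in enumerate(m_values):
        if x.size < m + 2:
            raise ValueError(f"series too short for m={m}")
        dists = _template_maxdist(x, m + 1)
        db = np.sort(dists[m - 1])
        da = np.sort(dists[m])
        b = np.searchsorted(db, r_arr * sigma, side="right")
        a = np.searchsorted(da, r_arr * sigma, side="right")
        ok = (a > 0) & (b > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = -np.log(a / b)
        out[mi, ok] = vals[ok]
    return out


_METRICS = {"mssd": mssd, "sd": sd, "sampen": None}


def metric_matrix(
    dataset: list[RoiTimeSeries],
    metric_name: str,
    params: EntropyParams | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Subjects x ROI matrix of a metric, rows in dataset order.

    Series are z-normalized before metric computation (disable with
    ``normalize=False`` for already-normalized input).  Sample-entropy
    estimation failures propagate as NaN cells with a logged warning.

    Raises
    ------
    ValueError
        If subjects disagree on ROI labels or the metric name is unknown.
    """
    if metric_name not in _METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; choose from {sorted(_METRICS)}")
    if metric_name == "sampen" and params is None:
        raise ValueError("sample entropy requires EntropyParams")
    if not dataset:
        raise ValueError("empty dataset")
    labels = dataset[0].roi_labels
    for s in dataset[1:]:
        if s.roi_labels != labels:
            raise ValueError(
                f"ROI labels of subject {s.subject_id!r} do not match "
                f"subject {dataset[0].subject_id!r}"
            )
    out = np.empty((len(dataset), len(labels)))
    n_failures = 0
    for i, s in enumerate(dataset):
        z = znormalize(s) if normalize else s
        for j in range(z.n_rois):
            col = z.data[:, j]
            if metric_name == "sampen":
                v = sample_entropy(col, params)
                if is_entropy_failure(v):
                    n_failures += 1
            elif metric_name == "mssd":
                v = mssd(col)
            else:
                v = sd(col)
            out[i, j] = v
    if n_failures:
        logger.warning(
            "sample entropy estimation failed for %d subject/ROI cells "
            "(recorded as NaN)", n_failures,
        )
    return out
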
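"""Calibration of sample-entropy parameters (m, r) on noise-reference voxels.

Sample entropy depends on two free parameters: the pattern length ``m`` and
the tolerance factor ``r``.  The calibration procedure computes entropy for
every voxel of each subject's CSF (noise-reference) mask over a grid of
(m, r) combinations, summarizes each combination by a standard-error-like
dispersion statistic

    SE = 1.96 * (sigma_SampEn / mean_SampEn)**2

(1.96 times the squared coefficient of variation across voxels, computed per
subject), and flags a combination *acceptable* when the median SE across
subjects is below a threshold (default 0.1) and no estimation failure
occurred in any voxel of any subject.  Grey-matter entropy is then averaged
over a selected set of acceptable conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from boldvar.signal_metrics import EntropyParams, sample_entropy_grid

logger = logging.getLogger(__name__)

#: Grid of pattern lengths examined during calibration.
DEFAULT_M_VALUES: tuple[int, ...] = (1, 2, 3, 4)
#: Grid of tolerance factors: 0.05 to 0.80 in steps of 0.05.
DEFAULT_R_VALUES: tuple[float, ...] = tuple(np.round(np.arange(1, 17) * 0.05, 2))
#: Conditions averaged for grey-matter entropy: the acceptable m = 2 cells,
#: excluding r = 0.20 (its entropy contrasts with the other m = 2 tolerances).
DEFAULT_SELECTED_CONDITIONS: tuple[tuple[int, float], ...] = tuple(
    (2, round(r, 2)) for r in (0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65)
)


@dataclass(frozen=True)
class CsfVoxelSet:
    """Noise-reference (CSF) voxel time courses for one subject: V x T."""

    subject_id: str
    voxel_series: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxel_series, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("voxel_series must be a V x T array with V >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("voxel_series contains non-finite values")
        object.__setattr__(self, "voxel_series", arr)

    @property
    def n_voxels(self) -> int:
        return self.voxel_series.shape[0]


@dataclass(frozen=True)
class CalibrationCell:
    """Summary of one (m, r) grid cell across subjects."""

    m: int
    r: float
    per_subject_se: tuple[float, ...]
    median_se: float
    failure_count: int
    acceptable: bool


@dataclass(frozen=True)
class EntropyCalibrationGrid:
    """Full (m, r) calibration grid with per-cell summaries."""

    m_values: tuple[int, ...]
    r_values: tuple[float, ...]
    cells: tuple[tuple[CalibrationCell, ...], ...]  # [m_index][r_index]
    se_threshold: float = 0.1

    def cell(self, m: int, r: float) -> CalibrationCell:
        mi = self.m_values.index(m)
        ri = int(np.argmin(np.abs(np.asarray(self.r_values) - r)))
        if abs(self.r_values[ri] - r) > 1e-9:
            raise KeyError(f"r={r} not on the grid")
        return self.cells[mi][ri]

    def acceptable_conditions(self) -> list[tuple[int, float]]:
        return [
            (c.m, c.r) for row in self.cells for c in row if c.acceptable
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (m, r) cell."""
        rows = [
            {
                "m": c.m,
                "r": c.r,
                "median_se": c.median_se,
                "failures": c.failure_count,
                "acceptable": c.acceptable,
            }
            for row in self.cells
            for c in row
        ]
        return pd.DataFrame(rows)


def _voxel_entropies(
    csf: CsfVoxelSet, m_values: list[int], r_values: list[float]
) -> np.ndarray:
    """Entropy of every voxel over the (m, r) grid: V x M x R, NaN = failure."""
    out = np.empty((csf.n_voxels, len(m_values), len(r_values)))
    for v in range(csf.n_voxels):
        out[v] = sample_entropy_grid(csf.voxel_series[v], m_values, r_values)
    return out


def _se_from_entropies(ent: np.ndarray, squared: bool = True) -> tuple[float, int]:
    """SE statistic and failure count from one subject's voxel entropies.

    ``ent`` holds one entropy value per voxel (NaN = failure).  sigma is the
    SD (ddof=1) over non-failed voxels and SampEn their mean; the statistic is
    1.96 * (sigma/SampEn)**2 as printed in the source procedure (the
    unsquared coefficient-of-variation variant is available via ``squared``).
    Returns NaN when fewer than two voxels succeeded or the mean is zero.
    """
    fails = int(np.count_nonzero(np.isnan(ent)))
    ok = ent[~np.isnan(ent)]
    if ok.size < 2:
        return float("nan"), fails
    mean = ok.mean()
    if mean == 0:
        return float("nan"), fails
    cv = np.std(ok, ddof=1) / mean
    return float(1.96 * (cv * cv if squared else abs(cv))), fails


def entropy_se(
    csf: CsfVoxelSet, params: EntropyParams, squared: bool = True
) -> tuple[float, int]:
    """Entropy standard-error statistic for one subject's CSF voxels.

    Returns ``(se, failure_count)`` where ``se`` is
    ``1.96 * (sigma_SampEn / mean_SampEn)**2`` over the subject's non-failed
    voxel entropies (NaN if undefined: all voxels failed, fewer than two
    succeeded, or the mean entropy is zero).
    """
    ent = _voxel_entropies(csf, [params.m], [params.r])[:, 0, 0]
    return _se_from_entropies(ent, squared=squared)


def build_grid(
    csf_sets: list[CsfVoxelSet],
    m_values: list[int] | tuple[int, ...] = DEFAULT_M_VALUES,
    r_values: list[float] | tuple[float, ...] = DEFAULT_R_VALUES,
    se_threshold: float = 0.1,
    squared_se: bool = True,
) -> EntropyCalibrationGrid:
    """Evaluate the acceptability of every (m, r) combination.

    Per cell: ``median_se`` is the median across subjects of the per-subject
    SE statistic, ``failure_count`` sums estimation failures over all voxels
    and subjects, and ``acceptable`` requires ``median_se < se_threshold``
    and ``failure_count == 0``.  An undefined (NaN) median also renders the
    cell unacceptable: a degenerate reference signal carries no calibration
    information.
    """
    if not csf_sets:
        raise ValueError("need at least one subject")
    m_values = [int(m) for m in m_values]
    r_values = [float(r) for r in r_values]
    if not m_values or not r_values:
        raise ValueError("m_values and r_values must be non-empty")

    n_sub = len(csf_sets)
    se = np.full((n_sub, len(m_values), len(r_values)), np.nan)
    fails = np.zeros((n_sub, len(m_values), len(r_values)), dtype=int)
    for s, csf in enumerate(csf_sets):
        ent = _voxel_entropies(csf, m_values, r_values)  # V x M x R
        for mi in range(len(m_values)):
            for ri in range(len(r_values)):
                se[s, mi, ri], fails[s, mi, ri] = _se_from_entropies(
                    ent[:, mi, ri], squared=squared_se
                )

    rows = []
    for mi, m in enumerate(m_values):
        row = []
        for ri, r in enumerate(r_values):
            cell_se = se[:, mi, ri]
            n_fail = int(fails[:, mi, ri].sum())
            median = float(np.median(cell_se))  # NaN propagates
            ok = bool(
                np.isfinite(median) and median < se_threshold and n_fail == 0
            )
            row.append(
                CalibrationCell(
                    m=m,
                    r=r,
                    per_subject_se=tuple(float(v) for v in cell_se),
                    median_se=median,
                    failure_count=n_fail,
                    acceptable=ok,
                )
            )
        rows.append(tuple(row))
    return EntropyCalibrationGrid(
        m_values=tuple(m_values),
        r_values=tuple(r_values),
        cells=tuple(rows),
        se_threshold=se_threshold,
    )


def average_over_conditions(
    entropy_tensor: np.ndarray,
    conditions: list[tuple[int, float]],
    selected: list[tuple[int, float]],
    grid: EntropyCalibrationGrid | None = None,
    allow_unacceptable: bool = False,
) -> np.ndarray:
    """Average a subjects x R x conditions entropy tensor over selected cells.

    ``conditions`` names the (m, r) pair behind each slice of the tensor's
    last axis; ``selected`` picks which are averaged (cell-wise arithmetic
    mean).  Failed (NaN) cells are excluded pairwise from their cell's mean,
    with a logged count, rather than dropping the subject.

    If a calibration ``grid`` is given, every selected condition must be
    flagged acceptable unless ``allow_unacceptable`` is set.
    """
    entropy_tensor = np.asarray(entropy_tensor, dtype=float)
    if entropy_tensor.ndim != 3:
        raise ValueError("entropy_tensor must be subjects x ROI x conditions")
    if entropy_tensor.shape[2] != len(conditions):
        raise ValueError("conditions list does not match tensor's last axis")
    if not selected:
        raise ValueError("empty condition selection")
    lookup = {(int(m), round(float(r), 6)): i for i, (m, r) in enumerate(conditions)}
    idx = []
    for m, r in selected:
        key = (int(m), round(float(r), 6))
        if key not in lookup:
            raise KeyError(f"condition (m={m}, r={r}) not present in the tensor")
        if grid is not None and not allow_unacceptable:
            if not grid.cell(int(m), float(r)).acceptable:
                raise ValueError(
                    f"condition (m={m}, r={r}) is not acceptable; pass "
                    "allow_unacceptable=True to override"
                )
        idx.append(lookup[key])
    sub = entropy_tensor[:, :, idx]
    n_missing = int(np.count_nonzero(np.isnan(sub)))
    if n_missing:
        logger.warning(
            "excluding %d failed entropy cells from condition averaging", n_missing
        )
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub, axis=2)
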
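"""Weighted global efficiency of structural connectivity matrices.

A structural connectome is an R x R nonnegative weight matrix (streamline
counts normalized by samples).  Weights are first masked by a binary
anatomical-presence matrix (CoCoMac-style) to suppress tractography false
positives.  Global efficiency (GE) summarizes the network's capacity for
parallel information transfer: edge lengths are reciprocals of weights,
shortest path lengths d_ij come from Dijkstra's algorithm, and

    GE = 1 / (R (R - 1)) * sum_{i != j} 1 / d_ij,

with 1/inf := 0 for disconnected pairs.  Because tractography output can be
asymmetric, matrices are symmetrized by the arithmetic mean of (i, j) and
(j, i) by default before efficiency is computed.

Head-motion (or any scalar covariate) can be regressed out of per-subject GE
values by ordinary least squares, with the grand mean added back so the
residualized values stay on an interpretable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


@dataclass(frozen=True)
class ConnectivityMatrix:
    """R x R nonnegative structural weights, zero diagonal."""

    roi_labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        r = len(self.roi_labels)
        if w.shape != (r, r):
            raise ValueError(f"weights must be {r} x {r}, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-connections (nonzero diagonal) are not allowed")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass(frozen=True)
class PresenceMask:
    """Binary matrix of anatomically documented connections, false diagonal."""

    mask: np.ndarray = field(repr=False)
    directed: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        if np.any(np.diag(m)):
            raise ValueError("mask diagonal must be false (no self-connections)")
        if not self.directed and not np.array_equal(m, m.T):
            raise ValueError("undirected mask must be symmetric")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class EfficiencyResult:
    """Per-subject global efficiency, optionally covariate-residualized."""

    subject_id: str
    ge: float
    residualized_ge: float | None = None


def apply_mask(sc: ConnectivityMatrix, mask: PresenceMask) -> ConnectivityMatrix:
    """Zero all weights where the presence mask is false; others unchanged."""
    if mask.mask.shape != sc.weights.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match weights {sc.weights.shape}"
        )
    return replace(sc, weights=np.where(mask.mask, sc.weights, 0.0))


def global_efficiency(sc: ConnectivityMatrix, symmetrize: bool = True) -> float:
    """Average inverse shortest-path length over all ordered node pairs.

    Edge length is the reciprocal of the weight for positive weights; zero
    weights are absent edges.  Disconnected pairs contribute 0.  A complete
    unit-weight graph has GE exactly 1; an edgeless graph has GE 0.
    """
    r = sc.n_rois
    if r < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    w = sc.weights
    if symmetrize:
        w = 0.5 * (w + w.T)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    dist = dijkstra(csr_matrix(lengths), directed=not symmetrize)
    np.fill_diagonal(dist, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist), 1.0 / dist, 0.0)
    return float(inv.sum() / (r * (r - 1)))


def residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on ``[1, covariate]``, grand mean added back.

    The output has exactly zero sample correlation with the covariate.  Mean
    restoration is cosmetic (downstream multivariate analyses are
    translation-insensitive) but keeps the values on their original scale.
    """
    y = np.asarray(values, dtype=float).ravel()
    c = np.asarray(covariate, dtype=float).ravel()
    if y.size != c.size:
        raise ValueError("values and covariate must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 subjects to residualize")
    if np.ptp(c) == 0:
        raise ValueError("covariate is constant; residualization is undefined")
    design = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid + y.mean()
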
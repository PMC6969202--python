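"""Mean-centering and behavioral partial least squares (PLS).

PLS finds orthogonal latent variables (LVs) that explain the maximal
covariance between a block of brain variables and either a study design
(mean-centering PLS: contrasts between groups/conditions) or a block of
behavior variables (behavioral PLS).  Both reduce to a singular value
decomposition of a cross-block matrix:

* mean-centering PLS decomposes the groups x brain-variables matrix of group
  means after removing each column's grand mean across groups;
* behavioral PLS decomposes the behavior x brain correlation matrix, computed
  within each group and stacked group-wise.

For each LV the right singular vector is the *brain salience* (weights over
brain variables), the left singular vector the *design/behavior salience*,
and subjects project onto saliences as brain/behavior *scores*.  LV
significance is assessed by permuting subject rows and re-computing singular
values; salience reliability by stratified bootstrap resampling, summarized
as the bootstrap ratio (BSR): original salience over its bootstrap standard
error, with |BSR| >= 2 marking a reliable variable (~95% confidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Conventional reliability threshold on the bootstrap ratio.
BSR_THRESHOLD = 2.0


@dataclass(frozen=True)
class PlsResult:
    """Fitted PLS decomposition plus optional resampling inference.

    Attributes
    ----------
    kind
        ``"mean_centering"`` or ``"behavioral"``.
    singular_values
        Per-LV singular values of the cross-block matrix, descending.
    covariance_explained
        Squared singular values over their sum (fractions summing to 1).
    brain_saliences
        brain-variables x LVs right singular vectors (unit norm per LV).
    design_saliences
        Left singular vectors: groups x LVs (mean-centering) or stacked
        (group x behavior-variable) x LVs (behavioral).
    brain_scores, behavior_scores
        Subject-level projections onto the saliences.
    group_order
        Group labels in the order used for stacking.
    behavior_names
        Behavior column names (behavioral PLS only).
    perm_p, bsr, behavior_ci
        Filled by :func:`permutation_test` / :func:`bootstrap`.
    """

    kind: str
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    brain_saliences: np.ndarray
    design_saliences: np.ndarray
    brain_scores: np.ndarray
    group_order: tuple[str, ...]
    behavior_scores: np.ndarray | None = None
    behavior_names: tuple[str, ...] | None = None
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None
    behavior_ci: np.ndarray | None = None

    @property
    def n_lv(self) -> int:
        return self.singular_values.size

    def reliable_brain_variables(
        self, lv: int = 0, threshold: float = BSR_THRESHOLD
    ) -> np.ndarray:
        """Boolean mask of brain variables with |BSR| >= threshold on one LV."""
        if self.bsr is None:
            raise ValueError("run bootstrap() first")
        return np.abs(self.bsr[:, lv]) >= threshold


def _group_order(labels: np.ndarray) -> tuple:
    return tuple(dict.fromkeys(labels.tolist()))


def _zscore_cols(a: np.ndarray, what: str, names=None) -> np.ndarray:
    mu = a.mean(axis=0)
    sigma = a.std(axis=0, ddof=1)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"zero-variance {what} variable: {label}")
    return (a - mu) / sigma


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|value| element of each brain salience positive."""
    for k in range(v.shape[1]):
        col = v[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            v[:, k] = -col
            u[:, k] = -u[:, k]
    return u, v


def _svd_cross(cross: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    return u, s, vt.T


def _mc_cross(X: np.ndarray, labels: np.ndarray, order: tuple[str, ...]) -> np.ndarray:
    """Column-centered matrix of group means (groups x brain variables)."""
    means = np.stack([X[labels == g].mean(axis=0) for g in order])
    return means - means.mean(axis=0)


def _beh_cross(
    X: np.ndarray, Y: np.ndarray, labels: np.ndarray, order: tuple[str, ...]
) -> np.ndarray:
    """Stacked within-group behavior x brain correlation matrices."""
    blocks = []
    for g in order:
        rows = labels == g
        zx = _zscore_cols(X[rows], "brain")
        zy = _zscore_cols(Y[rows], "behavior")
        blocks.append(zy.T @ zx / (rows.sum() - 1))
    return np.vstack(blocks)


def mean_centering_pls(X: np.ndarray, labels) -> PlsResult:
    """Mean-centering PLS: optimal contrasts between groups or conditions.

    Builds the groups x brain-variables matrix of group means, removes each
    column's grand mean across groups, and decomposes it by SVD.  Design
    saliences are the left singular vectors (one weight per group), brain
    saliences the right; brain scores are ``X @ brain_saliences``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("X must be subjects x brain variables")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must match the rows of X")
    order = _group_order(labels)
    if len(order) < 2:
        raise ValueError("mean-centering PLS needs at least 2 groups/conditions")
    for g in order:
        if (labels == g).sum() < 1:
            raise ValueError(f"group {g!r} has no rows")
    if np.isnan(X).any():
        raise ValueError("X contains missing cells")
    cross = _mc_cross(X, labels, order)
    u, s, v = _svd_cross(cross)
    u, v = _fix_signs(u, v)
    total = (s**2).sum()
    return PlsResult(
        kind="mean_centering",
        singular_values=s,
        covariance_explained=s**2 / total if total > 0 else np.zeros_like(s),
        brain_saliences=v,
        design_saliences=u,
        brain_scores=X @ v,
        group_order=order,
    )


def behavioral_pls(
    X: np.ndarray, Y: np.ndarray, labels=None, behavior_names=None
) -> PlsResult:
    """Behavioral PLS: covariance patterns between brain and behavior blocks.

    Within each group, every brain and behavior column is z-normalized and
    the behavior x brain Pearson correlation matrix is formed; group blocks
    are stacked row-wise and decomposed by SVD.  Behavior saliences are the
    left singular vectors (one block of rows per group), brain saliences the
    right.  Brain scores are ``X @ brain_saliences``; behavior scores project
    each subject's z-scored behavior onto their group's salience block.

    Pairwise behavior correlations above \\|r\\| = 0.8 are logged as a
    collinearity warning (strongly overlapping predictors bias the pattern).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D subjects x variables arrays")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing cells are not allowed at fit time")
    if labels is None:
        labels = np.zeros(X.shape[0], dtype=int)
    labels = np.asarray(labels)
    order = _group_order(labels)
    for g in order:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} needs at least 3 subjects for correlations")
    if behavior_names is not None and len(behavior_names) != Y.shape[1]:
        raise ValueError("behavior_names length does not match Y")

    if Y.shape[1] > 1:
        corr = np.corrcoef(_zscore_cols(Y, "behavior", behavior_names), rowvar=False)
        hi = np.argwhere(np.triu(np.abs(corr) > 0.8, k=1))
        for i, j in hi:
            ni = behavior_names[i] if behavior_names else f"col{i}"
            nj = behavior_names[j] if behavior_names else f"col{j}"
            logger.warning(
                "behavior variables %s and %s are highly correlated "
                "(|r| = %.2f > 0.8); consider dropping one", ni, nj, abs(corr[i, j]),
            )

    cross = _beh_cross(X, Y, labels, order)
    u, s, v = _svd_cross(cross)
    u, v = _fix_signs(u, v)
    total = (s**2).sum()

    q = Y.shape[1]
    behavior_scores = np.empty((X.shape[0], s.size))
    for gi, g in enumerate(order):
        rows = labels == g
        zy = _zscore_cols(Y[rows], "behavior", behavior_names)
        behavior_scores[rows] = zy @ u[gi * q : (gi + 1) * q]

    return PlsResult(
        kind="behavioral",
        singular_values=s,
        covariance_explained=s**2 / total if total > 0 else np.zeros_like(s),
        brain_saliences=v,
        design_saliences=u,
        brain_scores=X @ v,
        behavior_scores=behavior_scores,
        behavior_names=tuple(behavior_names) if behavior_names else None,
        group_order=order,
    )


def _refit_singular_values(
    result: PlsResult, X: np.ndarray, Y_or_labels, labels
) -> np.ndarray:
    if result.kind == "mean_centering":
        cross = _mc_cross(X, np.asarray(Y_or_labels), result.group_order)
    else:
        cross = _beh_cross(X, np.asarray(Y_or_labels, dtype=float), labels,
                           result.group_order)
    return np.linalg.svd(cross, compute_uv=False)


def permutation_test(
    result: PlsResult,
    X: np.ndarray,
    Y_or_labels,
    labels=None,
    n_perm: int = 1000,
    seed: int | None = None,
    smoothed: bool = True,
) -> PlsResult:
    """Permutation significance of each LV's singular value.

    Subject rows of the brain block are reshuffled across the whole sample
    (breaking both group and behavior linkage), the cross-block matrix and
    its singular values recomputed; the p-value per LV is the proportion of
    permuted singular values at least as large as the observed one.  With
    ``smoothed`` (default) the proportion is ``(count + 1) / (n_perm + 1)``
    so p is never exactly 0; set it false for the plain proportion.

    Returns a copy of ``result`` with ``perm_p`` filled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    if result.kind == "mean_centering":
        labels = np.asarray(Y_or_labels)
    else:
        labels = (np.zeros(X.shape[0], dtype=int) if labels is None
                  else np.asarray(labels))
    rng = np.random.default_rng(seed)
    s_obs = result.singular_values
    count = np.zeros(s_obs.size, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        s_perm = _refit_singular_values(result, X[perm], Y_or_labels, labels)
        count += s_perm[: s_obs.size] >= s_obs
    if smoothed:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    return replace(result, perm_p=p)


def _procrustes_rotation(v_orig: np.ndarray, v_boot: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||v_boot Q - v_orig||_F."""
    a, _, bt = np.linalg.svd(v_boot.T @ v_orig, full_matrices=False)
    return a @ bt


def bootstrap(
    result: PlsResult,
    X: np.ndarray,
    Y_or_labels,
    labels=None,
    n_boot: int = 500,
    seed: int | None = None,
    procrustes: bool = True,
    max_retries: int = 100,
) -> PlsResult:
    """Bootstrap reliability of saliences: BSR and 95% CIs.

    Subjects are resampled with replacement within their group (stratified,
    preserving group sizes).  Each bootstrap cross-block matrix is
    decomposed and the solution aligned to the original — by Procrustes
    rotation of the brain saliences (default) or by per-LV sign matching —
    before accumulating variability.  The bootstrap ratio per brain variable
    and LV is the original salience over the bootstrap standard deviation;
    percentile 95% CIs are returned for the design/behavior saliences.

    Resamples that produce a zero-variance column are redrawn, up to
    ``max_retries`` consecutive failures.

    Returns a copy of ``result`` with ``bsr`` and ``behavior_ci`` filled.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(X, dtype=float)
    if result.kind == "mean_centering":
        labels = np.asarray(Y_or_labels)
        Y = None
    else:
        Y = np.asarray(Y_or_labels, dtype=float)
        labels = (np.zeros(X.shape[0], dtype=int) if labels is None
                  else np.asarray(labels))
    group_rows = {g: np.flatnonzero(labels == g) for g in result.group_order}
    for g, rows in group_rows.items():
        if rows.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects to bootstrap")

    rng = np.random.default_rng(seed)
    n_lv = result.n_lv
    v_orig = result.brain_saliences
    u_orig = result.design_saliences
    v_boots = np.empty((n_boot,) + v_orig.shape)
    u_boots = np.empty((n_boot,) + u_orig.shape)

    b = 0
    retries = 0
    while b < n_boot:
        idx = np.concatenate(
            [rng.choice(rows, size=rows.size, replace=True)
             for rows in group_rows.values()]
        )
        lab_b = np.concatenate(
            [np.repeat(g, rows.size) for g, rows in group_rows.items()]
        )
        try:
            if result.kind == "mean_centering":
                cross = _mc_cross(X[idx], lab_b, result.group_order)
            else:
                cross = _beh_cross(X[idx], Y[idx], lab_b, result.group_order)
        except ValueError:
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    "too many degenerate bootstrap resamples (zero-variance column)"
                )
            continue
        retries = 0
        u_b, s_b, v_b = _svd_cross(cross)
        u_b, v_b = u_b[:, :n_lv], v_b[:, :n_lv]
        if procrustes:
            q = _procrustes_rotation(v_orig, v_b)
            v_b = v_b @ q
            u_b = u_b @ q
        else:
            flip = np.sign(np.einsum("ij,ij->j", v_b, v_orig))
            flip[flip == 0] = 1.0
            v_b = v_b * flip
            u_b = u_b * flip
        v_boots[b] = v_b
        u_boots[b] = u_b
        b += 1

    v_sd = v_boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(v_sd > 0, v_orig / v_sd, np.inf * np.sign(v_orig))
    ci = np.percentile(u_boots, [2.5, 97.5], axis=0)  # 2 x rows x LVs
    return replace(result, bsr=bsr, behavior_ci=ci)
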
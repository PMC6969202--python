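"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without imaging data:

* BOLD series are AR(1) processes.  The lag-1 coefficient phi tunes both
  variability and complexity: a z-scored AR(1) series has population MSSD
  2(1 - phi), and larger phi also lowers sample entropy.  A subset of
  "planted" ROIs ties phi linearly to a per-subject latent trait, creating a
  low-rank brain pattern; the remaining ROIs draw phi independently.
* CSF reference voxels are iid standard-normal series (entropy-stable white
  noise), feeding the (m, r) calibration.
* Structural weight matrices are symmetric nonnegative weights on a random
  presence mask, scaled by a per-subject efficiency knob coupled to the same
  latent trait, so global efficiency varies across subjects in a known
  ordering.
* Behavior columns are built from the latent brain score
  ``s = X @ planted_salience`` as ``b = effect_size * z(s) + noise``, with
  per-column sign flips (efficiency/age/IQ load positively, symptom severity
  negatively); head motion (FD) is independent noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from boldvar.signal_metrics import RoiTimeSeries, znormalize
from boldvar.entropy_calibration import CsfVoxelSet
from boldvar.structural_network import ConnectivityMatrix, PresenceMask

# rng stream offsets so each generator has an independent substream
_STREAM_LATENT, _STREAM_BOLD, _STREAM_CSF, _STREAM_SC, _STREAM_BEHAVIOR = range(5)

#: Default behavior columns and the sign of their loading on the latent trait.
DEFAULT_BEHAVIOR_SIGNS: dict[str, float] = {
    "ge": 1.0,
    "age": 1.0,
    "iq": 1.0,
    "srs_total": -1.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the modelled study design: two groups of 20 and 17
    subjects, 82 cortical ROIs, 180 time points per series.

    Attributes
    ----------
    group_sizes
        Mapping of group label to subject count.
    n_rois, n_timepoints
        Dimensions of each subject's ROI x time matrix.
    ar_range
        (low, high) bounds of the lag-1 AR coefficient across subjects/ROIs.
    n_planted
        Number of ROIs whose AR coefficient follows the latent trait; the
        planted salience puts equal weight on every 4th ROI index.
    effect_size
        Slope linking the z-scored latent brain score to each behavior
        column (0 = null: behavior independent of brain).
    noise_sd
        SD of the additive noise on each behavior column, relative to the
        unit-SD signal term.
    n_csf_voxels
        Reference voxels per subject for entropy calibration.
    sc_density
        Fraction of off-diagonal ROI pairs with an anatomically present
        connection.
    sc_latent_coupling
        Strength of the link between the latent trait and the per-subject
        weight scale (hence global efficiency).
    seed
        Base seed; all generators derive independent substreams from it.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ASD": 20, "TD": 17}
    )
    n_rois: int = 82
    n_timepoints: int = 180
    ar_range: tuple[float, float] = (0.1, 0.8)
    n_planted: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_csf_voxels: int = 25
    sc_density: float = 0.3
    sc_latent_coupling: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ar_range
        if not (0 <= lo <= hi <= 0.95):
            raise ValueError("ar_range must satisfy 0 <= low <= high <= 0.95")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if not (0 <= self.sc_density <= 1):
            raise ValueError("sc_density must lie in [0, 1]")
        if self.n_planted > self.n_rois:
            raise ValueError("cannot plant more ROIs than exist")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def subject_ids(self) -> tuple[str, ...]:
        out = []
        for g, n in self.group_sizes.items():
            out.extend(f"{g}{i + 1:03d}" for i in range(n))
        return tuple(out)

    @property
    def group_labels(self) -> tuple[str, ...]:
        out = []
        for g, n in self.group_sizes.items():
            out.extend([g] * n)
        return tuple(out)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(f"ROI{i + 1:03d}" for i in range(self.n_rois))

    @property
    def planted_rois(self) -> np.ndarray:
        """Indices of latent-coupled ROIs: every 4th index, wrapping as needed."""
        step = max(1, self.n_rois // max(self.n_planted, 1))
        idx = (np.arange(self.n_planted) * step) % self.n_rois
        return np.unique(idx)[: self.n_planted]

    @property
    def planted_salience(self) -> np.ndarray:
        """Unit-norm brain pattern: equal weight on the planted ROIs."""
        w = np.zeros(self.n_rois)
        idx = self.planted_rois
        if idx.size:
            w[idx] = 1.0 / np.sqrt(idx.size)
        return w


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def subject_latents(config: SimulationConfig) -> np.ndarray:
    """Per-subject latent trait u ~ Uniform(-1, 1), fixed by the seed."""
    return _rng(config, _STREAM_LATENT).uniform(-1, 1, size=config.n_subjects)


def _ar1(rng: np.random.Generator, phi: float, n: int, burn: int = 50) -> np.ndarray:
    eps = rng.standard_normal(n + burn)
    x = np.empty(n + burn)
    x[0] = eps[0] / np.sqrt(1 - phi**2) if phi < 1 else eps[0]
    for t in range(1, n + burn):
        x[t] = phi * x[t - 1] + eps[t]
    return x[burn:]


def generate_bold(config: SimulationConfig) -> list[RoiTimeSeries]:
    """AR(1) BOLD series per subject and ROI, z-normalized.

    Planted ROIs use ``phi = mid - half_width * u`` (u the subject latent, so
    a higher latent trait means lower phi, hence *higher* MSSD and entropy);
    the remaining ROIs draw phi iid uniform over ``ar_range``.
    """
    rng = _rng(config, _STREAM_BOLD)
    u = subject_latents(config)
    lo, hi = config.ar_range
    mid, half = (lo + hi) / 2, (hi - lo) / 2
    planted = set(config.planted_rois.tolist())
    out = []
    for s, (sid, grp) in enumerate(zip(config.subject_ids, config.group_labels)):
        data = np.empty((config.n_timepoints, config.n_rois))
        for j in range(config.n_rois):
            phi = mid - half * u[s] if j in planted else rng.uniform(lo, hi)
            data[:, j] = _ar1(rng, phi, config.n_timepoints)
        out.append(
            znormalize(
                RoiTimeSeries(
                    subject_id=sid, roi_labels=config.roi_labels,
                    data=data, group=grp,
                )
            )
        )
    return out


def generate_csf(config: SimulationConfig) -> list[CsfVoxelSet]:
    """iid standard-normal noise-reference voxel series, V x T per subject."""
    rng = _rng(config, _STREAM_CSF)
    return [
        CsfVoxelSet(
            subject_id=sid,
            voxel_series=rng.standard_normal(
                (config.n_csf_voxels, config.n_timepoints)
            ),
        )
        for sid in config.subject_ids
    ]


def generate_sc(
    config: SimulationConfig,
) -> tuple[dict[str, ConnectivityMatrix], PresenceMask]:
    """Symmetric nonnegative weight matrices on a shared random presence mask.

    Edge weights are lognormal; each subject's weights are scaled by an
    efficiency knob ``exp(sc_latent_coupling * u)`` so that global efficiency
    increases with the latent trait (on a fully connected graph GE scales
    linearly with the knob).
    """
    if config.sc_density == 0:
        raise ValueError("sc_density = 0 yields an empty graph; no connectivity")
    rng = _rng(config, _STREAM_SC)
    r = config.n_rois
    iu = np.triu_indices(r, k=1)
    present = rng.random(iu[0].size) < config.sc_density
    mask = np.zeros((r, r), dtype=bool)
    mask[iu] = present
    mask |= mask.T
    pmask = PresenceMask(mask=mask)

    u = subject_latents(config)
    mats: dict[str, ConnectivityMatrix] = {}
    for s, sid in enumerate(config.subject_ids):
        base = np.zeros((r, r))
        w = rng.lognormal(mean=0.0, sigma=0.5, size=iu[0].size) * present
        base[iu] = w
        base += base.T
        knob = float(np.exp(config.sc_latent_coupling * u[s]))
        mats[sid] = ConnectivityMatrix(
            roi_labels=config.roi_labels, weights=knob * base
        )
    return mats, pmask


def generate_behavior(
    brain_metric_matrix: np.ndarray,
    config: SimulationConfig,
    signs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Behavior table carrying a planted low-rank link to the brain matrix.

    The latent brain score ``s = X @ planted_salience`` is z-scored; each
    behavior column is ``sign * effect_size * z(s) + noise_sd * eps`` and is
    then z-normalized.  Head motion (``fd``) is independent noise.  Returns a
    DataFrame indexed by subject with ``group`` plus the behavior columns.
    """
    X = np.asarray(brain_metric_matrix, dtype=float)
    if X.shape != (config.n_subjects, config.n_rois):
        raise ValueError(
            f"brain matrix must be {config.n_subjects} x {config.n_rois}, "
            f"got {X.shape}"
        )
    w = config.planted_salience
    if w.size != X.shape[1]:
        raise ValueError("planted salience length does not match brain matrix")
    rng = _rng(config, _STREAM_BEHAVIOR)
    s = X @ w
    sd = s.std(ddof=1)
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    signs = DEFAULT_BEHAVIOR_SIGNS if signs is None else signs
    cols = {"group": list(config.group_labels)}
    for name, sign in signs.items():
        b = sign * config.effect_size * z + config.noise_sd * rng.standard_normal(
            config.n_subjects
        )
        bsd = b.std(ddof=1)
        cols[name] = (b - b.mean()) / bsd if bsd > 0 else np.zeros_like(b)
    fd = rng.standard_normal(config.n_subjects)
    cols["fd"] = (fd - fd.mean()) / fd.std(ddof=1)
    return pd.DataFrame(cols, index=pd.Index(config.subject_ids, name="subject_id"))
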
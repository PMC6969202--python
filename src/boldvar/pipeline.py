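"""End-to-end orchestration: simulate, measure, calibrate, decompose, report.

``simulate_study`` writes a complete study directory from a single
:class:`~boldvar.synthetic_data.SimulationConfig`;``run_pipeline`` executes
the full analysis on any conforming directory:

1. per-ROI MSSD and SD from the BOLD series;
2. entropy-parameter calibration on the CSF reference voxels, then grey-matter
   sample entropy averaged over the selected acceptable (m, r) conditions;
3. global efficiency of the masked structural matrices, residualized on head
   motion (FD);
4. mean-centering PLS group contrasts for MSSD and entropy, with permutation
   significance;
5. behavioral PLS of each brain metric against [GE, age, IQ, symptom
   severity], with permutation and bootstrap inference;
6. cohort statistics tables.

All outputs are TSV/JSON; a provenance record (seed, version, config hash)
accompanies them, and identical config + seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from boldvar import __version__
from boldvar import io as bio
from boldvar.entropy_calibration import (
    DEFAULT_M_VALUES,
    DEFAULT_R_VALUES,
    build_grid,
    average_over_conditions,
)
from boldvar.pls_engine import (
    PlsResult,
    behavioral_pls,
    bootstrap,
    mean_centering_pls,
    permutation_test,
)
from boldvar.signal_metrics import metric_matrix, sample_entropy_grid, znormalize
from boldvar.structural_network import apply_mask, global_efficiency, residualize
from boldvar.synthetic_data import (
    SimulationConfig,
    generate_behavior,
    generate_bold,
    generate_csf,
    generate_sc,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run over a study directory."""

    data_dir: Path
    out_dir: Path
    m_values: tuple[int, ...] = DEFAULT_M_VALUES
    r_values: tuple[float, ...] = DEFAULT_R_VALUES
    se_threshold: float = 0.1
    average_m: int = 2
    excluded_r: tuple[float, ...] = (0.2,)
    n_perm: int = 1000
    n_boot: int = 500
    seed: int = 0
    bsr_threshold: float = 2.0
    behavior_columns: tuple[str, ...] = ("age", "iq", "srs_total")
    fd_column: str = "fd"

    def __post_init__(self) -> None:
        if self.bsr_threshold <= 0:
            raise ValueError("bsr_threshold must be positive")
        object.__setattr__(self, "data_dir", Path(self.data_dir))
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    def config_hash(self) -> str:
        """Hash of the analysis settings (paths excluded)."""
        payload = {k: str(v) for k, v in asdict(self).items()
                   if k not in ("data_dir", "out_dir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def simulate_study(config: SimulationConfig, outdir: Path) -> Path:
    """Write a full synthetic study directory (deterministic in the seed)."""
    outdir = Path(outdir)
    for sub in ("bold", "csf", "sc"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    bold = generate_bold(config)
    csf = generate_csf(config)
    sc, mask = generate_sc(config)
    mssd_mat = metric_matrix(bold, "mssd", normalize=False)
    behavior = generate_behavior(
        mssd_mat, config, signs={"age": 1.0, "iq": 1.0, "srs_total": -1.0}
    )

    rows = []
    for series, voxels in zip(bold, csf):
        sid = series.subject_id
        bio.write_timeseries(outdir / "bold" / f"{sid}.tsv", series)
        bio.write_csf(outdir / "csf" / f"{sid}.tsv", voxels)
        bio.write_matrix(outdir / "sc" / f"{sid}.tsv",
                         config.roi_labels, sc[sid].weights)
        rows.append(
            {
                "subject_id": sid,
                "group": series.group,
                "bold": f"bold/{sid}.tsv",
                "csf": f"csf/{sid}.tsv",
                "sc": f"sc/{sid}.tsv",
            }
        )
    bio.write_matrix(outdir / "mask.tsv", config.roi_labels,
                     mask.mask.astype(int))
    bio.write_manifest(outdir / "manifest.tsv", rows)
    bio.write_behavior(outdir / "behavior.csv", behavior)
    (outdir / "simulation_config.json").write_text(
        json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(config).items()},
            indent=2, sort_keys=True,
        )
    )
    return outdir


def _check_subjects(manifest: pd.DataFrame, behavior: pd.DataFrame) -> None:
    man = set(manifest["subject_id"])
    beh = set(behavior.index)
    if man != beh:
        missing = sorted(man ^ beh)
        raise ValueError(
            f"subject sets of manifest and behavior table differ: {missing}"
        )


def _entropy_matrix(
    dataset, m: int, r_values: list[float]
) -> np.ndarray:
    """Subjects x ROI entropy averaged over (m, r) conditions (NaN-excluded)."""
    n_sub, n_roi = len(dataset), dataset[0].n_rois
    tensor = np.empty((n_sub, n_roi, len(r_values)))
    for i, series in enumerate(dataset):
        z = znormalize(series)
        for j in range(n_roi):
            tensor[i, j] = sample_entropy_grid(z.data[:, j], [m], r_values)[0]
    conditions = [(m, r) for r in r_values]
    return average_over_conditions(tensor, conditions, conditions)


def _pls_to_dict(res: PlsResult, bsr_threshold: float) -> dict:
    out = {
        "kind": res.kind,
        "singular_values": res.singular_values.tolist(),
        "covariance_explained": res.covariance_explained.tolist(),
        "group_order": list(res.group_order),
    }
    if res.perm_p is not None:
        out["perm_p"] = res.perm_p.tolist()
    if res.bsr is not None:
        out["n_reliable_lv1"] = int(
            np.count_nonzero(np.abs(res.bsr[:, 0]) >= bsr_threshold)
        )
    if res.behavior_names:
        out["behavior_names"] = list(res.behavior_names)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the result bundle."""
    data, out = config.data_dir, config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    manifest = bio.read_manifest(data / "manifest.tsv")
    behavior = bio.read_behavior(data / "behavior.csv")
    _check_subjects(manifest, behavior)
    behavior = behavior.loc[manifest["subject_id"]]
    groups = manifest["group"].to_numpy()

    bold = [
        bio.read_timeseries(data / row.bold, row.subject_id, row.group)
        for row in manifest.itertuples()
    ]
    csf = [
        bio.read_csf(data / row.csf, row.subject_id)
        for row in manifest.itertuples()
    ]
    mask = bio.read_mask(data / "mask.tsv")
    sc = {
        row.subject_id: bio.read_connectivity(data / row.sc)
        for row in manifest.itertuples()
    }

    roi_labels = list(bold[0].roi_labels)
    subject_ids = manifest["subject_id"].tolist()

    logger.info("computing MSSD and SD for %d subjects", len(bold))
    mssd_mat = metric_matrix(bold, "mssd")
    sd_mat = metric_matrix(bold, "sd")
    _write_metric(out / "mssd.tsv", subject_ids, roi_labels, mssd_mat)
    _write_metric(out / "sd.tsv", subject_ids, roi_labels, sd_mat)

    logger.info("calibrating entropy parameters on CSF voxels")
    grid = build_grid(csf, config.m_values, config.r_values, config.se_threshold)
    grid.to_frame().to_csv(out / "calibration_grid.tsv", sep="\t", index=False)
    selected_r = [
        r for (m, r) in grid.acceptable_conditions()
        if m == config.average_m
        and not any(abs(r - x) < 1e-9 for x in config.excluded_r)
    ]
    if not selected_r:
        raise RuntimeError(
            f"no acceptable conditions at m={config.average_m} after exclusions"
        )
    logger.info("averaging entropy over m=%d, r=%s", config.average_m, selected_r)
    entropy_mat = _entropy_matrix(bold, config.average_m, selected_r)
    _write_metric(out / "entropy.tsv", subject_ids, roi_labels, entropy_mat)

    logger.info("computing global efficiency")
    ge = np.array(
        [global_efficiency(apply_mask(sc[sid], mask)) for sid in subject_ids]
    )
    fd = behavior[config.fd_column].to_numpy(dtype=float)
    ge_resid = residualize(ge, fd)
    pd.DataFrame(
        {"subject_id": subject_ids, "ge": ge, "residualized_ge": ge_resid}
    ).to_csv(out / "efficiency.tsv", sep="\t", index=False)

    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    results: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_subjects": len(subject_ids),
            "n_rois": len(roi_labels),
        },
        "selected_conditions": [[config.average_m, r] for r in selected_r],
    }

    Y = np.column_stack(
        [ge_resid] + [behavior[c].to_numpy(dtype=float)
                      for c in config.behavior_columns]
    )
    behavior_names = ("ge",) + tuple(config.behavior_columns)

    for name, X, k in (("mssd", mssd_mat, 0), ("entropy", entropy_mat, 2)):
        if np.isnan(X).any():
            raise RuntimeError(f"{name} matrix contains missing cells")
        logger.info("mean-centering PLS (%s) group contrast", name)
        mc = mean_centering_pls(X, groups)
        mc = permutation_test(mc, X, groups, n_perm=config.n_perm,
                              seed=int(rng_seeds[k]))
        results[f"mean_centering_{name}"] = _pls_to_dict(mc, config.bsr_threshold)

        logger.info("behavioral PLS (%s)", name)
        bp = behavioral_pls(X, Y, labels=groups, behavior_names=behavior_names)
        bp = permutation_test(bp, X, Y, labels=groups, n_perm=config.n_perm,
                              seed=int(rng_seeds[k + 1]))
        bp = bootstrap(bp, X, Y, labels=groups, n_boot=config.n_boot,
                       seed=int(rng_seeds[k + 1]))
        results[f"behavioral_{name}"] = _pls_to_dict(bp, config.bsr_threshold)
        _write_pls_tables(out, f"behavioral_{name}", bp, roi_labels,
                          behavior_names, subject_ids)

    results["group_t_tests"] = _cohort_tests(behavior, groups, config)
    (out / "results.json").write_text(json.dumps(results, indent=2))
    return results


def _cohort_tests(behavior: pd.DataFrame, groups: np.ndarray,
                  config: RunConfig) -> dict:
    from boldvar.inferential_stats import pooled_t_raw

    order = list(dict.fromkeys(groups))
    out = {}
    for col in config.behavior_columns:
        x = behavior[col].to_numpy(dtype=float)
        res = pooled_t_raw(x[groups == order[0]], x[groups == order[1]])
        out[col] = {"t": res.statistic, "df": res.df, "p": res.p}
    return out


def _write_metric(path: Path, subject_ids, roi_labels, mat: np.ndarray) -> None:
    df = pd.DataFrame(mat, columns=roi_labels)
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _write_pls_tables(out: Path, stem: str, res: PlsResult, roi_labels,
                      behavior_names, subject_ids) -> None:
    pd.DataFrame(
        res.brain_saliences,
        index=pd.Index(roi_labels, name="roi"),
        columns=[f"LV{i + 1}" for i in range(res.n_lv)],
    ).to_csv(out / f"{stem}_brain_saliences.tsv", sep="\t")
    if res.bsr is not None:
        pd.DataFrame(
            res.bsr,
            index=pd.Index(roi_labels, name="roi"),
            columns=[f"LV{i + 1}" for i in range(res.n_lv)],
        ).to_csv(out / f"{stem}_bsr.tsv", sep="\t")
    scores = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "brain_score_lv1": res.brain_scores[:, 0],
        }
    )
    if res.behavior_scores is not None:
        scores["behavior_score_lv1"] = res.behavior_scores[:, 0]
    scores.to_csv(out / f"{stem}_scores.tsv", sep="\t", index=False)
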
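"""Tabular I/O: time-series, connectivity and behavior tables (TSV/CSV).

All on-disk formats are plain text.  A study directory contains:

* ``manifest.tsv`` — subject_id, group, and relative paths to each subject's
  BOLD, CSF and structural-connectivity files;
* per-subject BOLD: T x R tab-separated matrix with a header row of ROI
  labels;
* per-subject CSF: V x T tab-separated matrix (no header);
* per-subject SC: R x R tab-separated matrix with ROI header;
* ``mask.tsv`` — R x R binary presence matrix with ROI header;
* ``behavior.csv`` — subject_id-indexed behavior/covariate columns
  including ``group``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from boldvar.signal_metrics import RoiTimeSeries
from boldvar.entropy_calibration import CsfVoxelSet
from boldvar.structural_network import ConnectivityMatrix, PresenceMask


def write_timeseries(path: Path, series: RoiTimeSeries) -> None:
    pd.DataFrame(series.data, columns=list(series.roi_labels)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_timeseries(path: Path, subject_id: str, group: str = "") -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id,
        roi_labels=tuple(df.columns),
        data=df.to_numpy(dtype=float),
        group=group,
    )


def write_csf(path: Path, csf: CsfVoxelSet) -> None:
    np.savetxt(path, csf.voxel_series, delimiter="\t", fmt="%.6f")


def read_csf(path: Path, subject_id: str) -> CsfVoxelSet:
    return CsfVoxelSet(
        subject_id=subject_id,
        voxel_series=np.loadtxt(path, delimiter="\t", ndmin=2),
    )


def write_matrix(path: Path, labels, matrix: np.ndarray) -> None:
    pd.DataFrame(matrix, columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_connectivity(path: Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(
        roi_labels=tuple(df.columns), weights=df.to_numpy(dtype=float)
    )


def read_mask(path: Path, directed: bool = False) -> PresenceMask:
    df = pd.read_csv(path, sep="\t")
    return PresenceMask(mask=df.to_numpy(dtype=float) != 0, directed=directed)


def write_behavior(path: Path, behavior: pd.DataFrame) -> None:
    behavior.to_csv(path, index=True)


def read_behavior(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_manifest(path: Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df
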
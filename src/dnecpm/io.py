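"""Plain-text readers and writers for cohort data.

All formats are tabular text: time-series TSV (rows = time, columns =
nodes, header row of node ids), whitespace-delimited 6-column motion files,
a cohort manifest CSV, and dnE TSVs with node ids on both axes.  The
pipeline's contract starts at extracted ROI time series, so no imaging
containers are read here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditioning import MotionParams, RoiTimeSeries
from .errors import InputError
from .network import DnEMatrix

MANIFEST_REQUIRED = ["subject_id", "timeseries_path", "updrs_off", "updrs_on"]


def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    """Write a subject's series as TSV, one row per time point."""
    pd.DataFrame(ts.data.T, columns=ts.node_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_timeseries(path: str | Path, subject_id: str | None = None,
                    tr_seconds: float = 2.0) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise InputError(f"empty time-series file: {path}")
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float).T,
        tr_seconds=tr_seconds,
        node_ids=[str(c) for c in df.columns],
    )


def read_motion(path: str | Path, subject_id: str | None = None) -> MotionParams:
    """Read whitespace-delimited rigid-body parameters (3 mm + 3 rad columns)."""
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    return MotionParams(subject_id=subject_id or path.stem, data=data)


def write_dne(path: str | Path, dne: DnEMatrix) -> None:
    pd.DataFrame(dne.data, index=dne.node_ids, columns=dne.node_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_dne(path: str | Path) -> DnEMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DnEMatrix(data=df.to_numpy(dtype=float),
                     node_ids=[str(c) for c in df.columns])


def load_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Required columns: subject_id, timeseries_path, updrs_off, updrs_on;
    motion_path is optional (empty = none).  Relative paths are resolved
    against the manifest's directory.  Violations are reported with 1-based
    data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} missing column(s): {missing}")
    if "motion_path" not in df.columns:
        df["motion_path"] = ""
    df["motion_path"] = df["motion_path"].fillna("")
    problems = []
    dup = df["subject_id"].duplicated(keep=False)
    for row, sid in zip(df.index[dup] + 1, df.loc[dup, "subject_id"]):
        problems.append(f"row {row}: duplicate subject_id {sid!r}")
    base = path.parent

    def resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    for row, rec in df.iterrows():
        for col in ("updrs_off", "updrs_on"):
            if not np.isfinite(rec[col]):
                problems.append(f"row {row + 1}: non-finite {col}")
        if check_files:
            tsp = resolve(rec["timeseries_path"])
            if not tsp.exists():
                problems.append(f"row {row + 1}: missing time-series file {tsp}")
            if rec["motion_path"]:
                mp = resolve(rec["motion_path"])
                if not mp.exists():
                    problems.append(f"row {row + 1}: missing motion file {mp}")
    if problems:
        raise InputError("invalid manifest:\n" + "\n".join(problems))
    df["timeseries_path"] = [str(resolve(p)) for p in df["timeseries_path"]]
    df["motion_path"] = [str(resolve(p)) if p else "" for p in df["motion_path"]]
    return df


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON run-configuration file into a flat dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise InputError(f"config file {path} must hold a mapping")
    return loaded
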
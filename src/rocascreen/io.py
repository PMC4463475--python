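"""CSV and YAML I/O for cohorts, episode logs and configuration.

All tables are plain UTF-8 CSV with a header; output files start with a
``#`` comment line recording the package version, seed and a hash of the
generating configuration, which pandas skips on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortConfig, CaseKinetics, TruthRecord, WomanTrajectory
from .model import BiomarkerSeries, HealthyModelParams, TriageThresholds
from .protocol import ProtocolConfig

SERIES_COLUMNS = ["subject_id", "t_years", "ca125_u_ml", "age_entry"]
TRUTH_COLUMNS = ["subject_id", "is_case", "onset_time", "clinical_dx_time",
                 "type_label", "stage"]
TRAJ_COLUMNS = ["subject_id", "log_baseline", "slope", "onset_time"]


def config_hash(obj) -> str:
    """Short stable hash of a (nested) dataclass or dict configuration."""
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        return o
    blob = json.dumps(enc(obj), sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header(seed, config) -> str:
    return f"# rocascreen {__version__} seed={seed} config={config_hash(config)}\n"


def _write_csv(df: pd.DataFrame, path, seed, config) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_header(seed, config))
        df.to_csv(fh, index=False)


def write_cohort(cohort: Cohort, out_dir, seed=None) -> dict:
    """Write cohort.csv, truth.csv and trajectories.csv under ``out_dir``.

    The trajectory file carries the latent paths so a later ``screen`` run
    can draw repeat samples consistent with the generating process.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed if seed is None else seed

    rows = []
    for s in cohort.series:
        for t, v in zip(s.times, s.values):
            rows.append((s.subject_id, t, v, s.age_at_entry))
    series_df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    truth_df = cohort.truth_frame()
    traj_df = pd.DataFrame(
        [(tr.subject_id, tr.log_baseline, tr.slope,
          tr.onset_time if math.isfinite(tr.onset_time) else "")
         for tr in cohort.trajectories],
        columns=TRAJ_COLUMNS,
    )
    paths = {
        "series": out_dir / "cohort.csv",
        "truth": out_dir / "truth.csv",
        "trajectories": out_dir / "trajectories.csv",
    }
    _write_csv(series_df, paths["series"], seed, cohort.config)
    _write_csv(truth_df, paths["truth"], seed, cohort.config)
    _write_csv(traj_df, paths["trajectories"], seed, cohort.config)
    return paths


def read_series_csv(path) -> list[BiomarkerSeries]:
    """Read a per-sample cohort CSV into one series per subject.

    Rows must be grouped by subject with strictly increasing times;
    validation errors name the offending data row (1-based, excluding
    header and comment lines).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("t_years", "ca125_u_ml", "age_entry"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[~(df["ca125_u_ml"] > 0) | ~np.isfinite(df["ca125_u_ml"])]
    if len(bad):
        raise ValueError(f"{path}: non-positive CA-125 at data row {bad[0] + 1}")
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        t = g["t_years"].to_numpy(float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            row = int(g.index[np.argmin(np.r_[np.inf, np.diff(t)])]) + 1
            raise ValueError(f"{path}: non-monotone times for subject {sid!r} "
                             f"near data row {row}")
        out.append(BiomarkerSeries(str(sid), t, g["ca125_u_ml"].to_numpy(float),
                                   float(g["age_entry"].iloc[0])))
    return out


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["is_case"] = df["is_case"].astype(bool)
    return df


def read_trajectories_csv(path) -> list[WomanTrajectory]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for row in df.itertuples():
        onset = row.onset_time
        if onset is None or (isinstance(onset, float) and math.isnan(onset)) or onset == "":
            onset = math.inf
        out.append(WomanTrajectory(str(row.subject_id), float(row.log_baseline),
                                   float(row.slope), float(onset)))
    return out


def read_cohort(directory, config: Optional[CohortConfig] = None) -> Cohort:
    """Reassemble a Cohort from a directory written by :func:`write_cohort`."""
    directory = Path(directory)
    series = read_series_csv(directory / "cohort.csv")
    truth_df = read_truth_csv(directory / "truth.csv")
    truth_map = {}
    for row in truth_df.itertuples():
        def opt(x):
            return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x
        if row.is_case:
            truth_map[row.subject_id] = TruthRecord(
                row.subject_id, True, float(row.onset_time),
                opt(row.clinical_dx_time), opt(row.type_label), opt(row.stage))
        else:
            truth_map[row.subject_id] = TruthRecord(row.subject_id, False)
    traj_path = directory / "trajectories.csv"
    if traj_path.exists():
        trajs = {tr.subject_id: tr for tr in read_trajectories_csv(traj_path)}
    else:
        # fall back to flat paths at each woman's observed geometric mean
        trajs = {
            s.subject_id: WomanTrajectory(s.subject_id,
                                          float(np.mean(np.log(s.values))), 0.0, math.inf)
            for s in series
        }
    truth = [truth_map[s.subject_id] for s in series]
    trajectories = [trajs[s.subject_id] for s in series]
    if config is None:
        config = CohortConfig(n_women=len(series))
    return Cohort(series, truth, trajectories, config)


def write_episode_log(log: pd.DataFrame, path, seed, config) -> None:
    _write_csv(log, path, seed, config)


def read_episode_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", keep_default_na=True)
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("triage", "scan_status", "terminal"):
        df[col] = df[col].fillna("")
    return df


def load_config(path) -> dict:
    """Load a YAML config file into typed configuration objects.

    Recognised top-level sections: ``era`` (triage cutoff era), ``seed``,
    ``cohort``, ``protocol``, ``healthy`` and ``kinetics``; all fields
    optional, falling back to package defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    healthy = HealthyModelParams(**raw.get("healthy", {}))
    kinetics_raw = raw.get("kinetics", {})
    if "doubling_time_months" in kinetics_raw:
        kinetics_raw["doubling_time_months"] = tuple(kinetics_raw["doubling_time_months"])
    kinetics = CaseKinetics(**kinetics_raw)
    thresholds = TriageThresholds.for_era(raw.get("era", "post2005"))
    cohort_raw = dict(raw.get("cohort", {}))
    cohort_raw.setdefault("seed", raw.get("seed"))
    cohort_cfg = CohortConfig(control_params=healthy, kinetics=kinetics, **cohort_raw)
    protocol_cfg = ProtocolConfig(thresholds=thresholds, healthy=healthy,
                                  **raw.get("protocol", {}))
    return {
        "seed": raw.get("seed"),
        "cohort": cohort_cfg,
        "protocol": protocol_cfg,
        "thresholds": thresholds,
    }
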
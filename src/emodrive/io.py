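"""File formats: trajectory CSV, PAD CSV, model JSON, YAML configuration.

A trajectory file holds one driver x condition run as 1 Hz samples with
columns ``time_s, v1_kmh, v2_kmh, ac1_ms2, ac2_ms2, d_m`` (synthetic runs
are expanded from their 10-s windows, values held constant within a window,
so window aggregation recovers the original windows exactly).  PAD reports
are ``minute, P, A, D`` on the original [-1, 1] scale.  Models serialize to
JSON at full float precision and round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hmm import HMMParams
from .preprocess import TRAJECTORY_COLUMNS
from .synthetic import DriverProfile, Episode

_TRAJ_NAME = re.compile(r"traj_driver(?P<driver>\d+)_(?P<condition>[a-z]+)\.csv$")


def trajectory_filename(driver_id: int, condition: str) -> str:
    return f"traj_driver{driver_id:03d}_{condition}.csv"


def pad_filename(driver_id: int, condition: str) -> str:
    return f"pad_driver{driver_id:03d}_{condition}.csv"


def expand_windows(windows: pd.DataFrame, dt_s: float = 10.0, hz: float = 1.0) -> pd.DataFrame:
    """Expand 10-s windows to constant-valued 1 Hz samples."""
    reps = int(round(dt_s * hz))
    n = len(windows)
    t = np.arange(n * reps) / hz
    rep = np.repeat(np.arange(n), reps)
    return pd.DataFrame(
        {
            "time_s": t,
            "v1_kmh": windows["v1"].to_numpy()[rep],
            "v2_kmh": windows["v2"].to_numpy()[rep],
            "ac1_ms2": windows["ac1"].to_numpy()[rep],
            "ac2_ms2": windows["ac2"].to_numpy()[rep],
            "d_m": windows["d"].to_numpy()[rep],
        }
    )


def write_episode(episode: Episode, out_dir: Path, dt_s: float = 10.0) -> list[Path]:
    """Write one episode's trajectory (and PAD reports, if any) as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    traj = expand_windows(episode.windows, dt_s=dt_s)
    p = out_dir / trajectory_filename(episode.driver_id, episode.condition)
    traj.to_csv(p, index=False, float_format="%.17g")
    paths.append(p)
    if episode.pad_reports is not None:
        q = out_dir / pad_filename(episode.driver_id, episode.condition)
        episode.pad_reports.to_csv(q, index=False, float_format="%.17g")
        paths.append(q)
    return paths


def read_trajectory(path: Path) -> pd.DataFrame:
    """Read and validate one trajectory CSV; rows are sorted by time."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    bad = df[list(TRAJECTORY_COLUMNS)].apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    )
    nan_rows = bad.isna().any(axis=1)
    if nan_rows.any():
        lines = (np.flatnonzero(nan_rows.to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: non-numeric cells on line(s) {lines[:10]}")
    return (
        bad.sort_values("time_s", kind="stable").reset_index(drop=True)
    )


def read_trajectories(directory: Path) -> list[tuple[int, str, pd.DataFrame]]:
    """All trajectory files of a directory as (driver_id, condition, samples)."""
    directory = Path(directory)
    out = []
    for p in sorted(directory.glob("traj_driver*.csv")):
        m = _TRAJ_NAME.search(p.name)
        if not m:
            continue
        out.append((int(m.group("driver")), m.group("condition"), read_trajectory(p)))
    if not out:
        raise FileNotFoundError(f"no trajectory files under {directory}")
    return out


def read_pad_reports(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("minute", "P", "A", "D") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values("minute", kind="stable").reset_index(drop=True)


def write_profiles(profiles: list[DriverProfile], path: Path) -> None:
    pd.DataFrame(
        [{"driver_id": p.driver_id, "ve": p.ve, "de": p.de} for p in profiles]
    ).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path: Path) -> list[DriverProfile]:
    df = pd.read_csv(path)
    return [
        DriverProfile(int(r.driver_id), float(r.ve), float(r.de))
        for r in df.itertuples()
    ]


def save_model(params: HMMParams, path: Path) -> None:
    Path(path).write_text(params.to_json())


def load_model(path: Path) -> HMMParams:
    return HMMParams.from_json(Path(path).read_text())


def load_config_file(path: Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
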
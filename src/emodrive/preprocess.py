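"""Windowing, discretization and intention labeling for car-following traces.

The raw signal is a per-sample trace of the following car's speed ``v1``
(km/h), the lead car's speed ``v2`` (km/h), both accelerations (m/s^2) and
the bumper-to-bumper gap ``d`` (m).  Analysis operates on 10-s windows: each
window is the arithmetic mean of the samples it covers, augmented with the
derived variables

* ``dv  = v1 - v2``   relative speed (km/h)
* ``dac = ac1 - ac2`` relative acceleration (m/s^2)
* ``dve = v1 - ve``   expected-speed deviator (km/h), ``ve`` the driver's
  expected (desired maximum safe) speed
* ``dde = d - de``    expected-distance deviator (m), ``de`` the driver's
  expected following distance

Every variable is then coded into three ordered levels by fixed thresholds,
and the triple (``dde`` level, ``d`` level, ``dve`` level) is packed into one
of 27 observation symbols.  The driving intention at window ``t`` is defined
by the acceleration class observed at window ``t + 1``: class 1 = decelerate
(Int1), class 2 = keep speed (Int2), class 3 = accelerate (Int3).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: (lower, upper) bounds per variable; level 1 below, level 3 above, level 2
#: otherwise (boundary values fall in the middle class, keeping the map total).
#: The relative-acceleration lower bound is symmetric with its upper bound.
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "dve": (-5.0, 5.0),
    "dde": (-5.0, 5.0),
    "v1": (55.0, 60.0),
    "v2": (55.0, 60.0),
    "ac1": (-0.5, 0.5),
    "ac2": (-0.5, 0.5),
    "d": (8.0, 13.0),
    "dv": (-5.0, 5.0),
    "dac": (-0.15, 0.15),
}

#: canonical variable order (used for deterministic tie-breaking downstream)
VARIABLE_ORDER: tuple[str, ...] = (
    "dve", "dde", "v1", "v2", "ac1", "ac2", "d", "dv", "dac",
)

#: the three variables that form the observation symbol, in packing order
OBSERVATION_VARS: tuple[str, str, str] = ("dde", "d", "dve")

#: columns expected in a raw trajectory table
TRAJECTORY_COLUMNS: tuple[str, ...] = (
    "time_s", "v1_kmh", "v2_kmh", "ac1_ms2", "ac2_ms2", "d_m",
)

INTENTION_NAMES = {1: "Int1", 2: "Int2", 3: "Int3"}


def discretize_value(x, low: float, high: float):
    """Map values to levels 1/2/3 with a closed middle interval."""
    x = np.asarray(x, dtype=float)
    return np.where(x < low, 1, np.where(x > high, 3, 2)).astype(np.int64)


def discretize(
    windows: pd.DataFrame,
    thresholds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Discretize every kinematic variable of a window table into levels.

    Parameters
    ----------
    windows
        One row per window with at least the columns in ``VARIABLE_ORDER``.
    thresholds
        Optional per-variable (lower, upper) bounds; defaults to the built-in
        table.  Must cover all nine variables.

    Returns
    -------
    DataFrame with the same index and one integer level column per variable.
    """
    rules = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = [v for v in VARIABLE_ORDER if v not in rules]
    if missing:
        raise ValueError(f"thresholds missing variables: {missing}")
    absent = [v for v in VARIABLE_ORDER if v not in windows.columns]
    if absent:
        raise ValueError(f"window table missing columns: {absent}")
    out = {}
    for var in VARIABLE_ORDER:
        low, high = rules[var]
        if not low < high:
            raise ValueError(f"invalid bounds for {var!r}: ({low}, {high})")
        out[var] = discretize_value(windows[var].to_numpy(), low, high)
    return pd.DataFrame(out, index=windows.index)


def encode_observation(dde_level, d_level, dve_level):
    """Pack (dde, d, dve) levels into a symbol in 1..27.

    The packing is ``(dde - 1) * 9 + (d - 1) * 3 + dve`` so (1, 1, 1) -> 1 and
    (3, 3, 3) -> 27.
    """
    dde_level = np.asarray(dde_level, dtype=np.int64)
    d_level = np.asarray(d_level, dtype=np.int64)
    dve_level = np.asarray(dve_level, dtype=np.int64)
    for name, lev in (("dde", dde_level), ("d", d_level), ("dve", dve_level)):
        if np.any((lev < 1) | (lev > 3)):
            raise ValueError(f"{name} level outside 1..3")
    return (dde_level - 1) * 9 + (d_level - 1) * 3 + dve_level


def decode_observation(symbol):
    """Inverse of :func:`encode_observation`; returns (dde, d, dve) levels."""
    symbol = np.asarray(symbol, dtype=np.int64)
    if np.any((symbol < 1) | (symbol > 27)):
        raise ValueError("observation symbol outside 1..27")
    z = symbol - 1
    return z // 9 + 1, (z % 9) // 3 + 1, z % 3 + 1


def observations_from_levels(levels: pd.DataFrame) -> np.ndarray:
    """Observation symbol per window from a discretized window table."""
    return encode_observation(
        levels["dde"].to_numpy(), levels["d"].to_numpy(), levels["dve"].to_numpy()
    )


def label_intentions(ac1_levels: Sequence[int]) -> np.ndarray:
    """Intention labels from following-car acceleration classes.

    The acceleration class realised at window ``t + 1`` names the intention
    held at window ``t``, so ``T`` windows yield ``T - 1`` labels.
    """
    levels = np.asarray(ac1_levels, dtype=np.int64)
    if levels.ndim != 1 or levels.size < 2:
        raise ValueError("need at least two windows to label intentions")
    if np.any((levels < 1) | (levels > 3)):
        raise ValueError("ac1 level outside 1..3")
    return levels[1:].copy()


def window_aggregate(samples: pd.DataFrame, window_s: float, profile) -> pd.DataFrame:
    """Aggregate a raw trajectory into fixed-duration windows.

    Each full window is the arithmetic mean of its samples; a trailing
    partial window is dropped.  ``profile`` must expose ``ve`` (km/h) and
    ``de`` (m); the deviators are computed from the window means.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if samples.empty:
        raise ValueError("empty trajectory")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"trajectory missing columns: {missing}")
    df = samples.sort_values("time_s", kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else window_s
    span = t[-1] - t[0] + dt
    n_win = int(np.floor(span / window_s + 1e-9))
    if n_win < 1:
        raise ValueError("trajectory shorter than one window")
    idx = np.floor((t - t[0]) / window_s).astype(int)
    keep = idx < n_win
    grouped = df.loc[keep].groupby(idx[keep])
    agg = grouped[["v1_kmh", "v2_kmh", "ac1_ms2", "ac2_ms2", "d_m"]].mean()
    windows = pd.DataFrame(
        {
            "t_index": agg.index.to_numpy(),
            "v1": agg["v1_kmh"].to_numpy(),
            "v2": agg["v2_kmh"].to_numpy(),
            "ac1": agg["ac1_ms2"].to_numpy(),
            "ac2": agg["ac2_ms2"].to_numpy(),
            "d": agg["d_m"].to_numpy(),
        }
    )
    windows["dv"] = windows["v1"] - windows["v2"]
    windows["dac"] = windows["ac1"] - windows["ac2"]
    windows["dve"] = windows["v1"] - float(profile.ve)
    windows["dde"] = windows["d"] - float(profile.de)
    if np.any(windows["d"].to_numpy() <= 0):
        raise ValueError("non-positive gap in aggregated windows")
    return windows.reset_index(drop=True)
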
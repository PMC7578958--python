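"""Synthetic car-following study generator.

Emulates the data-collection design the analysis assumes: 62 licensed
drivers, each with a measured expected speed ``ve`` and expected following
distance ``de``, following a lead car running at 60 +/- 5 km/h for 10
minutes per condition (one natural run plus eight emotion-induced runs),
with per-minute PAD self-reports during the emotion runs.

The latent driving-intention process of a run is a 3-state Markov chain
(decelerate / keep / accelerate) whose initial and transition structure is
condition-dependent.  The following car's mean window acceleration is drawn
uniformly inside the discretization class interval of the *previous*
window's intention, so the behaviour-based labeling rule recovers the
simulated intention sequence exactly.  Speeds and gap evolve by first-order
kinematics with relaxation toward the lead speed and the expected distance
(a minimal car-following regulator; without it, integrating class-level
accelerations over 10-s windows drives the state into saturation within a
few minutes, which no human car-following record shows).

Per-emotion intention occupancies encode the qualitative direction of the
emotion effects (e.g. anger raises acceleration and depresses deceleration;
anxiety depresses speed-keeping) as editable presets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pad as _pad
from .preprocess import DEFAULT_THRESHOLDS

CONDITIONS: tuple[str, ...] = (
    "natural", "anger", "surprise", "fear", "anxiety",
    "helplessness", "contempt", "relief", "pleasure",
)

EMOTIONS: tuple[str, ...] = CONDITIONS[1:]

#: open acceleration class intervals are truncated at this magnitude (m/s^2)
ACCEL_TRUNCATION = 2.0

#: stationary intention occupancy per condition.  natural is the trained
#: natural-state estimate; emotions shift it in the direction reported for
#: each emotion (anger/contempt: accelerate up, decelerate down; fear:
#: decelerate up, accelerate down; helplessness: both extremes down;
#: anxiety/surprise: keep-speed down; relief: unchanged; pleasure:
#: decelerate up).
CONDITION_OCCUPANCY: dict[str, tuple[float, float, float]] = {
    "natural": (0.247, 0.468, 0.285),
    "anger": (0.150, 0.490, 0.360),
    "surprise": (0.280, 0.410, 0.310),
    "fear": (0.330, 0.510, 0.160),
    "anxiety": (0.300, 0.330, 0.370),
    "helplessness": (0.200, 0.560, 0.240),
    "contempt": (0.190, 0.480, 0.330),
    "relief": (0.250, 0.465, 0.285),
    "pleasure": (0.300, 0.440, 0.260),
}

#: self-transition excess over the stationary mixing kernel
DEFAULT_STICKINESS = 0.3


@dataclass
class DriverProfile:
    """A driver's expected speed (km/h) and expected following distance (m)."""

    driver_id: int
    ve: float
    de: float

    def __post_init__(self) -> None:
        if self.ve <= 0 or self.de <= 0:
            raise ValueError("expected speed and distance must be positive")


def chain_from_occupancy(occupancy, stickiness: float = DEFAULT_STICKINESS):
    """(pi, A) of a 3-state chain with the given stationary distribution.

    ``A = (1 - s) * 1 occ^T + s * I`` mixes toward the target occupancy with
    self-transition excess ``s``; its stationary distribution is exactly
    ``occupancy``, and transitions into higher-occupancy intentions are
    uniformly larger, matching the observed coupling between occupancy and
    transition shifts.
    """
    occ = np.asarray(occupancy, dtype=float)
    if not 0 <= stickiness < 1:
        raise ValueError("stickiness must lie in [0, 1)")
    A = (1 - stickiness) * np.tile(occ, (occ.size, 1)) + stickiness * np.eye(occ.size)
    return occ.copy(), A


def default_emission_matrix() -> np.ndarray:
    """A plausible 3 x 27 emission matrix for model-based simulation.

    Built as a product of per-variable level tendencies: decelerating drivers
    tend to sit above their expectations (close gap, surplus speed),
    accelerating drivers below them.  Used when sampling symbol sequences
    directly from a model rather than through the kinematic generator.
    """
    level_dists = {
        # rows: intention 1..3; columns: level 1..3 of each variable
        "dde": np.array([[0.50, 0.40, 0.10], [0.20, 0.60, 0.20], [0.10, 0.40, 0.50]]),
        "d": np.array([[0.50, 0.40, 0.10], [0.20, 0.60, 0.20], [0.10, 0.40, 0.50]]),
        "dve": np.array([[0.10, 0.40, 0.50], [0.20, 0.60, 0.20], [0.50, 0.40, 0.10]]),
    }
    B = np.empty((3, 27))
    for j in range(27):
        dde, d, dve = j // 9, (j % 9) // 3, j % 3
        B[:, j] = (
            level_dists["dde"][:, dde]
            * level_dists["d"][:, d]
            * level_dists["dve"][:, dve]
        )
    return B / B.sum(axis=1, keepdims=True)


@dataclass
class ConditionSpec:
    """Ground-truth generative settings for one experimental condition."""

    condition: str
    pi_true: np.ndarray
    A_true: np.ndarray
    B_true: np.ndarray
    pad_target: np.ndarray | None = None  # original [-1, 1]^3 space
    pad_noise_sd: float = 0.12
    effective_rate: float = 0.8

    def __post_init__(self) -> None:
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.B_true = np.asarray(self.B_true, dtype=float)
        for name, m in (("pi_true", self.pi_true), ("A_true", self.A_true),
                        ("B_true", self.B_true)):
            if np.any(m < 0) or not np.allclose(m.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{name} is not a stochastic array")
        if self.pad_target is not None:
            self.pad_target = np.asarray(self.pad_target, dtype=float)
        if not 0 <= self.effective_rate <= 1:
            raise ValueError("effective_rate must lie in [0, 1]")
        if self.pad_noise_sd < 0:
            raise ValueError("pad_noise_sd must be non-negative")


def default_condition_specs(
    stickiness: float = DEFAULT_STICKINESS,
    effective_rate: float = 0.8,
    pad_noise_sd: float = 0.12,
) -> dict[str, ConditionSpec]:
    """The preset ConditionSpec per condition (natural + eight emotions)."""
    B = default_emission_matrix()
    specs = {}
    for name in CONDITIONS:
        pi, A = chain_from_occupancy(CONDITION_OCCUPANCY[name], stickiness)
        target = None
        if name != "natural":
            target = _pad.reference_original(name)
        specs[name] = ConditionSpec(
            condition=name,
            pi_true=pi,
            A_true=A,
            B_true=B,
            pad_target=target,
            pad_noise_sd=pad_noise_sd,
            effective_rate=effective_rate,
        )
    return specs


@dataclass
class Episode:
    """One driver x condition run: 10-s windows plus per-minute PAD reports."""

    driver_id: int
    condition: str
    windows: pd.DataFrame
    intentions: np.ndarray
    pad_reports: pd.DataFrame | None = None


def episode_rng(rng_seed: int, driver_id: int, condition: str) -> np.random.Generator:
    """One stream per (seed, driver, condition), reproducible under parallelism."""
    tag = zlib.crc32(condition.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((rng_seed, driver_id, tag)))


def gen_driver_profiles(
    n_drivers: int,
    rng_seed: int,
    ve_range: tuple[float, float] = (58.0, 72.0),
    de_range: tuple[float, float] = (8.0, 14.0),
) -> list[DriverProfile]:
    """Draw driver profiles with ve and de uniform over configured ranges."""
    if n_drivers < 1:
        raise ValueError("n_drivers must be >= 1")
    for name, (lo, hi) in (("ve_range", ve_range), ("de_range", de_range)):
        if lo <= 0 or hi <= lo:
            raise ValueError(f"{name} must be positive and increasing")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xD1)))
    ve = rng.uniform(*ve_range, size=n_drivers)
    de = rng.uniform(*de_range, size=n_drivers)
    return [DriverProfile(i, float(ve[i]), float(de[i])) for i in range(n_drivers)]


def _accel_interval(level: int) -> tuple[float, float]:
    low, high = DEFAULT_THRESHOLDS["ac1"]
    return ((-ACCEL_TRUNCATION, low), (low, high), (high, ACCEL_TRUNCATION))[level - 1]


@dataclass
class KinematicConfig:
    """Regulator gains and bounds of the window-level dynamics."""

    dt_s: float = 10.0
    speed_gain: float = 0.5        # relaxation of v1 toward v2 per window
    accel_scale: float = 4.0       # km/h change in v1 per 1 m/s^2 window-mean ac1
    gap_gain: float = 0.3          # relaxation of d toward de per window
    gap_coupling: float = 0.4      # share of the relative-speed displacement
    lead_ar: float = 0.8           # AR(1) coefficient of the lead-speed wobble
    lead_sd: float = 1.2           # innovation SD of the lead speed (km/h)
    lead_speed: float = 60.0
    lead_band: float = 5.0         # lead speed clipped to lead_speed +/- band
    v1_bounds: tuple[float, float] = (20.0, 90.0)
    min_gap: float = 2.0
    max_gap: float = 80.0


def gen_episode(
    profile: DriverProfile,
    spec: ConditionSpec,
    n_windows: int = 60,
    rng_seed: int = 0,
    kinematics: KinematicConfig | None = None,
) -> Episode:
    """Simulate one 10-s-window car-following run for a driver and condition.

    The intention chain (length ``n_windows - 1``) is drawn from
    (pi_true, A_true); the following car's acceleration at window ``t`` falls
    uniformly inside the class interval of the intention at ``t - 1``; speeds
    and gap follow the regulated first-order kinematics.  PAD reports (one
    per simulated minute) are attached for emotion conditions.
    """
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    kin = kinematics or KinematicConfig()
    rng = episode_rng(rng_seed, profile.driver_id, spec.condition)

    # latent intention chain; an extra pre-episode draw feeds window 0
    T = n_windows
    intent = np.empty(T - 1, dtype=np.int64)
    intent[0] = rng.choice(3, p=spec.pi_true) + 1
    for t in range(1, T - 1):
        intent[t] = rng.choice(3, p=spec.A_true[intent[t - 1] - 1]) + 1
    pre_intent = int(rng.choice(3, p=spec.pi_true)) + 1

    ac1 = np.empty(T)
    lo, hi = _accel_interval(pre_intent)
    ac1[0] = rng.uniform(lo, hi)
    for t in range(1, T):
        lo, hi = _accel_interval(int(intent[t - 1]))
        ac1[t] = rng.uniform(lo, hi)

    # lead car: AR(1) wobble around the nominal lead speed
    v2 = np.empty(T)
    w = rng.normal(0.0, kin.lead_sd / np.sqrt(max(1 - kin.lead_ar**2, 1e-9)))
    for t in range(T):
        v2[t] = np.clip(
            kin.lead_speed + w,
            kin.lead_speed - kin.lead_band,
            kin.lead_speed + kin.lead_band,
        )
        w = kin.lead_ar * w + rng.normal(0.0, kin.lead_sd)
    ac2 = np.zeros(T)
    ac2[1:] = np.diff(v2) / 3.6 / kin.dt_s

    v1 = np.empty(T)
    d = np.empty(T)
    v1_prev, d_prev = v2[0], profile.de
    for t in range(T):
        v1[t] = np.clip(
            v1_prev + kin.speed_gain * (v2[t] - v1_prev) + kin.accel_scale * ac1[t],
            *kin.v1_bounds,
        )
        d[t] = np.clip(
            d_prev
            + kin.gap_gain * (profile.de - d_prev)
            + kin.gap_coupling * (v2[t] - v1[t]) * kin.dt_s / 3.6,
            kin.min_gap,
            kin.max_gap,
        )
        v1_prev, d_prev = v1[t], d[t]

    windows = pd.DataFrame(
        {
            "t_index": np.arange(T),
            "v1": v1,
            "v2": v2,
            "ac1": ac1,
            "ac2": ac2,
            "d": d,
            "dv": v1 - v2,
            "dac": ac1 - ac2,
            "dve": v1 - profile.ve,
            "dde": d - profile.de,
        }
    )
    reports = None
    if spec.pad_target is not None:
        n_minutes = max(1, int(round(T * kin.dt_s / 60.0)))
        reports = gen_pad_reports(spec, n_minutes, rng=rng)
    return Episode(profile.driver_id, spec.condition, windows, intent, reports)


def gen_pad_reports(
    spec: ConditionSpec,
    n_reports: int,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-minute PAD self-reports scattered around the condition's target.

    A fraction ``effective_rate`` of reports lands strictly inside the 0.25
    effectiveness radius (isotropic Gaussian with SD ``pad_noise_sd``,
    rejection-sampled into the ball and the cube); the remainder is displaced
    beyond the radius.
    """
    if n_reports < 1:
        raise ValueError("n_reports must be >= 1")
    if spec.pad_target is None:
        raise ValueError(f"condition {spec.condition!r} has no PAD target")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    target = spec.pad_target
    rows = np.empty((n_reports, 3))
    effective = rng.random(n_reports) < spec.effective_rate
    for i in range(n_reports):
        if effective[i]:
            if spec.pad_noise_sd == 0:
                rows[i] = target
                continue
            while True:
                x = target + rng.normal(0.0, spec.pad_noise_sd, size=3)
                if (
                    np.linalg.norm(x - target) < _pad.EFFECTIVENESS_RADIUS
                    and np.all(np.abs(x) <= 1)
                ):
                    rows[i] = x
                    break
        else:
            sd = max(spec.pad_noise_sd, 0.35)
            while True:
                x = target + rng.normal(0.0, sd, size=3)
                if (
                    np.linalg.norm(x - target) >= _pad.EFFECTIVENESS_RADIUS
                    and np.all(np.abs(x) <= 1)
                ):
                    rows[i] = x
                    break
    return pd.DataFrame(
        {"minute": np.arange(n_reports), "P": rows[:, 0], "A": rows[:, 1], "D": rows[:, 2]}
    )


def gen_dataset(
    profiles: list[DriverProfile],
    specs: dict[str, ConditionSpec],
    n_windows: int = 60,
    rng_seed: int = 0,
    kinematics: KinematicConfig | None = None,
) -> list[Episode]:
    """All driver x condition episodes, each on its own random stream."""
    return [
        gen_episode(p, spec, n_windows, rng_seed, kinematics)
        for spec in specs.values()
        for p in profiles
    ]
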
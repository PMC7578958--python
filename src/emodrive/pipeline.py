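"""End-to-end orchestration: simulate -> preprocess -> train -> analyze.

``run_experiment`` executes the whole study in memory and returns all
intermediate products; the CLI wraps the same stages with on-disk artifacts.
Every stochastic step derives its stream from the configured seed, so a
fixed configuration reproduces identical results.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis, pad, preprocess, synthetic
from .factors import CANDIDATE_VARS, FactorSelector
from .hmm import IntentionHMM, evaluate_accuracy


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study and the analysis."""

    seed: int = 0
    n_drivers: int = 62
    n_windows: int = 60            # 10 min of 10-s windows per run
    window_s: float = 10.0
    ve_range: tuple[float, float] = (58.0, 72.0)
    de_range: tuple[float, float] = (8.0, 14.0)
    conditions: tuple[str, ...] = synthetic.CONDITIONS
    effective_rate: float = 0.8
    pad_noise_sd: float = 0.12
    pad_threshold: float = pad.EFFECTIVENESS_RADIUS
    stickiness: float = synthetic.DEFAULT_STICKINESS
    train_fraction_natural: float = 0.685
    train_fraction_emotion: float = 0.70
    init_mode: str = "supervised"
    smoothing: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    emission_floor: float = 1e-10
    prior_mode: str = "occupancy"
    thresholds: dict = field(
        default_factory=lambda: dict(preprocess.DEFAULT_THRESHOLDS)
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


def simulate(config: PipelineConfig):
    """Driver profiles, condition specs and all episodes."""
    profiles = synthetic.gen_driver_profiles(
        config.n_drivers, config.seed, config.ve_range, config.de_range
    )
    specs = {
        name: spec
        for name, spec in synthetic.default_condition_specs(
            config.stickiness, config.effective_rate, config.pad_noise_sd
        ).items()
        if name in config.conditions
    }
    episodes = synthetic.gen_dataset(profiles, specs, config.n_windows, config.seed)
    return profiles, specs, episodes


def _effective_window_mask(episode, config: PipelineConfig) -> np.ndarray:
    """Per-window keep mask from the per-minute PAD effectiveness filter."""
    n = len(episode.windows)
    if episode.condition == "natural" or episode.pad_reports is None:
        return np.ones(n, dtype=bool)
    records, _ = pad.effectiveness_filter(
        episode.pad_reports[["P", "A", "D"]].to_numpy(),
        episode.condition,
        threshold=config.pad_threshold,
    )
    eff = records["effective"].to_numpy()
    minute = (np.arange(n) * config.window_s // 60).astype(int)
    minute = np.minimum(minute, len(eff) - 1)
    return eff[minute]


def _contiguous_segments(mask: np.ndarray) -> list[slice]:
    runs = []
    start = None
    for i, keep in enumerate(mask):
        if keep and start is None:
            start = i
        elif not keep and start is not None:
            runs.append(slice(start, i))
            start = None
    if start is not None:
        runs.append(slice(start, len(mask)))
    return runs


def episode_sequences(episode, config: PipelineConfig) -> list[dict]:
    """Labeled observation sequences of one episode.

    Emotion runs are cut at ineffective minutes; each contiguous effective
    segment with at least two windows becomes one sequence (intention labels
    are local to a segment, so segmentation never fabricates transitions).
    """
    mask = _effective_window_mask(episode, config)
    levels = preprocess.discretize(episode.windows, config.thresholds)
    out = []
    for seg in _contiguous_segments(mask):
        if seg.stop - seg.start < 2:
            continue
        seg_levels = levels.iloc[seg]
        obs = preprocess.observations_from_levels(seg_levels)
        labels = preprocess.label_intentions(seg_levels["ac1"].to_numpy())
        out.append(
            {
                "driver_id": episode.driver_id,
                "condition": episode.condition,
                "obs": obs[:-1],      # observation at the last window has no label
                "labels": labels,
            }
        )
    return out


def build_sequences(episodes, config: PipelineConfig) -> dict[str, list[dict]]:
    """Sequences grouped by condition."""
    grouped: dict[str, list[dict]] = {}
    for ep in episodes:
        grouped.setdefault(ep.condition, []).extend(episode_sequences(ep, config))
    return grouped


def split_sequences(seqs: list[dict], condition: str, config: PipelineConfig):
    """Seeded per-sequence train/test split for one condition."""
    frac = (
        config.train_fraction_natural
        if condition == "natural"
        else config.train_fraction_emotion
    )
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, zlib.crc32(condition.encode()), 0x5B))
    )
    order = rng.permutation(len(seqs))
    n_train = max(1, int(round(frac * len(seqs))))
    train = [seqs[i] for i in order[:n_train]]
    test = [seqs[i] for i in order[n_train:]]
    return train, test


def train_models(
    sequences: dict[str, list[dict]], config: PipelineConfig
) -> dict[str, dict]:
    """Fit one intention HMM per condition on its training split."""
    out = {}
    for condition, seqs in sequences.items():
        train, test = split_sequences(seqs, condition, config)
        est = IntentionHMM(
            init=config.init_mode,
            smoothing=config.smoothing,
            tol=config.tol,
            max_iter=config.max_iter,
            emission_floor=config.emission_floor,
        )
        est.fit([s["obs"] for s in train], [s["labels"] for s in train])
        est.params_.metadata.update(
            {
                "condition": condition,
                "occupancy": est.occupancy_.tolist(),
                "n_train_sequences": len(train),
                "n_test_sequences": len(test),
                "converged": bool(est.report_.converged) if est.report_ else None,
                "n_iter": est.report_.n_iter if est.report_ else 0,
            }
        )
        out[condition] = {"estimator": est, "train": train, "test": test}
    return out


def evaluate_models(models: dict[str, dict]) -> pd.DataFrame:
    """Held-out per-intention prediction accuracy with 95% CIs."""
    rows = []
    for condition, bundle in models.items():
        est, test = bundle["estimator"], bundle["test"]
        if not test:
            continue
        acc = evaluate_accuracy(
            est.params_, [s["obs"] for s in test], [s["labels"] for s in test]
        )
        for intention, val in acc.items():
            if val is None:
                continue
            rows.append(
                {
                    "condition": condition,
                    "intention": intention,
                    "accuracy": val["accuracy"],
                    "n": val["n"],
                    "ci_low": val["ci"][0],
                    "ci_high": val["ci"][1],
                }
            )
    return pd.DataFrame(rows)


def factor_stage(episodes, config: PipelineConfig) -> FactorSelector:
    """Factor-analyze the eight candidate observables over all windows."""
    frames = [ep.windows[list(CANDIDATE_VARS)] for ep in episodes]
    table = pd.concat(frames, ignore_index=True)
    return FactorSelector(n_factors=3).fit(table)


def driver_probability_tables(
    sequences: dict[str, list[dict]], smoothing: float = 0.5
) -> dict[str, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Per-condition, per-driver occupancy and transition estimates."""
    out: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for condition, seqs in sequences.items():
        by_driver: dict[int, list[np.ndarray]] = {}
        for s in seqs:
            by_driver.setdefault(s["driver_id"], []).append(s["labels"])
        out[condition] = {
            d: analysis.participant_probabilities(labels, smoothing)
            for d, labels in sorted(by_driver.items())
        }
    return out


def emotion_comparison(
    models: dict[str, dict],
    sequences: dict[str, list[dict]],
    config: PipelineConfig,
) -> dict:
    """Change rates and t/F/q significance tests of every emotion vs natural."""
    natural = models["natural"]["estimator"].params_
    emotion_params = {
        c: b["estimator"].params_ for c, b in models.items() if c != "natural"
    }
    gr = analysis.change_rate_table(emotion_params, natural, config.prior_mode)

    tables = driver_probability_tables(sequences)
    drivers = sorted(tables["natural"].keys())
    occ_nat = np.array([tables["natural"][d][0] for d in drivers])
    trans_nat = np.array([tables["natural"][d][1] for d in drivers])

    t_occ_rows, t_trans_rows = [], []
    f_rows, q_frames = [], []
    occ_by_emotion: dict[str, np.ndarray] = {}
    trans_by_emotion: dict[str, np.ndarray] = {}
    for emotion in emotion_params:
        common = [d for d in drivers if d in tables[emotion]]
        occ_em = np.array([tables[emotion][d][0] for d in common])
        trans_em = np.array([tables[emotion][d][1] for d in common])
        occ_by_emotion[emotion] = occ_em
        trans_by_emotion[emotion] = trans_em
        sel = [drivers.index(d) for d in common]
        for i in range(3):
            r = analysis.paired_t_test(occ_nat[sel, i], occ_em[:, i])
            t_occ_rows.append(
                {"comparison": f"Ne-{emotion}", "intention": i + 1,
                 "t": r.statistic, "df": r.df[0], "p": r.p_value, "sig": r.stars}
            )
            for j in range(3):
                a, b = trans_nat[sel, i, j], trans_em[:, i, j]
                ok = ~(np.isnan(a) | np.isnan(b))
                if ok.sum() < 2:
                    continue
                r = analysis.paired_t_test(a[ok], b[ok])
                t_trans_rows.append(
                    {"comparison": f"Ne-{emotion}", "from": i + 1, "to": j + 1,
                     "t": r.statistic, "df": r.df[0], "p": r.p_value, "sig": r.stars}
                )
    emotions = list(emotion_params)
    for i in range(3) if len(emotions) >= 2 else ():
        for j in range(3):
            groups = []
            for e in emotions:
                col = trans_by_emotion[e][:, i, j]
                groups.append(col[~np.isnan(col)])
            if any(g.size < 2 for g in groups):
                continue
            r = analysis.one_way_f_test(groups)
            f_rows.append(
                {"from": i + 1, "to": j + 1, "F": r.statistic,
                 "df1": r.df[0], "df2": r.df[1], "p": r.p_value, "sig": r.stars}
            )
            qt = analysis.q_test(groups, labels=emotions)
            qt.insert(0, "to", j + 1)
            qt.insert(0, "from", i + 1)
            q_frames.append(qt)
    return {
        "change_rates": gr,
        "t_occupancy": pd.DataFrame(t_occ_rows),
        "t_transitions": pd.DataFrame(t_trans_rows),
        "f_transitions": pd.DataFrame(f_rows),
        "q_transitions": (
            pd.concat(q_frames, ignore_index=True) if q_frames else pd.DataFrame()
        ),
    }


def run_experiment(config: PipelineConfig) -> dict:
    """The full in-memory study; returns every stage's products."""
    profiles, specs, episodes = simulate(config)
    sequences = build_sequences(episodes, config)
    models = train_models(sequences, config)
    accuracy = evaluate_models(models)
    comparison = (
        emotion_comparison(models, sequences, config)
        if "natural" in models and len(models) > 1
        else None
    )
    return {
        "config": config,
        "profiles": profiles,
        "specs": specs,
        "episodes": episodes,
        "sequences": sequences,
        "models": models,
        "accuracy": accuracy,
        "comparison": comparison,
    }
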
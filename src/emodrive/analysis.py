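"""Environment states, intention posteriors, change rates and significance tests.

The 27 observation symbols are re-expressed as nine environment states
``Wn = (Sd, Rd)``:

* satisfaction degree ``Sd`` combines how well the current speed and gap
  meet the driver's expectations.  The speed component ``Sd1`` is 0/1/2 for
  expected-speed deviator levels 1/2/3 and the distance component ``Sd2`` is
  0/1/2 for expected-distance deviator levels 3/2/1 (a *large* gap means the
  distance need is unmet).  The component sum maps 0-1 -> Sd 1 (low
  satisfaction), 2 -> Sd 2, 3-4 -> Sd 3 (over-met).
* risk degree ``Rd`` is 4 minus the gap level: the shortest-gap class is the
  riskiest (Rd 3).

Per environment state, the intention distribution follows from Bayes:
``P(q_i | O) = P(q_i) b_i(O) / sum_j P(q_j) b_j(O)`` per member symbol,
mixed over the three symbols of the state with weights ``P(O)``.  The
change rate of intention i under emotion j in state n is

    Gr = (P(Int_i | W_n, Em_j) - P(Int_i | W_n)) / P(Int_i | W_n) * 100%.

Emotion-vs-natural comparisons use paired t-tests over per-driver estimates
(one merged sample per driver), a one-way F-test across the eight emotions,
and studentized-range (Tukey HSD) pairwise q-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import HMMParams
from .preprocess import decode_observation

#: significance bands and their star convention
STAR_LEVELS: tuple[tuple[float, str], ...] = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "-"


@dataclass
class TestResult:
    statistic: float
    df: tuple
    p_value: float
    stars: str
    flag: str | None = None


# ---------------------------------------------------------------------------
# environment-state construction


def sd_components(dve_level: int, dde_level: int) -> tuple[int, int]:
    """(Sd1, Sd2) from the expected-speed and expected-distance levels."""
    if dve_level not in (1, 2, 3) or dde_level not in (1, 2, 3):
        raise ValueError("levels must lie in 1..3")
    return dve_level - 1, 3 - dde_level


def sd_from_components(sd1: int, sd2: int) -> int:
    """Satisfaction degree from its components: sum 0-1 -> 1, 2 -> 2, 3-4 -> 3."""
    if sd1 not in (0, 1, 2) or sd2 not in (0, 1, 2):
        raise ValueError("components must lie in 0..2")
    total = sd1 + sd2
    return 1 if total <= 1 else (2 if total == 2 else 3)


def rd_from_level(d_level: int) -> int:
    """Risk degree: gap levels 1/2/3 map to Rd 3/2/1."""
    if d_level not in (1, 2, 3):
        raise ValueError("gap level must lie in 1..3")
    return 4 - d_level


def environment_state(symbol: int) -> tuple[int, int, int]:
    """(Sd, Rd, n) of an observation symbol; n = (Sd - 1) * 3 + Rd in 1..9."""
    dde, d, dve = decode_observation(symbol)
    sd = sd_from_components(*sd_components(int(dve), int(dde)))
    rd = rd_from_level(int(d))
    return sd, rd, (sd - 1) * 3 + rd


def symbol_environment_table() -> pd.DataFrame:
    """All 27 symbols with their levels and environment state."""
    rows = []
    for o in range(1, 28):
        dde, d, dve = (int(x) for x in decode_observation(o))
        sd, rd, n = environment_state(o)
        rows.append({"symbol": o, "dde": dde, "d": d, "dve": dve,
                     "Sd": sd, "Rd": rd, "Wn": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posteriors and change rates


def bayes_posterior(prior, B, symbol: int) -> np.ndarray:
    """P(intention | observation symbol) by Bayes' rule."""
    prior = np.asarray(prior, dtype=float)
    B = np.asarray(B, dtype=float)
    col = B[:, int(symbol) - 1]
    num = prior * col
    z = num.sum()
    if z <= 0:
        raise ValueError(f"symbol {symbol} has zero probability under the model")
    return num / z


def environment_posterior(prior, B, wn: int) -> np.ndarray:
    """P(intention | Wn): member-symbol posteriors mixed by symbol mass P(O)."""
    if not 1 <= int(wn) <= 9:
        raise ValueError("environment state index must lie in 1..9")
    prior = np.asarray(prior, dtype=float)
    B = np.asarray(B, dtype=float)
    members = [o for o in range(1, 28) if environment_state(o)[2] == int(wn)]
    weights = np.array([float(prior @ B[:, o - 1]) for o in members])
    if weights.sum() <= 0:
        raise ValueError(f"all symbols of W{wn} are unobservable under the model")
    mix = np.zeros(prior.shape)
    for o, w in zip(members, weights):
        if w > 0:
            mix += w * bayes_posterior(prior, B, o)
    return mix / weights.sum()


def change_rate(p_emotion: float, p_natural: float) -> float:
    """Percent change of an intention probability relative to the natural state."""
    if p_natural == 0:
        return float("nan")
    return (p_emotion - p_natural) / p_natural * 100.0


def model_prior(params: HMMParams, mode: str = "occupancy") -> np.ndarray:
    """The P(q_i) used in the Bayes posterior.

    ``occupancy`` (default) uses the expected time-averaged state occupancy
    recorded at training time (falling back to the stationary distribution of
    A); ``pi`` uses the initial-state distribution.
    """
    if mode == "pi":
        return params.pi
    if mode == "occupancy":
        occ = params.metadata.get("occupancy")
        if occ is not None:
            return np.asarray(occ, dtype=float)
        return params.stationary_distribution()
    raise ValueError(f"unknown prior mode {mode!r}")


def change_rate_table(
    emotion_models: dict[str, HMMParams],
    natural_model: HMMParams,
    prior_mode: str = "occupancy",
) -> pd.DataFrame:
    """Long-format Gr (%) per emotion x environment state x intention."""
    p_nat = {
        wn: environment_posterior(model_prior(natural_model, prior_mode),
                                  natural_model.B, wn)
        for wn in range(1, 10)
    }
    rows = []
    for emotion, model in emotion_models.items():
        prior = model_prior(model, prior_mode)
        for wn in range(1, 10):
            pe = environment_posterior(prior, model.B, wn)
            sd, rd = (wn - 1) // 3 + 1, (wn - 1) % 3 + 1
            for i in range(3):
                rows.append(
                    {
                        "emotion": emotion,
                        "Wn": wn,
                        "Sd": sd,
                        "Rd": rd,
                        "intention": i + 1,
                        "p_emotion": float(pe[i]),
                        "p_natural": float(p_nat[wn][i]),
                        "Gr": change_rate(float(pe[i]), float(p_nat[wn][i])),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-driver estimates and significance tests


def participant_probabilities(
    label_seqs: list[np.ndarray], smoothing: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """One driver's intention occupancy (3,) and transition table (3, 3).

    ``label_seqs`` are the driver's labeled sequences (actual and virtual
    runs merged as one sample).  Rows of the transition table sum to 1;
    ``smoothing`` adds pseudo-counts.
    """
    occ = np.full(3, smoothing, dtype=float)
    trans = np.full((3, 3), smoothing, dtype=float)
    n_trans = 0
    for seq in label_seqs:
        s = np.asarray(seq, dtype=np.int64) - 1
        if s.size == 0:
            continue
        occ += np.bincount(s, minlength=3)
        if s.size > 1:
            np.add.at(trans, (s[:-1], s[1:]), 1.0)
            n_trans += s.size - 1
    if occ.sum() == 0:
        raise ValueError("driver has no labeled windows")
    if n_trans == 0 and smoothing == 0:
        raise ValueError("driver has no labeled transitions")
    row_sums = trans.sum(axis=1, keepdims=True)
    trans = np.divide(trans, row_sums, out=np.full_like(trans, np.nan),
                      where=row_sums > 0)
    return occ / occ.sum(), trans


def paired_t_test(sample_a, sample_b) -> TestResult:
    """Two-sided paired t-test; df = n - 1."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("samples must be 1-D, equal-length, n >= 2")
    diff = a - b
    if np.all(diff == 0):
        return TestResult(0.0, (a.size - 1,), 1.0, "-")
    if np.std(diff, ddof=1) == 0:
        return TestResult(float("inf") * np.sign(diff.mean()), (a.size - 1,),
                          0.0, "***", flag="zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), (a.size - 1,), float(p), significance_stars(float(p)))


def one_way_f_test(groups) -> TestResult:
    """One-way ANOVA across groups; df = (k - 1, N - k)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    if all(np.std(g, ddof=1) == 0 for g in gs):
        return TestResult(float("nan"), (k - 1, n_total - k), float("nan"),
                          "-", flag="zero within-group variance")
    f, p = stats.f_oneway(*gs)
    return TestResult(float(f), (k - 1, n_total - k), float(p),
                      significance_stars(float(p)))


def q_test(groups, labels=None) -> pd.DataFrame:
    """Pairwise studentized-range (Tukey HSD) comparisons.

    q = |mean_i - mean_j| / sqrt(MSW / 2 * (1/n_i + 1/n_j)) with the pooled
    within-group mean square; p-values from the studentized-range
    distribution with (k, N - k) parameters.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    k = len(gs)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    n_total = sum(g.size for g in gs)
    df_w = n_total - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    msw = ssw / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(gs[i].mean() - gs[j].mean())
            if msw == 0:
                q = float("inf") if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            else:
                se = np.sqrt(msw / 2 * (1 / gs[i].size + 1 / gs[j].size))
                q = diff / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "q": float(q),
                    "df": df_w,
                    "p_value": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
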
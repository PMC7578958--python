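"""Discrete hidden Markov model over driving intentions.

The latent state is the driving intention (decelerate / keep speed /
accelerate, N = 3); the emission alphabet is the 27 discretized environment
symbols.  The model is the classic lambda = (pi, A, B): initial state
distribution, state transition matrix and emission matrix.  Training is
expectation-maximization (Baum-Welch) over multiple independent sequences
with per-step scaling; because behaviour-derived intention labels exist, a
supervised relative-frequency initializer is provided and is the default
starting point for EM.

Prediction is one-step: given the current intention ``i`` and the next
window's observation ``o``, the next intention is ``argmax_j a_ij b_j(o)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

N_INTENTIONS = 3
N_SYMBOLS = 27

_ATOL = 1e-9


def _check_stochastic(name: str, m: np.ndarray, axis: int = -1) -> None:
    if np.any(m < 0):
        raise ValueError(f"{name} has negative entries")
    s = m.sum(axis=axis)
    if not np.allclose(s, 1.0, atol=_ATOL):
        raise ValueError(f"{name} rows must sum to 1 (got {s})")


@dataclass
class HMMParams:
    """lambda = (pi, A, B) for N intentions over M observation symbols."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.pi.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A shape inconsistent with pi")
        if self.B.ndim != 2 or self.B.shape[0] != n:
            raise ValueError("B shape inconsistent with pi")
        _check_stochastic("pi", self.pi)
        _check_stochastic("A", self.A)
        _check_stochastic("B", self.B)

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of A, normalized to a distribution."""
        w, v = np.linalg.eig(self.A.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, k])
        p = np.abs(p)
        return p / p.sum()

    def to_json(self) -> str:
        payload = {
            "n_states": self.n_states,
            "n_symbols": self.n_symbols,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        payload = json.loads(text)
        return cls(
            pi=np.array(payload["pi"]),
            A=np.array(payload["A"]),
            B=np.array(payload["B"]),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class TrainingReport:
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    #: expected time-averaged state occupancy under the fitted model
    state_occupancy: np.ndarray | None = None


def _as_index_array(obs: Sequence[int], n_symbols: int) -> np.ndarray:
    o = np.asarray(obs, dtype=np.int64)
    if o.ndim != 1 or o.size == 0:
        raise ValueError("observation sequence must be non-empty and 1-D")
    if np.any((o < 1) | (o > n_symbols)):
        raise ValueError(f"observation symbols must lie in 1..{n_symbols}")
    return o - 1


def _batch_forward(pi, A, B, obs0):
    """Scaled forward pass over a batch of equal-length sequences.

    obs0 : (S, T) 0-based symbol indices.
    Returns (alpha_hat (S, T, N), log_c (S, T)) where alpha_hat is the
    per-step normalized forward variable and log_c the log normalizers, so
    log P(Y|lambda) per sequence is ``log_c.sum(axis=1)``.
    """
    S, T = obs0.shape
    N = pi.shape[0]
    alpha = np.empty((S, T, N))
    logc = np.empty((S, T))
    a = pi[None, :] * B[:, obs0[:, 0]].T
    for t in range(T):
        if t > 0:
            a = (alpha[:, t - 1] @ A) * B[:, obs0[:, t]].T
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise FloatingPointError(
                f"forward recursion underflow at step {t}: an observed symbol "
                "has zero probability under every state"
            )
        alpha[:, t] = a / c[:, None]
        logc[:, t] = np.log(c)
    return alpha, logc


def _batch_backward(A, B, obs0, logc):
    """Scaled backward pass matching :func:`_batch_forward`'s normalizers."""
    S, T = obs0.shape
    N = A.shape[0]
    beta = np.empty((S, T, N))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = (beta[:, t + 1] * B[:, obs0[:, t + 1]].T) @ A.T
        beta[:, t] = b / np.exp(logc[:, t + 1])[:, None]
    return beta


def forward_loglik(params: HMMParams, obs: Sequence[int]) -> float:
    """log P(Y | lambda) of one observation sequence via scaled forward."""
    o = _as_index_array(obs, params.n_symbols)
    _, logc = _batch_forward(params.pi, params.A, params.B, o[None, :])
    return float(logc.sum())


def supervised_init(
    obs_seqs: Iterable[Sequence[int]],
    label_seqs: Iterable[Sequence[int]],
    smoothing: float = 1.0,
    n_states: int = N_INTENTIONS,
    n_symbols: int = N_SYMBOLS,
) -> HMMParams:
    """Relative-frequency estimate of (pi, A, B) from labeled sequences.

    ``label_seqs`` carry intentions 1..N aligned with ``obs_seqs`` (both of
    the same length per sequence).  ``smoothing`` is a pseudo-count added to
    every cell before normalizing.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    pi_c = np.full(n_states, smoothing, dtype=float)
    A_c = np.full((n_states, n_states), smoothing, dtype=float)
    B_c = np.full((n_states, n_symbols), smoothing, dtype=float)
    occ = np.zeros(n_states)
    n_seen = 0
    for obs, labels in zip(obs_seqs, label_seqs):
        o = _as_index_array(obs, n_symbols)
        s = np.asarray(labels, dtype=np.int64)
        if s.shape != o.shape:
            raise ValueError("labels and observations must align per sequence")
        if np.any((s < 1) | (s > n_states)):
            raise ValueError(f"intention labels must lie in 1..{n_states}")
        s0 = s - 1
        pi_c[s0[0]] += 1.0
        np.add.at(A_c, (s0[:-1], s0[1:]), 1.0)
        np.add.at(B_c, (s0, o), 1.0)
        occ += np.bincount(s0, minlength=n_states)
        n_seen += 1
    if n_seen == 0:
        raise ValueError("no labeled sequences supplied")

    def _rows(counts: np.ndarray) -> np.ndarray:
        # a state never observed gets a uniform row (no evidence either way)
        sums = counts.sum(axis=1, keepdims=True)
        uniform = np.full_like(counts, 1.0 / counts.shape[1])
        return np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), uniform)

    params = HMMParams(pi=pi_c / pi_c.sum(), A=_rows(A_c), B=_rows(B_c))
    params.metadata["label_occupancy"] = (occ / occ.sum()).tolist()
    return params


def _group_by_length(seqs: list[np.ndarray]) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(s.size, []).append(i)
    return {
        T: (np.array(ix), np.stack([seqs[i] for i in ix]))
        for T, ix in groups.items()
    }


def baum_welch(
    init: HMMParams,
    obs_seqs: Iterable[Sequence[int]],
    tol: float = 1e-6,
    max_iter: int = 500,
    emission_floor: float = 1e-10,
) -> tuple[HMMParams, TrainingReport]:
    """Multi-sequence EM re-estimation of lambda.

    Sequences are treated as independent; expected counts (gamma/xi) are
    accumulated over all of them per iteration.  Convergence is a relative
    total log-likelihood change below ``tol``.  After each M-step the
    emission matrix is floored at ``emission_floor`` and renormalized so
    unseen symbols stay predictable.
    """
    seqs = [_as_index_array(o, init.n_symbols) for o in obs_seqs]
    if not seqs:
        raise ValueError("no observation sequences supplied")
    batches = _group_by_length(seqs)
    pi, A, B = init.pi.copy(), init.A.copy(), init.B.copy()
    N, M = init.n_states, init.n_symbols
    trace: list[float] = []
    converged = False
    occupancy = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pi_acc = np.zeros(N)
        A_num = np.zeros((N, N))
        B_num = np.zeros((N, M))
        occ_acc = np.zeros(N)
        total_ll = 0.0
        n_windows = 0
        for _, obs0 in batches.values():
            S, T = obs0.shape
            alpha, logc = _batch_forward(pi, A, B, obs0)
            beta = _batch_backward(A, B, obs0, logc)
            total_ll += float(logc.sum())
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            pi_acc += gamma[:, 0].sum(axis=0)
            occ_acc += gamma.sum(axis=(0, 1))
            n_windows += S * T
            # expected emission counts
            for t in range(T):
                np.add.at(B_num, (slice(None), obs0[:, t]), gamma[:, t].T)
            if T > 1:
                # xi_t(i,j) = alpha_hat_t(i) a_ij b_j(o_{t+1}) beta_hat_{t+1}(j) / c_{t+1}
                emis = B[:, obs0[:, 1:].ravel()].T.reshape(S, T - 1, N)
                w = emis * beta[:, 1:] / np.exp(logc[:, 1:])[:, :, None]
                A_num += A * (
                    alpha[:, :-1].reshape(-1, N).T @ w.reshape(-1, N)
                )
        trace.append(total_ll)
        if len(trace) > 1:
            prev = trace[-2]
            denom = max(abs(prev), 1.0)
            if (total_ll - prev) / denom < tol:
                converged = True
                occupancy = occ_acc / occ_acc.sum()
                break
        # M-step
        pi = pi_acc / pi_acc.sum()
        A = A_num / A_num.sum(axis=1, keepdims=True)
        B = np.maximum(B_num, emission_floor)
        B /= B.sum(axis=1, keepdims=True)
        occupancy = occ_acc / occ_acc.sum()
    params = HMMParams(pi=pi, A=A, B=B)
    report = TrainingReport(trace, n_iter, converged, occupancy)
    return params, report


def predict_next_intention(
    params: HMMParams, current_intention: int, next_obs: int
) -> tuple[int, np.ndarray]:
    """One-step intention prediction.

    Given the intention ``i`` held now and the observation symbol of the next
    window, the predicted next intention is ``argmax_j a_ij b_j(o)``; ties
    break toward the lower intention index.  Returns the 1-based intention
    and the normalized weight vector.  If every candidate weight is zero the
    transition row alone decides (with a degenerate, unnormalized posterior).
    """
    if not 1 <= current_intention <= params.n_states:
        raise ValueError("current intention outside 1..N")
    o = int(_as_index_array([next_obs], params.n_symbols)[0])
    w = params.A[current_intention - 1] * params.B[:, o]
    z = w.sum()
    if z > 0:
        w = w / z
    else:
        w = params.A[current_intention - 1].copy()
    return int(np.argmax(w)) + 1, w


def evaluate_accuracy(
    params: HMMParams,
    obs_seqs: Iterable[Sequence[int]],
    label_seqs: Iterable[Sequence[int]],
    z: float = 1.959963984540054,
) -> dict:
    """Per-intention one-step prediction accuracy with normal-approximation CI.

    For every position t >= 1 of each held-out sequence, the intention at t is
    predicted from the true intention at t-1 and the observation at t, and
    scored against the true label at t.  Accuracy is grouped by the true
    label; the CI is p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), clamped to
    [0, 1].  Classes never seen in the held-out data are reported absent.
    """
    correct = np.zeros(params.n_states, dtype=np.int64)
    attempted = np.zeros(params.n_states, dtype=np.int64)
    for obs, labels in zip(obs_seqs, label_seqs):
        o = _as_index_array(obs, params.n_symbols)
        s = np.asarray(labels, dtype=np.int64)
        if s.shape != o.shape:
            raise ValueError("labels and observations must align per sequence")
        for t in range(1, o.size):
            pred, _ = predict_next_intention(params, int(s[t - 1]), int(o[t]) + 1)
            attempted[s[t] - 1] += 1
            correct[s[t] - 1] += pred == s[t]
    out = {}
    for i in range(params.n_states):
        if attempted[i] == 0:
            out[i + 1] = None
            continue
        p = correct[i] / attempted[i]
        half = z * np.sqrt(p * (1 - p) / attempted[i])
        out[i + 1] = {
            "accuracy": float(p),
            "n": int(attempted[i]),
            "ci": (float(max(0.0, p - half)), float(min(1.0, p + half))),
        }
    return out


def sample_sequences(
    params: HMMParams, n_sequences: int, length: int, rng
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Draw (observations, states) sequence pairs from lambda; 1-based symbols."""
    if n_sequences < 1 or length < 1:
        raise ValueError("need at least one sequence of length >= 1")
    rng = np.random.default_rng(rng)
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    cum_B = np.cumsum(params.B, axis=1)
    states = np.empty((n_sequences, length), dtype=np.int64)
    states[:, 0] = np.searchsorted(cum_pi, rng.random(n_sequences), side="right")
    for t in range(1, length):
        u = rng.random(n_sequences)
        states[:, t] = (u[:, None] >= cum_A[states[:, t - 1]]).sum(axis=1)
    u = rng.random((n_sequences, length))
    obs = (u[:, :, None] >= cum_B[states]).sum(axis=2)
    states = np.minimum(states, params.n_states - 1)
    obs = np.minimum(obs, params.n_symbols - 1)
    return [o + 1 for o in obs], [s + 1 for s in states]


class IntentionHMM:
    """Scikit-learn style estimator wrapping supervised init + Baum-Welch.

    Parameters
    ----------
    n_states, n_symbols : alphabet sizes (3 intentions, 27 symbols).
    init : {"supervised+em", "supervised", "em"}
        Training mode.  "supervised" skips EM refinement; "em" starts from a
        seeded random stochastic initialization and needs no labels.
    smoothing : pseudo-count for the supervised initializer.
    tol, max_iter : EM stopping rule (relative log-likelihood change).
    emission_floor : post-M-step floor on emission probabilities.
    random_state : seed for the "em" initializer.

    Attributes (after fit)
    ----------------------
    params_ : HMMParams
    report_ : TrainingReport (None in pure supervised mode)
    occupancy_ : expected intention occupancy used as the Bayes prior
    """

    def __init__(
        self,
        n_states: int = N_INTENTIONS,
        n_symbols: int = N_SYMBOLS,
        init: str = "supervised+em",
        smoothing: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        emission_floor: float = 1e-10,
        random_state: int | None = 0,
    ):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.init = init
        self.smoothing = smoothing
        self.tol = tol
        self.max_iter = max_iter
        self.emission_floor = emission_floor
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_states", "n_symbols", "init", "smoothing", "tol",
                "max_iter", "emission_floor", "random_state",
            )
        }

    def set_params(self, **kwargs) -> "IntentionHMM":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _random_init(self) -> HMMParams:
        rng = np.random.default_rng(self.random_state)
        pi = rng.dirichlet(np.ones(self.n_states))
        A = rng.dirichlet(np.ones(self.n_states), size=self.n_states)
        B = rng.dirichlet(np.ones(self.n_symbols), size=self.n_states)
        return HMMParams(pi=pi, A=A, B=B)

    def fit(self, X: Iterable[Sequence[int]], y: Iterable[Sequence[int]] | None = None):
        """Fit from observation sequences ``X`` and aligned label sequences ``y``."""
        X = [np.asarray(x, dtype=np.int64) for x in X]
        if self.init in ("supervised+em", "supervised"):
            if y is None:
                raise ValueError(f"init={self.init!r} requires label sequences")
            y = [np.asarray(s, dtype=np.int64) for s in y]
            start = supervised_init(
                X, y, self.smoothing, self.n_states, self.n_symbols
            )
        elif self.init == "em":
            start = self._random_init()
        else:
            raise ValueError(f"unknown init mode {self.init!r}")
        if self.init == "supervised":
            self.params_, self.report_ = start, None
            occ = start.metadata.get("label_occupancy")
            self.occupancy_ = np.asarray(occ, dtype=float)
        else:
            self.params_, self.report_ = baum_welch(
                start, X, self.tol, self.max_iter, self.emission_floor
            )
            self.occupancy_ = np.asarray(self.report_.state_occupancy, dtype=float)
        return self

    def predict(self, current_intentions, next_observations) -> np.ndarray:
        """Vector of one-step predictions (1-based intentions)."""
        self._check_fitted()
        return np.array(
            [
                predict_next_intention(self.params_, int(i), int(o))[0]
                for i, o in zip(current_intentions, next_observations)
            ],
            dtype=np.int64,
        )

    def score(self, X: Iterable[Sequence[int]]) -> float:
        """Total log-likelihood of held-out observation sequences."""
        self._check_fitted()
        return float(sum(forward_loglik(self.params_, x) for x in X))

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("IntentionHMM instance is not fitted yet")
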
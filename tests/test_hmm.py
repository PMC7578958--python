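import itertools

import numpy as np
import pytest

from emodrive.hmm import (
    HMMParams,
    IntentionHMM,
    baum_welch,
    evaluate_accuracy,
    forward_loglik,
    predict_next_intention,
    sample_sequences,
    supervised_init,
)
from conftest import random_hmm


def enumerate_loglik(params: HMMParams, obs) -> float:
    """Brute-force P(Y|lambda): sum over all N^T hidden-state paths."""
    o = np.asarray(obs) - 1
    total = 0.0
    for path in itertools.product(range(params.n_states), repeat=o.size):
        p = params.pi[path[0]] * params.B[path[0], o[0]]
        for t in range(1, o.size):
            p *= params.A[path[t - 1], path[t]] * params.B[path[t], o[t]]
        total += p
    return float(np.log(total))


def test_forward_single_step_known_value():
    params = HMMParams(
        pi=[1.0, 0.0, 0.0],
        A=np.full((3, 3), 1 / 3),
        B=np.column_stack([[0.5, 0.1, 0.2], [0.5, 0.9, 0.8]]),
    )
    assert forward_loglik(params, [1]) == pytest.approx(np.log(0.5))


def test_forward_uniform_model_closed_form(rng):
    M = 27
    params = HMMParams(
        pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3), B=np.full((3, M), 1 / M)
    )
    obs = rng.integers(1, M + 1, size=13)
    assert forward_loglik(params, obs) == pytest.approx(13 * np.log(1 / M))


def test_forward_matches_path_enumeration(rng):
    for _ in range(20):
        params = random_hmm(rng, n_symbols=5)
        T = int(rng.integers(2, 7))
        obs = rng.integers(1, 6, size=T)
        got = forward_loglik(params, obs)
        want = enumerate_loglik(params, obs)
        assert got == pytest.approx(want, rel=1e-10)


def test_forward_matches_hmmlearn(rng):
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    params = random_hmm(rng)
    ref = hmmlearn.CategoricalHMM(n_components=3, n_features=27, init_params="")
    ref.startprob_, ref.transmat_, ref.emissionprob_ = params.pi, params.A, params.B
    obs = rng.integers(1, 28, size=40)
    assert forward_loglik(params, obs) == pytest.approx(
        float(ref.score((obs - 1).reshape(-1, 1))), rel=1e-10
    )


def test_forward_rejects_bad_symbols(rng):
    params = random_hmm(rng)
    with pytest.raises(ValueError):
        forward_loglik(params, [0])
    with pytest.raises(ValueError):
        forward_loglik(params, [])


def test_supervised_init_single_transition():
    params = supervised_init([[5, 7]], [[1, 1]], smoothing=0.0)
    assert np.allclose(params.A[0], [1, 0, 0])
    assert np.allclose(params.pi, [1, 0, 0])


def test_supervised_init_smoothing_strictly_positive():
    params = supervised_init([[5, 7]], [[1, 1]], smoothing=0.5)
    assert np.all(params.pi > 0)
    assert np.all(params.A > 0)
    assert np.all(params.B > 0)


def test_supervised_init_pi_recovery_binomial(rng):
    pi = np.array([0.2, 0.5, 0.3])
    n = 10_000
    first = rng.choice(3, size=n, p=pi) + 1
    seqs = [[1, 1]] * n
    labels = [[int(f), 2] for f in first]
    params = supervised_init(seqs, labels, smoothing=0.0)
    se = np.sqrt(pi * (1 - pi) / n)
    assert np.all(np.abs(params.pi - pi) < 3 * se)


def _bw_invariants(params: HMMParams):
    assert np.isclose(params.pi.sum(), 1, atol=1e-9)
    assert np.allclose(params.A.sum(axis=1), 1, atol=1e-9)
    assert np.allclose(params.B.sum(axis=1), 1, atol=1e-9)
    assert np.all(params.pi >= 0) and np.all(params.A >= 0) and np.all(params.B >= 0)


def test_baum_welch_loglik_monotone_and_invariants(rng):
    """EM never decreases the total log-likelihood; outputs stay stochastic."""
    for seed in range(10):
        r = np.random.default_rng(seed)
        truth = random_hmm(r, n_symbols=8)
        obs, _ = sample_sequences(truth, 12, 30, r)
        init = random_hmm(r, n_symbols=8)
        fitted, report = baum_welch(init, obs, tol=1e-8, max_iter=40)
        trace = np.asarray(report.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))
        _bw_invariants(fitted)


def test_baum_welch_intermediate_iterates_stochastic(rng, separated):
    obs, _ = sample_sequences(separated, 10, 25, rng)
    for max_iter in (1, 3, 10):
        fitted, _ = baum_welch(random_hmm(np.random.default_rng(4)), obs,
                               tol=0.0, max_iter=max_iter)
        _bw_invariants(fitted)


def test_baum_welch_fixed_point_stable(rng, separated):
    obs, _ = sample_sequences(separated, 30, 40, rng)
    converged, _ = baum_welch(separated, obs, tol=1e-10, max_iter=300)
    again, report = baum_welch(converged, obs, tol=1e-10, max_iter=1)
    assert np.max(np.abs(again.A - converged.A)) < 1e-3
    assert np.max(np.abs(again.pi - converged.pi)) < 1e-3


def test_baum_welch_recovers_known_model(separated):
    """Supervised init + EM recover A from data simulated by a separated model."""
    obs, states = sample_sequences(separated, 600, 50, np.random.default_rng(0))
    init = supervised_init(obs, states, smoothing=1.0)
    fitted, report = baum_welch(init, obs, tol=1e-6, max_iter=200)
    assert np.max(np.abs(fitted.A - separated.A)) < 0.05
    assert report.converged


def test_recovery_error_decreases_with_data(separated):
    def err(n_seq, seed):
        obs, states = sample_sequences(separated, n_seq, 50, np.random.default_rng(seed))
        init = supervised_init(obs, states, smoothing=1.0)
        fitted, _ = baum_welch(init, obs, tol=1e-6, max_iter=100)
        return np.mean(np.abs(fitted.A - separated.A))

    seeds = range(5)
    small = np.mean([err(500, s) for s in seeds])
    large = np.mean([err(5000, s) for s in seeds])
    assert large <= small


def test_predict_identity_transitions_keep_intention(rng):
    params = HMMParams(pi=[1 / 3] * 3, A=np.eye(3), B=random_hmm(rng).B)
    for i in (1, 2, 3):
        pred, w = predict_next_intention(params, i, 14)
        assert pred == i
        assert w.sum() == pytest.approx(1.0)


def test_predict_uniform_transitions_follow_emissions(rng):
    B = random_hmm(rng).B
    params = HMMParams(pi=[1 / 3] * 3, A=np.full((3, 3), 1 / 3), B=B)
    for o in (1, 9, 27):
        pred, _ = predict_next_intention(params, 2, o)
        assert pred == int(np.argmax(B[:, o - 1])) + 1


def test_predict_matches_hand_computed_table():
    A = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.4, 0.5]])
    B = np.zeros((3, 27))
    B[:, 0] = [0.1, 0.3, 0.6]
    B[:, 1:] = (1 - B[:, 0])[:, None] / 26
    params = HMMParams(pi=[1 / 3] * 3, A=A, B=B)
    # from intention 1 on symbol 1: weights (0.6*0.1, 0.3*0.3, 0.1*0.6)
    pred, w = predict_next_intention(params, 1, 1)
    hand = np.array([0.06, 0.09, 0.06])
    assert np.allclose(w, hand / hand.sum())
    assert pred == 2


def test_predict_ties_break_to_lower_intention():
    params = HMMParams(pi=[1 / 3] * 3, A=np.full((3, 3), 1 / 3),
                       B=np.full((3, 27), 1 / 27))
    pred, _ = predict_next_intention(params, 3, 5)
    assert pred == 1


def test_accuracy_all_correct_clamps_ci():
    params = HMMParams(pi=[1 / 3] * 3, A=np.eye(3), B=np.full((3, 27), 1 / 27))
    seqs = [[1, 1]] * 50
    labels = [[2, 2]] * 50
    out = evaluate_accuracy(params, seqs, labels)
    assert out[2]["accuracy"] == 1.0
    assert out[2]["ci"][1] == 1.0
    assert out[1] is None and out[3] is None


def test_accuracy_half_correct_closed_form_ci():
    """p_hat = 0.5 at n = 100 gives the textbook CI (0.402, 0.598)."""
    params = HMMParams(pi=[1 / 3] * 3, A=np.eye(3), B=np.full((3, 27), 1 / 27))
    seqs = [[1, 1]] * 100
    labels = [[1, 1]] * 50 + [[2, 1]] * 50  # identity A predicts the previous label
    out = evaluate_accuracy(params, seqs, labels)
    assert out[1]["accuracy"] == pytest.approx(0.5)
    assert out[1]["n"] == 100
    assert out[1]["ci"][0] == pytest.approx(0.402, abs=5e-4)
    assert out[1]["ci"][1] == pytest.approx(0.598, abs=5e-4)


def test_accuracy_beats_chance_on_separated_model(separated, rng):
    obs, states = sample_sequences(separated, 200, 40, rng)
    init = supervised_init(obs, states, smoothing=1.0)
    out = evaluate_accuracy(init, obs, states)
    for i in (1, 2, 3):
        assert out[i]["accuracy"] > 0.60


def test_params_json_roundtrip_bit_exact(rng):
    params = random_hmm(rng)
    params.metadata["condition"] = "anger"
    clone = HMMParams.from_json(params.to_json())
    assert np.array_equal(params.pi, clone.pi)
    assert np.array_equal(params.A, clone.A)
    assert np.array_equal(params.B, clone.B)
    assert clone.metadata["condition"] == "anger"


def test_params_validation_rejects_bad_rows():
    with pytest.raises(ValueError):
        HMMParams(pi=[0.5, 0.5, 0.1], A=np.eye(3), B=np.full((3, 27), 1 / 27))
    with pytest.raises(ValueError):
        HMMParams(pi=[1, 0, 0], A=np.eye(3) * 0.9, B=np.full((3, 27), 1 / 27))


def test_estimator_api_fit_predict_and_params(separated, rng):
    obs, states = sample_sequences(separated, 50, 30, rng)
    est = IntentionHMM(init="supervised", smoothing=1.0)
    assert est.get_params()["init"] == "supervised"
    est.set_params(smoothing=0.5)
    est.fit(obs, states)
    assert est.occupancy_.shape == (3,)
    preds = est.predict([1, 2, 3], [1, 10, 20])
    assert preds.shape == (3,)
    assert set(preds) <= {1, 2, 3}
    assert np.isfinite(est.score(obs[:5]))
    with pytest.raises(ValueError):
        est.set_params(bogus=1)
    with pytest.raises(ValueError):
        IntentionHMM(init="supervised").fit(obs)  # labels required


def test_estimator_em_mode_needs_no_labels(separated, rng):
    obs, _ = sample_sequences(separated, 20, 25, rng)
    est = IntentionHMM(init="em", max_iter=15, random_state=1).fit(obs)
    _bw_invariants(est.params_)


def test_estimator_sklearn_clone_compatible():
    sklearn_base = pytest.importorskip("sklearn.base")
    est = IntentionHMM(smoothing=0.25, max_iter=7)
    clone = sklearn_base.clone(est)
    assert clone.get_params() == est.get_params()
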
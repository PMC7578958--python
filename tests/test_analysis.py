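import itertools

import numpy as np
import pytest
from scipy import stats

from emodrive.analysis import (
    bayes_posterior,
    change_rate,
    environment_posterior,
    environment_state,
    one_way_f_test,
    paired_t_test,
    participant_probabilities,
    q_test,
    rd_from_level,
    sd_components,
    sd_from_components,
    significance_stars,
    symbol_environment_table,
)
from emodrive.hmm import HMMParams
from emodrive.preprocess import encode_observation

# satisfaction-degree truth table: speed component 0/1/2 for dve levels 1/2/3,
# distance component 0/1/2 for dde levels 3/2/1, sum mapped 0-1/2/3-4 -> 1/2/3
SD_TRUTH = {
    (1, 3): 1, (1, 2): 1, (1, 1): 2,
    (2, 3): 1, (2, 2): 2, (2, 1): 3,
    (3, 3): 2, (3, 2): 3, (3, 1): 3,
}


@pytest.mark.parametrize("dve,dde", list(itertools.product((1, 2, 3), repeat=2)))
def test_sd_rules_exhaustive(dve, dde):
    sd1, sd2 = sd_components(dve, dde)
    assert sd1 == dve - 1
    assert sd2 == {3: 0, 2: 1, 1: 2}[dde]
    assert sd_from_components(sd1, sd2) == SD_TRUTH[(dve, dde)]


@pytest.mark.parametrize("d_level,rd", [(1, 3), (2, 2), (3, 1)])
def test_rd_rule(d_level, rd):
    assert rd_from_level(d_level) == rd


def test_rule_inputs_validated():
    with pytest.raises(ValueError):
        sd_components(0, 1)
    with pytest.raises(ValueError):
        sd_from_components(3, 0)
    with pytest.raises(ValueError):
        rd_from_level(4)


def test_symbol_partition_into_environment_states():
    """The 27 symbols partition into 9 environment states of exactly 3 each."""
    table = symbol_environment_table()
    counts = table.groupby("Wn")["symbol"].count()
    assert counts.tolist() == [3] * 9
    assert set(table["symbol"]) == set(range(1, 28))
    for row in table.itertuples():
        assert row.Wn == (row.Sd - 1) * 3 + row.Rd


def make_params(pi, B):
    return HMMParams(pi=pi, A=np.full((3, 3), 1 / 3), B=B)


def test_bayes_posterior_identities(rng):
    pi = np.array([0.2, 0.5, 0.3])
    B = np.full((3, 27), 1 / 27)
    assert np.allclose(bayes_posterior(pi, B, 5), pi)  # equal columns cancel
    B2 = rng.dirichlet(np.ones(27), size=3)
    col = B2[:, 7]
    assert np.allclose(
        bayes_posterior(np.full(3, 1 / 3), B2, 8), col / col.sum()
    )


def test_bayes_posterior_worked_example():
    pi = np.array([0.2, 0.5, 0.3])
    B = np.zeros((3, 27))
    B[:, 0] = [0.1, 0.2, 0.4]
    B[:, 1:] = (1 - B[:, 0])[:, None] / 26
    got = bayes_posterior(pi, B, 1)
    assert np.allclose(got, [0.02 / 0.24, 0.10 / 0.24, 0.12 / 0.24])
    assert got.sum() == pytest.approx(1.0)


def test_bayes_posterior_unobservable_symbol_errors():
    pi = np.array([1.0, 0.0, 0.0])
    B = np.zeros((3, 27))
    B[:, 0] = 1.0
    with pytest.raises(ValueError, match="zero probability"):
        bayes_posterior(pi, B, 5)


def _wn_members(wn):
    return [o for o in range(1, 28) if environment_state(o)[2] == wn]


def test_environment_posterior_mixture_of_equals_is_identity():
    pi = np.array([0.25, 0.45, 0.30])
    B = np.full((3, 27), 1 / 27)
    for wn in range(1, 10):
        assert np.allclose(environment_posterior(pi, B, wn), pi)


def test_environment_posterior_degenerate_single_symbol():
    pi = np.full(3, 1 / 3)
    members = _wn_members(5)
    B = np.zeros((3, 27))
    B[:, members[0] - 1] = [0.3, 0.5, 0.2]
    rest = 1 - B.sum(axis=1)
    others = [o - 1 for o in range(1, 28) if o not in members]
    B[:, others] = rest[:, None] / len(others)
    got = environment_posterior(pi, B, 5)
    assert np.allclose(got, bayes_posterior(pi, B, members[0]))


def test_environment_posterior_two_symbol_hand_mixture():
    pi = np.array([0.5, 0.3, 0.2])
    members = _wn_members(1)
    B = np.zeros((3, 27))
    B[:, members[0] - 1] = [0.2, 0.1, 0.1]
    B[:, members[1] - 1] = [0.1, 0.3, 0.1]
    others = [o - 1 for o in range(1, 28) if o not in members[:2]]
    rest = 1 - B.sum(axis=1)
    B[:, others] = rest[:, None] / len(others)
    w1 = float(pi @ B[:, members[0] - 1])
    w2 = float(pi @ B[:, members[1] - 1])
    w3 = float(pi @ B[:, members[2] - 1])
    hand = (
        w1 * bayes_posterior(pi, B, members[0])
        + w2 * bayes_posterior(pi, B, members[1])
        + w3 * bayes_posterior(pi, B, members[2])
    ) / (w1 + w2 + w3)
    got = environment_posterior(pi, B, 1)
    assert np.allclose(got, hand)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


def test_change_rate_values():
    assert change_rate(0.2, 0.2) == 0.0
    assert change_rate(0.3, 0.2) == pytest.approx(50.0)
    assert change_rate(0.1, 0.2) == pytest.approx(-50.0)
    assert np.isnan(change_rate(0.1, 0.0))


def test_paired_t_null_and_df():
    a = np.linspace(0, 1, 62)
    r = paired_t_test(a, a)
    assert r.statistic == 0.0 and r.stars == "-"
    assert r.df == (61,)


def test_paired_t_matches_textbook_formula(rng):
    a = rng.normal(size=15)
    b = a + rng.normal(0.3, 0.5, size=15)
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(15))
    p_hand = 2 * stats.t.sf(abs(t_hand), 14)
    r = paired_t_test(a, b)
    assert r.statistic == pytest.approx(t_hand)
    assert r.p_value == pytest.approx(p_hand)


def test_paired_t_zero_variance_flagged():
    a = np.zeros(10)
    r = paired_t_test(a, a + 1.0)
    assert np.isinf(r.statistic) and r.flag is not None


def test_f_test_degenerate_and_null():
    r = one_way_f_test([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
    assert r.flag is not None
    r2 = one_way_f_test([[0.0, 1.0, -1.0, 0.5], [0.1, -0.6, 1.0, -0.5]])
    assert r2.p_value > 0.1


def test_f_test_matches_sums_of_squares_oracle(rng):
    groups = [rng.normal(m, 1, size=12) for m in (0.0, 0.4, 1.0)]
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ssb / 2) / (ssw / (36 - 3))
    r = one_way_f_test(groups)
    assert r.statistic == pytest.approx(f_hand)
    assert r.df == (2, 33)


def test_q_test_worked_example_and_symmetry(rng):
    groups = [rng.normal(m, 1, size=10) for m in (0.0, 0.5, 1.5)]
    out = q_test(groups, labels=["a", "b", "c"])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / (30 - 3)
    q_hand = abs(groups[0].mean() - groups[1].mean()) / np.sqrt(msw / 10)
    row = out[(out.group_a == "a") & (out.group_b == "b")].iloc[0]
    assert row.q == pytest.approx(q_hand)
    # q is symmetric in its two groups
    out_rev = q_test(groups[::-1], labels=["c", "b", "a"])
    row_rev = out_rev[(out_rev.group_a == "b") & (out_rev.group_b == "a")].iloc[0]
    assert row_rev.q == pytest.approx(row.q)


def test_q_test_identical_means_zero():
    g = np.array([0.0, 1.0, -1.0, 0.4, -0.4])
    out = q_test([g, g + 0.0])
    assert out["q"].iloc[0] == pytest.approx(0.0)
    assert out["stars"].iloc[0] == "-"


def test_q_test_p_values_match_scipy_tukey(rng):
    """Dual route: our studentized-range p-values against scipy's Tukey HSD."""
    groups = [rng.normal(m, 1, size=14) for m in (0.0, 0.6, 1.1)]
    ours = q_test(groups, labels=["g1", "g2", "g3"])
    ref = stats.tukey_hsd(*groups)
    pairs = {("g1", "g2"): (0, 1), ("g1", "g3"): (0, 2), ("g2", "g3"): (1, 2)}
    for row in ours.itertuples():
        i, j = pairs[(row.group_a, row.group_b)]
        assert row.p_value == pytest.approx(ref.pvalue[i, j], abs=1e-8)


def test_significance_star_bands():
    assert significance_stars(0.005) == "***"
    assert significance_stars(0.03) == "**"
    assert significance_stars(0.07) == "*"
    assert significance_stars(0.2) == "-"


def test_participant_probabilities_simple_cases():
    occ, trans = participant_probabilities([np.array([1, 1, 1])])
    assert np.allclose(occ, [1, 0, 0])
    assert np.allclose(trans[0], [1, 0, 0])
    occ2, trans2 = participant_probabilities([np.array([1, 2, 1, 2, 1, 2])])
    assert trans2[0, 1] == pytest.approx(1.0)
    assert trans2[1, 0] == pytest.approx(1.0)


def test_participant_probabilities_long_chain_oracle(rng):
    """Frequencies converge to the generating chain's parameters."""
    A = np.array([[0.6, 0.3, 0.1], [0.2, 0.6, 0.2], [0.1, 0.3, 0.6]])
    n = 20_000
    s = np.empty(n, dtype=int)
    s[0] = 0
    cum = np.cumsum(A, axis=1)
    u = rng.random(n)
    for t in range(1, n):
        s[t] = np.searchsorted(cum[s[t - 1]], u[t], side="right")
    occ, trans = participant_probabilities([s + 1])
    stat = np.linalg.matrix_power(A, 200)[0]
    assert np.all(np.abs(occ - stat) < 3 * np.sqrt(stat * (1 - stat) / n) + 0.01)
    assert np.max(np.abs(trans - A)) < 0.02


def test_participant_probabilities_requires_data():
    with pytest.raises(ValueError):
        participant_probabilities([np.array([], dtype=int)])
    with pytest.raises(ValueError, match="transitions"):
        participant_probabilities([np.array([2])])
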
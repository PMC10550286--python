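"""Behavioral metrics, mixed ANOVA, effect sizes and Bayes factors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrplast.behavioral import (
    chi2_2x2,
    classify_bf,
    cohens_d_from_t,
    dominant_strategy,
    inverse_efficiency,
    jzs_bayes_factor,
    learning_rate,
    mixed_anova,
    partial_eta_squared,
    percent_gain,
    run_is_valid,
)

import oracles


@pytest.mark.parametrize("rt, acc, expected", [
    (800.0, 1.0, 800.0),
    (800.0, 0.5, 1600.0),
    (953.0, 0.87, 953.0 / 0.87),
])
def test_inverse_efficiency(rt, acc, expected):
    assert inverse_efficiency(rt, acc) == pytest.approx(expected)


def test_inverse_efficiency_zero_accuracy_flagged():
    with pytest.warns(UserWarning):
        assert np.isnan(inverse_efficiency(800.0, 0.0))


@pytest.mark.parametrize("ies, expected", [
    ([5, 4, 3, 2, 1], -1.0),
    ([7, 7, 7, 7, 7], 0.0),
    ([10, 8, 7, 7, 6], -0.9),  # Sxy=-9, Sxx=10 by hand
])
def test_learning_rate(ies, expected):
    assert learning_rate(ies) == pytest.approx(expected)


def test_learning_rate_too_few_days():
    with pytest.warns(UserWarning):
        assert np.isnan(learning_rate([1000.0, np.nan, np.nan, np.nan, np.nan]))


@pytest.mark.parametrize("pre, post, expected", [
    (0.8, 0.8, 0.0),
    (0.5, 0.75, 0.5),
    (2000.0, 1500.0, -0.25),
])
def test_percent_gain(pre, post, expected):
    assert percent_gain(pre, post) == pytest.approx(expected)


@settings(deadline=None, max_examples=30)
@given(rt=st.floats(1.0, 1e4), acc=st.floats(0.05, 1.0), c=st.floats(0.1, 10.0))
def test_rt_scale_covariance(rt, acc, c):
    """Multiplying all RTs by c multiplies IES by c and leaves RT gain unchanged."""
    assert inverse_efficiency(c * rt, acc) == pytest.approx(c * inverse_efficiency(rt, acc))
    assert percent_gain(c * rt, c * 0.8 * rt) == pytest.approx(percent_gain(rt, 0.8 * rt))


@pytest.mark.parametrize("codes, expected", [
    (["retrieval"] * 14, ("memory-based", 1.0)),
    (["retrieval"] * 8 + ["counting"] * 6, ("memory-based", 8 / 14)),
    (["retrieval"] * 7 + ["decomposition"] * 7, ("memory-based", 0.5)),  # tie
])
def test_dominant_strategy(codes, expected):
    label, rate = dominant_strategy(codes)
    assert (label, rate) == (expected[0], pytest.approx(expected[1]))


def test_dominant_strategy_edge_cases():
    with pytest.warns(UserWarning):
        label, rate = dominant_strategy([])
    assert label is None and np.isnan(rate)
    with pytest.warns(UserWarning):
        label, _ = dominant_strategy(["retrieval", "counting"], tie_rule="flag")
    assert label is None
    with pytest.raises(ValueError):
        dominant_strategy(["guessing"])


def test_run_validity_rule():
    assert run_is_valid(0.9, 0.0)
    assert not run_is_valid(0.4, 0.0)   # below-chance accuracy
    assert not run_is_valid(0.9, 0.3)   # non-response on 30% of trials
    assert run_is_valid(0.5, 0.29)      # both just inside the limits
    # conjunctive reading: only both violations together invalidate
    assert run_is_valid(0.4, 0.0, rule="all")
    assert not run_is_valid(0.4, 0.35, rule="all")


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

BALANCED = np.array([
    [3, 5, 7], [4, 6, 9], [2, 5, 8], [3, 6, 7], [5, 7, 9], [4, 5, 8],
    [6, 7, 8], [5, 8, 9], [7, 9, 12], [6, 8, 10], [5, 7, 9], [6, 9, 11],
], dtype=float)
BALANCED_GROUP = np.array(["A"] * 6 + ["B"] * 6)


def test_mixed_anova_matches_sums_of_squares_oracle():
    res = mixed_anova(BALANCED, BALANCED_GROUP)
    F_g, F_s, F_i = oracles.mixed_anova_ss(BALANCED, BALANCED_GROUP)
    assert res["group"].statistic == pytest.approx(F_g, rel=1e-10)
    assert res["session"].statistic == pytest.approx(F_s, rel=1e-10)
    assert res["session*group"].statistic == pytest.approx(F_i, rel=1e-10)
    # independent library cross-check (pingouin) on the same design
    import pandas as pd
    import pingouin as pg

    n, k = BALANCED.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "group": np.repeat(BALANCED_GROUP, k),
        "session": np.tile(np.arange(k), n),
        "value": BALANCED.ravel(),
    })
    aov = pg.mixed_anova(data=long, dv="value", within="session",
                         subject="subject", between="group").set_index("Source")
    assert res["group"].statistic == pytest.approx(aov.at["group", "F"])
    assert res["session"].statistic == pytest.approx(aov.at["session", "F"])
    assert res["session*group"].statistic == pytest.approx(aov.at["Interaction", "F"])
    # partial eta squared consistent with the F/df identity at every term
    for term in res.terms.values():
        assert term.effect_size == pytest.approx(
            partial_eta_squared(term.statistic, *term.df))


def test_mixed_anova_zero_group_difference():
    """Identical per-session means and zero noise give a between-group F of 0."""
    base = np.array([[1.0, 2.0, 3.0]])
    vals = np.repeat(base, 8, axis=0)
    grp = np.array(["A"] * 4 + ["B"] * 4)
    vals[[0, 1, 4, 5]] += 0.5  # identical subject offsets in both groups
    res = mixed_anova(vals, grp)
    assert res["group"].statistic == pytest.approx(0.0, abs=1e-12)
    assert res["session*group"].statistic == pytest.approx(0.0, abs=1e-12)


def test_mixed_anova_session_relabel_symmetry():
    """Permuting session columns consistently leaves the session F unchanged."""
    res = mixed_anova(BALANCED, BALANCED_GROUP)
    perm = BALANCED[:, [2, 0, 1]]
    res_p = mixed_anova(perm, BALANCED_GROUP)
    assert res_p["session"].statistic == pytest.approx(res["session"].statistic)


def test_mixed_anova_rejects_bad_designs():
    with pytest.raises(ValueError):
        mixed_anova(BALANCED[:7], np.array(["A"] * 6 + ["B"]))  # singleton group
    with pytest.raises(ValueError):
        mixed_anova(BALANCED, np.array(["A"] * 12))  # one group
    bad = BALANCED.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        mixed_anova(bad, BALANCED_GROUP)  # incomplete within-subject data


# ---------------------------------------------------------------------------
# effect sizes and Bayes factors
# ---------------------------------------------------------------------------

def test_effect_size_identities_basics():
    assert cohens_d_from_t(0.0, 17) == 0.0
    assert partial_eta_squared(0.0, 3, 50) == 0.0
    from nrplast.group import cohens_f
    assert cohens_f(0.0) == 0.0
    assert cohens_f(0.5) == pytest.approx(1.0)


def test_chi2_2x2():
    perfect = chi2_2x2(np.array([[10, 0], [0, 10]]))
    assert perfect.statistic == pytest.approx(20.0)   # chi2 = N, uncorrected
    assert perfect.effect_size == pytest.approx(1.0)
    null = chi2_2x2(np.array([[7, 3], [7, 3]]))
    assert null.statistic == pytest.approx(0.0)
    assert null.effect_size == pytest.approx(0.0)
    with pytest.raises(ValueError):
        chi2_2x2(np.array([[5, 5], [0, 0]]))  # zero margin


def test_jzs_bf_matches_independent_g_integral():
    """Cauchy-prior quadrature agrees with the variance-inflation integral."""
    for t, n1, n2 in [(2.54, 28, None), (0.86, 29, 26), (0.0, 12, None),
                      (-3.1, 20, 22), (1.2, 8, None)]:
        mine = jzs_bayes_factor(t, n1, n2)
        oracle = oracles.jzs_bf_g_integral(t, n1, n2)
        assert mine == pytest.approx(oracle, rel=1e-6)


def test_jzs_bf_monotone_in_t_and_null_favoring_at_zero():
    bfs = [jzs_bayes_factor(t, 28) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
    assert bfs[0] < 1.0
    assert jzs_bayes_factor(-2.0, 15) == pytest.approx(jzs_bayes_factor(2.0, 15))


@pytest.mark.parametrize("bf, band", [
    (7.75, "moderate H1"),
    (1.0, "insufficient"),
    (0.05, "strong H0"),
    (11.0, "strong H1"),
    (0.2, "moderate H0"),
])
def test_classify_bf(bf, band):
    assert classify_bf(bf) == band
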
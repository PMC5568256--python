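import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cumeta import BetaParams, TrialRecord, cumulate, posterior_summary, update

# printed cumulative posterior means (control, treated), 4 decimals
TABLE_MEANS = {
    1: (0.0952, 0.0476),
    3: (0.1753, 0.1517),
    5: (0.1908, 0.2218),
    13: (0.2463, 0.2410),
}


def test_update_single_trial():
    post = update(BetaParams(1, 1), 3, 40)
    assert (post.alpha, post.beta) == (4, 38)
    assert post.mean == pytest.approx(0.0952, abs=5e-5)


def test_update_no_data_is_identity():
    prior = BetaParams(2.5, 7.5)
    assert update(prior, 0, 0) == prior


def test_update_pooled_totals():
    post = update(BetaParams(1, 1), 133, 554)
    assert (post.alpha, post.beta) == (134, 422)
    assert post.mean == pytest.approx(0.2410, abs=5e-5)


def test_update_rejects_events_above_n():
    with pytest.raises(ValueError):
        update(BetaParams(1, 1), 5, 4)


def test_cumulate_reproduces_cumulative_means(knee_states):
    for k, (mc, mt) in TABLE_MEANS.items():
        state = knee_states[k - 1]
        assert state.control.mean == pytest.approx(mc, abs=5e-5)
        assert state.treated.mean == pytest.approx(mt, abs=5e-5)
    final = knee_states[-1]
    assert (final.control.alpha, final.control.beta) == (133, 407)
    assert (final.treated.alpha, final.treated.beta) == (134, 422)


def test_cumulate_conjugate_identity_with_counts(knee_states):
    # uniform start: alpha = 1 + cumulative events, beta = 1 + cumulative non-events
    for s in knee_states:
        assert s.control.alpha == 1 + s.cum_events_control
        assert s.control.beta == 1 + s.cum_n_control - s.cum_events_control
        assert s.treated.alpha == 1 + s.cum_events_treated
        assert s.treated.beta == 1 + s.cum_n_treated - s.cum_events_treated


def test_cumulate_rejects_unsorted():
    trials = [
        TrialRecord("a", "A", 2, 10, 1, 10, 1),
        TrialRecord("b", "B", 1, 10, 1, 10, 1),
    ]
    with pytest.raises(ValueError, match="sorted"):
        cumulate(trials)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    counts=st.lists(
        st.tuples(st.integers(1, 200), st.integers(0, 200)).map(lambda t: (max(t), min(t))),
        min_size=1,
        max_size=8,
    )
)
def test_batch_equals_sequential(counts):
    """Absorbing trials one at a time == one update with pooled totals, exactly."""
    trials = [TrialRecord(f"t{i}", "", i, n, e, n, e) for i, (n, e) in enumerate(counts)]
    final = cumulate(trials)[-1]
    pooled = update(BetaParams(1, 1), sum(e for _, e in counts), sum(n for n, _ in counts))
    assert final.control == pooled
    assert final.treated == pooled


def test_posterior_mean_between_prior_and_data():
    prior = BetaParams(3, 7)  # mean 0.3
    post = update(prior, 8, 10)  # data fraction 0.8
    assert prior.mean < post.mean < 0.8


def test_posterior_mean_converges_to_event_fraction():
    n = 10**6
    post = update(BetaParams(1, 1), int(0.37 * n), n)
    assert post.mean == pytest.approx(0.37, abs=1e-4)


def test_posterior_summary_uniform():
    mean, (lo, hi) = posterior_summary(BetaParams(1, 1), 0.95)
    assert mean == 0.5
    assert lo == pytest.approx(0.025, abs=1e-12)
    assert hi == pytest.approx(0.975, abs=1e-12)


def test_posterior_summary_final_arms():
    mean_t, (lo_t, hi_t) = posterior_summary(BetaParams(134, 422), 0.95)
    assert mean_t == pytest.approx(0.2410, abs=5e-5)
    assert (lo_t, hi_t) == pytest.approx((0.207, 0.277), abs=1.5e-3)
    mean_c, (lo_c, hi_c) = posterior_summary(BetaParams(133, 407), 0.95)
    assert mean_c == pytest.approx(0.2463, abs=5e-5)
    assert (lo_c, hi_c) == pytest.approx((0.210, 0.284), abs=1.5e-3)


def test_hpd_interval_no_wider_than_equal_tailed():
    p = BetaParams(4, 38)  # skewed: HPD should be strictly shorter
    _, (lo_et, hi_et) = posterior_summary(p, 0.95)
    _, (lo_h, hi_h) = posterior_summary(p, 0.95, hpd=True)
    assert hi_h - lo_h <= hi_et - lo_et + 1e-10
    from scipy import stats

    mass = stats.beta.cdf(hi_h, 4, 38) - stats.beta.cdf(lo_h, 4, 38)
    assert mass == pytest.approx(0.95, abs=1e-6)


def test_posterior_summary_bad_level():
    with pytest.raises(ValueError):
        posterior_summary(BetaParams(1, 1), 1.5)
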
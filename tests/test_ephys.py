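"""Unit-level response analysis: window rates, detection, strength,
categorization, selectivity, baseline drug effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import meaphys as m
from meaphys.ephys import TrialWindowRates


def rates_of(pre, post, pre_s=20.0, post_s=40.0):
    return TrialWindowRates(
        np.asarray(pre, dtype=float), np.asarray(post, dtype=float), pre_s, post_s
    )


class TestTrialRates:
    def test_hand_counted_half_open_windows(self):
        out = m.trial_rates(np.array([1.0, 2.0, 3.0]), [2.0], pre_s=2, post_s=2)
        # pre [0, 2) holds {1}; post [2, 4) holds {2, 3}
        assert out.pre_rates[0] == pytest.approx(0.5)
        assert out.post_rates[0] == pytest.approx(1.0)

    def test_empty_train_gives_zero_rates(self):
        out = m.trial_rates(np.array([]), [100.0, 200.0])
        assert (out.pre_rates == 0).all() and (out.post_rates == 0).all()

    def test_event_order_preserved(self):
        spikes = np.arange(0.25, 400.0, 0.5)  # 2 Hz regular
        out = m.trial_rates(spikes, [300.0, 100.0], pre_s=20, post_s=40)
        assert out.pre_rates[0] == pytest.approx(2.0)
        assert len(out.pre_rates) == 2

    def test_homogeneous_poisson_recovers_rate(self):
        rng = np.random.default_rng(0)
        t_end = 100 * 80.0 + 100
        n = rng.poisson(5.0 * t_end)
        spikes = np.sort(rng.uniform(0, t_end, n))
        onsets = 20.0 + 80.0 * np.arange(100)
        out = m.trial_rates(spikes, onsets)
        se_pre = np.sqrt(5.0 / 20.0 / 100)
        se_post = np.sqrt(5.0 / 40.0 / 100)
        assert abs(out.pre_rates.mean() - 5.0) <= 3 * se_pre
        assert abs(out.post_rates.mean() - 5.0) <= 3 * se_post

    def test_overlapping_windows_rejected_with_onsets_named(self):
        with pytest.raises(m.WindowError, match="100.0 and 130.0"):
            m.trial_rates(np.array([1.0]), [100.0, 130.0])

    def test_window_before_session_start_rejected(self):
        with pytest.raises(m.WindowError):
            m.trial_rates(np.array([1.0]), [10.0], pre_s=20)


class TestResponsivenessTest:
    def test_separated_groups_are_significant(self):
        p = m.responsiveness_test(rates_of([0.0] * 10, [10.0] * 10))
        assert p < 0.01

    def test_identical_groups_give_p_one(self):
        p = m.responsiveness_test(rates_of([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))
        assert p == 1.0

    def test_matches_scipy_kruskal(self):
        rng = np.random.default_rng(1)
        pre, post = rng.poisson(4.0, 8) / 20, rng.poisson(9.0, 8) / 40
        expected = stats.kruskal(pre, post).pvalue
        assert m.responsiveness_test(rates_of(pre, post)) == pytest.approx(expected)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        pre, post = rng.random(6), rng.random(6)
        assert m.responsiveness_test(rates_of(pre, post)) == pytest.approx(
            m.responsiveness_test(rates_of(post, pre))
        )

    def test_too_few_trials_raises(self):
        with pytest.raises(m.InsufficientDataError):
            m.responsiveness_test(rates_of([1.0, 2.0], [3.0, 4.0]))


class TestResponseStrength:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(2.0, 6.0, 0.5), (3.0, 3.0, 0.0), (0.0, 4.0, 1.0), (4.0, 0.0, -1.0),
         (0.0, 0.0, 0.0)],
    )
    def test_ratio_of_trial_means(self, pre, post, expected):
        out = m.response_strength(rates_of([pre] * 4, [post] * 4))
        assert out == pytest.approx(expected)

    @given(
        pre=st.lists(st.floats(0, 50), min_size=3, max_size=12),
        post=st.lists(st.floats(0, 50), min_size=3, max_size=12),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_antisymmetric(self, pre, post):
        s = m.response_strength(rates_of(pre, post))
        assert -1.0 <= s <= 1.0
        assert m.response_strength(rates_of(post, pre)) == pytest.approx(-s)


class TestCategorization:
    def test_strongest_significant_stimulus_wins(self):
        p = {"female": 0.001, "male": 0.2, "predator": 0.004}
        s = {"female": 0.4, "male": 0.1, "predator": 0.2}
        assert m.categorize_unit(p, s) == "female"

    def test_no_significant_means_nonresponsive(self):
        p = {"female": 0.5, "male": 0.9, "predator": 0.2}
        s = {"female": 0.4, "male": 0.1, "predator": 0.5}
        assert m.categorize_unit(p, s) == "nonresponsive"

    def test_suppressed_responses_cannot_win(self):
        p = {"female": 0.001, "male": 0.5, "predator": 0.5}
        s = {"female": -0.6, "male": 0.0, "predator": 0.0}
        assert m.categorize_unit(p, s) == "nonresponsive"

    def test_control_stimulus_never_wins(self):
        p = {"female": 0.5, "control": 0.0001}
        s = {"female": 0.1, "control": 0.9}
        assert m.categorize_unit(p, s) == "nonresponsive"

    def test_tie_broken_by_p_then_fixed_order(self):
        p = {"female": 0.005, "predator": 0.001}
        s = {"female": 0.3, "predator": 0.3}
        assert m.categorize_unit(p, s) == "predator"
        p = {"female": 0.001, "predator": 0.001}
        assert m.categorize_unit(p, s) == "female"

    def test_alpha_nesting_monotone(self, control_session):
        cfg, _, events, spikes = control_session
        strict = m.profile_units(spikes, events, alpha=0.01)
        loose = m.profile_units(spikes, events, alpha=0.05)
        n_strict = (strict.groupby("unit_id")["category"].first() != "nonresponsive").sum()
        n_loose = (loose.groupby("unit_id")["category"].first() != "nonresponsive").sum()
        assert n_loose >= n_strict


class TestSelectivity:
    def test_single_positive_maps_to_vertex(self):
        out = m.selectivity_coordinates(
            {"female": 0.6, "male": 0.0, "predator": 0.0}, {"female": True}
        )
        assert out.as_tuple() == (1.0, 0.0, 0.0)

    def test_symmetric_strengths_map_to_centroid(self):
        out = m.selectivity_coordinates(
            {"female": 0.3, "male": 0.3, "predator": 0.3}, {"female": True}
        )
        assert out.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert not out.degenerate

    def test_rectify_then_normalize(self):
        out = m.selectivity_coordinates(
            {"female": 0.4, "male": -0.2, "predator": 0.4}, {"female": True}
        )
        assert out.as_tuple() == pytest.approx((0.5, 0.0, 0.5))

    def test_all_rectified_zero_is_flagged_centroid(self):
        out = m.selectivity_coordinates(
            {"female": -0.4, "male": -0.2, "predator": 0.0}, {"female": True}
        )
        assert out.degenerate and sum(out.as_tuple()) == pytest.approx(1.0)

    def test_nonresponsive_unit_rejected(self):
        with pytest.raises(ValueError):
            m.selectivity_coordinates({"female": 0.4}, {"female": False})

    @given(
        st.tuples(
            st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
        ).filter(lambda t: max(t) > 1e-6)
    )
    @settings(deadline=None, max_examples=50)
    def test_coordinates_live_on_simplex(self, strengths):
        f, ml, p = strengths
        out = m.selectivity_coordinates(
            {"female": f, "male": ml, "predator": p}, {"female": True}
        )
        assert min(out.as_tuple()) >= 0
        assert sum(out.as_tuple()) == pytest.approx(1.0)


class TestBaselineRateChange:
    def test_rate_step_is_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(20):
            before = np.sort(rng.uniform(0, 600, rng.poisson(5.0 * 600)))
            after = 600 + np.sort(rng.uniform(0, 600, rng.poisson(2.5 * 600)))
            out = m.baseline_rate_change(
                np.concatenate([before, after]), (0, 600), (600, 1200)
            )
            detected += out.p_value < 0.05
            assert out.rate_before > out.rate_after
        assert detected >= 18

    def test_null_rates_close_and_not_all_significant(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(20):
            spikes = np.sort(rng.uniform(0, 1200, rng.poisson(4.0 * 1200)))
            out = m.baseline_rate_change(spikes, (0, 600), (600, 1200))
            pvals.append(out.p_value)
        assert np.mean(np.array(pvals) < 0.05) < 0.3

    def test_empty_train_gives_zero_rates_p_one(self):
        out = m.baseline_rate_change(np.array([]), (0, 600), (600, 1200))
        assert out.rate_before == 0 and out.rate_after == 0 and out.p_value == 1.0

    def test_epoch_overlapping_stimulus_window_rejected(self):
        with pytest.raises(m.WindowError):
            m.baseline_rate_change(
                np.array([1.0]), (0, 600), (600, 1200), stimulus_onsets=[590.0]
            )


class TestProfileInvariances:
    def test_time_translation_invariance(self, toy_spikes_events):
        spikes, events = toy_spikes_events
        base = m.profile_units(spikes, events)
        shifted_spikes = spikes.assign(spike_time_s=spikes.spike_time_s + 500)
        shifted_events = events.assign(onset_s=events.onset_s + 500)
        shifted = m.profile_units(shifted_spikes, shifted_events)
        for col in ("pre_rate", "post_rate", "p_value", "strength", "category"):
            assert (base[col] == shifted[col]).all()

    def test_stimulus_order_invariance(self, toy_spikes_events):
        spikes, events = toy_spikes_events
        base = m.profile_units(spikes, events).set_index(["unit_id", "stimulus"])
        reordered = m.profile_units(
            spikes, events.iloc[::-1].reset_index(drop=True)
        ).set_index(["unit_id", "stimulus"])
        assert (
            base["category"].sort_index() == reordered["category"].sort_index()
        ).all()

    def test_toy_profile_hand_rates(self, toy_spikes_events):
        spikes, events = toy_spikes_events
        prof = m.profile_units(spikes, events).set_index(["unit_id", "stimulus"])
        # u0: 1 spike in each 20 s pre window, 2 in each 40 s post window
        assert prof.loc[("u0", "A"), "pre_rate"] == pytest.approx(0.05)
        assert prof.loc[("u0", "A"), "post_rate"] == pytest.approx(0.05)
        # u1: 1 Hz regular -> identical pre/post, strength 0, p = 1
        assert prof.loc[("u1", "B"), "strength"] == pytest.approx(0.0)
        assert prof.loc[("u1", "B"), "p_value"] == 1.0
        assert prof.loc[("u1", "B"), "category"] == "nonresponsive"
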
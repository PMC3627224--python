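"""Pairing events, spike density and predictor correlations: brute-force
oracles, closed forms and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cheeseboard import predictors as pr


def brute_force_pairing(pre, post, w=0.02):
    preceded = sum(any(0 < t - s < w for s in post) for t in pre)
    followed = sum(any(0 < s - t < w for s in post) for t in pre)
    return preceded, followed


class TestPairingEvents:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 1.0, 10))
        post = np.sort(rng.uniform(0, 1.0, 10))
        s = pr.pairing_events(pre, post, [(0.0, 1.0)])
        exp_prec, exp_foll = brute_force_pairing(pre, post)
        assert (s.n_pre_window, s.n_post_window) == (exp_prec, exp_foll)

    def test_silent_post_zero_counts(self):
        s = pr.pairing_events(np.arange(10.0), [], [(0, 10)])
        assert s.n_pre_window == 0 and s.n_post_window == 0

    def test_exact_coincidence_excluded(self):
        t = np.arange(10.0)
        s = pr.pairing_events(t, t, [(0, 10)])
        assert s.n_pre_window == 0 and s.n_post_window == 0

    def test_fixed_offset_train(self):
        pre = np.arange(0.0, 1.0, 0.1)
        post = pre + 0.005
        s = pr.pairing_events(pre, post, [(0.0, 2.0)])
        exp = brute_force_pairing(pre, post)
        assert (s.n_pre_window, s.n_post_window) == exp
        assert s.n_post_window == len(pre)

    def test_independence_closed_form(self):
        # P(any post within 20 ms) = 1 - exp(-lambda * 0.02)
        lam = 10.0
        rng = np.random.default_rng(1)
        pre = np.sort(rng.uniform(1, 599, 1200))
        post = np.sort(rng.uniform(0, 600, rng.poisson(lam * 600)))
        s = pr.pairing_events(pre, post, [(0, 600)])
        p = 1 - np.exp(-lam * 0.02)
        half = 1.96 * np.sqrt(p * (1 - p) / len(pre))
        assert abs(s.n_post_window / len(pre) - p) < half
        assert abs(s.n_pre_window / len(pre) - p) < half

    def test_empty_epochs_rejected(self):
        with pytest.raises(ValueError):
            pr.pairing_events([1.0], [1.0], np.empty((0, 2)))


class TestGoalSplit:
    def track(self):
        t = np.arange(0, 10, 0.025)
        return pd.DataFrame({"time": t, "x": np.zeros_like(t),
                             "y": np.zeros_like(t)})

    def test_all_events_at_goal(self):
        pre = np.arange(0.5, 9.5, 0.5)
        post = pre + 0.005
        s = pr.pairing_events(pre, post, [(0, 10)], track=self.track(),
                              goals=[(0.0, 0.0)])
        n_in, n_out = pr.goal_split(s)
        assert n_in == len(s.events) and n_out == 0

    def test_no_goals_all_outside(self):
        pre = np.arange(0.5, 9.5, 0.5)
        post = pre + 0.005
        s = pr.pairing_events(pre, post, [(0, 10)], track=self.track(),
                              goals=[])
        n_in, n_out = pr.goal_split(s)
        assert n_in == 0 and n_out == len(s.events)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_totals_conserved(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 10, 0.025)
        track = pd.DataFrame({"time": t,
                              "x": rng.uniform(-50, 50, len(t)),
                              "y": rng.uniform(-50, 50, len(t))})
        pre = np.sort(rng.uniform(0, 10, 50))
        post = np.sort(rng.uniform(0, 10, 50))
        goals = rng.uniform(-50, 50, (3, 2))
        s = pr.pairing_events(pre, post, [(0, 10)], track=track, goals=goals)
        n_in, n_out = pr.goal_split(s)
        assert n_in + n_out == len(s.events)


class TestSpikeDensity:
    def test_single_spike_closed_form(self):
        d = pr.spike_density([3.0], sigma=0.02)
        assert d(3.0) == pytest.approx(1 / (0.02 * np.sqrt(2 * np.pi)),
                                       abs=1e-9)
        assert d(3.0) == pytest.approx(19.947, abs=1e-3)

    def test_integral_equals_spike_count(self):
        rng = np.random.default_rng(2)
        spikes = np.sort(rng.uniform(5, 95, 200))
        d = pr.spike_density(spikes)
        t = np.arange(0, 100, 0.002)
        assert np.trapezoid(np.atleast_1d(d(t)), t) == pytest.approx(200,
                                                                     rel=1e-3)

    def test_poisson_time_average_near_rate(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 600, rng.poisson(10 * 600)))
        d = pr.spike_density(spikes)
        q = rng.uniform(10, 590, 500)
        assert np.mean(np.atleast_1d(d(q))) == pytest.approx(10.0, rel=0.05)

    def test_queries_match_direct_summation(self):
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, 10, 300))
        d = pr.spike_density(spikes)
        q = rng.uniform(0, 10, 100)
        norm = 1 / (0.02 * np.sqrt(2 * np.pi))
        direct = np.array([
            norm * np.exp(-0.5 * ((spikes - t) / 0.02) ** 2).sum() for t in q
        ])
        assert np.allclose(np.atleast_1d(d(q)), direct, atol=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            pr.spike_density([1.0], sigma=0.0)


class TestDensityAtPreSpikes:
    def test_independent_normalized_near_one(self):
        rng = np.random.default_rng(5)
        post = np.sort(rng.uniform(0, 600, rng.poisson(10 * 600)))
        pre = np.sort(rng.uniform(10, 590, 500))
        s = pr.density_at_pre_spikes(pr.spike_density(post), pre, 10.0)
        assert s.normalized_density == pytest.approx(1.0, abs=0.1)

    def test_pre_at_post_times_above_one(self):
        rng = np.random.default_rng(6)
        post = np.sort(rng.uniform(0, 600, 3000))
        s = pr.density_at_pre_spikes(pr.spike_density(post), post[::5], 5.0)
        assert s.normalized_density > 1.0

    def test_pre_in_gaps_below_one(self):
        post = np.sort(np.concatenate([np.arange(0, 300, 0.1)]))
        pre = np.arange(300.5, 400.0, 1.0)   # silent period
        s = pr.density_at_pre_spikes(pr.spike_density(post), pre,
                                     len(post) / 400.0)
        assert s.normalized_density < 1.0

    def test_zero_rate_flagged(self):
        s = pr.density_at_pre_spikes(pr.spike_density([1.0]),
                                     np.arange(10.0), 0.0)
        assert np.isnan(s.normalized_density) and s.flag == "zero_post_rate"

    def test_too_few_pre_spikes_rejected(self):
        with pytest.raises(ValueError):
            pr.density_at_pre_spikes(pr.spike_density([1.0]), [1.0], 1.0)


class TestPredictorAnalysis:
    def planted_table(self, n=40, seed=7, density_only=False):
        rng = np.random.default_rng(seed)
        pairing = rng.poisson(200, n).astype(float)
        density = rng.uniform(5, 15, n)
        if density_only:
            delta = 0.02 * (density - 10) + 0.002 * rng.standard_normal(n)
        else:
            delta = 0.0005 * pairing + 0.005 * rng.standard_normal(n)
        return pd.DataFrame({
            "delta_transmission": delta,
            "n_pre_window": pairing // 2, "n_post_window": pairing // 2,
            "n_inside": pairing // 4, "n_outside": pairing // 4,
            "mean_density": density,
            "mean_speed": rng.uniform(10, 20, n),
        })

    def test_planted_pairing_dependence_recovered(self):
        rep = pr.predictor_analysis(self.planted_table())
        assert rep["correlations"]["n_pre_window"]["r"] > 0.7

    def test_density_dependence_survives_partial(self):
        rep = pr.predictor_analysis(self.planted_table(density_only=True))
        assert rep["partial_density_given_pairing"]["r"] > 0.5
        assert rep["partial_density_given_pairing"]["p"] < 0.01

    def test_shuffled_outcome_within_null_bounds(self):
        t = self.planted_table(n=60, seed=8)
        rng = np.random.default_rng(9)
        t["delta_transmission"] = rng.permutation(
            t.delta_transmission.to_numpy())
        rep = pr.predictor_analysis(t)
        bound = 3.3 / np.sqrt(len(t))     # ~99.9% null band for Pearson r
        for v in rep["correlations"].values():
            assert abs(v["r"]) < bound

    def test_constant_predictor_flagged(self):
        t = self.planted_table()
        t["n_inside"] = 5
        rep = pr.predictor_analysis(t)
        assert rep["correlations"]["n_inside"]["flag"] == "constant_predictor"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pr.predictor_analysis(self.planted_table(n=5))
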
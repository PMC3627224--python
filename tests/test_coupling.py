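"""Cross-correlogram construction, chance baseline, monosynaptic detection,
transmission/latency estimation and epoch tracking."""

import numpy as np
import pytest

from cheeseboard import coupling as cp
from cheeseboard.synthetic import simulate_coupled_pair


def echo_pair(n=600, offset_ms=1.5):
    pre = np.arange(n, dtype=float) + 0.3
    return pre, pre + offset_ms / 1000.0


def manual_ccg(counts_by_lag, n_ref=1000):
    n_side = int(round(cp.WINDOW_MS / cp.BIN_MS))
    lags = cp.BIN_MS * np.arange(-n_side, n_side + 1)
    counts = np.zeros(len(lags))
    for lag, c in counts_by_lag.items():
        counts[np.argmin(np.abs(lags - lag))] = c
    return cp.CrossCorrelogram(bin_width=cp.BIN_MS, lags=lags, counts=counts,
                               n_ref=n_ref)


class TestBuildCCG:
    def test_echo_train_all_mass_in_one_bin(self):
        pre, post = echo_pair()
        ccg = cp.build_ccg(pre, post)
        k = np.argmin(np.abs(ccg.lags - 1.5))
        assert ccg.prob[k] == pytest.approx(1.0)
        assert ccg.counts.sum() == len(pre)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 100, 300))
        b = np.sort(rng.uniform(0, 100, 800))
        f = cp.build_ccg(a, b)
        r = cp.build_ccg(b, a)
        assert np.array_equal(f.counts, r.counts[::-1])

    def test_independent_poisson_flat_at_analytic_level(self):
        pre, post = simulate_coupled_pair(1000.0, 1.0, 10.0, 0.0, seed=1)
        ccg = cp.build_ccg(pre, post)
        expect = 10.0 * cp.BIN_MS / 1000.0          # rate * bin width
        sd = np.sqrt(expect / ccg.n_ref)
        off_zero = np.abs(ccg.lags) > 1e-9
        assert np.all(np.abs(ccg.prob[off_zero] - expect) < 5 * sd)
        assert abs(ccg.prob.mean() - expect) < 3 * sd / np.sqrt(len(ccg.lags))

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            cp.build_ccg([], [1.0])

    def test_low_count_flag(self):
        ccg = cp.build_ccg(np.arange(50.0), np.arange(50.0) + 0.001)
        assert ccg.low_count


class TestChanceBaseline:
    def test_flat_ccg(self):
        ccg = manual_ccg({lag: 5 for lag in np.arange(-50, 50.5, 0.5)})
        m, s = cp.chance_baseline(ccg)
        assert m == pytest.approx(0.005)
        assert s == pytest.approx(0.0)

    def test_mono_peak_outside_chance_window(self):
        flat = manual_ccg({lag: 5 for lag in np.arange(-50, 50.5, 0.5)})
        peaked = manual_ccg({**{lag: 5 for lag in np.arange(-50, 50.5, 0.5)},
                             1.5: 300})
        assert cp.chance_baseline(flat) == cp.chance_baseline(peaked)

    def test_independent_pair_baseline_near_rate(self):
        pre, post = simulate_coupled_pair(1000.0, 1.0, 10.0, 0.0, seed=2)
        m, _ = cp.chance_baseline(cp.build_ccg(pre, post))
        assert m == pytest.approx(0.005, abs=0.0008)


class TestDetectMono:
    def test_strong_pair_detected(self):
        pre, post = simulate_coupled_pair(1000.0, 2.0, 10.0, 0.1, seed=3)
        assert cp.detect_mono(cp.build_ccg(pre, post)).significant

    def test_peak_at_5ms_not_significant(self):
        pre, post = echo_pair(offset_ms=5.0)
        det = cp.detect_mono(cp.build_ccg(pre, post))
        assert not det.significant

    def test_tie_breaks_to_earlier_bin(self):
        ccg = manual_ccg({1.0: 50, 2.0: 50})
        det = cp.detect_mono(ccg)
        assert det.peak_lag_ms == pytest.approx(1.0)

    def test_zero_counts_flagged_insufficient(self):
        ccg = manual_ccg({})
        det = cp.detect_mono(ccg)
        assert not det.significant and det.flag == "insufficient_data"


class TestTransmission:
    def test_flat_ccg_exactly_zero(self):
        ccg = manual_ccg({lag: 8 for lag in np.arange(-50, 50.5, 0.5)})
        assert cp.transmission(ccg).prob == pytest.approx(0.0, abs=1e-15)

    def test_recovers_weight(self):
        pre, post = simulate_coupled_pair(2000.0, 2.0, 10.0, 0.20, seed=4)
        est = cp.transmission(cp.build_ccg(pre, post)).prob
        assert est == pytest.approx(0.20, abs=0.02)

    def test_null_weight_within_binomial_noise(self):
        pre, post = simulate_coupled_pair(1000.0, 2.0, 10.0, 0.0, seed=5)
        ccg = cp.build_ccg(pre, post)
        est = cp.transmission(ccg).prob
        lam = 0.005 * ccg.n_ref
        sd = np.sqrt(5 * lam) / ccg.n_ref        # 5 mono bins of Poisson mass
        assert abs(est) < 3 * (sd + np.sqrt(lam / 82) / ccg.n_ref * 5)

    def test_baseline_rate_confound_removed(self):
        # doubling the interneuron baseline rate must not bias transmission
        for rate, seed in ((10.0, 6), (20.0, 7)):
            pre, post = simulate_coupled_pair(2000.0, 2.0, rate, 0.1,
                                              seed=seed)
            est = cp.transmission(cp.build_ccg(pre, post)).prob
            assert est == pytest.approx(0.1, abs=0.02)

    def test_controls_reported(self):
        pre, post = simulate_coupled_pair(1000.0, 2.0, 10.0, 0.2, seed=8)
        t = cp.transmission(cp.build_ccg(pre, post))
        assert abs(t.excess_5ms) < 0.01
        assert t.chance_30_50 == pytest.approx(0.005, abs=0.002)


class TestLatency:
    def test_single_bin_center(self):
        ccg = manual_ccg({1.5: 200})
        assert cp.latency(ccg) == pytest.approx(1.5)

    def test_two_equal_bins_weighted_mean(self):
        ccg = manual_ccg({1.0: 100, 2.0: 100})
        assert cp.latency(ccg) == pytest.approx(1.5)

    def test_recovers_generator_delay(self):
        pre, post = simulate_coupled_pair(2000.0, 2.0, 10.0, 0.2,
                                          delay_ms=1.5, jitter_ms=0.2, seed=9)
        lat = cp.latency(cp.build_ccg(pre, post))
        assert lat == pytest.approx(1.5, abs=0.2)

    def test_nonsignificant_undefined(self):
        pre, post = simulate_coupled_pair(600.0, 1.0, 10.0, 0.0, seed=10)
        assert np.isnan(cp.latency(cp.build_ccg(pre, post)))


class TestCoincidence:
    def test_identical_trains_unity_at_zero(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 100, 500))
        lags, coef = cp.coincidence_corrcoef(t, t, epochs=[(0, 100)])
        assert coef[np.argmin(np.abs(lags))] == pytest.approx(1.0)

    def test_independent_pair_near_zero(self):
        pre, post = simulate_coupled_pair(600.0, 2.0, 10.0, 0.0, seed=12)
        lags, coef = cp.coincidence_corrcoef(pre, post, epochs=[(0, 600)])
        nbins = 600.0 / (cp.BIN_MS / 1000.0)
        assert np.max(np.abs(coef)) < 4.0 / np.sqrt(nbins)

    def test_thinning_scaling_of_both_measures(self):
        # thinning both trains by 50% halves the per-reference transmission
        # estimate; the Pearson-normalized coincidence peak, whose expected
        # value is w*sqrt(rate_pre/rate_post) for sparse bins, also halves
        # (w -> w/2 while the rate ratio is preserved)
        pre, post = simulate_coupled_pair(3000.0, 4.0, 16.0, 0.4, seed=13)
        rng = np.random.default_rng(14)
        pre_t = pre[rng.random(len(pre)) < 0.5]
        post_t = post[rng.random(len(post)) < 0.5]
        tr_full = cp.transmission(cp.build_ccg(pre, post)).prob
        tr_thin = cp.transmission(cp.build_ccg(pre_t, post_t)).prob
        assert tr_thin == pytest.approx(0.5 * tr_full, rel=0.25)
        _, c_full = cp.coincidence_corrcoef(pre, post, epochs=[(0, 3000)])
        _, c_thin = cp.coincidence_corrcoef(pre_t, post_t,
                                            epochs=[(0, 3000)])
        assert c_thin.max() == pytest.approx(0.5 * c_full.max(), rel=0.35)

    def test_coincidence_symmetric_in_rate_scale(self):
        # unlike transmission, the coefficient does not depend on which
        # train is designated reference
        pre, post = simulate_coupled_pair(1000.0, 4.0, 16.0, 0.3, seed=18)
        _, fwd = cp.coincidence_corrcoef(pre, post, epochs=[(0, 1000)])
        _, rev = cp.coincidence_corrcoef(post, pre, epochs=[(0, 1000)])
        assert fwd.max() == pytest.approx(rev.max(), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cp.coincidence_corrcoef([1.0], [], epochs=[(0, 10)])


class TestTrackEpochs:
    def w_ramp(self, w0, w1, lo, hi):
        def w(t):
            f = np.clip((np.asarray(t) - lo) / (hi - lo), 0, 1)
            return w0 + (w1 - w0) * f
        return w

    def epochs(self):
        return {
            "preprobe": [(0.0, 500.0)], "presleep": [(500.0, 1000.0)],
            "q1": [(1000.0, 1150.0)], "q2": [(1150.0, 1300.0)],
            "q3": [(1300.0, 1450.0)], "q4": [(1450.0, 1600.0)],
            "postsleep": [(1600.0, 2100.0)], "postprobe": [(2100.0, 2600.0)],
        }

    def test_learning_restricted_drift_recovered(self):
        w = self.w_ramp(0.05, 0.15, 1000.0, 1600.0)
        pre, post = simulate_coupled_pair(2600.0, 3.0, 10.0, w, seed=15)
        pair = cp.track_epochs(pre, post, 0, 1, self.epochs())
        assert pair.significant
        assert pair.deltas["transmission_probes"] == pytest.approx(0.10,
                                                                   abs=0.025)
        assert pair.deltas["transmission_sleeps"] == pytest.approx(0.10,
                                                                   abs=0.025)
        # quartile means of the ramp: q1 ~ 0.0625, q4 ~ 0.1375
        assert pair.deltas["transmission_learning"] == pytest.approx(0.075,
                                                                     abs=0.03)

    def test_constant_weight_null_deltas(self):
        pre, post = simulate_coupled_pair(2600.0, 3.0, 10.0, 0.1, seed=16)
        pair = cp.track_epochs(pre, post, 0, 1, self.epochs())
        for key in ("transmission_probes", "transmission_sleeps",
                    "transmission_learning"):
            assert abs(pair.deltas[key]) < 0.03

    def test_low_count_epoch_excluded_from_deltas(self):
        pre, post = simulate_coupled_pair(2600.0, 3.0, 10.0, 0.1, seed=17)
        eps = self.epochs()
        eps["preprobe"] = [(0.0, 10.0)]     # ~30 ref spikes -> low count
        pair = cp.track_epochs(pre, post, 0, 1, eps)
        assert pair.epochs["preprobe"].low_count
        assert np.isnan(pair.deltas["transmission_probes"])


class TestLearningQuartiles:
    def test_equal_total_time(self):
        trials = [(float(i * 10), float(i * 10 + 8)) for i in range(10)]
        q = cp.learning_quartiles(trials)
        durs = [np.sum(iv[:, 1] - iv[:, 0]) for iv in q.values()]
        assert np.allclose(durs, 20.0)
        total = np.vstack(list(q.values()))
        assert np.sum(total[:, 1] - total[:, 0]) == pytest.approx(80.0)
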
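"""Estimator-recovery benchmarks on synthetic ground truth.

Every analysis in the package has a latent target in the generator; the
functions here run the full estimation path on freshly simulated data and
measure how well the targets are recovered: transmission-probability and
latency recovery on coupled pairs, monosynaptic detection error rates on
independent and weakly coupled pairs, per-cycle map-state decoding and
interneuron classification on a full simulated day, and directional
ensemble checks (probe vs sleep transmission deltas, latency-probability
coupling, pairing-count dependence of the weight change).
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from . import association, predictors
from .coupling import (build_ccg, detect_mono, latency, track_epochs,
                       transmission)
from .pipeline import Pipeline, PipelineConfig, decoding_accuracy
from .synthetic import (SimConfig, evoked_spikes, poisson_times,
                        simulate_coupled_pair)

PRE_RATE_HZ = 2.0        # typical active pyramidal cell
POST_RATE_HZ = 10.0      # typical interneuron baseline
DELAY_MS = 1.5
JITTER_MS = 0.2


# ---------------------------------------------------------------------------
# pair-level recovery
# ---------------------------------------------------------------------------

def pair_recovery(w_values, n_pairs_each, duration_s, seed,
                  pre_rate=PRE_RATE_HZ, post_rate=POST_RATE_HZ,
                  delay_ms=DELAY_MS, jitter_ms=JITTER_MS) -> pd.DataFrame:
    """Transmission/latency estimates on simulated pairs of known weight."""
    ss = np.random.SeedSequence([seed, 101])
    rows = []
    seeds = ss.spawn(len(list(w_values)) * n_pairs_each)
    k = 0
    for w in w_values:
        for _ in range(n_pairs_each):
            pre, post = simulate_coupled_pair(
                duration_s, pre_rate, post_rate, w,
                delay_ms=delay_ms, jitter_ms=jitter_ms, seed=seeds[k])
            k += 1
            ccg = build_ccg(pre, post)
            det = detect_mono(ccg)
            rows.append({
                "w_true": w, "n_pre": len(pre),
                "transmission": transmission(ccg).prob,
                "latency_ms": latency(ccg, require_significant=False),
                "significant": det.significant,
            })
    df = pd.DataFrame(rows)
    df["error"] = df.transmission - df.w_true
    df["latency_error_ms"] = df.latency_ms - delay_ms
    return df


def latency_shift_recovery(n_pairs, shift_ms, duration_s, seed,
                           w=0.15) -> float:
    """Fraction of pairs whose estimated latency change across two epochs
    recovers the sign of an injected ±``shift_ms`` delay shift."""
    correct = 0
    for i in range(n_pairs):
        s = shift_ms if i % 2 == 0 else -shift_ms
        pre_a, post_a = simulate_coupled_pair(
            duration_s, PRE_RATE_HZ, POST_RATE_HZ, w, delay_ms=DELAY_MS,
            jitter_ms=JITTER_MS, seed=np.random.SeedSequence(
                [seed, 102, i, 0]))
        pre_b, post_b = simulate_coupled_pair(
            duration_s, PRE_RATE_HZ, POST_RATE_HZ, w, delay_ms=DELAY_MS + s,
            jitter_ms=JITTER_MS, seed=np.random.SeedSequence(
                [seed, 102, i, 1]))
        la = latency(build_ccg(pre_a, post_a), require_significant=False)
        lb = latency(build_ccg(pre_b, post_b), require_significant=False)
        if np.isfinite(la) and np.isfinite(lb) and np.sign(lb - la) == np.sign(s):
            correct += 1
    return correct / n_pairs


def detection_rates(n_null, n_connected, duration_s, seed, w_connected=0.05,
                    null_pre_rate=1.0, null_post_rate=10.0,
                    conn_pre_rate=2.0) -> dict:
    """Monosynaptic detection error rates.

    False positives over independent Poisson pairs; sensitivity over weakly
    coupled pairs (w = 0.05).
    """
    fp = 0
    for i in range(n_null):
        pre, post = simulate_coupled_pair(
            duration_s, null_pre_rate, null_post_rate, 0.0,
            seed=np.random.SeedSequence([seed, 103, i]))
        fp += int(detect_mono(build_ccg(pre, post)).significant)
    hits = 0
    for i in range(n_connected):
        pre, post = simulate_coupled_pair(
            duration_s, conn_pre_rate, null_post_rate, w_connected,
            seed=np.random.SeedSequence([seed, 104, i]))
        hits += int(detect_mono(build_ccg(pre, post)).significant)
    return {
        "false_positive_rate": fp / n_null,
        "sensitivity": hits / n_connected,
        "n_null": n_null, "n_connected": n_connected,
    }


# ---------------------------------------------------------------------------
# full-day recovery (decoding, interneuron classification)
# ---------------------------------------------------------------------------

def benchmark_config(seed: int) -> SimConfig:
    """Simulated-day conditions for the recovery benchmarks: a median-sized
    ensemble of 40 pyramidal cells, 24 interneurons (8 per association
    class), 40 trials, probes/rests shortened so a run takes about a
    minute."""
    return SimConfig(n_pyr=40, n_int=24, n_trials=40, trial_duration=30.0,
                     probe_duration=400.0, rest_duration=150.0,
                     intertrial_gap=4.0, seed=seed)


def session_recovery(seed, config: SimConfig | None = None,
                     out_dir: str | None = None,
                     n_uncoupled_units: int = 200) -> dict:
    """Run the full pipeline on one simulated day and score recovery.

    Returns decoding accuracy (all valid cycles, and cycles with >= 10
    active cells), the interneuron classification confusion counts and
    sensitivities, the type-I rate of the association screen over
    ``n_uncoupled_units`` extra independent-Poisson units, and the
    rate-change indices per true class.
    """
    if config is None:
        config = benchmark_config(seed)
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="cheeseboard_bench_")
    pcfg = PipelineConfig(out_dir=out_dir, seed=config.seed, sim=config)
    pipe = Pipeline(pcfg)
    products = pipe.run(force=True)
    truth = pipe.truth
    b = pipe.bundle
    expr = products["expr"]

    out: dict = {
        "decoding_all": decoding_accuracy(expr, truth),
        "decoding_10active": decoding_accuracy(expr, truth, min_active=10),
    }

    # interneuron classification vs truth
    assoc = products["associations"]
    ints = assoc[assoc["class"].isin(["pInt", "nInt", "uInt"])]
    pred = {int(u): c for u, c in zip(ints.unit_id, ints["class"])}
    sens = {}
    for cls in ("pInt", "nInt"):
        members = [u for u, c in truth.int_class.items() if c == cls]
        hit = sum(pred.get(u) == cls for u in members)
        sens[cls] = {"n": len(members), "recovered": hit,
                     "sensitivity": hit / len(members) if members else None}
    out["int_sensitivity"] = sens

    # type-I rate: independent homogeneous units against the same z series
    window = association.last_trials_window(expr, b.trial_intervals(),
                                            pcfg.last_n_trials)
    tcyc = products["cycles"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 105]))
    false_pos = 0
    lo, hi = float(tcyc.min()), float(tcyc.max())
    for _ in range(n_uncoupled_units):
        st = np.sort(rng.uniform(lo, hi, size=rng.poisson(
            POST_RATE_HZ * (hi - lo))))
        ifr = association.instantaneous_rates(st, tcyc)
        res = association.associate(ifr, expr, window)
        false_pos += int(res.cls != "uInt")
    out["uncoupled_type1"] = {"n": n_uncoupled_units, "false_pos": false_pos,
                              "rate": false_pos / n_uncoupled_units}

    # rate-change index sign by true class
    span = (float(b.trial_intervals()[:, 0].min()),
            float(b.trial_intervals()[:, 1].max()))
    win = min(600.0, (span[1] - span[0]) / 2.0)
    idx_by_class: dict = {"pInt": [], "nInt": [], "uInt": []}
    for u, cls in truth.int_class.items():
        r = association.rate_change(b.spike_times(u), span, u, window_s=win)
        if np.isfinite(r.index):
            idx_by_class[cls].append(r.index)
    out["rate_change_index"] = {
        cls: {"n": len(v), "mean": float(np.mean(v)) if v else None,
              "n_positive": int(np.sum(np.asarray(v) > 0))}
        for cls, v in idx_by_class.items()
    }
    out["_products"] = products
    out["_truth"] = truth
    out["_pipe"] = pipe
    return out


# ---------------------------------------------------------------------------
# ensemble directional checks
# ---------------------------------------------------------------------------

_EPOCHS = {
    "preprobe": [(0.0, 600.0)],
    "presleep": [(600.0, 1200.0)],
    "q1": [(1200.0, 1350.0)], "q2": [(1350.0, 1500.0)],
    "q3": [(1500.0, 1650.0)], "q4": [(1650.0, 1800.0)],
    "postsleep": [(1800.0, 2400.0)],
    "postprobe": [(2400.0, 3000.0)],
}


def _ramp_w(w0, w1, lo=1200.0, hi=1800.0):
    def w(t):
        frac = np.clip((np.asarray(t) - lo) / (hi - lo), 0.0, 1.0)
        return w0 + (w1 - w0) * frac
    return w


def ensemble_deltas(n_pairs, seed, couple_latency=True,
                    latency_slope_ms=1.0) -> pd.DataFrame:
    """Pairs whose weight drifts during a 'learning' span only; per-pair
    transmission/latency deltas across probe and sleep epochs."""
    rows = []
    for i in range(n_pairs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 106, i]))
        w0 = rng.uniform(0.05, 0.30)
        w1 = float(np.clip(w0 + rng.uniform(-0.15, 0.15), 0.01, 0.5))
        wfun = _ramp_w(w0, w1)
        if couple_latency:
            def dfun(t, w0=w0, wfun=wfun):
                return np.clip(DELAY_MS - latency_slope_ms * (wfun(t) - w0),
                               0.7, 2.3)
        else:
            dfun = DELAY_MS
        pre, post = simulate_coupled_pair(
            3000.0, PRE_RATE_HZ, POST_RATE_HZ, wfun, delay_ms=dfun,
            jitter_ms=JITTER_MS, seed=np.random.SeedSequence([seed, 107, i]))
        pair = track_epochs(pre, post, i, 1000 + i, _EPOCHS)
        rows.append({
            "w0": w0, "w1": w1, "dw": w1 - w0,
            "significant": pair.significant,
            **pair.deltas,
        })
    return pd.DataFrame(rows)


def pairing_dependence(n_pairs, seed, w0=0.02, dw_per_event=None,
                       dw_max=0.30) -> pd.DataFrame:
    """Plant a weight change proportional to the pairing-event count.

    Baseline pre/post trains for the learning span are drawn first, the
    20 ms pairing events counted on them, and the weight change set
    proportional to that count; probes before/after measure the realized
    transmission change.
    """
    # first pass: baseline counts, to calibrate the proportionality constant
    metas = []
    for i in range(n_pairs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 108, i]))
        pre_rate = rng.uniform(0.5, 4.0)
        s_pre = np.random.SeedSequence([seed, 109, i, 0])
        s_post = np.random.SeedSequence([seed, 109, i, 1])
        pre_learn = poisson_times(pre_rate, [(600.0, 1200.0)],
                                  np.random.default_rng(s_pre))
        post_learn = poisson_times(POST_RATE_HZ, [(600.0, 1200.0)],
                                   np.random.default_rng(s_post))
        summ = predictors.pairing_events(pre_learn, post_learn,
                                         [(600.0, 1200.0)])
        count = summ.n_pre_window + summ.n_post_window
        metas.append((pre_rate, pre_learn, post_learn, count))
    max_count = max(m[3] for m in metas)
    c = dw_per_event if dw_per_event is not None else dw_max / max_count

    rows = []
    for i, (pre_rate, pre_learn, post_learn, count) in enumerate(metas):
        dw = c * count
        rng = np.random.default_rng(np.random.SeedSequence([seed, 110, i]))
        pre_pre = poisson_times(pre_rate, [(0.0, 600.0)], rng)
        pre_post = poisson_times(pre_rate, [(1200.0, 1800.0)], rng)
        post_pre = poisson_times(POST_RATE_HZ, [(0.0, 600.0)], rng)
        post_post = poisson_times(POST_RATE_HZ, [(1200.0, 1800.0)], rng)
        pre_all = np.sort(np.concatenate([pre_pre, pre_learn, pre_post]))
        wfun = _ramp_w(w0, w0 + dw, lo=600.0, hi=1200.0)
        ev = evoked_spikes(pre_all, wfun(pre_all), DELAY_MS, JITTER_MS, rng)
        post_all = np.sort(np.concatenate(
            [post_pre, post_learn, post_post, ev]))
        t_probe_pre = build_ccg(pre_all, post_all, epochs=[(0.0, 600.0)])
        t_probe_post = build_ccg(pre_all, post_all, epochs=[(1200.0, 1800.0)])
        # recount pairing on the realized trains (evoked spikes included)
        summ = predictors.pairing_events(pre_all, post_all,
                                         [(600.0, 1200.0)])
        rows.append({
            "pre_rate": pre_rate, "dw": dw,
            "n_pre_window": summ.n_pre_window,
            "n_post_window": summ.n_post_window,
            "delta_transmission": (transmission(t_probe_post).prob
                                   - transmission(t_probe_pre).prob),
        })
    return pd.DataFrame(rows)
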
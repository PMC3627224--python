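"""Predictors of pyramidal→interneuron connection change.

Three candidate drivers of the learning-related change in spike transmission
probability are quantified per pair: (1) pairing events — presynaptic spikes
preceded and/or followed by a postsynaptic interneuron spike within 20 ms,
counted during the theta epochs of learning and positioned on the track so
they can be split into inside vs outside the goal areas; (2) the
interneuron's spike density (Gaussian kernel, σ = 20 ms) sampled at
presynaptic spike times, raw and normalized by the interneuron's mean rate;
(3) running speed at those times, retained as a partial-correlation control.
``predictor_analysis`` relates the per-pair transmission change to these
predictors with Pearson and residualization-based partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import as_intervals, restrict

PAIRING_WINDOW_S = 0.020
DENSITY_SIGMA_S = 0.020
GOAL_RADIUS_CM = 20.0


@dataclass
class PairingSummary:
    pre_id: int
    post_id: int
    n_pre_window: int        # pre spikes preceded by a post spike within 20 ms
    n_post_window: int       # pre spikes followed within 20 ms
    events: pd.DataFrame     # t, x, y, preceded, followed, inside_goal


def pairing_events(pre, post, epochs, track=None, goals=(),
                   radius=GOAL_RADIUS_CM, window=PAIRING_WINDOW_S,
                   pre_id=-1, post_id=-1) -> PairingSummary:
    """Count pairing events during theta epochs of learning.

    For each presynaptic spike t the open intervals (t-20 ms, t) and
    (t, t+20 ms) are tested for any postsynaptic spike (exact coincidences
    excluded); counts are kept separately, and each event is positioned by
    interpolating the track at t and classified inside/outside the goal
    areas.
    """
    epochs = as_intervals(epochs)
    if epochs.size == 0:
        raise ValueError("epochs must be nonempty")
    pre_e = restrict(np.asarray(pre, dtype=float), epochs)
    post = np.asarray(post, dtype=float)

    lo = np.searchsorted(post, pre_e - window, side="right")
    at = np.searchsorted(post, pre_e, side="left")
    after = np.searchsorted(post, pre_e, side="right")
    hi = np.searchsorted(post, pre_e + window, side="left")
    preceded = lo < at          # any post strictly inside (t-w, t)
    followed = after < hi       # any post strictly inside (t, t+w)

    if track is not None and len(pre_e):
        x = np.interp(pre_e, track.time, track.x)
        y = np.interp(pre_e, track.time, track.y)
    else:
        x = np.full(len(pre_e), np.nan)
        y = np.full(len(pre_e), np.nan)
    goals = np.asarray(goals, dtype=float).reshape(-1, 2)
    if goals.size:
        d = np.min(np.hypot(x[:, None] - goals[None, :, 0],
                            y[:, None] - goals[None, :, 1]), axis=1)
        inside = d <= radius
    else:
        inside = np.zeros(len(pre_e), dtype=bool)

    any_pair = preceded | followed
    events = pd.DataFrame({
        "t": pre_e[any_pair], "x": x[any_pair], "y": y[any_pair],
        "preceded": preceded[any_pair], "followed": followed[any_pair],
        "inside_goal": inside[any_pair],
    })
    return PairingSummary(pre_id, post_id, int(preceded.sum()),
                          int(followed.sum()), events)


def goal_split(summary: PairingSummary) -> tuple[int, int]:
    """(n_inside, n_outside) pairing events; totals are conserved."""
    n_in = int(summary.events.inside_goal.sum())
    return n_in, len(summary.events) - n_in


class SpikeDensity:
    """Continuous spike density: sum of unit-integral Gaussian kernels (Hz).

    Evaluated by exact kernel summation over spikes within ±8σ of the query
    (the truncated tail is below double precision at that range).
    """

    def __init__(self, spike_times, sigma=DENSITY_SIGMA_S):
        if sigma <= 0:
            raise ValueError("kernel width must be positive")
        self.spikes = np.sort(np.asarray(spike_times, dtype=float))
        self.sigma = float(sigma)
        self._norm = 1.0 / (self.sigma * np.sqrt(2 * np.pi))

    def __call__(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty(len(t))
        reach = 8 * self.sigma
        lo = np.searchsorted(self.spikes, t - reach)
        hi = np.searchsorted(self.spikes, t + reach)
        for i, (q, a, b) in enumerate(zip(t, lo, hi)):
            d = self.spikes[a:b] - q
            out[i] = self._norm * np.exp(-0.5 * (d / self.sigma) ** 2).sum()
        return out if out.shape != (1,) else float(out[0])


def spike_density(spike_times, sigma=DENSITY_SIGMA_S) -> SpikeDensity:
    return SpikeDensity(spike_times, sigma)


@dataclass
class DensitySummary:
    pre_id: int
    post_id: int
    mean_density: float          # Hz at pre spike times
    normalized_density: float    # / interneuron mean rate
    mean_speed: float            # cm/s at those times
    flag: str = ""


def density_at_pre_spikes(density: SpikeDensity, pre_spikes, post_mean_rate,
                          speed_t=None, speed=None, pre_id=-1, post_id=-1
                          ) -> DensitySummary:
    """Mean (and rate-normalized) interneuron spike density at presynaptic
    spike times, plus mean running speed there (partial-correlation
    control)."""
    pre = np.asarray(pre_spikes, dtype=float)
    if len(pre) < 10:
        raise ValueError("need at least 10 presynaptic spikes")
    dens = np.atleast_1d(density(pre))
    mean_d = float(np.mean(dens))
    if post_mean_rate > 0:
        norm, flag = mean_d / post_mean_rate, ""
    else:
        norm, flag = float("nan"), "zero_post_rate"
    sp = float(np.mean(np.interp(pre, speed_t, speed))) \
        if speed_t is not None else float("nan")
    return DensitySummary(pre_id, post_id, mean_d, norm, sp, flag)


def _pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan"), float("nan"), int(ok.sum())
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), int(ok.sum())


def partial_correlation(x, y, control):
    """Correlation of x and y after regressing the control out of both."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    c = np.asarray(control, float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    if ok.sum() < 4 or np.std(c[ok]) == 0:
        return float("nan"), float("nan")
    A = np.stack([np.ones(ok.sum()), c[ok]], axis=1)
    rx = x[ok] - A @ np.linalg.lstsq(A, x[ok], rcond=None)[0]
    ry = y[ok] - A @ np.linalg.lstsq(A, y[ok], rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(rx, ry)
    return float(r), float(p)


def _slope_and_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0:
        return float("nan"), float("nan"), int(ok.sum())
    slope = float(np.polyfit(x[ok], y[ok], 1)[0])
    r, _, n = _pearson(x[ok], y[ok])
    return slope, r, n


def predictor_analysis(table: pd.DataFrame) -> dict:
    """Correlation report relating per-pair transmission change to its
    predictors.

    ``table`` columns: delta_transmission, n_pre_window, n_post_window,
    n_inside, n_outside, mean_density, optional mean_speed and
    goal_centric_pre.  Returns a JSON-serializable nested dict with Pearson
    correlations, partial correlations of density controlling for pairing
    count and for speed, and a goal-centric vs non-goal-centric regression
    slope comparison (Fisher z on the correlations).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 pairs")
    d = table.delta_transmission.to_numpy()
    report: dict = {"n_pairs": int(len(table)), "correlations": {}}
    for col in ("n_pre_window", "n_post_window", "n_inside", "n_outside",
                "mean_density"):
        if col not in table:
            continue
        x = table[col].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            report["correlations"][col] = {"r": None, "p": None,
                                           "flag": "constant_predictor"}
            continue
        r, p, n = _pearson(x, d)
        report["correlations"][col] = {"r": r, "p": p, "n": n}

    if "mean_density" in table:
        pairing_total = (table.n_pre_window + table.n_post_window).to_numpy(float)
        r, p = partial_correlation(table.mean_density.to_numpy(float), d,
                                   pairing_total)
        report["partial_density_given_pairing"] = {"r": r, "p": p}
        if "mean_speed" in table:
            r, p = partial_correlation(table.mean_density.to_numpy(float), d,
                                       table.mean_speed.to_numpy(float))
            report["partial_density_given_speed"] = {"r": r, "p": p}

    if "goal_centric_pre" in table:
        g = table.goal_centric_pre.to_numpy(dtype=bool)
        tot = (table.n_pre_window + table.n_post_window).to_numpy(float)
        s1, r1, n1 = _slope_and_r(tot[g], d[g])
        s0, r0, n0 = _slope_and_r(tot[~g], d[~g])
        if n1 > 3 and n0 > 3 and np.isfinite(r1) and np.isfinite(r0):
            z = (np.arctanh(np.clip(r1, -0.999999, 0.999999))
                 - np.arctanh(np.clip(r0, -0.999999, 0.999999))) \
                / np.sqrt(1 / (n1 - 3) + 1 / (n0 - 3))
        else:
            z = float("nan")
        report["goal_centric_slopes"] = {
            "slope_goal": s1, "slope_nongoal": s0,
            "r_goal": r1, "r_nongoal": r0, "fisher_z": float(z),
        }
    return report
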
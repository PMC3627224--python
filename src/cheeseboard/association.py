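"""Firing associations of single units to assembly-expression scores.

Each unit's instantaneous firing rate (IFR: spike count / duration per theta
cycle) is correlated (Pearson) with the per-cycle assembly expression score
z over a classification window (default: the last 10 learning trials, late
enough that associations are established).  Interneurons are classed pInt
(r > 0, p < 0.05), nInt (r < 0, p < 0.05) or uInt; the same screen applied
to pyramidal cells (with their own cell excluded from the population vector
upstream) yields assembly membership.  A logistic regression of the
new-map indicator (z > 0) on the IFR confirms the association (Wald
|z| > 1.960); it is reported, not used for class assignment.  p-values are
uncorrected, matching the screen this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
WALD_CRITICAL = 1.960
MIN_PAIRED_CYCLES = 30
LAST_N_TRIALS = 10


def instantaneous_rates(spike_times, cycles) -> np.ndarray:
    """Per-cycle firing rate in Hz (count / cycle duration)."""
    cycles = np.asarray(cycles, dtype=float).reshape(-1, 2)
    st = np.asarray(spike_times, dtype=float)
    counts = np.searchsorted(st, cycles[:, 1]) - np.searchsorted(st, cycles[:, 0])
    return counts / (cycles[:, 1] - cycles[:, 0])


@dataclass
class AssociationResult:
    unit_id: int
    r: float
    p_value: float
    cls: str                 # pInt / nInt / uInt (or pos/neg/none upstream)
    wald_z: float
    n_cycles: int
    flag: str = ""


def _logistic_wald(ifr, z):
    """Wald statistic of the IFR coefficient in logit(P(z>0)) ~ IFR."""
    import statsmodels.api as sm
    y = (z > 0).astype(float)
    if y.min() == y.max() or np.std(ifr) == 0:
        return float("nan")
    X = sm.add_constant(np.asarray(ifr, dtype=float))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return float(fit.tvalues[1])
    except Exception:
        return float("nan")


def associate(ifr, expr: pd.DataFrame, window=None, unit_id=-1,
              min_cycles=MIN_PAIRED_CYCLES) -> AssociationResult:
    """Pearson IFR-z association over valid cycles in a window.

    ``ifr`` is aligned with ``expr`` rows (one entry per cycle).  ``window``
    is an optional boolean mask or interval set restricting cycles (e.g. the
    last 10 learning trials).  Invalid cycles are dropped pairwise.
    """
    ifr = np.asarray(ifr, dtype=float)
    if len(ifr) != len(expr):
        raise ValueError("ifr and expression series must align")
    keep = expr.valid.to_numpy() & np.isfinite(expr.z.to_numpy())
    if window is not None:
        window = np.asarray(window)
        if window.dtype == bool:
            keep &= window
        else:
            from .core import in_intervals
            keep &= in_intervals(expr.t_mid.to_numpy(), window)
    x = ifr[keep]
    z = expr.z.to_numpy()[keep]
    n = len(x)
    if n < min_cycles:
        raise ValueError(
            f"only {n} valid paired cycles in window (need >= {min_cycles})"
        )
    if np.std(x) == 0:
        return AssociationResult(unit_id, float("nan"), float("nan"), "uInt",
                                 float("nan"), n, flag="constant_ifr")
    r, p = stats.pearsonr(x, z)
    if p < ALPHA and r > 0:
        cls = "pInt"
    elif p < ALPHA and r < 0:
        cls = "nInt"
    else:
        cls = "uInt"
    return AssociationResult(unit_id, float(r), float(p), cls,
                             _logistic_wald(x, z), n)


def last_trials_window(expr: pd.DataFrame, trial_intervals,
                       n_trials=LAST_N_TRIALS) -> np.ndarray:
    """Boolean mask selecting cycles in the last n learning trials."""
    iv = np.asarray(trial_intervals, dtype=float).reshape(-1, 2)
    iv = iv[np.argsort(iv[:, 0])][-n_trials:]
    from .core import in_intervals
    return in_intervals(expr.t_mid.to_numpy(), iv)


@dataclass
class RateChangeIndex:
    unit_id: int
    rate_first: float     # Hz, first 10 min of learning
    rate_last: float      # Hz, last 10 min
    index: float          # (last - first) / (last + first), in [-1, 1]


def rate_change(spike_times, learning_span, unit_id=-1,
                window_s=600.0) -> RateChangeIndex:
    """Rate-change index across learning: (last - first)/(last + first)
    over the first and last 10 min.  NaN when the unit is silent in both."""
    lo, hi = float(learning_span[0]), float(learning_span[1])
    if hi - lo < 2 * window_s:
        raise ValueError("learning period shorter than two rate windows")
    st = np.asarray(spike_times, dtype=float)
    n_first = np.searchsorted(st, lo + window_s) - np.searchsorted(st, lo)
    n_last = np.searchsorted(st, hi) - np.searchsorted(st, hi - window_s)
    r1, r2 = n_first / window_s, n_last / window_s
    idx = float("nan") if r1 + r2 == 0 else (r2 - r1) / (r2 + r1)
    return RateChangeIndex(unit_id, r1, r2, idx)


def swr_rate_histogram(spike_times, swr_peaks, bin_s=0.020, span_s=0.5):
    """Event-triggered firing-rate histogram around SWR power peaks.

    Returns (bin_centers, rate_hz): average rate per 20 ms bin over
    [-span, +span] relative to each event peak.
    """
    peaks = np.asarray(swr_peaks, dtype=float)
    if len(peaks) < 10:
        raise ValueError("need at least 10 SWR events")
    st = np.asarray(spike_times, dtype=float)
    nbins = int(round(2 * span_s / bin_s))
    edges = -span_s + bin_s * np.arange(nbins + 1)
    counts = np.zeros(nbins)
    for p in peaks:
        rel = st[(st >= p - span_s) & (st < p + span_s)] - p
        counts += np.histogram(rel, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / (len(peaks) * bin_s)
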
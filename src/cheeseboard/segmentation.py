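"""Behavioral-state segmentation and oscillatory event detection from LFP.

Sessions are split into exploration vs rest using running speed and the
theta/delta power ratio (multitaper, 1600 ms windows stepped by 800 ms):
rest requires speed < 5 cm/s and ratio < 2 sustained for at least 2.4 s (two
consecutive windows); shorter immobility is bridged into exploration.
Individual theta cycles are delimited by successive negative peaks of the
5–28 Hz filtered trace (the wide band keeps peak times sharp) and kept only
when their implied frequency lies in the 5–12 Hz theta band.  Gamma cycles
use a 30–80 Hz band; sharp wave/ripples (SWRs) are detected as 150–250 Hz
power excursions beyond mean + 7 SD of the rest background, with the
threshold set on the first rest session and reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import as_intervals, in_intervals, intersect_intervals

SPEED_THRESHOLD = 5.0        # cm/s
RATIO_THRESHOLD = 2.0
MIN_REST_S = 2.4             # two consecutive multitaper windows
THETA_BAND = (5.0, 12.0)
DELTA_BAND = (2.0, 4.0)
THETA_FILTER_BAND = (5.0, 28.0)   # wide band for sharp negative-peak times
GAMMA_BAND = (30.0, 80.0)
RIPPLE_BAND = (150.0, 250.0)
SWR_THRESHOLD_SD = 7.0


def theta_delta_ratio(lfp, fs, window_s=1.6, step_s=0.8, nw=3.0, t0=0.0):
    """Theta (5–12 Hz) over delta (2–4 Hz) multitaper power per window.

    Returns (t_centers, ratio).  Traces shorter than one window yield an
    empty series with a warning.
    """
    lfp = np.asarray(lfp, dtype=float)
    if fs < 250:
        raise ValueError("sampling rate must be >= 250 Hz")
    nwin = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if len(lfp) < nwin:
        warnings.warn("trace shorter than one analysis window; empty ratio series")
        return np.empty(0), np.empty(0)
    tapers = signal.windows.dpss(nwin, nw, Kmax=int(2 * nw - 1))
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    th = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    de = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    starts = np.arange(0, len(lfp) - nwin + 1, step)
    centers = t0 + (starts + nwin / 2) / fs
    ratio = np.empty(len(starts))
    for i, s in enumerate(starts):
        seg = lfp[s:s + nwin]
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        psd = spec.mean(axis=0)
        ratio[i] = psd[th].sum() / max(psd[de].sum(), 1e-300)
    return centers, ratio


@dataclass
class StateIntervals:
    """Exploration/rest partition of a session (plus uncovered spans)."""

    intervals: pd.DataFrame     # label in {exploration, rest}, t_start, t_end
    unlabeled: np.ndarray       # (n, 2) spans not covered by both inputs

    def of(self, label: str) -> np.ndarray:
        df = self.intervals[self.intervals.label == label]
        return as_intervals(df[["t_start", "t_end"]].to_numpy()) if len(df) \
            else np.empty((0, 2))


def segment_states(ratio_t, ratio, speed_t, speed, window_s=1.6, step_s=0.8
                   ) -> StateIntervals:
    """Label time as rest (immobile + low theta/delta, sustained >= 2.4 s)
    or exploration (everything else within coverage).

    Spans outside the joint coverage of the two series are reported as
    unlabeled, never silently filled.
    """
    ratio_t = np.asarray(ratio_t, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    speed_t = np.asarray(speed_t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if len(ratio_t) == 0 or len(speed_t) == 0:
        raise ValueError("both series must be non-empty")

    lo = max(ratio_t[0] - window_s / 2, speed_t[0])
    hi = min(ratio_t[-1] + window_s / 2, speed_t[-1])
    session = (min(ratio_t[0] - window_s / 2, speed_t[0]),
               max(ratio_t[-1] + window_s / 2, speed_t[-1]))
    unlabeled = []
    if lo > session[0]:
        unlabeled.append((session[0], lo))
    if hi < session[1]:
        unlabeled.append((hi, session[1]))

    sp_w = np.interp(ratio_t, speed_t, speed)
    rest_flag = (sp_w < SPEED_THRESHOLD) & (ratio < RATIO_THRESHOLD)

    win_start = ratio_t - window_s / 2
    win_end = ratio_t + window_s / 2
    rest_spans = []
    i = 0
    while i < len(rest_flag):
        if rest_flag[i]:
            j = i
            while j + 1 < len(rest_flag) and rest_flag[j + 1]:
                j += 1
            if j > i:  # >= two consecutive windows -> >= 2.4 s
                rest_spans.append((max(win_start[i], lo), min(win_end[j], hi)))
            i = j + 1
        else:
            i += 1
    rest_spans = [s for s in rest_spans if s[1] - s[0] >= MIN_REST_S - 1e-9]

    rows = []
    cursor = lo
    for s, e in rest_spans:
        if s > cursor:
            rows.append(("exploration", cursor, s))
        rows.append(("rest", s, e))
        cursor = e
    if hi > cursor:
        rows.append(("exploration", cursor, hi))
    return StateIntervals(
        intervals=pd.DataFrame(rows, columns=["label", "t_start", "t_end"]),
        unlabeled=as_intervals(np.array(unlabeled).reshape(-1, 2)
                               if unlabeled else np.empty((0, 2))),
    )


def _bandpass(lfp, fs, band, order=3):
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, lfp)   # zero-phase


def _negative_peak_cycles(lfp, fs, band, valid_freq, intervals, t0=0.0):
    filt = _bandpass(np.asarray(lfp, dtype=float), fs, band)
    peaks, _ = signal.find_peaks(-filt)
    tp = t0 + peaks / fs
    cycles = []
    for lo, hi in as_intervals(intervals):
        inside = tp[(tp >= lo) & (tp <= hi)]
        if len(inside) < 2:
            continue
        dur = np.diff(inside)
        ok = (dur >= 1.0 / valid_freq[1]) & (dur <= 1.0 / valid_freq[0])
        cycles.append(np.stack([inside[:-1][ok], inside[1:][ok]], axis=1))
    if not cycles:
        return np.empty((0, 2))
    return np.concatenate(cycles, axis=0)


def detect_theta_cycles(lfp, fs, exploration_intervals, t0=0.0) -> np.ndarray:
    """Theta cycles as spans between successive negative peaks of the
    zero-phase 5–28 Hz filtered LFP, keeping durations implying 5–12 Hz."""
    return _negative_peak_cycles(lfp, fs, THETA_FILTER_BAND, THETA_BAND,
                                 exploration_intervals, t0)


def detect_gamma_cycles(lfp, fs, intervals, t0=0.0) -> np.ndarray:
    """Gamma cycles from the 30–80 Hz band, durations implying 30–80 Hz."""
    return _negative_peak_cycles(lfp, fs, GAMMA_BAND, GAMMA_BAND, intervals, t0)


def ripple_power(lfp, fs, smooth_s=0.01):
    """Summed ripple-band (150–250 Hz) RMS power across channels."""
    arr = np.atleast_2d(np.asarray(lfp, dtype=float))
    total = np.zeros(arr.shape[1])
    for ch in arr:
        filt = _bandpass(ch, fs, RIPPLE_BAND)
        total += filt ** 2
    w = max(1, int(round(smooth_s * fs)))
    power = np.sqrt(np.convolve(total, np.ones(w) / w, mode="same"))
    return power


def detect_swr(lfp, fs, rest_intervals, threshold_sd=SWR_THRESHOLD_SD,
               reference=None, t0=0.0, threshold_intervals=None) -> pd.DataFrame:
    """Sharp wave/ripple events: ripple power > rest mean + ``threshold_sd``·SD.

    Background statistics come from ``threshold_intervals`` (default: the
    first rest interval set, emulating a threshold fixed on the first sleep
    session and reused), with one re-estimation pass excluding detected
    events.  ``reference`` (a ripple-free channel) is subtracted before
    filtering when given.  Returns a table (t_peak, t_start, t_end,
    peak_power).
    """
    arr = np.atleast_2d(np.asarray(lfp, dtype=float))
    if reference is not None:
        arr = arr - np.asarray(reference, dtype=float)[None, :]
    rest = as_intervals(rest_intervals)
    if rest.size == 0:
        return pd.DataFrame(columns=["t_peak", "t_start", "t_end", "peak_power"])
    power = ripple_power(arr, fs)
    t = t0 + np.arange(arr.shape[1]) / fs
    bg_iv = as_intervals(threshold_intervals) if threshold_intervals is not None \
        else rest
    bg = power[in_intervals(t, bg_iv)]
    if len(bg) == 0:
        raise ValueError("no samples inside threshold intervals")
    if np.std(bg) == 0:
        raise ValueError("flat LFP: zero background SD, cannot set threshold")

    def find(thresh, edge):
        above = power > thresh
        above &= in_intervals(t, rest)
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, len(above)]
        rows = []
        for s, e in zip(starts, ends):
            # extend to the surrounding lower-threshold crossing
            s2 = s
            while s2 > 0 and power[s2 - 1] > edge:
                s2 -= 1
            e2 = e
            while e2 < len(power) and power[e2] > edge:
                e2 += 1
            k = s + int(np.argmax(power[s:e]))
            rows.append((t[k], t[s2], t[min(e2, len(t) - 1)], power[k]))
        return rows

    for _ in range(2):   # one re-estimation pass excluding events
        mean, sd = float(np.mean(bg)), float(np.std(bg))
        thresh = mean + threshold_sd * sd
        edge = mean + 2.0 * sd
        rows = find(thresh, edge)
        if rows:
            ev_iv = as_intervals([(r[1], r[2]) for r in rows])
            keep = ~in_intervals(t, ev_iv) & in_intervals(t, bg_iv)
            bg = power[keep]
            if len(bg) == 0 or np.std(bg) == 0:
                break
    df = pd.DataFrame(rows, columns=["t_peak", "t_start", "t_end", "peak_power"])
    # merge events whose spans overlap after extension
    if len(df) > 1:
        merged = []
        for row in df.itertuples(index=False):
            if merged and row.t_start <= merged[-1][2]:
                last = merged[-1]
                best = row if row.peak_power > last[3] else None
                merged[-1] = (
                    best.t_peak if best is not None else last[0],
                    last[1], max(last[2], row.t_end),
                    max(last[3], row.peak_power),
                )
            else:
                merged.append(tuple(row))
        df = pd.DataFrame(merged, columns=df.columns)
    return df.reset_index(drop=True)


def exploration_from_bundle(bundle, ratio=None) -> StateIntervals:
    """Segment a full SessionBundle (convenience wrapper)."""
    from .core import speed_from_track
    rt, rr = theta_delta_ratio(bundle.lfp if bundle.lfp.ndim == 1
                               else bundle.lfp[0], bundle.lfp_rate)
    st, sp = speed_from_track(bundle.position)
    return segment_states(rt, rr, st, sp)
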
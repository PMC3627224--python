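"""Synthetic five-session cheeseboard experiments with known ground truth.

The generator emulates one recording day of a goal-learning task on a circular
("cheeseboard") arena: an unrewarded probe, a rest/sleep period, a block of
learning trials, a second rest and a final probe.  Pyramidal cells are
simulated as place cells carrying two spatial maps ("old" and "new"); on every
theta cycle of exploratory behavior a latent state decides which map drives
the population, with the probability of the new map rising across learning
trials (flickering).  Interneurons fire a baseline modulated by the expressed
assembly, plus spikes evoked through explicit pyramidal→interneuron
connections whose transmission probability w(t) drifts during the learning
session only.  Every latent quantity an estimator might try to recover —
per-cycle map state, connection weights over time, interneuron association
class, field parameters — is returned as :class:`GroundTruth`.

Times are seconds, positions cm, delays/jitters milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import INT, PYR, SessionBundle, as_intervals, in_intervals

OLD, NEW = "old", "new"


# ---------------------------------------------------------------------------
# configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connection:
    """A plastic pyramidal→interneuron monosynaptic connection.

    ``w_start``/``w_end`` are the spike transmission probabilities before and
    after learning; the weight ramps linearly across the learning session and
    is constant elsewhere.  ``delay_ms`` is the synaptic delay at w_start; if
    the simulation couples latency to weight, the effective delay shrinks as w
    grows.
    """

    pre: int
    post: int
    w_start: float
    w_end: float
    delay_ms: float = 1.5
    jitter_ms: float = 0.2


@dataclass(frozen=True)
class FieldParams:
    cx: float
    cy: float
    sigma: float       # cm
    peak: float        # Hz


def default_flicker_schedule(n_trials: int) -> np.ndarray:
    """Per-trial probability that a theta cycle expresses the new map.

    Sigmoidal rise: the new map appears abruptly within the initial trials
    and dominates late learning, mirroring rapid goal-map formation.
    """
    i = np.arange(n_trials)
    p = 0.05 + 0.90 / (1.0 + np.exp(-(i - n_trials / 4.0) / (n_trials / 10.0)))
    return np.clip(p, 0.0, 1.0)


def default_goals(arena_radius: float) -> np.ndarray:
    r = arena_radius * 0.5
    ang = np.deg2rad([90.0, 210.0, 330.0])
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


@dataclass
class SimConfig:
    """Parameters of one simulated experiment day.

    Defaults reproduce the protocol scale of the emulated task: ~25 min probe
    and rest sessions around ~40 short learning trials, a median-sized
    ensemble of 40 pyramidal cells, and connection weights in the range of
    reported monosynaptic peak probabilities (~0.05-0.3).
    """

    arena_radius: float = 60.0          # cm
    n_pyr: int = 40
    n_int: int = 24
    n_trials: int = 40
    trial_duration: float = 45.0        # s
    probe_duration: float = 1500.0      # s
    rest_duration: float = 1500.0       # s
    intertrial_gap: float = 5.0         # s, animal in start box
    theta_freq: float = 8.0             # Hz
    mean_speed: float = 15.0            # cm/s
    frac_remap: float = 0.6             # fraction of pyr cells whose new field differs
    flicker_schedule: Sequence[float] | None = None   # p_new per trial
    goals: np.ndarray | None = None
    connection_table: Sequence[Connection] | None = None
    int_base_rate: float = 10.0         # Hz
    pyr_peak_rate: float = 15.0         # Hz in-field peak
    seed: int = 0

    # secondary knobs (held fixed across the study conditions)
    field_sigma: float = 12.0           # cm, mean place-field width
    theta_mod: float = 0.5              # pyr theta modulation depth
    int_theta_mod: float = 0.3
    pyr_rest_rate: float = 1.0          # Hz during rest/sleep
    int_assembly_gain: float = 0.8      # bulk rate modulation of p/nInt by new-map state
    frac_new_dominant: float = 0.6      # of remapped cells, fraction stronger in new map
    off_map_peak_frac: float = 0.4      # peak in the non-preferred map
    latency_w_slope: float = 1.0        # ms of delay reduction per unit weight increase
    lfp_rate: float = 1000.0            # Hz
    pos_rate: float = 40.0              # Hz
    swr_rate: float = 0.2               # Hz of band-limited transients during rest
    add_swr: bool = True

    def __post_init__(self):
        if self.flicker_schedule is None:
            self.flicker_schedule = default_flicker_schedule(self.n_trials)
        self.flicker_schedule = np.asarray(self.flicker_schedule, dtype=float)
        if len(self.flicker_schedule) != self.n_trials:
            raise ValueError("flicker_schedule length must equal n_trials")
        if np.any(self.flicker_schedule < 0) or np.any(self.flicker_schedule > 1):
            raise ValueError("p_new must lie in [0, 1]")
        if np.any(np.diff(self.flicker_schedule) < -1e-12):
            raise ValueError("p_new must be nondecreasing across trials")
        if self.goals is None:
            self.goals = default_goals(self.arena_radius)
        self.goals = np.asarray(self.goals, dtype=float).reshape(-1, 2)
        if np.any(np.hypot(self.goals[:, 0], self.goals[:, 1]) > self.arena_radius):
            raise ValueError("all goals must lie inside the arena")
        if self.connection_table is not None:
            for c in self.connection_table:
                if not (0.0 <= c.w_start <= 1.0 and 0.0 <= c.w_end <= 1.0):
                    raise ValueError("connection weights must lie in [0, 1]")
                if not (0.5 < c.delay_ms < 2.5):
                    raise ValueError("synaptic delay must lie in (0.5, 2.5) ms")


@dataclass
class GroundTruth:
    """Latent variables of a simulated day."""

    cycle_state: pd.DataFrame       # t_start, t_end, trial (-1 outside learning), state
    connections: list[Connection]
    learning_span: tuple[float, float]
    int_class: dict[int, str]       # unit_id -> pInt / nInt / uInt
    field_params: dict[tuple[int, str], FieldParams]   # (unit_id, map) -> params
    int_gain: dict[int, float]      # signed bulk assembly gain per interneuron
    phi_pref: dict[int, float]      # preferred theta phase per unit

    def w_at(self, conn: Connection, t) -> np.ndarray:
        """Transmission probability of a connection at time(s) t.

        Constant outside the learning session (learning-restricted
        plasticity), linear ramp within it.
        """
        t = np.asarray(t, dtype=float)
        lo, hi = self.learning_span
        frac = np.clip((t - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
        return conn.w_start + (conn.w_end - conn.w_start) * frac


# ---------------------------------------------------------------------------
# forward model pieces
# ---------------------------------------------------------------------------

def place_rate(cell_fields, map_state, x, y, theta_phase, theta_mod=0.0,
               phi_pref=0.0):
    """Instantaneous firing rate of a place cell under the active map.

    Gaussian spatial tuning times a cosine theta modulation:
    ``peak * exp(-d^2 / (2 sigma^2)) * (1 + m cos(phase - phi_pref))`` where d
    is the distance to the active map's field center.
    """
    if not 0.0 <= theta_mod <= 1.0:
        raise ValueError("theta modulation depth must lie in [0, 1]")
    f = cell_fields[map_state]
    if f.sigma <= 0:
        raise ValueError("field width must be positive")
    d2 = (np.asarray(x) - f.cx) ** 2 + (np.asarray(y) - f.cy) ** 2
    rate = f.peak * np.exp(-d2 / (2.0 * f.sigma**2))
    rate = rate * (1.0 + theta_mod * np.cos(np.asarray(theta_phase) - phi_pref))
    return rate


def generate_trajectory(config: SimConfig, interval, seed, goals_to_visit=None,
                        resting=False, rest_pos=None) -> pd.DataFrame:
    """Smoothed random walk confined to the arena disc.

    During learning trials pass ``goals_to_visit``: the walk steers to each
    goal in turn before wandering, so every goal is visited at least once.
    With ``resting=True`` the animal sits at ``rest_pos`` with negligible
    drift (start-box immobility).
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if t1 <= t0:
        raise ValueError("interval duration must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.pos_rate
    n = max(2, int(round((t1 - t0) * config.pos_rate)))
    t = t0 + np.arange(n) * dt
    R = config.arena_radius

    if resting:
        if rest_pos is None:
            rest_pos = (R - 3.0, 0.0)
        jit = rng.normal(0.0, 0.08, size=(n, 2)).cumsum(axis=0)
        jit -= np.linspace(0, 1, n)[:, None] * jit[-1] / 1.0  # keep bounded
        jit = np.clip(jit, -1.5, 1.5)
        xy = np.asarray(rest_pos, dtype=float) + 0.02 * jit
        return pd.DataFrame({"time": t, "x": xy[:, 0], "y": xy[:, 1]})

    pos = np.empty((n, 2))
    pos[0] = rng.uniform(-R / 2, R / 2, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    speed = config.mean_speed

    waypoints = []
    if goals_to_visit is not None and len(goals_to_visit):
        order = rng.permutation(len(goals_to_visit))
        waypoints = [np.asarray(goals_to_visit[i], dtype=float) for i in order]

    def random_waypoint():
        r = 0.9 * R * math.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        return np.array([r * math.cos(a), r * math.sin(a)])

    target = waypoints.pop(0) if waypoints else random_waypoint()
    kappa, sig_h = 3.0, 1.2
    tau_s, sig_s = 2.0, 4.0
    for k in range(1, n):
        p = pos[k - 1]
        d = target - p
        dist = math.hypot(d[0], d[1])
        if dist < 6.0:
            target = waypoints.pop(0) if waypoints else random_waypoint()
            d = target - p
        goal_ang = math.atan2(d[1], d[0])
        if math.hypot(p[0], p[1]) > R - 4.0:
            goal_ang = math.atan2(-p[1], -p[0])   # steer back toward center
        dang = (goal_ang - heading + np.pi) % (2 * np.pi) - np.pi
        heading += kappa * dang * dt + sig_h * math.sqrt(dt) * rng.normal()
        speed += (config.mean_speed - speed) * dt / tau_s \
            + sig_s * math.sqrt(dt) * rng.normal()
        speed = min(max(speed, 6.0), 2.5 * config.mean_speed)
        step = speed * dt
        q = p + step * np.array([math.cos(heading), math.sin(heading)])
        r = math.hypot(q[0], q[1])
        if r > R - 1.0:
            q *= (R - 1.0) / r
        pos[k] = q
    return pd.DataFrame({"time": t, "x": pos[:, 0], "y": pos[:, 1]})


def poisson_times(rate_hz: float, intervals, rng) -> np.ndarray:
    """Homogeneous Poisson spike times within a set of intervals."""
    out = []
    for lo, hi in as_intervals(intervals):
        n = rng.poisson(rate_hz * (hi - lo))
        out.append(np.sort(rng.uniform(lo, hi, size=n)))
    return np.concatenate(out) if out else np.empty(0)


def thin_spikes(rate: np.ndarray, t_grid: np.ndarray, dt: float, rng) -> np.ndarray:
    """Inhomogeneous Poisson by per-slot thinning, uniformly jittered in-slot.

    ``rate`` is sampled on ``t_grid`` with spacing ``dt`` (1 ms by default in
    the session builder, so cross-correlogram structure is preserved to
    sub-ms precision).
    """
    p = np.clip(rate * dt, 0.0, 1.0)
    hit = rng.random(p.shape) < p
    times = t_grid[hit] + rng.uniform(0.0, dt, size=int(hit.sum()))
    return np.sort(times)


def evoked_spikes(pre_times, w, delay_ms, jitter_ms, rng) -> np.ndarray:
    """One evoked postsynaptic spike per presynaptic spike with prob w.

    ``w`` and ``delay_ms`` may be scalars or arrays aligned with
    ``pre_times`` (time-varying weight / latency).
    """
    pre_times = np.asarray(pre_times, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), pre_times.shape)
    delay = np.broadcast_to(np.asarray(delay_ms, dtype=float), pre_times.shape)
    hit = rng.random(pre_times.shape) < w
    n = int(hit.sum())
    t = pre_times[hit] + (delay[hit] + rng.normal(0.0, jitter_ms, size=n)) / 1000.0
    return np.sort(t)


def simulate_coupled_pair(duration, pre_rate, post_rate, w, delay_ms=1.5,
                          jitter_ms=0.2, seed=0, t0=0.0):
    """A standalone pyramidal→interneuron pair on [t0, t0+duration).

    ``w`` and ``delay_ms`` may be callables of time (evaluated at each
    presynaptic spike) for drifting weights/latencies.  Returns
    (pre_times, post_times).
    """
    rng = np.random.default_rng(seed)
    pre = poisson_times(pre_rate, [(t0, t0 + duration)], rng)
    base = poisson_times(post_rate, [(t0, t0 + duration)], rng)
    w_arr = w(pre) if callable(w) else w
    d_arr = delay_ms(pre) if callable(delay_ms) else delay_ms
    ev = evoked_spikes(pre, w_arr, d_arr, jitter_ms, rng)
    post = np.sort(np.concatenate([base, ev]))
    return pre, post


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def build_intervals(config: SimConfig) -> pd.DataFrame:
    rows = []
    t = 0.0
    rows.append(("preprobe", t, t + config.probe_duration))
    t += config.probe_duration
    rows.append(("presleep", t, t + config.rest_duration))
    t += config.rest_duration
    for i in range(config.n_trials):
        rows.append((f"trial{i + 1:02d}", t, t + config.trial_duration))
        t += config.trial_duration
        if i < config.n_trials - 1:
            rows.append(("intertrial", t, t + config.intertrial_gap))
            t += config.intertrial_gap
    rows.append(("postsleep", t, t + config.rest_duration))
    t += config.rest_duration
    rows.append(("postprobe", t, t + config.probe_duration))
    return pd.DataFrame(rows, columns=["label", "t_start", "t_end"])


def _moving_labels(intervals: pd.DataFrame) -> pd.DataFrame:
    mask = intervals.label.isin(["preprobe", "postprobe"]) \
        | intervals.label.str.startswith("trial")
    return intervals[mask]


def assign_fields(config: SimConfig, rng) -> tuple[dict, dict]:
    """Draw two-map field parameters and cell roles.

    Roles: 'new' members carry a strong goal-anchored field in the new map
    (weak old field), 'old' members the converse, 'stable' cells keep one
    field in both maps.  Returns (field_params, role per cell).
    """
    n_remap = int(round(config.frac_remap * config.n_pyr))
    n_new = int(round(config.frac_new_dominant * n_remap))
    roles = {}
    fields = {}
    R = config.arena_radius

    def rand_center():
        r = 0.85 * R * math.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        return r * math.cos(a), r * math.sin(a)

    def goal_center():
        g = config.goals[rng.integers(len(config.goals))]
        for _ in range(100):
            c = g + rng.normal(0.0, 8.0, size=2)
            if math.hypot(c[0], c[1]) < 0.9 * R:
                return float(c[0]), float(c[1])
        return float(g[0]), float(g[1])

    order = rng.permutation(config.n_pyr)
    for j, cell in enumerate(order):
        cell = int(cell)
        sigma = config.field_sigma * rng.uniform(0.8, 1.2)
        peak = config.pyr_peak_rate * rng.uniform(0.7, 1.3)
        weak = config.off_map_peak_frac * peak
        if j < n_new:
            roles[cell] = "new"
            fields[(cell, OLD)] = FieldParams(*rand_center(), sigma, weak)
            fields[(cell, NEW)] = FieldParams(*goal_center(), sigma, peak)
        elif j < n_remap:
            roles[cell] = "old"
            fields[(cell, OLD)] = FieldParams(*rand_center(), sigma, peak)
            fields[(cell, NEW)] = FieldParams(*rand_center(), sigma, weak)
        else:
            roles[cell] = "stable"
            cx, cy = rand_center()
            fields[(cell, OLD)] = FieldParams(cx, cy, sigma, peak)
            fields[(cell, NEW)] = FieldParams(cx, cy, sigma, peak)
    return fields, roles


def default_connection_table(config: SimConfig, roles: dict, rng
                             ) -> tuple[list[Connection], dict, dict]:
    """Connections realizing the learning-related reconfiguration.

    pInt interneurons strengthen inputs from new-assembly cells and weaken
    those from old-assembly cells; nInt interneurons do the opposite; uInt
    keep a stable input from a map-stable cell.  Interneuron unit ids follow
    the pyramidal ids.
    """
    new_cells = [c for c, r in roles.items() if r == "new"]
    old_cells = [c for c, r in roles.items() if r == "old"]
    stable_cells = [c for c, r in roles.items() if r == "stable"]
    n_each = config.n_int // 3
    int_ids = list(range(config.n_pyr, config.n_pyr + config.n_int))
    int_class, int_gain = {}, {}
    conns: list[Connection] = []

    def draw_delay():
        return float(np.clip(rng.normal(1.5, 0.25), 0.8, 2.2))

    def pick(pool, k):
        k = min(k, len(pool))
        return [int(c) for c in rng.choice(pool, size=k, replace=False)]

    for idx, unit in enumerate(int_ids):
        if idx < n_each:
            int_class[unit] = "pInt"
            int_gain[unit] = config.int_assembly_gain
            for pre in pick(new_cells, 2):
                conns.append(Connection(pre, unit, 0.05, 0.28, draw_delay()))
            for pre in pick(old_cells, 1):
                conns.append(Connection(pre, unit, 0.25, 0.08, draw_delay()))
        elif idx < 2 * n_each:
            int_class[unit] = "nInt"
            int_gain[unit] = -config.int_assembly_gain
            for pre in pick(old_cells, 2):
                conns.append(Connection(pre, unit, 0.05, 0.28, draw_delay()))
            for pre in pick(new_cells, 1):
                conns.append(Connection(pre, unit, 0.25, 0.08, draw_delay()))
        else:
            int_class[unit] = "uInt"
            int_gain[unit] = 0.0
            for pre in pick(stable_cells, 1):
                conns.append(Connection(pre, unit, 0.15, 0.15, draw_delay()))
    return conns, int_class, int_gain


def _theta_cycle_table(config: SimConfig, intervals: pd.DataFrame, rng
                       ) -> pd.DataFrame:
    """Ground-truth theta cycles (negative-peak delimited) with latent states."""
    f = config.theta_freq
    moving = _moving_labels(intervals)
    t_end = intervals.t_end.max()
    k_max = int(t_end * f) + 2
    peaks = (np.arange(k_max) + 0.5) / f      # cos(2*pi*f*t) minima
    rows = []
    for _, row in moving.iterrows():
        lo, hi, label = row.t_start, row.t_end, row.label
        trial = int(label[5:]) - 1 if label.startswith("trial") else -1
        inside = peaks[(peaks >= lo) & (peaks <= hi)]
        if len(inside) < 2:
            continue
        starts, ends = inside[:-1], inside[1:]
        if label == "preprobe":
            states = np.full(len(starts), OLD)
        elif label == "postprobe":
            states = np.full(len(starts), NEW)
        else:
            p = config.flicker_schedule[trial]
            states = np.where(rng.random(len(starts)) < p, NEW, OLD)
        for s, e, st in zip(starts, ends, states):
            rows.append((s, e, trial, st))
    return pd.DataFrame(rows, columns=["t_start", "t_end", "trial", "state"])


def _pink_noise(n, rng):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:] / freqs[1])
    sig = np.fft.irfft(spec * scale, n)
    return sig / (np.std(sig) + 1e-12)


def synthesize_lfp(config: SimConfig, intervals: pd.DataFrame, speed_t,
                   speed, rng) -> np.ndarray:
    """Single-channel LFP: speed-modulated theta + gamma during movement,
    delta-dominated signal (plus optional ripple transients) during rest,
    pink noise throughout."""
    fs = config.lfp_rate
    t_end = float(intervals.t_end.max())
    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    moving_iv = as_intervals(_moving_labels(intervals)[["t_start", "t_end"]].to_numpy())
    moving = in_intervals(t, moving_iv)
    sp = np.interp(t, speed_t, speed)

    lfp = 0.35 * _pink_noise(n, rng)
    phase = 2 * np.pi * config.theta_freq * t
    theta_amp = np.where(moving, 1.0 + 0.3 * sp / config.mean_speed, 0.10)
    lfp += theta_amp * np.cos(phase)
    gamma = 0.12 * np.cos(2 * np.pi * 42.0 * t) * (1 + np.cos(phase)) / 2.0
    lfp += np.where(moving, gamma, 0.0)
    delta = 1.3 * np.cos(2 * np.pi * 3.0 * t + 0.5 * np.sin(2 * np.pi * 0.05 * t))
    lfp += np.where(moving, 0.0, delta)

    if config.add_swr:
        rest_iv = intervals[intervals.label.isin(["presleep", "postsleep"])]
        for _, row in rest_iv.iterrows():
            n_ev = rng.poisson(config.swr_rate * (row.t_end - row.t_start))
            centers = rng.uniform(row.t_start + 0.5, row.t_end - 0.5, size=n_ev)
            for c in centers:
                i0 = int((c - 0.1) * fs)
                i1 = int((c + 0.1) * fs)
                tt = t[i0:i1]
                env = np.exp(-0.5 * ((tt - c) / 0.015) ** 2)
                lfp[i0:i1] += 2.5 * env * np.cos(2 * np.pi * 180.0 * (tt - c))
    return lfp


def emit_spikes(config: SimConfig, intervals: pd.DataFrame,
                position: pd.DataFrame, truth: GroundTruth, seed) -> pd.DataFrame:
    """Draw all spike trains given the latent state (see module docstring).

    Pyramidal cells: inhomogeneous Poisson with place/theta tuning under the
    per-cycle map state during exploration, homogeneous at the rest rate
    otherwise.  Interneurons: baseline modulated by the expressed assembly
    plus evoked spikes from each connection (additive, no refractory
    interaction).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    dt = 1e-3
    t_end = float(intervals.t_end.max())
    grid = np.arange(0.0, t_end, dt)
    x = np.interp(grid, position.time, position.x)
    y = np.interp(grid, position.time, position.y)
    phase = 2 * np.pi * config.theta_freq * grid

    cyc = truth.cycle_state
    # per-sample map state: -1 outside theta cycles, 0 old, 1 new
    state = np.full(len(grid), -1, dtype=np.int8)
    starts = cyc.t_start.to_numpy()
    ends = cyc.t_end.to_numpy()
    codes = (cyc.state.to_numpy() == NEW).astype(np.int8)
    idx = np.searchsorted(starts, grid, side="right") - 1
    ok = (idx >= 0) & (grid < ends[np.clip(idx, 0, None)])
    state[ok] = codes[idx[ok]]
    mov = state >= 0
    is_new = state == 1

    lo, hi = truth.learning_span
    ramp = np.clip((grid - lo) / max(hi - lo, 1e-12), 0.0, 1.0)

    rest_iv = []
    for _, row in intervals.iterrows():
        rest_iv.append((row.t_start, row.t_end))
    rest_iv = as_intervals(rest_iv)

    rows_id, rows_t, rows_type = [], [], []

    def add(unit, times, typ):
        times = np.unique(times)
        rows_id.append(np.full(len(times), unit))
        rows_t.append(times)
        rows_type.append(typ)

    pyr_spikes = {}
    child = ss.spawn(config.n_pyr + config.n_int + 1)
    for cell in range(config.n_pyr):
        rng = np.random.default_rng(child[cell])
        fo, fn = truth.field_params[(cell, OLD)], truth.field_params[(cell, NEW)]
        d2o = (x[mov] - fo.cx) ** 2 + (y[mov] - fo.cy) ** 2
        d2n = (x[mov] - fn.cx) ** 2 + (y[mov] - fn.cy) ** 2
        rate = np.where(
            is_new[mov],
            fn.peak * np.exp(-d2n / (2 * fn.sigma**2)),
            fo.peak * np.exp(-d2o / (2 * fo.sigma**2)),
        )
        rate *= 1.0 + config.theta_mod * np.cos(phase[mov] - truth.phi_pref[cell])
        t_mov = thin_spikes(rate, grid[mov], dt, rng)
        # during rest/immobility the cell keeps a low background rate so that
        # coupling remains measurable in sleep sessions
        t_rest = _rest_poisson(config.pyr_rest_rate, grid, mov, dt, rng)
        times = np.sort(np.concatenate([t_mov, t_rest]))
        pyr_spikes[cell] = times
        add(cell, times, PYR)

    for j, unit in enumerate(sorted(truth.int_class)):
        rng = np.random.default_rng(child[config.n_pyr + j])
        g = truth.int_gain[unit]
        mod = np.ones(int(mov.sum()))
        if g != 0.0:
            mod = 1.0 + g * ramp[mov] * is_new[mov]
            mod = np.clip(mod, 0.05, None)
        rate = config.int_base_rate * mod
        rate = rate * (1.0 + config.int_theta_mod
                       * np.cos(phase[mov] - truth.phi_pref[unit]))
        t_mov = thin_spikes(rate, grid[mov], dt, rng)
        t_rest = _rest_poisson(config.int_base_rate, grid, mov, dt, rng)
        evoked = []
        for conn in truth.connections:
            if conn.post != unit:
                continue
            pre = pyr_spikes[conn.pre]
            w = truth.w_at(conn, pre)
            delay = np.clip(
                conn.delay_ms - config.latency_w_slope * (w - conn.w_start),
                0.6, 2.4,
            )
            evoked.append(evoked_spikes(pre, w, delay, conn.jitter_ms, rng))
        times = np.sort(np.concatenate([t_mov, t_rest] + evoked))
        times = times[(times >= 0) & (times < t_end)]
        add(unit, times, INT)

    df = pd.DataFrame({
        "unit_id": np.concatenate(rows_id).astype(int),
        "time": np.concatenate(rows_t),
        "unit_type": np.repeat(rows_type, [len(a) for a in rows_t]),
    })
    return df.sort_values(["unit_id", "time"], kind="stable").reset_index(drop=True)


def _rest_poisson(rate_hz, grid, mov, dt, rng):
    """Homogeneous spikes on the non-exploratory part of the 1 ms grid."""
    quiet = ~mov
    p = rate_hz * dt
    hit = rng.random(int(quiet.sum())) < p
    return np.sort(grid[quiet][hit] + rng.uniform(0, dt, size=int(hit.sum())))


def generate_session(config: SimConfig) -> tuple[SessionBundle, GroundTruth]:
    """Simulate one full day.  Deterministic given (config, config.seed)."""
    ss = np.random.SeedSequence(config.seed)
    s_traj, s_cells, s_cycles, s_lfp, s_spikes = ss.spawn(5)
    intervals = build_intervals(config)

    # trajectory, interval by interval, on a uniform grid
    traj_parts = []
    traj_seeds = s_traj.spawn(len(intervals))
    for k, (_, row) in enumerate(intervals.iterrows()):
        lab = row.label
        if lab in ("presleep", "postsleep", "intertrial"):
            part = generate_trajectory(
                config, (row.t_start, row.t_end), traj_seeds[k], resting=True
            )
        elif lab.startswith("trial"):
            part = generate_trajectory(
                config, (row.t_start, row.t_end), traj_seeds[k],
                goals_to_visit=config.goals,
            )
        else:
            part = generate_trajectory(config, (row.t_start, row.t_end), traj_seeds[k])
        traj_parts.append(part)
    position = pd.concat(traj_parts, ignore_index=True)

    rng_cells = np.random.default_rng(s_cells)
    fields, roles = assign_fields(config, rng_cells)
    if config.connection_table is None:
        conns, int_class, int_gain = default_connection_table(
            config, roles, rng_cells
        )
    else:
        conns = list(config.connection_table)
        int_ids = range(config.n_pyr, config.n_pyr + config.n_int)
        int_class = {u: "uInt" for u in int_ids}
        int_gain = {u: 0.0 for u in int_ids}
    phi = {u: float(np.random.default_rng([config.seed, 7, u]).uniform(0, 2 * np.pi))
           for u in range(config.n_pyr + config.n_int)}

    cycle_state = _theta_cycle_table(config, intervals,
                                     np.random.default_rng(s_cycles))
    trials = intervals[intervals.label.str.startswith("trial")]
    truth = GroundTruth(
        cycle_state=cycle_state,
        connections=conns,
        learning_span=(float(trials.t_start.min()), float(trials.t_end.max())),
        int_class=int_class,
        field_params=fields,
        int_gain=int_gain,
        phi_pref=phi,
    )

    from .core import speed_from_track
    sp_t, sp = speed_from_track(position)
    lfp = synthesize_lfp(config, intervals, sp_t, sp,
                         np.random.default_rng(s_lfp))
    spikes = emit_spikes(config, intervals, position, truth,
                         s_spikes)
    bundle = SessionBundle(
        spikes=spikes, position=position, lfp=lfp,
        lfp_rate=config.lfp_rate, intervals=intervals, goals=config.goals,
    )
    return bundle, truth
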
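"""Shared containers and session I/O.

A recorded (or simulated) experiment day is held in a :class:`SessionBundle`:
spike times per unit, the animal's position track, one or more LFP channels,
goal coordinates and the labeled session/trial intervals.  All times are in
seconds, positions in cm, unit ids 0-based.  On disk a bundle is a directory of
plain-text tables (``spikes.tsv``, ``position.tsv``, ``intervals.tsv``,
``goals.tsv``) plus a raw float32 LFP trace (``lfp.bin`` + ``lfp.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PYR = "pyr"
INT = "int"

# canonical epoch labels of a five-session day, in temporal order
EPOCHS = ("preprobe", "presleep", "learning", "postsleep", "postprobe")


def as_intervals(arr) -> np.ndarray:
    """Coerce to an (n, 2) float array of [t_start, t_end) spans."""
    out = np.asarray(arr, dtype=float).reshape(-1, 2)
    if np.any(out[:, 1] < out[:, 0]):
        raise ValueError("interval with t_end < t_start")
    return out


def intervals_duration(intervals) -> float:
    iv = as_intervals(intervals)
    return float(np.sum(iv[:, 1] - iv[:, 0]))


def in_intervals(t, intervals) -> np.ndarray:
    """Boolean mask: which times fall inside any [t_start, t_end) span.

    Intervals must be sorted and non-overlapping.
    """
    iv = as_intervals(intervals)
    t = np.asarray(t, dtype=float)
    if iv.size == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(iv.ravel(), t, side="right")
    return idx % 2 == 1


def restrict(t, intervals) -> np.ndarray:
    """Return the subset of times that fall inside the intervals."""
    t = np.asarray(t, dtype=float)
    return t[in_intervals(t, intervals)]


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two sorted, non-overlapping interval sets."""
    a, b = as_intervals(a), as_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_intervals(np.array(out).reshape(-1, 2) if out else np.empty((0, 2)))


@dataclass
class SessionBundle:
    """One experiment day: spikes, position, LFP, goals and labeled intervals."""

    spikes: pd.DataFrame            # columns: unit_id, time, unit_type
    position: pd.DataFrame          # columns: time, x, y (uniform grid)
    lfp: np.ndarray                 # (n_samples,) or (n_channels, n_samples)
    lfp_rate: float                 # Hz
    intervals: pd.DataFrame         # columns: label, t_start, t_end
    goals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.goals = np.asarray(self.goals, dtype=float).reshape(-1, 2)

    # -- convenience accessors -------------------------------------------------

    def unit_ids(self, unit_type: str | None = None) -> np.ndarray:
        df = self.spikes
        if unit_type is not None:
            df = df[df.unit_type == unit_type]
        return np.unique(df.unit_id.to_numpy())

    def spike_times(self, unit_id: int) -> np.ndarray:
        return self.spikes.loc[self.spikes.unit_id == unit_id, "time"].to_numpy()

    def epoch(self, label: str) -> np.ndarray:
        """Intervals carrying the given label (trials: 'trial', pooled)."""
        df = self.intervals
        if label == "learning":
            df = df[df.label.str.startswith("trial")]
        else:
            df = df[df.label == label]
        if df.empty:
            return np.empty((0, 2))
        return as_intervals(df[["t_start", "t_end"]].to_numpy())

    def trial_intervals(self) -> np.ndarray:
        return self.epoch("learning")

    @property
    def t_start(self) -> float:
        return float(self.intervals.t_start.min())

    @property
    def t_end(self) -> float:
        return float(self.intervals.t_end.max())

    # -- disk round trip -------------------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(path / "spikes.tsv", sep="\t", index=False)
        self.position.to_csv(path / "position.tsv", sep="\t", index=False)
        self.intervals.to_csv(path / "intervals.tsv", sep="\t", index=False)
        pd.DataFrame(self.goals, columns=["x", "y"]).to_csv(
            path / "goals.tsv", sep="\t", index=False
        )
        lfp = np.atleast_2d(np.asarray(self.lfp, dtype=np.float32))
        lfp.astype("<f4").tofile(path / "lfp.bin")
        (path / "lfp.json").write_text(
            json.dumps({"rate": self.lfp_rate, "channels": lfp.shape[0]})
        )

    @classmethod
    def from_dir(cls, path) -> "SessionBundle":
        path = Path(path)
        meta = json.loads((path / "lfp.json").read_text())
        lfp = np.fromfile(path / "lfp.bin", dtype="<f4").reshape(
            int(meta["channels"]), -1
        )
        if lfp.shape[0] == 1:
            lfp = lfp[0]
        goals = pd.read_csv(path / "goals.tsv", sep="\t")
        return cls(
            spikes=pd.read_csv(path / "spikes.tsv", sep="\t"),
            position=pd.read_csv(path / "position.tsv", sep="\t"),
            lfp=np.asarray(lfp, dtype=float),
            lfp_rate=float(meta["rate"]),
            intervals=pd.read_csv(path / "intervals.tsv", sep="\t"),
            goals=goals[["x", "y"]].to_numpy(),
        )


def speed_from_track(position: pd.DataFrame, smooth_s: float = 0.25):
    """Running speed (cm/s) by central finite differences, boxcar-smoothed.

    Returns (t, speed) on the position time grid.
    """
    t = position.time.to_numpy()
    x = position.x.to_numpy()
    y = position.y.to_numpy()
    if len(t) < 3:
        raise ValueError("need at least 3 position samples")
    dt = np.median(np.diff(t))
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    sp = np.hypot(vx, vy)
    w = max(1, int(round(smooth_s / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        sp = np.convolve(sp, kernel, mode="same")
    return t, sp
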
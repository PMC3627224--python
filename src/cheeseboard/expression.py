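"""Per-cycle assembly-expression scoring: old map vs new map.

The rate maps of the screened pyramidal cells from the preprobe (old map)
and postprobe (new map) sessions are stacked into 3D population-vector
arrays (x-bin, y-bin, cell).  Within each theta (or gamma) cycle of the
learning session the instantaneous rate vector of the same cells is
correlated with the stored population vector of the animal's current
location in both stacks, and the two correlations are compared with
Fisher's r-to-z test:

    z = (atanh(r_post) - atanh(r_pre)) / sqrt(2 / (n - 3))

Positive z means the ongoing activity preferentially expresses the new
(postprobe) assemblies; negative z the old ones.  The two correlations share
the cycle vector, so the independent-samples Fisher comparison is an
approximation — kept deliberately, with the caveat documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .maps import RateMap

MIN_CELLS = 5
RECOMMENDED_MIN_CELLS = 14


@dataclass
class PopulationVectorStack:
    """Per-location population vectors of one probe session."""

    rates: np.ndarray          # (nx, ny, n_cells)
    cell_ids: np.ndarray       # fixed, recorded cell order
    visited: np.ndarray        # (nx, ny) bool
    bin_size: float
    origin: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return self.rates.shape[2]

    def vector_at(self, i, j) -> np.ndarray:
        return self.rates[i, j, :]

    def bin_of(self, x, y):
        i = int(np.floor((x - self.origin[0]) / self.bin_size))
        j = int(np.floor((y - self.origin[1]) / self.bin_size))
        return i, j

    def in_grid(self, i, j) -> bool:
        nx, ny, _ = self.rates.shape
        return 0 <= i < nx and 0 <= j < ny


def build_stack(rate_maps: Sequence[RateMap], cell_ids) -> PopulationVectorStack:
    """Stack per-cell rate maps (shared geometry) into a population array.

    Bins unvisited in the probe are masked; smoothed rates fill the stack.
    """
    if len(rate_maps) < 2:
        raise ValueError("need at least 2 cells to build a population stack")
    if len(rate_maps) != len(cell_ids):
        raise ValueError("one cell id per map required")
    first = rate_maps[0]
    for m in rate_maps[1:]:
        if not m.same_geometry(first):
            raise ValueError("rate maps have mismatched geometry")
    if len(rate_maps) < RECOMMENDED_MIN_CELLS:
        warnings.warn(
            f"population of {len(rate_maps)} cells is below the recommended "
            f"minimum of {RECOMMENDED_MIN_CELLS}"
        )
    rates = np.stack([np.where(m.visited, m.rate, np.nan) for m in rate_maps],
                     axis=2)
    visited = np.logical_and.reduce([m.visited for m in rate_maps])
    return PopulationVectorStack(
        rates=rates,
        cell_ids=np.asarray(cell_ids, dtype=int),
        visited=visited,
        bin_size=first.bin_size,
        origin=first.origin,
    )


def cycle_vector(spike_times_by_cell: Sequence[np.ndarray], cycle) -> np.ndarray:
    """Instantaneous rate vector: spike count in the cycle / duration (Hz)."""
    lo, hi = float(cycle[0]), float(cycle[1])
    if hi <= lo:
        raise ValueError("cycle duration must be positive")
    dur = hi - lo
    return np.array([
        (np.searchsorted(st, hi) - np.searchsorted(st, lo)) / dur
        for st in spike_times_by_cell
    ])


def cycle_count_matrix(spike_times_by_cell, cycles) -> np.ndarray:
    """(n_cycles, n_cells) spike counts, vectorized."""
    cycles = np.asarray(cycles, dtype=float).reshape(-1, 2)
    out = np.empty((len(cycles), len(spike_times_by_cell)))
    for c, st in enumerate(spike_times_by_cell):
        out[:, c] = (np.searchsorted(st, cycles[:, 1])
                     - np.searchsorted(st, cycles[:, 0]))
    return out


def fisher_z(r_pre, r_post, n_cells) -> float:
    """Fisher r-to-z comparison; positive favors the new (post) map."""
    if n_cells <= 3:
        raise ValueError("z undefined for n_cells <= 3")
    r_pre = np.clip(r_pre, -1 + 1e-15, 1 - 1e-15)
    r_post = np.clip(r_post, -1 + 1e-15, 1 - 1e-15)
    return float((np.arctanh(r_post) - np.arctanh(r_pre))
                 / np.sqrt(2.0 / (n_cells - 3)))


def _pearson(a, b):
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


@dataclass
class ExpressionScore:
    r_pre: float
    r_post: float
    z: float
    n_cells: int
    valid: bool


def expression_score(vec, stack_pre: PopulationVectorStack,
                     stack_post: PopulationVectorStack, location_bin,
                     exclude_cell=None) -> ExpressionScore:
    """Score one cycle vector against both probe stacks at one location.

    ``exclude_cell`` drops that cell everywhere (leave-one-out, used when the
    scored unit is itself part of the population).  Invalid (NaN z) when
    either correlation is undefined or the location is unvisited.
    """
    i, j = location_bin
    if not (stack_pre.in_grid(i, j) and stack_post.in_grid(i, j)):
        return ExpressionScore(np.nan, np.nan, np.nan, 0, False)
    if not (stack_pre.visited[i, j] and stack_post.visited[i, j]):
        return ExpressionScore(np.nan, np.nan, np.nan, 0, False)
    vec = np.asarray(vec, dtype=float)
    keep = np.ones(len(vec), dtype=bool)
    if exclude_cell is not None:
        keep &= stack_pre.cell_ids != exclude_cell
    pre = stack_pre.rates[i, j, keep]
    post = stack_post.rates[i, j, keep]
    v = vec[keep]
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post, v = pre[ok], post[ok], v[ok]
    n = len(v)
    if n <= 3:
        raise ValueError("fewer than 4 cells after exclusion; z undefined")
    r_pre = _pearson(v, pre)
    r_post = _pearson(v, post)
    if not (np.isfinite(r_pre) and np.isfinite(r_post)) or n < MIN_CELLS:
        return ExpressionScore(r_pre, r_post, np.nan, n, False)
    return ExpressionScore(r_pre, r_post, fisher_z(r_pre, r_post, n), n, True)


def expression_series(spike_times_by_cell, cycles, stack_pre,
                      stack_post, position, oscillation="theta",
                      theta_cycles=None, exclude_cell=None) -> pd.DataFrame:
    """Score every cycle; one row per cycle (CycleExpression table).

    Location is the track position at the cycle midpoint, mapped onto the
    probe grid.  Gamma-cycle rows record the containing theta cycle (or -1).
    Cycles whose population vector has no variance (e.g. all-zero) are kept
    but flagged invalid, never imputed.
    """
    cycles = np.asarray(cycles, dtype=float).reshape(-1, 2)
    counts = cycle_count_matrix(spike_times_by_cell, cycles)
    dur = cycles[:, 1] - cycles[:, 0]
    vecs = counts / dur[:, None]

    t_mid = cycles.mean(axis=1)
    x = np.interp(t_mid, position.time, position.x)
    y = np.interp(t_mid, position.time, position.y)

    keep = np.ones(stack_pre.n_cells, dtype=bool)
    if exclude_cell is not None:
        keep &= stack_pre.cell_ids != exclude_cell

    theta_id = np.full(len(cycles), -1)
    if oscillation == "gamma" and theta_cycles is not None:
        th = np.asarray(theta_cycles, dtype=float).reshape(-1, 2)
        if len(th):
            idx = np.searchsorted(th[:, 0], t_mid, side="right") - 1
            inside = (idx >= 0) & (t_mid < th[np.clip(idx, 0, None), 1])
            theta_id[inside] = idx[inside]

    rows = np.empty((len(cycles), 4))
    n_used = np.zeros(len(cycles), dtype=int)
    valid = np.zeros(len(cycles), dtype=bool)
    for k in range(len(cycles)):
        i, j = stack_pre.bin_of(x[k], y[k])
        if not (stack_pre.in_grid(i, j) and stack_pre.visited[i, j]
                and stack_post.visited[i, j]):
            rows[k] = (np.nan, np.nan, np.nan, np.nan)
            continue
        pre = stack_pre.rates[i, j, keep]
        post = stack_post.rates[i, j, keep]
        v = vecs[k, keep]
        ok = np.isfinite(pre) & np.isfinite(post)
        n = int(ok.sum())
        n_used[k] = n
        if n < MIN_CELLS:
            rows[k] = (np.nan, np.nan, np.nan, np.nan)
            continue
        r_pre = _pearson(v[ok], pre[ok])
        r_post = _pearson(v[ok], post[ok])
        if np.isfinite(r_pre) and np.isfinite(r_post):
            z = fisher_z(r_pre, r_post, n)
            rows[k] = (r_pre, r_post, z, 1.0)
            valid[k] = True
        else:
            rows[k] = (r_pre, r_post, np.nan, np.nan)

    n_active = (counts > 0).sum(axis=1)
    return pd.DataFrame({
        "cycle_id": np.arange(len(cycles)),
        "t_start": cycles[:, 0],
        "t_end": cycles[:, 1],
        "t_mid": t_mid,
        "r_pre": rows[:, 0],
        "r_post": rows[:, 1],
        "n_cells": n_used,
        "n_active": n_active,
        "z": rows[:, 2],
        "valid": valid,
        "oscillation": oscillation,
        "theta_cycle_id": theta_id,
    })
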
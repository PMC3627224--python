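"""Occupancy-normalized place rate maps and spatial-tuning statistics.

Rate maps are computed from exploratory samples only (speed > 5 cm/s), as
smoothed spike count over smoothed occupancy on a square grid.  Spatial
tuning is screened with two statistics: coherence, the Fisher z-transform of
the correlation between each bin's rate and the mean rate of its eight
nearest neighbors (computed on the unsmoothed map, since smoothing would
inflate it), and sparsity, (sum P_i R_i)^2 / sum P_i R_i^2 with P_i the
occupancy probability of bin i — the occupancy-weighted fraction of the
environment in which the cell fires.  A place cell requires coherence >= 0.6
and sparsity <= 0.3; remapping between two maps is flagged when their
rate-bin correlation (place-field similarity) is < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import as_intervals, in_intervals

SPEED_THRESHOLD = 5.0        # cm/s
COHERENCE_MIN = 0.6          # z units
SPARSITY_MAX = 0.3
SIMILARITY_REMAP = 0.2
DEFAULT_BIN_CM = 4.0
DEFAULT_SMOOTH_CM = 4.0
DEFAULT_GOAL_RADIUS_CM = 20.0


@dataclass
class RateMap:
    """Occupancy-normalized 2D firing-rate grid.

    ``rate`` is the smoothed map used for peaks and population vectors;
    ``raw_rate`` (unsmoothed counts / unsmoothed occupancy) backs the
    coherence statistic.  Bins never visited are masked (NaN rate).
    """

    bin_size: float
    origin: tuple[float, float]        # (x, y) of the low corner of bin (0, 0)
    occupancy: np.ndarray              # seconds per bin, unsmoothed
    rate: np.ndarray                   # Hz, NaN where unvisited
    raw_rate: np.ndarray               # Hz, NaN where unvisited
    visited: np.ndarray                # bool
    spike_count: np.ndarray            # unsmoothed spikes per bin

    @property
    def shape(self):
        return self.occupancy.shape

    def same_geometry(self, other: "RateMap") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.bin_size, other.bin_size)
                and np.allclose(self.origin, other.origin))

    def bin_of(self, x, y):
        """Bin index of a point; bin i covers [origin + i*bin, origin + (i+1)*bin)."""
        i = int(np.floor((x - self.origin[0]) / self.bin_size))
        j = int(np.floor((y - self.origin[1]) / self.bin_size))
        return i, j

    def peak_location(self):
        """(x, y) center of the maximum-rate visited bin; None if all silent."""
        r = np.where(self.visited, self.rate, -np.inf)
        if not np.isfinite(r).any() or np.nanmax(r) <= 0:
            return None
        i, j = np.unravel_index(np.argmax(r), r.shape)
        return (self.origin[0] + (i + 0.5) * self.bin_size,
                self.origin[1] + (j + 0.5) * self.bin_size)

    @property
    def peak_rate(self):
        vals = self.rate[self.visited]
        return float(np.nanmax(vals)) if vals.size else float("nan")

    def to_tsv(self, path) -> None:
        """Write the smoothed rate grid as a TSV matrix (NaN = unvisited)."""
        header = (f"# bin_size={self.bin_size} origin={self.origin[0]}"
                  f",{self.origin[1]}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.rate, delimiter="\t", fmt="%.6g")


def compute_rate_map(spike_times, position, intervals, bin_size=DEFAULT_BIN_CM,
                     smoothing_sd=DEFAULT_SMOOTH_CM, extent=None,
                     speed=None) -> RateMap:
    """Rate map of one unit from exploratory epochs (speed > 5 cm/s).

    ``extent`` fixes the grid as (x0, x1, y0, y1) so maps from different
    sessions share geometry; defaults to the track's bounding box.
    ``speed`` may be a precomputed series aligned with the track.
    """
    from .core import speed_from_track
    t = position.time.to_numpy()
    if speed is None:
        _, speed = speed_from_track(position)
    fs = 1.0 / np.median(np.diff(t))
    keep = in_intervals(t, intervals) & (speed > SPEED_THRESHOLD)
    if not keep.any():
        raise ValueError("zero occupancy after speed/interval filtering")
    xs, ys = position.x.to_numpy()[keep], position.y.to_numpy()[keep]

    if extent is None:
        extent = (position.x.min(), position.x.max(),
                  position.y.min(), position.y.max())
    x0, x1, y0, y1 = map(float, extent)
    nx = max(1, int(np.ceil((x1 - x0) / bin_size)))
    ny = max(1, int(np.ceil((y1 - y0) / bin_size)))
    edges_x = x0 + bin_size * np.arange(nx + 1)
    edges_y = y0 + bin_size * np.arange(ny + 1)

    occ, _, _ = np.histogram2d(xs, ys, bins=[edges_x, edges_y])
    occ /= fs   # samples -> seconds

    st = np.asarray(spike_times, dtype=float)
    # spikes inherit the speed/interval filter of their nearest track sample
    idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
    st = st[keep[idx]]
    sx = np.interp(st, t, position.x.to_numpy())
    sy = np.interp(st, t, position.y.to_numpy())
    cnt, _, _ = np.histogram2d(sx, sy, bins=[edges_x, edges_y])

    visited = occ > 0
    raw = np.full(occ.shape, np.nan)
    raw[visited] = cnt[visited] / occ[visited]

    if smoothing_sd > 0:
        sig = smoothing_sd / bin_size
        occ_s = ndimage.gaussian_filter(occ, sig, mode="constant")
        cnt_s = ndimage.gaussian_filter(cnt, sig, mode="constant")
    else:
        occ_s, cnt_s = occ, cnt
    rate = np.full(occ.shape, np.nan)
    ok = visited & (occ_s > 0)
    rate[ok] = cnt_s[ok] / occ_s[ok]

    return RateMap(bin_size=float(bin_size), origin=(x0, y0), occupancy=occ,
                   rate=rate, raw_rate=raw, visited=visited, spike_count=cnt)


def coherence(rate_map: RateMap, min_bins=10, min_neighbors=4) -> float:
    """Fisher z of the correlation between each bin's (unsmoothed) rate and
    its visited 8-neighbor mean.  NaN when undefined (constant map or too
    few qualifying bins)."""
    r = rate_map.raw_rate
    v = rate_map.visited.astype(float)
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)
    filled = np.where(rate_map.visited, r, 0.0)
    nb_sum = ndimage.convolve(filled, kernel, mode="constant")
    nb_cnt = ndimage.convolve(v, kernel, mode="constant")
    ok = rate_map.visited & (nb_cnt >= min_neighbors)
    if ok.sum() < min_bins:
        return float("nan")
    a = r[ok]
    b = nb_sum[ok] / nb_cnt[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    rho = float(np.corrcoef(a, b)[0, 1])
    rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    return float(np.arctanh(rho))


def sparsity(rate_map: RateMap) -> float:
    """(sum P_i R_i)^2 / sum P_i R_i^2 over visited bins; in (0, 1]."""
    occ = rate_map.occupancy[rate_map.visited]
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy")
    p = occ / occ.sum()
    r = rate_map.raw_rate[rate_map.visited]
    denom = np.sum(p * r**2)
    if denom == 0:
        return float("nan")    # silent map: statistic undefined
    return float(np.sum(p * r) ** 2 / denom)


def field_similarity(map_a: RateMap, map_b: RateMap, min_bins=10) -> float:
    """Pearson correlation of rates over bins visited in both maps."""
    if not map_a.same_geometry(map_b):
        raise ValueError("rate maps have mismatched geometry")
    both = map_a.visited & map_b.visited
    if both.sum() < min_bins:
        return float("nan")
    a, b = map_a.rate[both], map_b.rate[both]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def is_goal_centric(rate_map: RateMap, goals, radius=DEFAULT_GOAL_RADIUS_CM) -> bool:
    """True iff the map's peak lies within ``radius`` of any goal."""
    peak = rate_map.peak_location()
    if peak is None:
        return False
    goals = np.asarray(goals, dtype=float).reshape(-1, 2)
    if goals.size == 0:
        return False
    d = np.hypot(goals[:, 0] - peak[0], goals[:, 1] - peak[1])
    return bool(np.min(d) <= radius)


@dataclass
class PlaceFieldStats:
    unit_id: int
    coherence: float
    sparsity: float
    peak_rate: float
    peak_location: tuple[float, float] | None
    is_place_cell: bool
    is_goal_centric: bool


def place_field_stats(unit_id, rate_map: RateMap, goals=(),
                      goal_radius=DEFAULT_GOAL_RADIUS_CM) -> PlaceFieldStats:
    coh = coherence(rate_map)
    spa = sparsity(rate_map)
    ok = (np.isfinite(coh) and np.isfinite(spa)
          and coh >= COHERENCE_MIN and spa <= SPARSITY_MAX)
    return PlaceFieldStats(
        unit_id=int(unit_id),
        coherence=coh,
        sparsity=spa,
        peak_rate=rate_map.peak_rate,
        peak_location=rate_map.peak_location(),
        is_place_cell=bool(ok),
        is_goal_centric=is_goal_centric(rate_map, goals, goal_radius),
    )
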
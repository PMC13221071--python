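"""Occupancy-normalized rate maps, Skaggs information and goal-reorganization labels.

Rate maps bin the 150-cm maze into 5 x 5 cm bins, keep only samples where the
animal moved faster than 4 cm/s, mask bins occupied for less than 200 ms, and
smooth the rate map with a Gaussian kernel (5 bins, sigma = 1.5 bins) whose
weights are renormalized over valid bins so firing does not bleed into
unvisited territory.

Spatial tuning is summarized by the Skaggs information

    I = sum_i p_i (r_i / rbar) log2(r_i / rbar)   [bits/spike]

over valid bins, with occupancy probabilities p_i renormalized over the same
support and rbar = sum_i p_i r_i.

Goal coding is scored by overlap between a unit's peak region (bins with rate
>= 80% of the map peak; maps require a >1 Hz peak) and a 3 x 3-bin window
centred on each rewarded well (a 15-cm neighbourhood).  A unit is
*goal-related* if its peak region overlaps the previous-day goals in the
pre-probe map or the current-day goals in the post-probe map, and a
*reorganization* cell if it does both - i.e. its field tracked the daily goal
switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PositionTrack, Unit

BIN_CM = 5.0
MIN_OCCUPANCY_S = 0.2
SPEED_MIN_CMS = 4.0
SMOOTH_KERNEL_BINS = 5
SMOOTH_SIGMA_BINS = 1.5
PEAK_FRACTION = 0.8
MIN_PEAK_RATE_HZ = 1.0
MAZE_EXTENT_CM = 150.0


@dataclass
class RateMap:
    """Smoothed occupancy-normalized firing-rate grid for one unit.

    ``rate`` is NaN where ``valid_mask`` is False (occupancy under 200 ms).
    Bin (0, 0) sits at the lower-left corner of the square grid covering the
    maze; ``origin`` is that corner in maze coordinates.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    valid_mask: np.ndarray
    origin: tuple[float, float]
    bin_cm: float = BIN_CM
    peak_rate: float = field(init=False)
    peak_bin: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.valid_mask.any():
            masked = np.where(self.valid_mask, self.rate, -np.inf)
            flat = int(np.argmax(masked))
            self.peak_bin = tuple(np.unravel_index(flat, self.rate.shape))
            self.peak_rate = float(self.rate[self.peak_bin])
        else:
            self.peak_bin = (0, 0)
            self.peak_rate = 0.0

    @property
    def n_bins(self) -> int:
        return int(self.valid_mask.sum())

    def bin_of(self, xy: np.ndarray) -> tuple[int, int]:
        """Grid bin (row, col) containing a maze-frame point, by floor division."""
        x, y = float(xy[0]), float(xy[1])
        col = int(np.floor((x - self.origin[0]) / self.bin_cm))
        row = int(np.floor((y - self.origin[1]) / self.bin_cm))
        n_rows, n_cols = self.rate.shape
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(f"point {xy} outside the rate-map grid")
        return row, col


def _gaussian_kernel(size: int = SMOOTH_KERNEL_BINS, sigma: float = SMOOTH_SIGMA_BINS) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _masked_smooth(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gaussian smoothing with kernel weights renormalized over valid bins."""
    from scipy.signal import convolve2d

    k = _gaussian_kernel()
    v = np.where(mask, values, 0.0)
    num = convolve2d(v, k, mode="same")
    den = convolve2d(mask.astype(float), k, mode="same")
    out = np.full_like(values, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def compute_rate_map(
    unit: Unit,
    track: PositionTrack,
    speed_min: float = SPEED_MIN_CMS,
    extent: float = MAZE_EXTENT_CM,
    smooth: bool = True,
) -> RateMap:
    """Bin spikes and occupancy at 5 cm, divide, mask, then smooth.

    Occupancy per bin is the cumulative time of >``speed_min`` track samples;
    spikes are positioned by linear interpolation of the track at spike times
    and kept only when the instantaneous speed at the spike exceeds the same
    threshold.  Division happens before smoothing; the smoothed map defines
    the peak and feeds every downstream statistic.
    """
    n_bins = int(np.ceil(extent / BIN_CM))
    origin = (-extent / 2.0, -extent / 2.0)
    edges = origin[0] + BIN_CM * np.arange(n_bins + 1)

    moving = track.velocity > speed_min
    if not moving.any():
        raise ValueError("no track samples above the speed threshold")
    dt = 1.0 / track.fs
    occ, _, _ = np.histogram2d(
        track.y[moving], track.x[moving], bins=(edges, edges)
    )
    occ *= dt
    if occ.sum() == 0:
        raise ValueError("zero total occupancy")

    st = unit.spike_times
    st = st[(st >= track.times[0]) & (st <= track.times[-1])]
    sx = np.interp(st, track.times, track.x)
    sy = np.interp(st, track.times, track.y)
    sv = np.interp(st, track.times, track.velocity)
    keep = sv > speed_min
    spikes, _, _ = np.histogram2d(sy[keep], sx[keep], bins=(edges, edges))

    valid = occ >= MIN_OCCUPANCY_S
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(valid, spikes / occ, np.nan)
    if smooth:
        rate = _masked_smooth(np.nan_to_num(rate), valid)
    return RateMap(rate=rate, occupancy=occ, valid_mask=valid, origin=origin)


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs information in bits/spike; NaN when the mean rate is zero."""
    valid = rate_map.valid_mask
    if not valid.any():
        raise ValueError("rate map has no valid bins")
    p = rate_map.occupancy[valid]
    p = p / p.sum()
    r = rate_map.rate[valid]
    rbar = float(np.sum(p * r))
    if rbar == 0:
        return float("nan")
    ratio = r / rbar
    terms = np.zeros_like(ratio)
    pos = ratio > 0
    terms[pos] = p[pos] * ratio[pos] * np.log2(ratio[pos])
    return float(terms.sum())


def peak_region(rate_map: RateMap, frac: float = PEAK_FRACTION) -> set[tuple[int, int]]:
    """Valid bins with rate >= ``frac`` of the map peak (ties kept).

    Maps with peak rate <= 1 Hz carry too little signal and are excluded from
    goal classification; this raises so callers can record the exclusion.
    """
    if rate_map.peak_rate <= MIN_PEAK_RATE_HZ:
        raise ValueError(
            f"peak rate {rate_map.peak_rate:.3f} Hz <= {MIN_PEAK_RATE_HZ} Hz"
        )
    rows, cols = np.where(
        rate_map.valid_mask & (rate_map.rate >= frac * rate_map.peak_rate)
    )
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def goal_window(rate_map: RateMap, goal_xy: np.ndarray) -> set[tuple[int, int]]:
    """3 x 3 block of bins centred on the bin containing the goal."""
    row, col = rate_map.bin_of(goal_xy)
    n_rows, n_cols = rate_map.rate.shape
    return {
        (r, c)
        for r in range(row - 1, row + 2)
        for c in range(col - 1, col + 2)
        if 0 <= r < n_rows and 0 <= c < n_cols
    }


def goal_overlap(
    peak_bins: set[tuple[int, int]], goals: np.ndarray, rate_map: RateMap
) -> int:
    """Max over the two goals of |peak region ∩ 3x3 goal window| (0..9)."""
    goals = np.atleast_2d(np.asarray(goals, dtype=float))
    return max(len(peak_bins & goal_window(rate_map, g)) for g in goals)


def peak_to_goal_distance(rate_map: RateMap, goals: np.ndarray) -> float:
    """Min Euclidean distance (cm) from the peak bin centre to a goal."""
    goals = np.atleast_2d(np.asarray(goals, dtype=float))
    row, col = rate_map.peak_bin
    cx = rate_map.origin[0] + (col + 0.5) * rate_map.bin_cm
    cy = rate_map.origin[1] + (row + 0.5) * rate_map.bin_cm
    return float(np.min(np.hypot(goals[:, 0] - cx, goals[:, 1] - cy)))


@dataclass
class GoalOverlapResult:
    unit_id: str
    overlap_prev: int
    overlap_curr: int
    peak_to_goal_prev: float
    peak_to_goal_curr: float
    peak_region_size_pre: int
    peak_region_size_post: int
    goal_related: bool
    reorganization: bool


def classify_goal_cells(
    unit_id: str,
    pre_map: RateMap,
    post_map: RateMap,
    goals_previous: np.ndarray,
    goals_current: np.ndarray,
) -> GoalOverlapResult:
    """Label a unit from its pre- and post-probe maps.

    Overlap with the previous-day goal set is evaluated on the pre-probe map
    and overlap with the current-day goal set on the post-probe map.  Either
    overlap makes the unit goal-related; both together make it a
    reorganization cell (reorganization implies goal-related by construction).
    Raises if either map fails the >1 Hz peak-rate rule.
    """
    pre_bins = peak_region(pre_map)
    post_bins = peak_region(post_map)
    ov_prev = goal_overlap(pre_bins, goals_previous, pre_map)
    ov_curr = goal_overlap(post_bins, goals_current, post_map)
    return GoalOverlapResult(
        unit_id=unit_id,
        overlap_prev=ov_prev,
        overlap_curr=ov_curr,
        peak_to_goal_prev=peak_to_goal_distance(pre_map, goals_previous),
        peak_to_goal_curr=peak_to_goal_distance(post_map, goals_current),
        peak_region_size_pre=len(pre_bins),
        peak_region_size_post=len(post_bins),
        goal_related=ov_prev > 0 or ov_curr > 0,
        reorganization=ov_prev > 0 and ov_curr > 0,
    )


def session_fractions(labels: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per (session, region, cell_type) fraction of units with ``column`` True.

    ``labels`` needs columns session_id, region, cell_type and the boolean
    ``column``.  Empty strata simply do not appear (fraction undefined).
    """
    grouped = labels.groupby(["session_id", "region", "cell_type"])[column]
    out = grouped.agg(fraction="mean", eligible="size", labeled="sum").reset_index()
    return out
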
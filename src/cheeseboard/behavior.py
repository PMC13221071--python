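"""Trajectory metrics, goal-visit detection, epoch segmentation and breakpoint fits.

Within each learning trial only two behavioral states are distinguished:
*Goal* (the animal is within 15 cm of a rewarded well) and *Navigation*
(travel from the start box to the first goal, or between the two goals).
Because each trial visits two goals, this yields four ordered epochs per
complete trial: Navigation1, Goal1, Navigation2, Goal2, labelled by order of
arrival rather than by goal identity.  Trials 1-10, 11-20, 21-30 and 31-40
form learning blocks 1-4.

Learning curves (e.g. trial-by-trial path length) are summarized with a
continuous one-breakpoint piecewise-linear model

    y_i = b0 + b1 * x_i + b2 * max(0, x_i - tau) + e_i

fitted by grid search over integer candidate breakpoints with OLS at each
candidate; b1 is the pre-breakpoint slope and b1 + b2 the post-breakpoint
slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Epoch, PositionTrack, _track_speed

GOAL_RADIUS_CM = 15.0
VISIT_MERGE_GAP_FRAMES = 50
BLOCK_SIZE_TRIALS = 10
#: continuous absence (s) from the goal zone that terminates a Goal epoch
GOAL_DWELL_BREAK_S = 1.0


def compute_velocity(track: PositionTrack) -> np.ndarray:
    """Speed in cm/s at every track sample (shared definition, see core)."""
    return _track_speed(track.times, track.x, track.y)


@dataclass
class Visit:
    goal_index: int
    start_frame: int
    end_frame: int  # inclusive

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive frame indices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_goal_visits(
    track: PositionTrack,
    goals: np.ndarray,
    radius: float = GOAL_RADIUS_CM,
    merge_gap: int = VISIT_MERGE_GAP_FRAMES,
) -> list[Visit]:
    """Merged ROI entry events per goal.

    Consecutive in-ROI frames form one event; two adjacent events are merged
    when the gap between them does not exceed ``merge_gap`` frames (about 1 s
    at 50 Hz), which suppresses brief pass-throughs and tracking dropouts.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    goals = np.atleast_2d(np.asarray(goals, dtype=float))
    visits: list[Visit] = []
    for gi, (gx, gy) in enumerate(goals):
        inside = np.hypot(track.x - gx, track.y - gy) <= radius
        merged: list[list[int]] = []
        for start, end in _runs(inside):
            if merged and start - merged[-1][1] - 1 <= merge_gap:
                merged[-1][1] = end
            else:
                merged.append([start, end])
        visits.extend(Visit(gi, s, e) for s, e in merged)
    return visits


class IncompleteTrialWarning(UserWarning):
    pass


def segment_epochs(
    track: PositionTrack,
    goals: np.ndarray,
    trials: list[tuple[float, float]],
    start_box: tuple[float, float, float, float],
) -> list[Epoch]:
    """Segment each trial into Navigation1, Goal1, Navigation2, Goal2.

    Navigation1 runs from the first frame outside the start-box rectangle to
    the first frame inside the 15-cm zone of whichever goal is reached first;
    Goal1 is the dwell at that goal (terminated by a >= 1-s continuous absence
    from the zone); Navigation2 and Goal2 repeat the pattern for the remaining
    goal.  Trials that never reach both goals are flagged and skipped.
    """
    goals = np.asarray(goals, dtype=float)
    xmin, xmax, ymin, ymax = start_box
    t = track.times
    epochs: list[Epoch] = []
    gap_frames = int(round(GOAL_DWELL_BREAK_S * track.fs))

    for trial_idx, (t0, t1) in enumerate(trials):
        lo, hi = np.searchsorted(t, [t0, t1])
        block = trial_idx // BLOCK_SIZE_TRIALS + 1
        sl = slice(lo, hi)
        x, y = track.x[sl], track.y[sl]
        in_box = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        out_idx = np.flatnonzero(~in_box)
        if out_idx.size == 0:
            warnings.warn(
                f"trial {trial_idx}: never left the start box", IncompleteTrialWarning
            )
            continue
        exit_f = int(out_idx[0])

        inside = [
            np.hypot(x - gx, y - gy) <= GOAL_RADIUS_CM for gx, gy in goals
        ]

        def first_entry(goal_i: int, after: int) -> int | None:
            hits = np.flatnonzero(inside[goal_i][after:])
            return None if hits.size == 0 else after + int(hits[0])

        def dwell_end(goal_i: int, entry: int) -> int:
            # last in-zone frame before a continuous absence of >= gap_frames
            mask = inside[goal_i]
            last = entry
            i = entry
            while i < mask.size:
                if mask[i]:
                    last = i
                    i += 1
                else:
                    nxt = np.flatnonzero(mask[i:])
                    if nxt.size == 0 or nxt[0] >= gap_frames:
                        break
                    i += int(nxt[0])
            return last

        e1 = [first_entry(0, exit_f), first_entry(1, exit_f)]
        if e1[0] is None and e1[1] is None:
            warnings.warn(
                f"trial {trial_idx}: reached no goal", IncompleteTrialWarning
            )
            continue
        first_goal = 0 if (e1[1] is None or (e1[0] is not None and e1[0] <= e1[1])) else 1
        entry1 = e1[first_goal]
        end1 = dwell_end(first_goal, entry1)
        second_goal = 1 - first_goal
        entry2 = first_entry(second_goal, end1 + 1)
        if entry2 is None:
            warnings.warn(
                f"trial {trial_idx}: reached only one goal", IncompleteTrialWarning
            )
            continue
        end2 = dwell_end(second_goal, entry2)

        def tt(frame: int) -> float:
            return float(t[lo + frame])

        epochs.extend(
            [
                Epoch("Navigation1", trial_idx, block, tt(exit_f), tt(entry1)),
                Epoch("Goal1", trial_idx, block, tt(entry1), tt(end1)),
                Epoch("Navigation2", trial_idx, block, tt(end1), tt(entry2)),
                Epoch("Goal2", trial_idx, block, tt(entry2), tt(end2)),
            ]
        )
    return epochs


def trajectory_length(track: PositionTrack, trial: tuple[float, float]) -> float:
    """Total path length (cm) over the trial window: sum of step lengths."""
    lo, hi = np.searchsorted(track.times, trial)
    x, y = track.x[lo:hi], track.y[lo:hi]
    if x.size < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


@dataclass
class BreakpointFit:
    tau: int
    beta0: float
    beta1: float
    beta2: float
    rss: float

    @property
    def pre_slope(self) -> float:
        return self.beta1

    @property
    def post_slope(self) -> float:
        return self.beta1 + self.beta2


def fit_breakpoint(y: np.ndarray, x: np.ndarray | None = None) -> BreakpointFit:
    """Grid-search OLS fit of the one-breakpoint piecewise-linear model.

    Candidate breakpoints are the integer trials 3 .. n-2 (endpoints excluded
    so both segments retain support); ties in RSS resolve to the smallest
    candidate.  Rank-deficient candidate designs are skipped.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        raise ValueError("breakpoint fit needs at least 5 trials")
    if not np.all(np.isfinite(y)):
        raise ValueError("breakpoint fit requires finite y")
    x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, float)

    best: BreakpointFit | None = None
    for tau in range(3, y.size - 1):
        hinge = np.maximum(0.0, x - tau)
        design = np.column_stack([np.ones_like(x), x, hinge])
        if np.linalg.matrix_rank(design) < 3:
            continue
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        if best is None or rss < best.rss - 1e-12:
            best = BreakpointFit(tau, *(float(b) for b in beta), rss)
    if best is None:
        raise ValueError("no full-rank breakpoint candidate")
    return best


def velocity_distribution(
    speeds: np.ndarray, bin_width: float = 2.0, vmax: float = 50.0
) -> np.ndarray:
    """z-scored histogram of speeds in 2-cm/s bins over 0-50 cm/s (25 bins)."""
    speeds = np.asarray(speeds, dtype=float)
    edges = np.arange(0.0, vmax + bin_width, bin_width)
    counts, _ = np.histogram(speeds, bins=edges)
    counts = counts.astype(float)
    sd = counts.std()
    if sd == 0:
        raise ValueError("speed histogram has zero variance across bins")
    return (counts - counts.mean()) / sd
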
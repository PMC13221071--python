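"""Theta phase locking of single units and jitter-tested short-latency CCG coordination.

Pairwise coordination follows the excess-coincidence logic: spike trains are
binarized at 1 ms, the directed cross-correlogram CCG(tau) over lags of
+-50 ms is normalized by the reference neuron's spike count N_A, a baseline
estimated from absolute lags of 20-50 ms is subtracted, and the coordination
strength T_obs is the maximum excess within 1-3 ms (within-region pairs) or
1-5 ms (cross-region pairs).  Significance comes from 1,000 surrogate trains
in which every target spike is shifted by an independent integer offset drawn
uniformly from [-25, 25] ms (coarse rate structure preserved, fine timing
destroyed), with the one-sided empirical p value

    p = (1 + #{T_k >= T_obs}) / (1 + N_surr)

and Benjamini-Hochberg correction (q < 0.05) within each group of pairs
sharing a reference neuron.  Learning trends over the four blocks are
classified only when the OLS slope beta of strength against block number and
the net change Delta = B4 - B1 agree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LAGS = 50  # +-50 ms at 1-ms resolution
BASELINE_LAGS = (20, 50)
WINDOW_WITHIN = (1, 3)
WINDOW_CROSS = (1, 5)
N_SURROGATES = 1000
JITTER_MS = 25
MIN_PHASE_SPIKES = 50


# ---------------------------------------------------------------------------
# theta phase locking


@dataclass
class PhaseLocking:
    unit_id: str
    n_spikes: int
    rayleigh_p: float
    kappa: float  # NaN unless rayleigh_p < 0.05
    preferred_phase_deg: float
    histogram: np.ndarray  # 36 bins over 0-360 degrees
    bin_edges_deg: np.ndarray


def spikes_in_intervals(spike_times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Spike times falling inside any of the (start, end) intervals."""
    if not intervals:
        return np.empty(0)
    arr = np.asarray(intervals)
    starts, ends = arr[:, 0], arr[:, 1]
    idx = np.searchsorted(starts, spike_times, side="right") - 1
    ok = (idx >= 0) & (spike_times <= ends[np.clip(idx, 0, len(ends) - 1)])
    return spike_times[ok]


def theta_phase_locking(
    unit_id: str,
    spike_times: np.ndarray,
    cycles: list[tuple[float, float]],
    phase: np.ndarray,
    fs: float = 1000.0,
    n_hist_bins: int = 36,
) -> PhaseLocking | None:
    """Phase histogram, Rayleigh test, and von Mises kappa for one unit.

    Spikes are restricted to valid theta cycles (already SWR-excluded by the
    cycle detector).  Units contributing fewer than 50 spikes are excluded
    (returns None).  kappa is estimated by maximum-likelihood von Mises fit
    only when the Rayleigh test rejects uniformity at p < 0.05.
    """
    from pingouin import circ_rayleigh
    from scipy.stats import vonmises

    st = spikes_in_intervals(np.asarray(spike_times, float), cycles)
    if st.size < MIN_PHASE_SPIKES:
        return None
    sample = np.clip(np.round(st * fs).astype(int), 0, phase.size - 1)
    phases = phase[sample]  # radians in (-pi, pi]

    z, p = circ_rayleigh(phases)
    kappa = float("nan")
    pref = float(np.degrees(np.angle(np.mean(np.exp(1j * phases)))) % 360.0)
    if p < 0.05:
        kappa, _, _ = vonmises.fit(phases, fscale=1)
        kappa = float(kappa)
    edges = np.linspace(0.0, 360.0, n_hist_bins + 1)
    hist, _ = np.histogram(np.degrees(phases) % 360.0, bins=edges)
    return PhaseLocking(unit_id, int(st.size), float(p), kappa, pref, hist, edges)


# ---------------------------------------------------------------------------
# cross-correlogram coordination


def binarize_ms(spike_times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Unique sorted 1-ms bin indices of spikes in [t0, t1)."""
    st = np.asarray(spike_times, float)
    st = st[(st >= t0) & (st < t1)]
    return np.unique(np.floor((st - t0) * 1000.0).astype(np.int64))


@dataclass
class PairCoordination:
    ref_id: str
    target_id: str
    window: tuple[int, int]
    ccg_norm: np.ndarray  # 101 lags, -50..50 ms
    baseline: float
    strength: float
    p_emp: float = float("nan")
    significant: bool = False
    lags: np.ndarray = field(default_factory=lambda: np.arange(-N_LAGS, N_LAGS + 1))

    @property
    def excess(self) -> np.ndarray:
        return self.ccg_norm - self.baseline


def _ccg_from_deltas(deltas: np.ndarray, n_ref: int) -> np.ndarray:
    hist = np.bincount(deltas + N_LAGS, minlength=2 * N_LAGS + 1)
    return hist / n_ref


def _pair_deltas(ref_bins: np.ndarray, tgt_bins: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """All (target - ref) bin differences within +-max_lag.

    Returns the delta array and, aligned with it, the index of the target
    spike producing each delta (needed to propagate per-spike jitter).
    """
    lo = np.searchsorted(ref_bins, tgt_bins - max_lag, side="left")
    hi = np.searchsorted(ref_bins, tgt_bins + max_lag, side="right")
    counts = hi - lo
    tgt_idx = np.repeat(np.arange(tgt_bins.size), counts)
    # ragged gather of ref indices per target spike
    ref_idx = np.concatenate(
        [np.arange(a, b) for a, b in zip(lo, hi)]
    ) if counts.sum() else np.empty(0, dtype=int)
    deltas = tgt_bins[tgt_idx] - ref_bins[ref_idx]
    return deltas.astype(np.int64), tgt_idx


def ccg_excess(
    ref_bins: np.ndarray,
    tgt_bins: np.ndarray,
    window: tuple[int, int] = WINDOW_CROSS,
    ref_id: str = "A",
    target_id: str = "B",
) -> PairCoordination:
    """Normalized CCG, long-lag baseline, and short-latency strength.

    ``window`` is inclusive of both end lags (1-3 means lags {1, 2, 3}).
    Raises if the reference train is empty.
    """
    if ref_bins.size == 0:
        raise ValueError("reference train has no spikes in the block")
    deltas, _ = _pair_deltas(ref_bins, tgt_bins, N_LAGS)
    ccg = _ccg_from_deltas(deltas, ref_bins.size)
    lags = np.arange(-N_LAGS, N_LAGS + 1)
    base_sel = (np.abs(lags) >= BASELINE_LAGS[0]) & (np.abs(lags) <= BASELINE_LAGS[1])
    baseline = float(ccg[base_sel].mean())
    win_sel = (lags >= window[0]) & (lags <= window[1])
    strength = float((ccg - baseline)[win_sel].max())
    return PairCoordination(ref_id, target_id, window, ccg, baseline, strength)


def jitter_null(
    ref_bins: np.ndarray,
    tgt_bins: np.ndarray,
    window: tuple[int, int] = WINDOW_CROSS,
    n_surr: int = N_SURROGATES,
    jitter: int = JITTER_MS,
    rng: np.random.Generator | None = None,
    observed: PairCoordination | None = None,
) -> PairCoordination:
    """Empirical one-sided p value of the coordination strength.

    Every surrogate shifts each target spike by an independent uniform integer
    offset in [-jitter, jitter]; colliding spikes re-binarize to a single
    occupied 1-ms bin.  The surrogate statistic T_k is recomputed exactly as
    the observed one, and p = (1 + #{T_k >= T_obs}) / (1 + n_surr); the
    smallest attainable p is 1/(n_surr + 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    pair = observed or ccg_excess(ref_bins, tgt_bins, window)

    # candidate pairs within +-(50 + jitter) ms can land inside +-50 after jitter
    deltas, tgt_idx = _pair_deltas(ref_bins, tgt_bins, N_LAGS + jitter)
    n_t = tgt_bins.size
    offsets = rng.integers(-jitter, jitter + 1, size=(n_surr, n_t)).astype(np.int64)

    # per-surrogate duplicate mask: spikes jittered into an occupied bin
    jittered = tgt_bins[None, :] + offsets
    order = np.argsort(jittered, axis=1, kind="stable")
    sorted_j = np.take_along_axis(jittered, order, axis=1)
    dup_sorted = np.zeros_like(jittered, dtype=bool)
    dup_sorted[:, 1:] = sorted_j[:, 1:] == sorted_j[:, :-1]
    dup = np.empty_like(dup_sorted)
    np.put_along_axis(dup, order, dup_sorted, axis=1)

    shifted = deltas[None, :] + offsets[:, tgt_idx]
    valid = (np.abs(shifted) <= N_LAGS) & ~dup[:, tgt_idx]
    rows = np.broadcast_to(np.arange(n_surr)[:, None], shifted.shape)
    flat = rows[valid] * (2 * N_LAGS + 1) + (shifted[valid] + N_LAGS)
    counts = np.bincount(flat, minlength=n_surr * (2 * N_LAGS + 1)).reshape(
        n_surr, 2 * N_LAGS + 1
    )
    norm = counts / ref_bins.size
    lags = np.arange(-N_LAGS, N_LAGS + 1)
    base_sel = (np.abs(lags) >= BASELINE_LAGS[0]) & (np.abs(lags) <= BASELINE_LAGS[1])
    win_sel = (lags >= window[0]) & (lags <= window[1])
    t_k = (norm[:, win_sel] - norm[:, base_sel].mean(axis=1, keepdims=True)).max(axis=1)

    pair.p_emp = float((1 + np.sum(t_k >= pair.strength)) / (1 + n_surr))
    return pair


def fdr_by_reference(
    pvals: np.ndarray, ref_ids: np.ndarray, q: float = 0.05
) -> np.ndarray:
    """Benjamini-Hochberg step-up applied within each reference-neuron group."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, float)
    ref_ids = np.asarray(ref_ids)
    flags = np.zeros(pvals.size, dtype=bool)
    for ref in np.unique(ref_ids):
        sel = ref_ids == ref
        flags[sel] = multipletests(pvals[sel], alpha=q, method="fdr_bh")[0]
    return flags


def classify_trend(strengths: np.ndarray) -> tuple[str, float, float]:
    """Label a pair's four block strengths as increased/decreased/unclassified.

    beta is the OLS slope of strength on block number {1..4}; Delta = B4 - B1.
    A label is assigned only when the signs of beta and Delta agree.
    Returns (label, beta, delta).
    """
    strengths = np.asarray(strengths, float)
    if strengths.size != 4 or not np.all(np.isfinite(strengths)):
        return "unclassified", float("nan"), float("nan")
    x = np.arange(1, 5, dtype=float)
    beta = float(np.polyfit(x, strengths, 1)[0])
    delta = float(strengths[3] - strengths[0])
    if beta > 0 and delta > 0:
        return "increased", beta, delta
    if beta < 0 and delta < 0:
        return "decreased", beta, delta
    return "unclassified", beta, delta


def pair_direction(ref_region: str, target_region: str) -> str:
    if ref_region == target_region:
        return f"within_{ref_region}"
    return f"{ref_region}->{target_region}"


def reorganization_pair_counts(pairs: pd.DataFrame) -> pd.DataFrame:
    """Session-level counts of reorganization-labelled neurons in trend pairs.

    ``pairs`` needs one row per significant pair with columns ``session_id``,
    ``ref_region``, ``target_region``, ``trend`` and ``ref_reorganization``
    (the label of the pair's first constituent neuron; pairs with missing
    labels should be dropped by the caller).  Returns one row per
    session x direction x trend with reorganization / non-reorganization
    counts.
    """
    df = pairs.copy()
    df["direction"] = [
        pair_direction(r, t) for r, t in zip(df["ref_region"], df["target_region"])
    ]
    df = df[df["trend"].isin(["increased", "decreased"])]
    out = (
        df.groupby(["session_id", "direction", "trend"])["ref_reorganization"]
        .agg(reorganization="sum", total="size")
        .reset_index()
    )
    out["reorganization"] = out["reorganization"].astype(int)
    out["non_reorganization"] = out["total"] - out["reorganization"]
    return out
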
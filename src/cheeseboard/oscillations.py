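"""LFP filtering, spectral power, phase coupling, theta-cycle and SWR detection.

Bands follow the study conventions: theta 4-12 Hz, low gamma 30-60 Hz, high
gamma 60-90 Hz, ripple 150-250 Hz; the delta band used only for the
theta/delta gate is 1-4 Hz (a standard convention, configurable).  All
filtering is a 4th-order Butterworth applied forward-backward (zero phase);
instantaneous phase and amplitude come from the analytic signal (Hilbert
transform), with phase zero at the filtered-signal peak and cycle boundaries
at troughs (phase +-pi).

Coupling metrics:

* PLV = |mean exp(i(phi1 - phi2))| - same-frequency phase synchronization,
  1 for a constant phase offset, ~N^-1/2 for independent phases.
* r_{n:m} = |mean exp(i(n phi_theta - m phi_gamma))| - cross-frequency
  phase-phase coupling, scanned over 1:1 .. 1:10.
* Modulation index MI = (Hmax - H)/Hmax where H is the entropy of the mean
  amplitude-envelope distribution over 18 phase bins of 20 degrees and
  Hmax = log 18; MI = 0 for a phase-uniform envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt, welch

from .core import LfpSignal

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 12.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 90.0),
    "ripple": (150.0, 250.0),
}

N_PHASE_BINS = 18
SWR_Z_THRESHOLD = 3.0
SWR_SPEED_MAX_CMS = 4.0
SWR_EXCLUSION_PAD_S = 0.1
SWR_MIN_DURATION_S = 0.02
SWR_ENVELOPE_SMOOTH_S = 0.01
THETA_DELTA_RATIO = 3.0
THETA_SPEED_MIN_CMS = 4.0


def bandpass(x: np.ndarray, band: str | tuple[float, float], fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    # second-order sections keep the low-frequency bands numerically stable
    sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, (-pi, pi]) and amplitude envelope."""

    phase: np.ndarray
    amplitude: np.ndarray
    band: tuple[float, float]
    fs: float


def phase_series(x: np.ndarray, band: str | tuple[float, float], fs: float = 1000.0) -> PhaseSeries:
    filtered = bandpass(x, band, fs)
    analytic = hilbert(filtered)
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return PhaseSeries(np.angle(analytic), np.abs(analytic), (lo, hi), fs)


def welch_power(
    x: np.ndarray, fs: float = 1000.0, window_s: float = 1.0, overlap: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with a 1-s window and 90% overlap (1-Hz frequency grid)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < 2 * nperseg:
        raise ValueError("signal shorter than two Welch windows")
    return welch(x, fs=fs, nperseg=nperseg, noverlap=int(round(overlap * nperseg)))


def band_power(freqs: np.ndarray, psd: np.ndarray, band: str | tuple[float, float]) -> float:
    lo, hi = BANDS[band] if isinstance(band, str) else band
    sel = (freqs >= lo) & (freqs <= hi)
    return float(psd[sel].mean())


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value |mean exp(i(phi1 - phi2))| in [0, 1]."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def nm_plv(theta_phase: np.ndarray, gamma_phase: np.ndarray, n: int, m: int) -> float:
    """n:m phase synchronization for m gamma cycles per n theta cycles.

    Computed as |mean exp(i(m phi_theta - n phi_gamma))|: when the gamma
    phase advances m/n times as fast as theta (m gamma cycles within n theta
    cycles), the weighted difference is constant and the statistic is 1, so a
    1:m scan peaks at the generating frequency ratio.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive integers")
    return plv(m * np.asarray(theta_phase, float), n * np.asarray(gamma_phase, float))


@dataclass
class CouplingResult:
    mi: float
    p_j: np.ndarray
    entropy: float
    hmax: float
    phase_bin_edges: np.ndarray
    empty_bins: int = 0


def pac_mi(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> CouplingResult:
    """Normalized-entropy modulation index of phase-amplitude coupling.

    The phase series is divided into ``n_bins`` equal bins spanning the full
    cycle, the mean amplitude envelope is computed per bin and normalized to a
    distribution P_j, and MI = (Hmax - H)/Hmax with H the Shannon entropy of
    P_j and Hmax = log(n_bins).  Phase bins with no samples contribute zero
    amplitude mass and are counted in ``empty_bins``.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.zeros(n_bins)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty]
    total = means.sum()
    if total == 0:
        raise ValueError("amplitude envelope sums to zero")
    p_j = means / total
    pos = p_j > 0
    h = float(-np.sum(p_j[pos] * np.log(p_j[pos])))
    hmax = float(np.log(n_bins))
    return CouplingResult(
        mi=max((hmax - h) / hmax, 0.0),  # rounding can leave -1e-16 at uniformity
        p_j=p_j,
        entropy=h,
        hmax=hmax,
        phase_bin_edges=edges,
        empty_bins=int(np.sum(~nonempty)),
    )


def _speed_at(lfp: LfpSignal, track_times: np.ndarray, speed: np.ndarray) -> np.ndarray:
    """Track speed resampled onto the LFP time base."""
    return np.interp(lfp.times, track_times, speed)


@dataclass
class SwrEvents:
    intervals: list[tuple[float, float]]
    exclusion_mask: np.ndarray  # True at samples to drop (events + 100 ms pad)
    fs: float


def detect_swr(
    lfp: LfpSignal,
    track_times: np.ndarray,
    speed: np.ndarray,
    z_threshold: float = SWR_Z_THRESHOLD,
) -> SwrEvents:
    """Sharp-wave-ripple events: ripple-band envelope > 3 SD at rest.

    The ripple-band envelope is lightly smoothed (10-ms moving average);
    baseline mean/SD are estimated over all samples with speed below 4 cm/s;
    events are contiguous super-threshold runs of at least 20 ms restricted
    to those immobile periods (the duration floor keeps single-sample noise
    excursions from registering as ripples).  The exclusion mask extends
    100 ms past each event so ripple tails do not leak into coupling,
    phase-locking, CCG or assembly analyses.
    """
    env = np.abs(hilbert(bandpass(lfp.samples, "ripple", lfp.fs)))
    win = max(int(round(SWR_ENVELOPE_SMOOTH_S * lfp.fs)), 1)
    kernel = np.ones(win) / win
    env = np.convolve(env, kernel, mode="same")
    v = _speed_at(lfp, track_times, speed)
    rest = v < SWR_SPEED_MAX_CMS
    if not rest.any():
        return SwrEvents([], np.zeros(len(lfp), dtype=bool), lfp.fs)
    mu, sd = env[rest].mean(), env[rest].std()
    if sd == 0:
        return SwrEvents([], np.zeros(len(lfp), dtype=bool), lfp.fs)
    above = ((env - mu) / sd > z_threshold) & rest
    pad = int(round(SWR_EXCLUSION_PAD_S * lfp.fs))
    mask = np.zeros(len(lfp), dtype=bool)
    intervals: list[tuple[float, float]] = []
    idx = np.flatnonzero(above)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        min_len = int(round(SWR_MIN_DURATION_S * lfp.fs))
        for s, e in zip(starts, ends):
            i0, i1 = int(idx[s]), int(idx[e])
            if i1 - i0 + 1 < min_len:
                continue
            intervals.append((i0 / lfp.fs, i1 / lfp.fs))
            mask[i0 : min(i1 + 1 + pad, mask.size)] = True
    return SwrEvents(intervals, mask, lfp.fs)


def detect_theta_cycles(
    lfp: LfpSignal,
    track_times: np.ndarray,
    speed: np.ndarray,
    swr_mask: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Trough-to-trough theta cycles during fast, theta-dominated epochs.

    A cycle (interval between two consecutive troughs of the theta-filtered
    signal) is kept when, over all its samples, speed > 4 cm/s, the
    theta/delta envelope ratio exceeds 3, and no SWR exclusion applies.
    """
    theta = bandpass(lfp.samples, "theta", lfp.fs)
    theta_env = np.abs(hilbert(theta))
    delta_env = np.abs(hilbert(bandpass(lfp.samples, "delta", lfp.fs)))
    v = _speed_at(lfp, track_times, speed)

    # troughs: peaks of the negated filtered trace, at least half a theta
    # period apart (12 Hz upper band edge -> ~83 ms)
    min_dist = int(lfp.fs / BANDS["theta"][1])
    troughs, _ = find_peaks(-theta, distance=min_dist)

    ok = (v > THETA_SPEED_MIN_CMS) & (delta_env > 0) & (
        np.divide(theta_env, np.maximum(delta_env, 1e-12)) > THETA_DELTA_RATIO
    )
    if swr_mask is not None:
        ok &= ~swr_mask
    cycles: list[tuple[float, float]] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        if ok[a : b + 1].all():
            cycles.append((a / lfp.fs, b / lfp.fs))
    return cycles


def speed_power_correlation(
    lfp: LfpSignal,
    track_times: np.ndarray,
    speed: np.ndarray,
    band: str | tuple[float, float],
    window_s: float = 0.2,
) -> tuple[float, float]:
    """Pearson correlation of band power vs mean speed in 200-ms windows."""
    from scipy.stats import pearsonr

    filtered = bandpass(lfp.samples, band, lfp.fs)
    v = _speed_at(lfp, track_times, speed)
    win = int(round(window_s * lfp.fs))
    n_win = len(lfp) // win
    if n_win < 10:
        raise ValueError("need at least 10 windows for the speed-power correlation")
    power = (filtered[: n_win * win] ** 2).reshape(n_win, win).mean(axis=1)
    mean_v = v[: n_win * win].reshape(n_win, win).mean(axis=1)
    r, p = pearsonr(power, mean_v)
    return float(r), float(p)
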
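"""Synthetic cheeseboard sessions with known ground truth.

Every analysis stage in this package is exercised against sessions produced
here: a 50-Hz trajectory performing 40 learning trials whose path length
shortens along a piecewise-linear schedule, 1-kHz LFP per region with
controllable theta phase lag (inter-regional PLV), theta-phase-modulated
gamma (phase-amplitude coupling) and ripple-band transients at goal dwells,
and spike trains with Gaussian place tuning, goal-referenced fields that
remap from the previous to the current day's goals, von Mises theta phase
locking, planted short-latency co-spiking pairs, and latent assembly
co-activation events.

The generator is fully deterministic given ``SynthConfig.seed`` and exposes
its ground truth (field centres, goal/remap flags, locking strengths, planted
pairs, assembly memberships, the path-length schedule) so recovery by the
corresponding analysis stage can be asserted exactly.

Default parameters mirror the study's recording conditions: 40 trials in
four blocks, two goals >50 cm apart and >20 cm from the maze edge on a
150-cm board, 8-Hz theta, 40/75-Hz gamma, ~25-min probe sessions, and
per-session unit yields of order 14-17 pyramidal cells and 4-5 interneurons
per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LfpSignal, PositionTrack, Session, Unit

TWO_PI = 2.0 * np.pi


@dataclass
class CcgPairSpec:
    ref: str  # unit id
    target: str
    latency_ms: int
    excess_prob: float


@dataclass
class AssemblySpec:
    members: list[str]
    event_rate_hz: float = 0.2


@dataclass
class SynthConfig:
    seed: int = 0
    # unit yields per region (per-session scale)
    n_pyr_dca1: int = 14
    n_int_dca1: int = 5
    n_pyr_mofc: int = 17
    n_int_mofc: int = 4
    # spatial tuning
    place_sigma_cm: float = 15.0
    place_peak_hz: float = 8.0
    base_rate_hz: float = 0.5
    int_rate_hz: float = 15.0
    goal_fraction: dict = field(
        default_factory=lambda: {"dCA1": 0.5, "mOFC": 0.65}
    )
    remap_fraction: dict = field(
        default_factory=lambda: {"dCA1": 0.6, "mOFC": 0.65}
    )
    # oscillations
    theta_hz: float = 8.0
    low_gamma_hz: float = 40.0
    high_gamma_hz: float = 75.0
    theta_amp: float = 3.0
    gamma_amp: float = 1.5
    noise_sd: float = 1.0
    pac_depth: float = 0.5
    pac_preferred_phase: float = 0.0
    plv_lag: float = 0.8  # mean inter-regional theta lag (rad)
    plv_lag_jitter: float = 0.3  # SD of the lag fluctuation (rad)
    swr_rate_hz: float = 0.25  # per second of goal dwell
    # spike timing
    theta_locked_fraction: float = 0.5
    theta_kappa: float = 1.5
    ccg_pairs: list[CcgPairSpec] = field(default_factory=list)
    assemblies: list[AssemblySpec] = field(default_factory=list)
    # behavior
    n_trials: int = 40
    breakpoint_trial: int = 10
    path_length_intercept: float = 700.0
    path_pre_slope: float = -30.0
    path_post_slope: float = 0.0
    travel_speed_cms: float = 25.0
    dwell_s: float = 2.0
    probe_duration_s: float = 1500.0
    maze_radius_cm: float = 75.0
    goal_edge_margin_cm: float = 20.0
    goal_min_separation_cm: float = 50.0
    track_fs: float = 50.0
    lfp_fs: float = 1000.0


@dataclass
class GroundTruth:
    place_centers: dict  # unit_id -> (x, y) used during the generated phase
    goal_cells: dict  # unit_id -> bool
    remap_cells: dict  # unit_id -> bool
    theta_locked: dict  # unit_id -> kappa (0 for unlocked)
    ccg_pairs: list[CcgPairSpec]
    assemblies: list[AssemblySpec]
    path_schedule: np.ndarray
    swr_times: list[float]


def path_length_schedule(config: SynthConfig) -> np.ndarray:
    """Target path length per trial: piecewise linear with one breakpoint."""
    x = np.arange(1, config.n_trials + 1, dtype=float)
    hinge = np.maximum(0.0, x - config.breakpoint_trial)
    return (
        config.path_length_intercept
        + config.path_pre_slope * x
        + (config.path_post_slope - config.path_pre_slope) * hinge
    )


def sample_goals(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Previous- and current-day goal pairs honouring placement constraints.

    Same-day goals are >50 cm apart, every current goal is >50 cm from every
    previous goal, and all goals sit >20 cm inside the maze edge.
    """
    r_max = config.maze_radius_cm - config.goal_edge_margin_cm
    sep = config.goal_min_separation_cm

    def draw_point() -> np.ndarray:
        while True:
            p = rng.uniform(-r_max, r_max, 2)
            if np.hypot(*p) <= r_max:
                return p

    for _ in range(10000):
        pts = [draw_point() for _ in range(4)]
        prev, curr = np.array(pts[:2]), np.array(pts[2:])
        ok = (
            np.hypot(*(prev[0] - prev[1])) > sep
            and np.hypot(*(curr[0] - curr[1])) > sep
            and all(
                np.hypot(*(c - p)) > sep for c in curr for p in prev
            )
        )
        if ok:
            return prev, curr
    raise RuntimeError("could not place goals under the separation constraints")


# ---------------------------------------------------------------------------
# trajectory


def _curved_points(
    p0: np.ndarray,
    p1: np.ndarray,
    target_len: float,
    maze_radius: float,
) -> np.ndarray:
    """Dense polyline from p0 to p1 whose arc length matches target_len.

    A perpendicular sinusoidal detour is added to the straight segment; the
    amplitude is found by bisection, with the maze-edge clipping applied
    inside the search so the final (clipped) arc length hits the target.
    The number of wiggles grows with the required extra length so detours
    stay tight enough to fit on the board.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = float(np.hypot(*(p1 - p0)))
    t = np.linspace(0.0, 1.0, 240)
    base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if d <= 0 or target_len <= d * 1.001:
        return base
    direction = (p1 - p0) / d
    normal = np.array([-direction[1], direction[0]])
    n_wiggles = max(2, int(np.ceil((target_len - d) / 25.0)))
    wave = np.sin(np.pi * n_wiggles * t)
    lim = maze_radius - 1.0

    def build(amp: float) -> np.ndarray:
        pts = base + amp * wave[:, None] * normal[None, :]
        radius = np.hypot(pts[:, 0], pts[:, 1])
        over = radius > lim
        pts[over] *= (lim / radius[over])[:, None]
        return pts

    def length(amp: float) -> float:
        pts = build(amp)
        return float(np.hypot(*np.diff(pts, axis=0).T).sum())

    lo, hi = 0.0, 10.0
    while length(hi) < target_len and hi < 500:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if length(mid) < target_len:
            lo = mid
        else:
            hi = mid
    return build(hi)


def _resample(points: np.ndarray, speeds: np.ndarray) -> np.ndarray:
    """Walk along a polyline at the given per-frame speeds (cm per frame)."""
    seg = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    s, out = 0.0, []
    i = 0
    while s < total:
        out.append(s)
        s += speeds[min(i, speeds.size - 1)]
        i += 1
    arc = np.asarray(out)
    x = np.interp(arc, cum, points[:, 0])
    y = np.interp(arc, cum, points[:, 1])
    return np.column_stack([x, y])


def generate_trajectory(
    config: SynthConfig, goals: np.ndarray, rng: np.random.Generator
) -> tuple[PositionTrack, list[tuple[float, float]], list[tuple[float, float]]]:
    """40-trial cheeseboard run: box -> goal1 -> goal2 -> box per trial.

    Per-trial total path length follows the piecewise-linear schedule (the
    extra length is distributed over the three travel legs as sinusoidal
    detours); each goal visit includes a low-speed dwell inside the 15-cm
    ROI.  Returns the track, the trial windows, and the goal-dwell windows
    (used downstream for ripple insertion).
    """
    fs = config.track_fs
    box_center = np.array([0.0, -config.maze_radius_cm + 3.0])
    g1, g2 = np.asarray(goals[0], float), np.asarray(goals[1], float)
    schedule = path_length_schedule(config)

    frames: list[np.ndarray] = []
    trials: list[tuple[float, float]] = []
    dwells: list[tuple[float, float]] = []
    t_cursor = 0.0

    def dwell_block(center: np.ndarray, duration: float) -> np.ndarray:
        n = int(round(duration * fs))
        jitter = rng.normal(0, 0.02, (n, 2)).cumsum(axis=0)
        jitter -= jitter.mean(axis=0)
        return center[None, :] + np.clip(jitter, -3, 3)

    for trial_i in range(config.n_trials):
        trial_start = t_cursor
        pre_box = dwell_block(box_center, 1.0)

        legs = [(box_center, g1), (g1, g2), (g2, box_center)]
        base_lens = [float(np.hypot(*(b - a))) for a, b in legs]
        base_total = sum(base_lens)
        target_total = max(schedule[trial_i], base_total * 1.05)
        extra = target_total - base_total

        leg_frames = []
        for (a, b), bl in zip(legs, base_lens):
            pts = _curved_points(
                a, b, bl + extra * bl / base_total, config.maze_radius_cm
            )
            n_f = max(int(len(pts) / 10), 8)
            speeds = np.clip(
                config.travel_speed_cms + rng.normal(0, 3.0, 4 * len(pts)), 8.0, 45.0
            ) / fs
            leg_frames.append(_resample(pts, speeds))

        parts = [pre_box, leg_frames[0]]
        t_local = pre_box.shape[0] + leg_frames[0].shape[0]
        for gi, g in enumerate((g1, g2)):
            dw = dwell_block(g, config.dwell_s)
            dwells.append(
                (trial_start + t_local / fs, trial_start + (t_local + dw.shape[0]) / fs)
            )
            parts.append(dw)
            t_local += dw.shape[0]
            if gi == 0:
                parts.append(leg_frames[1])
                t_local += leg_frames[1].shape[0]
        parts.append(leg_frames[2])
        parts.append(dwell_block(box_center, 1.0))
        block = np.concatenate(parts, axis=0)

        # keep the path inside the board
        radius = np.hypot(block[:, 0], block[:, 1])
        over = radius > config.maze_radius_cm - 1.0
        block[over] *= ((config.maze_radius_cm - 1.0) / radius[over])[:, None]

        frames.append(block)
        t_cursor = trial_start + block.shape[0] / fs
        trials.append((trial_start, t_cursor))

    xy = np.concatenate(frames, axis=0)
    times = np.arange(xy.shape[0]) / fs
    return PositionTrack(times, xy[:, 0], xy[:, 1]), trials, dwells


def generate_probe_trajectory(config: SynthConfig, rng: np.random.Generator) -> PositionTrack:
    """Unrewarded exploration covering the maze (smooth heading random walk)."""
    fs = config.track_fs
    n = int(config.probe_duration_s * fs)
    heading = rng.uniform(0, TWO_PI)
    pos = np.zeros((n, 2))
    p = np.array([0.0, 0.0])
    speed = 20.0
    for i in range(n):
        heading += rng.normal(0, 0.25)
        speed = np.clip(speed + rng.normal(0, 1.0), 8.0, 35.0)
        step = speed / fs * np.array([np.cos(heading), np.sin(heading)])
        p = p + step
        r = np.hypot(*p)
        if r > config.maze_radius_cm - 5.0:
            heading = np.arctan2(-p[1], -p[0]) + rng.normal(0, 0.3)
            p *= (config.maze_radius_cm - 5.0) / r
        pos[i] = p
    times = np.arange(n) / fs
    return PositionTrack(times, pos[:, 0], pos[:, 1])


# ---------------------------------------------------------------------------
# LFP


def generate_lfp(
    config: SynthConfig,
    duration_s: float,
    rng: np.random.Generator,
    swr_times: list[float] | None = None,
) -> tuple[dict[str, LfpSignal], np.ndarray]:
    """Theta/gamma LFP for both regions; returns signals and the theta phase.

    dCA1 carries the reference theta oscillation.  mOFC theta lags it by a
    mean of ``plv_lag`` radians with fluctuation SD ``plv_lag_jitter``
    (setting the jitter to zero yields perfect inter-regional phase locking).
    mOFC gamma rides on dCA1 theta phase with envelope
    1 + pac_depth * cos(phase - preferred), the textbook phase-amplitude
    coupling construction; pac_depth = 0 makes the envelope phase-uniform.
    Ripple-band bursts are added to dCA1 at the requested times.
    """
    fs = config.lfp_fs
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # slow random-walk frequency drift keeps the rhythm realistic
    drift = rng.normal(0, 0.02, n).cumsum() / fs
    theta_phase = TWO_PI * config.theta_hz * t + drift

    dca1 = config.theta_amp * np.cos(theta_phase) + rng.normal(0, config.noise_sd, n)

    # Ornstein-Uhlenbeck lag fluctuation around the mean inter-regional lag
    if config.plv_lag_jitter > 0:
        lag = np.empty(n)
        lag[0] = config.plv_lag
        alpha = 1.0 / (0.5 * fs)  # 0.5-s relaxation
        noise = rng.normal(0, config.plv_lag_jitter * np.sqrt(2 * alpha), n)
        for i in range(1, n):
            lag[i] = lag[i - 1] + alpha * (config.plv_lag - lag[i - 1]) + noise[i]
    else:
        lag = np.full(n, config.plv_lag)

    mofc_theta = 0.7 * config.theta_amp * np.cos(theta_phase - lag)
    envelope = 1.0 + config.pac_depth * np.cos(theta_phase - config.pac_preferred_phase)
    gamma_phase = TWO_PI * config.low_gamma_hz * t + rng.normal(0, 0.05, n).cumsum()
    hg_phase = TWO_PI * config.high_gamma_hz * t + rng.normal(0, 0.05, n).cumsum()
    mofc = (
        mofc_theta
        + config.gamma_amp * envelope * np.cos(gamma_phase)
        + 0.3 * config.gamma_amp * np.cos(hg_phase)
        + rng.normal(0, config.noise_sd, n)
    )

    if swr_times:
        burst_len = int(0.06 * fs)
        window = np.hanning(burst_len)
        for t0 in swr_times:
            i0 = int(t0 * fs)
            if i0 + burst_len >= n:
                continue
            tt = np.arange(burst_len) / fs
            dca1[i0 : i0 + burst_len] += (
                8.0 * config.noise_sd * window * np.cos(TWO_PI * 180.0 * tt)
            )

    return (
        {
            "dCA1": LfpSignal(dca1, fs, "dCA1"),
            "mOFC": LfpSignal(mofc, fs, "mOFC"),
        },
        theta_phase,
    )


def draw_swr_times(
    config: SynthConfig, dwells: list[tuple[float, float]], rng: np.random.Generator
) -> list[float]:
    """Poisson ripple times within goal dwells at ``swr_rate_hz``."""
    times = []
    for a, b in dwells:
        n_ev = rng.poisson(config.swr_rate_hz * (b - a))
        times.extend(rng.uniform(a, b - 0.08, n_ev) if n_ev else [])
    return sorted(float(x) for x in times)


# ---------------------------------------------------------------------------
# spikes


def _unit_metadata(cell_type: str, rng: np.random.Generator) -> tuple[float, float]:
    if cell_type == "pyramidal":
        return rng.uniform(0.5, 0.9), rng.uniform(1.0, 5.0)
    if cell_type == "narrow_interneuron":
        return rng.uniform(0.15, 0.42), rng.uniform(1.0, 10.0)
    return rng.uniform(0.45, 0.9), rng.uniform(6.5, 15.0)


def _poisson_spikes(rate_per_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli thinning on a 1-ms grid (exact for rates << 1 kHz)."""
    hits = np.flatnonzero(rng.random(rate_per_ms.size) < rate_per_ms)
    return hits / 1000.0 + rng.uniform(0, 1e-3, hits.size)


def generate_spikes(
    config: SynthConfig,
    track: PositionTrack,
    theta_phase: np.ndarray,
    goals_previous: np.ndarray,
    goals_current: np.ndarray,
    rng: np.random.Generator,
    phase: str = "learning",
) -> tuple[list[Unit], GroundTruth]:
    """Spike trains for all units with ground-truth tuning assignments.

    Goal cells place their field on a previous-day goal before learning and,
    when flagged as remapping, on a current-day goal during/after learning
    (``phase`` in {"pre", "learning", "post"}).  A configurable fraction of
    units is theta-phase locked via a von Mises rate multiplier.  Planted
    short-latency pairs copy reference spikes into the target at a fixed
    latency with the stated excess probability; assembly members co-spike
    within 20 ms of latent Poisson events.
    """
    duration = float(track.times[-1])
    n_ms = theta_phase.size
    t_ms = np.arange(n_ms) / 1000.0
    x_ms = np.interp(t_ms, track.times, track.x)
    y_ms = np.interp(t_ms, track.times, track.y)

    specs = []
    for region, n_pyr, n_int in (
        ("dCA1", config.n_pyr_dca1, config.n_int_dca1),
        ("mOFC", config.n_pyr_mofc, config.n_int_mofc),
    ):
        specs.extend((f"{region}_pyr_{i:02d}", region, "pyramidal") for i in range(n_pyr))
        specs.extend((f"{region}_int_{i:02d}", region, "interneuron") for i in range(n_int))

    centers: dict[str, tuple[float, float]] = {}
    goal_cells: dict[str, bool] = {}
    remap_cells: dict[str, bool] = {}
    locked: dict[str, float] = {}
    units: list[Unit] = []

    from scipy.special import i0 as bessel_i0

    for uid, region, kind in specs:
        if kind == "pyramidal":
            is_goal = rng.random() < config.goal_fraction[region]
            is_remap = bool(is_goal and rng.random() < config.remap_fraction[region])
            if is_goal:
                prev_goal = goals_previous[rng.integers(2)]
                curr_goal = goals_current[rng.integers(2)]
                if phase == "pre":
                    center = prev_goal
                elif is_remap:
                    center = curr_goal
                else:
                    center = prev_goal
            else:
                is_remap = False
                while True:
                    center = rng.uniform(-60, 60, 2)
                    if np.hypot(*center) < config.maze_radius_cm - 8:
                        break
            centers[uid] = (float(center[0]), float(center[1]))
            goal_cells[uid] = bool(is_goal)
            remap_cells[uid] = is_remap
            d2 = (x_ms - center[0]) ** 2 + (y_ms - center[1]) ** 2
            rate = config.base_rate_hz + config.place_peak_hz * np.exp(
                -d2 / (2 * config.place_sigma_cm**2)
            )
        else:
            # interneurons: high-rate, weakly tuned
            goal_cells[uid] = False
            remap_cells[uid] = False
            rate = np.full(n_ms, config.int_rate_hz)

        if rng.random() < config.theta_locked_fraction and config.theta_kappa > 0:
            kappa = config.theta_kappa
            mu = rng.uniform(0, TWO_PI)
            rate = rate * np.exp(kappa * np.cos(theta_phase - mu)) / bessel_i0(kappa)
            locked[uid] = kappa
        else:
            locked[uid] = 0.0

        st = _poisson_spikes(rate / 1000.0, rng)
        cell_type = (
            "pyramidal"
            if kind == "pyramidal"
            else ("narrow_interneuron" if rng.random() < 0.6 else "wide_interneuron")
        )
        ttp, tau = _unit_metadata(cell_type, rng)
        units.append(
            Unit(
                unit_id=uid,
                region=region,
                spike_times=st,
                trough_to_peak=ttp,
                acg_tau_rise=tau,
                mean_rate=st.size / duration,
                cell_type=cell_type,
            )
        )

    by_id = {u.unit_id: u for u in units}

    for pair in config.ccg_pairs:
        ref, tgt = by_id[pair.ref], by_id[pair.target]
        copied = ref.spike_times[rng.random(ref.n_spikes) < pair.excess_prob]
        extra = copied + pair.latency_ms / 1000.0
        merged = np.sort(np.concatenate([tgt.spike_times, extra]))
        tgt.spike_times = merged[merged < duration]
        tgt.mean_rate = tgt.spike_times.size / duration

    for asm in config.assemblies:
        n_ev = rng.poisson(asm.event_rate_hz * duration)
        events = rng.uniform(0, duration - 0.05, n_ev)
        for uid in asm.members:
            u = by_id[uid]
            jitters = rng.uniform(0, 0.02, n_ev)
            merged = np.sort(np.concatenate([u.spike_times, events + jitters]))
            u.spike_times = merged[merged < duration]
            u.mean_rate = u.spike_times.size / duration

    truth = GroundTruth(
        place_centers=centers,
        goal_cells=goal_cells,
        remap_cells=remap_cells,
        theta_locked=locked,
        ccg_pairs=list(config.ccg_pairs),
        assemblies=list(config.assemblies),
        path_schedule=path_length_schedule(config),
        swr_times=[],
    )
    return units, truth


# ---------------------------------------------------------------------------
# full sessions


def generate_session(
    config: SynthConfig, kind: str = "learning"
) -> tuple[Session, GroundTruth]:
    """One complete synthetic session with its ground truth.

    ``kind`` selects the learning session (40 trials, goal-directed runs) or
    an unrewarded probe ("pre_probe" / "post_probe", exploration only).  The
    same seed always regenerates the identical session.
    """
    if kind not in ("learning", "pre_probe", "post_probe"):
        raise ValueError(f"unknown session kind {kind!r}")
    rng = np.random.default_rng(config.seed)
    goals_prev, goals_curr = sample_goals(config, rng)

    if kind == "learning":
        track, trials, dwells = generate_trajectory(config, goals_curr, rng)
        swr_times = draw_swr_times(config, dwells, rng)
        spike_phase = "learning"
    else:
        track = generate_probe_trajectory(config, rng)
        trials, swr_times = [], []
        spike_phase = "pre" if kind == "pre_probe" else "post"

    duration = float(track.times[-1]) + 1.0 / config.track_fs
    lfp, theta_phase = generate_lfp(config, duration, rng, swr_times)
    units, truth = generate_spikes(
        config, track, theta_phase, goals_prev, goals_curr, rng, phase=spike_phase
    )
    truth.swr_times = swr_times

    session = Session(
        session_id=f"synth-{config.seed}-{kind}",
        units=units,
        track=track,
        lfp=lfp,
        goals_current=goals_curr,
        goals_previous=goals_prev,
        trials=trials,
        start_box=(-15.0, 15.0, -config.maze_radius_cm - 5.0, -config.maze_radius_cm + 12.0),
        maze_radius=config.maze_radius_cm,
    )
    return session, truth
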
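"""Pipeline orchestration: run every analysis stage over a session.

``run_pipeline`` executes behavior -> spatial -> oscillations -> spike_timing
-> assemblies -> decoding on one session with a shared SWR exclusion mask and
shared epoch definitions, returning a nested summary dictionary.  A single
master seed fans out per-stage child seeds through ``numpy.random.SeedSequence``
so a partial re-run of any stage reproduces bit-identically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import assemblies as asm
from . import behavior, decoding, oscillations, spatial, spike_timing
from .core import Session


@dataclass
class PipelineConfig:
    n_surrogates: int = 1000
    max_pairs: int | None = None  # cap on CCG pairs (None = all ordered pyr pairs)
    decode_tasks: tuple = ("stage",)
    nm_ratios: tuple = tuple((1, m) for m in range(1, 11))
    blocks: tuple = (1, 2, 3, 4)


@dataclass
class SessionSummary:
    session_id: str
    stages: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"session_id": self.session_id, "status": self.status, **self.stages}


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _block_interval(session: Session, block: int) -> tuple[float, float]:
    trials = [
        session.trials[i]
        for i in range((block - 1) * 10, min(block * 10, len(session.trials)))
    ]
    return trials[0][0], trials[-1][1]


def run_pipeline(session: Session, config: PipelineConfig | None = None, seed: int = 0) -> SessionSummary:
    """Run all stages; stage failures yield a partial summary with status."""
    config = config or PipelineConfig()
    seeds = _stage_seeds(seed, ["spike_timing", "assemblies", "decoding"])
    summary = SessionSummary(session.session_id)
    track = session.track
    speed = track.velocity

    def run_stage(name, fn):
        try:
            summary.stages[name] = fn()
            summary.status[name] = "ok"
        except Exception as exc:  # pragma: no cover - defensive
            summary.status[name] = f"failed: {exc}"

    # -- behavior ---------------------------------------------------------
    def stage_behavior():
        epochs = behavior.segment_epochs(
            track, session.goals_current, session.trials, session.start_box
        )
        session.epochs = epochs
        lengths = [behavior.trajectory_length(track, tr) for tr in session.trials]
        out = {"trial_lengths_cm": lengths, "n_epochs": len(epochs)}
        if len(lengths) >= 5:
            fit = behavior.fit_breakpoint(np.asarray(lengths))
            out["breakpoint"] = {
                "tau": fit.tau,
                "pre_slope": fit.pre_slope,
                "post_slope": fit.post_slope,
                "rss": fit.rss,
            }
        return out

    run_stage("behavior", stage_behavior)

    # -- SWR mask (shared) ------------------------------------------------
    swr = oscillations.detect_swr(session.lfp["dCA1"], track.times, speed)

    # -- oscillations -----------------------------------------------------
    def stage_oscillations():
        out = {"swr_count": len(swr.intervals)}
        theta_ca1 = oscillations.phase_series(session.lfp["dCA1"].samples, "theta")
        theta_ofc = oscillations.phase_series(session.lfp["mOFC"].samples, "theta")
        out["plv_theta"] = oscillations.plv(theta_ca1.phase, theta_ofc.phase)
        lg = oscillations.phase_series(session.lfp["mOFC"].samples, "low_gamma")
        out["nm_plv"] = {
            f"{n}:{m}": oscillations.nm_plv(theta_ca1.phase, lg.phase, n, m)
            for n, m in config.nm_ratios
        }
        out["pac_mi_low_gamma"] = oscillations.pac_mi(theta_ca1.phase, lg.amplitude).mi
        freqs, psd = oscillations.welch_power(session.lfp["dCA1"].samples)
        out["theta_power_dca1"] = oscillations.band_power(freqs, psd, "theta")
        return out

    run_stage("oscillations", stage_oscillations)

    # -- spike timing -----------------------------------------------------
    def stage_pairs():
        rng = np.random.default_rng(seeds["spike_timing"])
        pyr = [u for u in session.units if u.cell_type == "pyramidal"]
        pairs = [
            (a, b) for a, b in itertools.permutations(pyr, 2)
        ]
        if config.max_pairs is not None:
            pairs = pairs[: config.max_pairs]
        rows = []
        for a, b in pairs:
            window = (
                spike_timing.WINDOW_WITHIN
                if a.region == b.region
                else spike_timing.WINDOW_CROSS
            )
            strengths, pvals = [], []
            for block in config.blocks:
                t0, t1 = _block_interval(session, block)
                rb = spike_timing.binarize_ms(a.spike_times, t0, t1)
                tb = spike_timing.binarize_ms(b.spike_times, t0, t1)
                if rb.size == 0:
                    strengths.append(np.nan)
                    pvals.append(np.nan)
                    continue
                pair = spike_timing.jitter_null(
                    rb, tb, window, n_surr=config.n_surrogates, rng=rng
                )
                strengths.append(pair.strength)
                pvals.append(pair.p_emp)
            trend, beta, delta = spike_timing.classify_trend(np.asarray(strengths))
            rows.append(
                {
                    "ref": a.unit_id,
                    "target": b.unit_id,
                    "ref_region": a.region,
                    "target_region": b.region,
                    "strengths": strengths,
                    "pvals": pvals,
                    "trend": trend,
                    "beta": beta,
                    "delta": delta,
                }
            )
        # per-block BH within reference groups
        for bi in range(len(config.blocks)):
            ps = np.array([r["pvals"][bi] for r in rows])
            refs = np.array([r["ref"] for r in rows])
            ok = np.isfinite(ps)
            flags = np.zeros(ps.size, dtype=bool)
            if ok.any():
                flags[ok] = spike_timing.fdr_by_reference(ps[ok], refs[ok])
            for r, f in zip(rows, flags):
                r.setdefault("significant", []).append(bool(f))
        return {"pairs": rows, "n_pairs": len(rows)}

    run_stage("spike_timing", stage_pairs)

    # -- assemblies -------------------------------------------------------
    def stage_assemblies():
        t0, t1 = session.trials[0][0], session.trials[-1][1]
        z, _, kept = asm.bin_and_zscore(
            [u.spike_times for u in session.units], t0, t1, swr_intervals=swr.intervals
        )
        n_sig, evals, _ = asm.mp_significant_components(z)
        patterns = asm.extract_assemblies(z, n_sig, seed=seeds["assemblies"])
        events = [asm.activation_events(p, z).events.size for p in patterns]
        return {
            "n_assemblies": n_sig,
            "top_eigenvalue": float(evals[0]),
            "event_counts": events,
            "kept_neurons": kept.tolist(),
        }

    run_stage("assemblies", stage_assemblies)

    # -- decoding ---------------------------------------------------------
    def stage_decoding():
        rng = np.random.default_rng(seeds["decoding"])
        out = {}
        regions = np.array([u.region for u in session.units])
        for task in config.decode_tasks:
            samples = decoding.build_samples(session, task, rng)
            task_out = {"ALL": decoding.decode(samples)}
            for region in ("dCA1", "mOFC"):
                idx = np.flatnonzero(regions == region)
                if idx.size:
                    task_out[region] = decoding.decode(samples, idx)
            out[task] = task_out
        return out

    run_stage("decoding", stage_decoding)

    # -- spatial (learning-session maps; probe classification is separate)
    def stage_spatial():
        rows = []
        for u in session.units:
            try:
                rm = spatial.compute_rate_map(u, track)
            except ValueError:
                continue
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "peak_rate": rm.peak_rate,
                    "skaggs_bits_per_spike": spatial.spatial_information(rm),
                }
            )
        return {"units": rows}

    run_stage("spatial", stage_spatial)

    return summary
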
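"""Session data model, on-disk format, unit filtering and cell-type classification.

A *session* is one daily recording on the cheeseboard maze: a set of sorted
units from dCA1 and mOFC, a 50-Hz head-position track, one 1-kHz LFP channel
per region, the two rewarded goal locations of the current and previous day,
and the trial structure of the learning session.

On disk a session is a directory of plain-text files:

``metadata.json``
    session id, goal coordinates, trial windows, start-box rectangle,
    maze radius, LFP sampling rate, and per-unit metadata.
``spikes.csv``
    columns ``unit_id,time_s``.
``track.csv``
    columns ``time_s,x_cm,y_cm``.
``lfp.csv``
    one column per region, in microvolts, sampled at ``lfp_fs``.

All times are seconds, positions centimetres in a maze-centred frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("dCA1", "mOFC")
CELL_TYPES = ("pyramidal", "narrow_interneuron", "wide_interneuron")

#: waveform trough-to-peak latency separating narrow from wide units (ms)
TROUGH_TO_PEAK_MS = 0.425
#: autocorrelogram tau-rise separating wide interneurons from pyramidal cells (ms)
ACG_TAU_RISE_MS = 6.0
#: minimum mean firing rate for a unit to enter any analysis (Hz)
MIN_RATE_HZ = 0.3

LFP_FS = 1000.0
TRACK_FS = 50.0


class SessionFormatError(ValueError):
    """A session directory is missing a stream or a table cannot be parsed."""


def classify_cell_type(trough_to_peak: float, acg_tau_rise: float) -> str:
    """Classify a unit from its waveform and autocorrelogram metrics.

    Units with trough-to-peak latency <= 0.425 ms are narrow-waveform
    interneurons; wider units with autocorrelogram tau-rise > 6 ms are
    wide-waveform interneurons; everything else is a putative pyramidal cell.
    The two thresholds partition the metric plane into exactly three regions.
    """
    if not (math.isfinite(trough_to_peak) and math.isfinite(acg_tau_rise)):
        raise ValueError(
            f"non-finite classification metrics: trough_to_peak={trough_to_peak}, "
            f"acg_tau_rise={acg_tau_rise}"
        )
    if trough_to_peak <= 0 or acg_tau_rise <= 0:
        raise ValueError("classification metrics must be positive")
    if trough_to_peak <= TROUGH_TO_PEAK_MS:
        return "narrow_interneuron"
    if acg_tau_rise > ACG_TAU_RISE_MS:
        return "wide_interneuron"
    return "pyramidal"


@dataclass
class Unit:
    """A sorted single unit with spike times and quality/type metadata."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    trough_to_peak: float
    acg_tau_rise: float
    mean_rate: float
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if not self.cell_type:
            self.cell_type = classify_cell_type(self.trough_to_peak, self.acg_tau_rise)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class PositionTrack:
    """Head position sampled at 50 Hz, with speed derived on demand.

    Speed is the centred finite-difference step length smoothed with a
    5-sample moving average; this is the single definition shared by every
    analysis stage (speed gating of rate maps, theta cycles, SWR detection,
    speed-power controls).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    _velocity: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def velocity(self) -> np.ndarray:
        if self._velocity is None:
            self._velocity = _track_speed(self.times, self.x, self.y)
        return self._velocity

    def __len__(self) -> int:
        return self.times.size


def _track_speed(times: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Centred finite-difference speed (cm/s), 5-sample moving average."""
    n = times.size
    if n < 3:
        raise ValueError("need at least 3 position samples to estimate speed")
    v = np.empty(n)
    dt2 = times[2:] - times[:-2]
    v[1:-1] = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2]) / dt2
    v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / (times[1] - times[0])
    v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / (times[-1] - times[-2])
    # edge-renormalized moving average keeps constants exactly constant
    kernel = np.ones(5)
    smooth = np.convolve(v, kernel, mode="same") / np.convolve(
        np.ones(n), kernel, mode="same"
    )
    return np.maximum(smooth, 0.0)


@dataclass
class LfpSignal:
    """One LFP channel, down-sampled to 1 kHz, in microvolts."""

    samples: np.ndarray
    fs: float
    region: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Epoch:
    label: str  # Goal1 | Goal2 | Navigation1 | Navigation2
    trial: int  # 0-based trial index
    block: int  # 1..4 (trials 1-10, 11-20, 21-30, 31-40)
    start_s: float
    end_s: float


@dataclass
class Session:
    """Container for one daily recording session."""

    session_id: str
    units: list[Unit]
    track: PositionTrack
    lfp: dict[str, LfpSignal]
    goals_current: np.ndarray  # (2, 2) cm
    goals_previous: np.ndarray  # (2, 2) cm
    trials: list[tuple[float, float]]
    epochs: list[Epoch] | None = None
    start_box: tuple[float, float, float, float] = (-15.0, 15.0, -85.0, -65.0)
    maze_radius: float = 75.0

    def __post_init__(self) -> None:
        self.goals_current = np.asarray(self.goals_current, dtype=float)
        self.goals_previous = np.asarray(self.goals_previous, dtype=float)

    def units_in(self, region: str | None = None, cell_type: str | None = None) -> list[Unit]:
        out = self.units
        if region is not None:
            out = [u for u in out if u.region == region]
        if cell_type is not None:
            out = [u for u in out if u.cell_type == cell_type]
        return out

    @property
    def duration(self) -> float:
        return float(self.track.times[-1] - self.track.times[0])


def filter_units(units: list[Unit], min_rate: float = MIN_RATE_HZ) -> list[Unit]:
    """Keep units whose mean firing rate is at least ``min_rate`` (inclusive)."""
    if min_rate < 0:
        raise ValueError("min_rate must be non-negative")
    return [u for u in units if u.mean_rate >= min_rate]


def validate_session(session: Session) -> list[str]:
    """Check all session invariants; return a list of violation messages."""
    bad: list[str] = []
    for u in session.units:
        st = u.spike_times
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            bad.append(f"unit {u.unit_id}: spike times not sorted/non-negative")
        if u.region not in REGIONS:
            bad.append(f"unit {u.unit_id}: unknown region {u.region!r}")
        if u.cell_type not in CELL_TYPES:
            bad.append(f"unit {u.unit_id}: unknown cell type {u.cell_type!r}")
    dt = np.diff(session.track.times)
    if dt.size and not np.allclose(dt, 1.0 / TRACK_FS, atol=2e-3):
        bad.append("track: sampling not uniform at 50 Hz")
    for region, sig in session.lfp.items():
        if sig.fs != LFP_FS:
            bad.append(f"lfp {region}: fs {sig.fs} != {LFP_FS}")
        if not np.all(np.isfinite(sig.samples)):
            bad.append(f"lfp {region}: non-finite samples")
    tr = session.trials
    for i, (a, b) in enumerate(tr):
        if b <= a:
            bad.append(f"trial {i}: end <= start")
        if i and a < tr[i - 1][1]:
            bad.append(f"trial {i}: overlaps previous trial")
    for name, goals in (("current", session.goals_current), ("previous", session.goals_previous)):
        if goals.shape != (2, 2):
            bad.append(f"goals_{name}: expected exactly two (x, y) points")
    return bad


# ---------------------------------------------------------------------------
# on-disk format


def write_session(session: Session, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = {
        "session_id": session.session_id,
        "goals_current": session.goals_current.tolist(),
        "goals_previous": session.goals_previous.tolist(),
        "trials": [list(t) for t in session.trials],
        "start_box": list(session.start_box),
        "maze_radius": session.maze_radius,
        "lfp_fs": {r: s.fs for r, s in session.lfp.items()},
        "units": [
            {
                "unit_id": u.unit_id,
                "region": u.region,
                "trough_to_peak": u.trough_to_peak,
                "acg_tau_rise": u.acg_tau_rise,
                "mean_rate": u.mean_rate,
                "cell_type": u.cell_type,
            }
            for u in session.units
        ],
        "epochs": None
        if session.epochs is None
        else [asdict(e) for e in session.epochs],
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))

    rows = [
        (u.unit_id, t) for u in session.units for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        directory / "spikes.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {"time_s": session.track.times, "x_cm": session.track.x, "y_cm": session.track.y}
    ).to_csv(directory / "track.csv", index=False, float_format="%.17g")
    pd.DataFrame({r: s.samples for r, s in session.lfp.items()}).to_csv(
        directory / "lfp.csv", index=False, float_format="%.17g"
    )
    return directory


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise SessionFormatError(f"missing session stream: {path.name}")
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surface the file name alongside pandas' line info
        raise SessionFormatError(f"cannot parse {path.name}: {exc}") from exc


def read_session(directory: str | Path) -> Session:
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise SessionFormatError("missing session stream: metadata.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"cannot parse metadata.json: {exc}") from exc

    spikes = _read_table(directory / "spikes.csv")
    track_df = _read_table(directory / "track.csv")
    lfp_df = _read_table(directory / "lfp.csv")

    by_unit = {
        uid: grp["time_s"].to_numpy()
        for uid, grp in spikes.groupby("unit_id", sort=False)
    }
    units = [
        Unit(
            unit_id=m["unit_id"],
            region=m["region"],
            spike_times=by_unit.get(m["unit_id"], np.empty(0)),
            trough_to_peak=m["trough_to_peak"],
            acg_tau_rise=m["acg_tau_rise"],
            mean_rate=m["mean_rate"],
            cell_type=m["cell_type"],
        )
        for m in meta["units"]
    ]
    lfp = {
        region: LfpSignal(lfp_df[region].to_numpy(), meta["lfp_fs"][region], region)
        for region in meta["lfp_fs"]
    }
    epochs = None
    if meta.get("epochs") is not None:
        epochs = [Epoch(**e) for e in meta["epochs"]]
    return Session(
        session_id=meta["session_id"],
        units=units,
        track=PositionTrack(
            track_df["time_s"].to_numpy(),
            track_df["x_cm"].to_numpy(),
            track_df["y_cm"].to_numpy(),
        ),
        lfp=lfp,
        goals_current=np.asarray(meta["goals_current"]),
        goals_previous=np.asarray(meta["goals_previous"]),
        trials=[tuple(t) for t in meta["trials"]],
        epochs=epochs,
        start_box=tuple(meta["start_box"]),
        maze_radius=meta["maze_radius"],
    )
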
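"""Data model and I/O for multimodal wearable recordings.

A recording bundles one :class:`SensorStream` per modality plus a single
target stream (heart rate, bpm).  Streams carry their own timestamps in
seconds from recording start; recording "days" are contiguous time spans
delimited by ``day_edges`` and serve as cross-validation folds downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "MultimodalRecording",
    "read_recording",
    "write_recording",
    "align_to_grid",
    "split_days",
    "concatenate",
]

#: streams feeding activity recognition by default (ankle accelerometer only)
DEFAULT_CONTEXT_SENSORS = ("ankle_accel",)


class RecordingError(ValueError):
    """Raised for malformed recordings, manifests or stream files."""


@dataclass
class SensorStream:
    """One modality's timestamped samples.

    Parameters
    ----------
    name : str
        Sensor identifier (e.g. ``"wrist_accel"``).
    timestamps : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    values : ndarray, shape (n, d)
        ``d`` channels per sample (1 for scalar sensors, 3 for accelerometers).
    rate : float
        Nominal sampling rate in Hz.
    channels : tuple of str
        Channel names, length ``d``.
    current_mA : float or None
        Average incremental current draw when the sensor is active; only
        needed for power accounting.
    """

    name: str
    timestamps: np.ndarray
    values: np.ndarray
    rate: float
    channels: tuple = ()
    current_mA: float | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.timestamps.ndim != 1:
            raise RecordingError(f"{self.name}: timestamps must be 1-d")
        if len(self.timestamps) != len(self.values):
            raise RecordingError(
                f"{self.name}: {len(self.timestamps)} timestamps vs "
                f"{len(self.values)} samples"
            )
        dt = np.diff(self.timestamps)
        if len(dt) and not np.all(dt > 0):
            i = int(np.argmin(dt > 0))
            raise RecordingError(
                f"{self.name}: timestamps not strictly increasing at row {i + 1}"
            )
        if self.rate <= 0:
            raise RecordingError(f"{self.name}: rate must be positive")
        if not self.channels:
            d = self.values.shape[1]
            self.channels = (self.name,) if d == 1 else tuple(
                f"{self.name}_{ax}" for ax in ("x", "y", "z")[:d]
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def slice_time(self, t0: float, t1: float) -> "SensorStream":
        """Samples with ``t0 <= t < t1`` (timestamps untouched)."""
        m = (self.timestamps >= t0) & (self.timestamps < t1)
        return replace(self, timestamps=self.timestamps[m], values=self.values[m])


@dataclass
class MultimodalRecording:
    """Full stream set ``X`` plus target stream ``y`` and day structure."""

    streams: dict
    target: SensorStream
    day_edges: np.ndarray  # (n_days + 1,) time edges; day d = [edge[d], edge[d+1])
    context_sensors: tuple = DEFAULT_CONTEXT_SENSORS
    labels: pd.DataFrame | None = None  # ground-truth states, testing only
    planted_support: tuple | None = None

    def __post_init__(self):
        self.day_edges = np.asarray(self.day_edges, dtype=float)
        if len(self.day_edges) < 2:
            raise RecordingError("need at least one day (two day edges)")
        for s in self.context_sensors:
            if s not in self.streams:
                raise RecordingError(f"context sensor {s!r} not in streams")

    @property
    def n_days(self) -> int:
        return len(self.day_edges) - 1

    def day_of(self, times: np.ndarray) -> np.ndarray:
        """Day index of each time (clipped into valid range)."""
        d = np.searchsorted(self.day_edges, times, side="right") - 1
        return np.clip(d, 0, self.n_days - 1)


def write_recording(rec: MultimodalRecording, out_dir) -> Path:
    """Write one CSV per modality plus ``labels.csv`` and ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, s in {**rec.streams, "hr": rec.target}.items():
        df = pd.DataFrame({"timestamp_s": s.timestamps})
        for j, ch in enumerate(s.channels):
            df[ch] = s.values[:, j]
        fn = f"{name}.csv"
        df.to_csv(out / fn, index=False)
        files[name] = {"file": fn, "rate_hz": s.rate, "channels": list(s.channels)}
    manifest = {
        "target": "hr",
        "streams": files,
        "day_edges_s": rec.day_edges.tolist(),
        "context_sensors": list(rec.context_sensors),
    }
    if rec.labels is not None:
        rec.labels.to_csv(out / "labels.csv", index=False)
        manifest["labels"] = "labels.csv"
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _read_stream(name, info, base: Path) -> SensorStream:
    fp = base / info["file"]
    if not fp.exists():
        raise RecordingError(f"stream {name!r}: missing file {fp}")
    df = pd.read_csv(fp)
    if "timestamp_s" != df.columns[0]:
        raise RecordingError(f"stream {name!r}: first column must be timestamp_s")
    ts = df["timestamp_s"].to_numpy(float)
    vals = df.iloc[:, 1:].to_numpy(float)
    s = SensorStream(name, ts, vals, info["rate_hz"],
                     channels=tuple(df.columns[1:]))
    # rate sanity: median spacing within 1 % of declared rate
    if len(ts) > 1:
        med = float(np.median(np.diff(ts)))
        if abs(med * info["rate_hz"] - 1.0) > 0.01:
            raise RecordingError(
                f"stream {name!r}: declared {info['rate_hz']} Hz but median "
                f"spacing {med:.4f} s (mismatch > 1%)"
            )
    return s


def read_recording(manifest_path) -> MultimodalRecording:
    """Load a recording from its ``manifest.json``."""
    mp = Path(manifest_path)
    if not mp.exists():
        raise RecordingError(f"manifest not found: {mp}")
    man = json.loads(mp.read_text())
    base = mp.parent
    target_name = man.get("target", "hr")
    if target_name not in man["streams"]:
        raise RecordingError(f"manifest lists no target stream {target_name!r}")
    streams = {}
    target = None
    for name, info in man["streams"].items():
        s = _read_stream(name, info, base)
        if name == target_name:
            target = s
        else:
            streams[name] = s
    labels = None
    if "labels" in man:
        labels = pd.read_csv(base / man["labels"])
    return MultimodalRecording(
        streams=streams,
        target=target,
        day_edges=np.asarray(man["day_edges_s"], float),
        context_sensors=tuple(man.get("context_sensors", DEFAULT_CONTEXT_SENSORS)),
        labels=labels,
    )


def _resample_channel(ts, vals, grid, dt):
    """One channel onto grid points: window-average if oversampled else interp."""
    native_dt = np.median(np.diff(ts)) if len(ts) > 1 else np.inf
    if native_dt <= dt:  # at or above grid rate: mean over [t, t+dt)
        edges = np.append(grid, grid[-1] + dt)
        idx = np.searchsorted(ts, edges)
        out = np.empty(len(grid))
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        cnt = np.diff(idx)
        with np.errstate(invalid="ignore"):
            out = (csum[idx[1:]] - csum[idx[:-1]]) / cnt
        empty = cnt == 0
        if empty.any():
            out[empty] = np.interp(grid[empty], ts, vals)
        return out
    return np.interp(grid, ts, vals)


def align_to_grid(rec: MultimodalRecording, rate: float = 1.0) -> MultimodalRecording:
    """Resample every stream to a common grid (default 1 Hz, the HR rate).

    Channels sampled at or above the grid rate are averaged over the forward
    window ``[t, t + 1/rate)``; slower channels are linearly interpolated.
    The grid covers, per day, the overlap of all streams.
    """
    dt = 1.0 / rate
    all_streams = {**rec.streams, "__target__": rec.target}
    new_vals = {k: [] for k in all_streams}
    grids = []
    edges = [None] * (rec.n_days + 1)
    for d in range(rec.n_days):
        t0, t1 = rec.day_edges[d], rec.day_edges[d + 1]
        lo, hi = t0, t1
        for s in all_streams.values():
            seg = s.slice_time(t0, t1)
            if len(seg.timestamps) == 0:
                raise RecordingError(f"stream {s.name!r} empty on day {d}")
            lo = max(lo, seg.timestamps[0])
            hi = min(hi, seg.timestamps[-1] + 1.0 / s.rate)
        if hi <= lo:
            raise RecordingError(f"no time overlap between streams on day {d}")
        start = np.ceil(lo / dt) * dt
        grid = np.arange(start, hi - 1e-9, dt)
        if len(grid) == 0:
            raise RecordingError(f"empty grid on day {d}")
        grids.append(grid)
        if edges[d] is None:
            edges[d] = grid[0]
        edges[d + 1] = grid[-1] + dt
        for k, s in all_streams.items():
            seg = s.slice_time(t0, t1)
            cols = [
                _resample_channel(seg.timestamps, seg.values[:, j], grid, dt)
                for j in range(s.n_channels)
            ]
            new_vals[k].append(np.column_stack(cols))
    grid_all = np.concatenate(grids)
    out_streams = {}
    for k, s in all_streams.items():
        vals = np.vstack(new_vals[k])
        ns = replace(s, timestamps=grid_all.copy(), values=vals, rate=rate)
        if k == "__target__":
            target = ns
        else:
            out_streams[k] = ns
    return MultimodalRecording(
        streams=out_streams,
        target=target,
        day_edges=np.asarray(edges, float),
        context_sensors=rec.context_sensors,
        labels=rec.labels,
        planted_support=rec.planted_support,
    )


def split_days(rec: MultimodalRecording) -> list:
    """One single-day recording per day; concatenation restores the original."""
    out = []
    for d in range(rec.n_days):
        t0, t1 = rec.day_edges[d], rec.day_edges[d + 1]
        streams = {k: s.slice_time(t0, t1) for k, s in rec.streams.items()}
        labels = None
        if rec.labels is not None:
            m = (rec.labels["timestamp_s"] >= t0) & (rec.labels["timestamp_s"] < t1)
            labels = rec.labels[m].reset_index(drop=True)
        out.append(
            MultimodalRecording(
                streams=streams,
                target=rec.target.slice_time(t0, t1),
                day_edges=np.array([t0, t1]),
                context_sensors=rec.context_sensors,
                labels=labels,
                planted_support=rec.planted_support,
            )
        )
    return out


def concatenate(recs: list) -> MultimodalRecording:
    """Inverse of :func:`split_days` for recordings contiguous in time."""
    first = recs[0]
    streams = {}
    for k in first.streams:
        ts = np.concatenate([r.streams[k].timestamps for r in recs])
        vals = np.vstack([r.streams[k].values for r in recs])
        streams[k] = replace(first.streams[k], timestamps=ts, values=vals)
    target = replace(
        first.target,
        timestamps=np.concatenate([r.target.timestamps for r in recs]),
        values=np.vstack([r.target.values for r in recs]),
    )
    edges = np.concatenate([[first.day_edges[0]], [r.day_edges[-1] for r in recs]])
    labels = None
    if first.labels is not None:
        labels = pd.concat([r.labels for r in recs], ignore_index=True)
    return MultimodalRecording(
        streams=streams, target=target, day_edges=edges,
        context_sensors=first.context_sensors, labels=labels,
        planted_support=first.planted_support,
    )
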
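"""Sliding-window feature extraction and the grouped design matrix.

Seven sensor groups feed the predictor, in this frozen order::

    body_temp (1) | env_temp (1) | humidity (1) | wrist_accel (21)
    | ankle_accel (21) | eda (6) | hr (3)

so the full design has p = 54 columns (51 when the heart-rate history
horizon ``delta_h`` is infinite and the hr group is omitted).

Accelerometer windows are framed on the sensor's *native* sampling grid —
spectral features need the full bandwidth — while scalar sensors use the
window mean and the response/history use the 1 Hz analysis grid.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import MultimodalRecording, RecordingError, _resample_channel

__all__ = [
    "GROUP_ORDER",
    "GroupedFeatureMatrix",
    "accel_features",
    "eda_features",
    "hr_history_features",
    "build_design",
]

GROUP_ORDER = (
    "body_temp", "env_temp", "humidity",
    "wrist_accel", "ankle_accel", "eda", "hr",
)

_AX = ("x", "y", "z")
_AX_STATS = ("mean", "var", "skew", "kurt", "peak_mag", "peak_freq")
ACCEL_FEATURE_NAMES = tuple(
    f"{st}_{ax}" for ax in _AX for st in _AX_STATS
) + ("cov_xy", "cov_xz", "cov_yz")
EDA_FEATURE_NAMES = ("mean", "trend", "var", "skew", "kurt", "range")
HR_FEATURE_NAMES = ("lag", "diff1", "diff2")

_EPS = 1e-12


class WindowTooShortError(ValueError):
    pass


def _moment_stats(dev: np.ndarray, var: np.ndarray):
    """Skewness and excess kurtosis from deviations; 0 for constant windows."""
    sd = np.sqrt(var)
    ok = var > _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, (dev ** 3).mean(axis=1) / np.where(ok, sd, 1) ** 3, 0.0)
        kurt = np.where(ok, (dev ** 4).mean(axis=1) / np.where(ok, var, 1) ** 2 - 3.0, 0.0)
    return skew, kurt


def accel_features_many(windows: np.ndarray, rate: float) -> np.ndarray:
    """Vectorized accelerometer features: ``windows`` is (n, m, 3) → (n, 21)."""
    n, m, _ = windows.shape
    if m < 8:
        raise WindowTooShortError(f"accelerometer window has {m} < 8 samples")
    mean = windows.mean(axis=1)                      # (n, 3)
    dev = windows - mean[:, None, :]
    var = (dev ** 2).mean(axis=1)
    # periodogram of the mean-removed window, rectangular taper
    F = np.fft.rfft(dev, axis=1)
    P = (np.abs(F) ** 2) / m                         # (n, nb, 3)
    Ppos = P[:, 1:, :]                               # bins in (0, Nyquist]
    peak_mag = Ppos.max(axis=1)
    peak_bin = Ppos.argmax(axis=1) + 1
    peak_freq = peak_bin * rate / m
    flat = peak_mag <= _EPS
    peak_freq = np.where(flat, 0.0, peak_freq)
    peak_mag = np.where(flat, 0.0, peak_mag)
    out = np.empty((n, 21))
    for a in range(3):
        sk, ku = _moment_stats(dev[:, :, a], var[:, a])
        out[:, 6 * a:6 * a + 6] = np.column_stack(
            [mean[:, a], var[:, a], sk, ku, peak_mag[:, a], peak_freq[:, a]]
        )
    out[:, 18] = (dev[:, :, 0] * dev[:, :, 1]).mean(axis=1)
    out[:, 19] = (dev[:, :, 0] * dev[:, :, 2]).mean(axis=1)
    out[:, 20] = (dev[:, :, 1] * dev[:, :, 2]).mean(axis=1)
    return out


def accel_features(window: np.ndarray, rate: float) -> np.ndarray:
    """21 features for one 3-axis window: per axis mean, variance, skewness,
    excess kurtosis, peak periodogram magnitude and its frequency, plus the
    three pairwise covariances (xy, xz, yz)."""
    window = np.asarray(window, float)
    return accel_features_many(window[None], rate)[0]


def eda_features_many(windows: np.ndarray, rel_times: np.ndarray) -> np.ndarray:
    """Vectorized EDA features: ``windows`` (n, m), ``rel_times`` (m,) → (n, 6)."""
    n, m = windows.shape
    if m < 4:
        raise WindowTooShortError(f"EDA window has {m} < 4 samples")
    t = rel_times - rel_times.mean()
    mean = windows.mean(axis=1)
    dev = windows - mean[:, None]
    var = (dev ** 2).mean(axis=1)
    trend = dev @ t / (t @ t)                        # least-squares slope
    sk, ku = _moment_stats(dev, var)
    rng = windows.max(axis=1) - windows.min(axis=1)
    return np.column_stack([mean, trend, var, sk, ku, rng])


def eda_features(window: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Mean, linear trend (slope vs time), variance, skewness, excess
    kurtosis and absolute range of one scalar window."""
    return eda_features_many(np.asarray(window, float)[None], np.asarray(times, float))[0]


def hr_history_features(y: np.ndarray, idx: int, lag: int) -> np.ndarray:
    """``[y(t−δh), Δy, Δ²y]`` on the 1 Hz grid; ``idx`` indexes time t."""
    j = idx - lag
    if j - 2 < 0:
        raise WindowTooShortError("insufficient heart-rate history")
    return np.array([y[j], y[j] - y[j - 1], y[j] - 2 * y[j - 1] + y[j - 2]])


@dataclass
class GroupedFeatureMatrix:
    """Design matrix partitioned into sensor groups.

    ``Z``/``y`` are stored in raw units; :meth:`standardize` returns a copy
    with zero-mean unit-sd columns (train-row statistics) plus the parameters
    needed to undo it.
    """

    Z: np.ndarray
    y: np.ndarray
    feature_names: list
    groups: dict                 # group name -> column index array
    end_times: np.ndarray
    day: np.ndarray
    delta_h: float
    window: float
    stride: float
    cluster: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float | None = None
    y_sd: float | None = None

    @property
    def n_rows(self) -> int:
        return self.Z.shape[0]

    @property
    def n_features(self) -> int:
        return self.Z.shape[1]

    @property
    def group_sizes(self) -> dict:
        return {k: len(v) for k, v in self.groups.items()}

    def standardize(self, train_mask=None) -> "GroupedFeatureMatrix":
        """Standardized copy; statistics from ``train_mask`` rows (default all).

        Zero-variance columns are left centred but unscaled (sd treated as 1).
        """
        m = np.ones(self.n_rows, bool) if train_mask is None else np.asarray(train_mask)
        mu = self.Z[m].mean(axis=0)
        sd = self.Z[m].std(axis=0)
        sd_safe = np.where(sd > _EPS, sd, 1.0)
        ym, ys = float(self.y[m].mean()), float(self.y[m].std())
        out = GroupedFeatureMatrix(
            Z=(self.Z - mu) / sd_safe, y=(self.y - ym) / (ys if ys > _EPS else 1.0),
            feature_names=self.feature_names, groups=self.groups,
            end_times=self.end_times, day=self.day, delta_h=self.delta_h,
            window=self.window, stride=self.stride, cluster=self.cluster,
            x_mean=mu, x_sd=sd_safe, y_mean=ym, y_sd=ys,
        )
        return out

    def save(self, path_prefix) -> None:
        """Persist as ``<prefix>.csv`` plus a JSON sidecar with the partition."""
        p = Path(path_prefix)
        df = pd.DataFrame(self.Z, columns=self.feature_names)
        df.insert(0, "timestamp_s", self.end_times)
        df["hr_bpm"] = self.y
        df["day"] = self.day
        if self.cluster is not None:
            df["cluster"] = self.cluster
        df.to_csv(p.with_suffix(".csv"), index=False)
        side = {
            "groups": {k: np.asarray(v).tolist() for k, v in self.groups.items()},
            "delta_h": None if math.isinf(self.delta_h) else self.delta_h,
            "window_s": self.window,
            "stride_s": self.stride,
        }
        p.with_suffix(".json").write_text(json.dumps(side, indent=1))


def _window_means(ts, vals, starts, ends):
    """Mean of a scalar channel over each half-open window [start, end)."""
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    i0 = np.searchsorted(ts, starts - 1e-9)
    i1 = np.searchsorted(ts, ends - 1e-9)
    cnt = i1 - i0
    if np.any(cnt <= 0):
        raise RecordingError("empty scalar window during feature extraction")
    return (csum[i1] - csum[i0]) / cnt


def _frames(ts, vals, starts, m):
    """Stack m consecutive samples starting at each window start index."""
    i0 = np.searchsorted(ts, starts - 1e-9)
    if np.any(i0 + m > len(ts)):
        raise RecordingError("window extends past end of stream")
    idx = i0[:, None] + np.arange(m)[None, :]
    return vals[idx]


def build_design(
    rec: MultimodalRecording,
    delta_h: float = 30.0,
    window: float = 5.0,
    stride: float = 1.0,
) -> GroupedFeatureMatrix:
    """Extract the grouped design matrix Z and response Y from a recording.

    One row per stride step (on the 1 Hz analysis grid) whose feature window
    ``[t−w, t)`` and heart-rate history ``t−δh−2 … t−δh`` are both available
    within the row's day; the response is HR at the row end-time ``t``.
    ``delta_h=inf`` omits the hr group entirely (6 groups, p = 51).
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    if delta_h <= 0:
        raise ValueError("delta_h must be positive (or inf)")
    include_hr = not math.isinf(delta_h)
    lag = int(round(delta_h)) if include_hr else 0

    rows_Z, rows_y, rows_t, rows_day = [], [], [], []
    for d in range(rec.n_days):
        t0, t1 = rec.day_edges[d], rec.day_edges[d + 1]
        tgt = rec.target.slice_time(t0, t1)
        # response on the 1 Hz grid (identity when HR is already 1 Hz)
        g0 = math.ceil(tgt.timestamps[0])
        grid = np.arange(g0, math.floor(tgt.timestamps[-1]) + 1.0)
        ygrid = _resample_channel(tgt.timestamps, tgt.values[:, 0], grid, 1.0)

        start_lim = max(window, (lag + 2) if include_hr else 0.0)
        # candidate end-times at the stride, offset so windows fit in-day
        streams_start = max(
            [rec.streams[k].slice_time(t0, t1).timestamps[0] for k in rec.streams]
            + [grid[0]]
        )
        tmin = streams_start + start_lim
        cand = grid[(grid >= tmin - 1e-9)]
        if stride != 1.0:
            step = int(round(stride))
            cand = cand[::step]
        if len(cand) == 0:
            raise RecordingError(
                f"day {d}: recording too short for window={window}, delta_h={delta_h}"
            )
        gi = np.searchsorted(grid, cand)  # exact grid positions

        cols, names, groups, offset = [], [], {}, 0

        def add_group(name, block, feat_names):
            nonlocal offset
            cols.append(block)
            names.extend(f"{name}__{fn}" for fn in feat_names)
            groups[name] = np.arange(offset, offset + block.shape[1])
            offset += block.shape[1]

        for name in ("body_temp", "env_temp", "humidity"):
            s = rec.streams[name].slice_time(t0, t1)
            v = _window_means(s.timestamps, s.values[:, 0], cand - window, cand)
            add_group(name, v[:, None], ("mean",))
        for name in ("wrist_accel", "ankle_accel"):
            s = rec.streams[name].slice_time(t0, t1)
            m = int(round(window * s.rate))
            W = _frames(s.timestamps, s.values, cand - window, m)
            add_group(name, accel_features_many(W, s.rate), ACCEL_FEATURE_NAMES)
        s = rec.streams["eda"].slice_time(t0, t1)
        m = int(round(window * s.rate))
        W = _frames(s.timestamps, s.values[:, 0], cand - window, m)
        add_group("eda", eda_features_many(W, np.arange(m) / s.rate),
                  EDA_FEATURE_NAMES)
        if include_hr:
            j = gi - lag
            block = np.column_stack([
                ygrid[j],
                ygrid[j] - ygrid[j - 1],
                ygrid[j] - 2 * ygrid[j - 1] + ygrid[j - 2],
            ])
            add_group("hr", block, HR_FEATURE_NAMES)

        rows_Z.append(np.hstack(cols))
        rows_y.append(ygrid[gi])
        rows_t.append(cand)
        rows_day.append(np.full(len(cand), d))

    return GroupedFeatureMatrix(
        Z=np.vstack(rows_Z),
        y=np.concatenate(rows_y),
        feature_names=names,
        groups=groups,
        end_times=np.concatenate(rows_t),
        day=np.concatenate(rows_day),
        delta_h=delta_h,
        window=window,
        stride=stride,
    )
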
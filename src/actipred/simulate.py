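"""Synthetic multimodal recordings with the structure the method assumes.

The generator emulates a four-day exercise protocol: per day, ten minutes of
walking, twenty minutes alternating walking and running laps, rest, two
fifteen-minute exercise sessions separated by five minutes of rest, and two
final ten-minute walks.  Activity states drive state-dependent accelerometer
waveforms and first-order heart-rate relaxation toward per-state setpoints;
electrodermal activity drifts slowly with a state-coupled component; the
temperature and humidity channels are near-constant noise.  Ground-truth
state labels are emitted for testing only — the pipeline never reads them.

A semi-Markov schedule (transition matrix + exponential dwell times) is
available as an alternative to the fixed protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import build_design
from .streams import MultimodalRecording, SensorStream

__all__ = [
    "SimConfig",
    "StateParams",
    "PlantedModel",
    "DEFAULT_PROTOCOL",
    "simulate_recording",
    "plant_linear_response",
    "calibrate_noise_sd",
]


class ConfigError(ValueError):
    pass


#: the default one-day protocol (state, duration s); "runwalk" alternates
#: walking and running laps internally.
DEFAULT_PROTOCOL = (
    ("walk", 600.0),
    ("runwalk", 1200.0),
    ("rest", 600.0),
    ("exercise", 900.0),
    ("rest", 300.0),
    ("exercise", 900.0),
    ("walk", 600.0),
    ("walk", 600.0),
)


@dataclass
class StateParams:
    """Per-state signal parameters."""

    accel_amp_g: float        # dominant oscillation amplitude at the ankle (g)
    accel_freq_hz: float      # dominant frequency (Hz)
    hr_setpoint_bpm: float    # heart-rate relaxation target (bpm)
    eda_gain_uS: float = 0.0  # state-coupled EDA elevation (µS)
    burst_freq_hz: float | None = None  # second frequency for burst states
    wrist_scale: float = 1.0  # wrist amplitude relative to ankle


DEFAULT_STATES = {
    # wrist_scale: arms swing less than the ankle moves while walking and
    # running, but dominate during (upper-body-heavy) exercise
    "rest": StateParams(0.03, 0.25, 70.0, 0.0, wrist_scale=1.0),
    "walk": StateParams(0.45, 1.8, 95.0, 0.10, wrist_scale=0.55),
    "run": StateParams(1.10, 2.8, 150.0, 0.40, wrist_scale=0.75),
    "exercise": StateParams(1.30, 1.0, 125.0, 0.30, burst_freq_hz=2.2,
                            wrist_scale=1.6),
}


@dataclass
class SimConfig:
    """Simulation configuration; defaults reproduce the study protocol."""

    n_days: int = 4
    protocol: tuple = DEFAULT_PROTOCOL
    # semi-Markov alternative: set states/transition/mean_dwell_s, protocol=None
    markov_states: tuple | None = None
    transition: np.ndarray | None = None
    mean_dwell_s: np.ndarray | None = None
    day_duration_s: float | None = None   # required for semi-Markov schedules

    states: dict = field(default_factory=lambda: dict(DEFAULT_STATES))
    walk_lap_s: float = 150.0
    run_lap_s: float = 90.0
    burst_block_s: float = 0.5

    hr_tau_s: float = 30.0
    hr_noise_sd_bpm: float = 1.5
    accel_noise_sd_g: float = 0.01
    accel_axis_scale: tuple = (1.0, 0.6, 0.3)

    eda_baseline_uS: float = 0.3
    eda_drift_uS_per_s: float = 2e-4
    eda_tau_s: float = 60.0
    eda_noise_sd_uS: float = 0.01

    body_temp_C: float = 33.5
    body_temp_sd: float = 0.05
    env_temp_C: float = 22.0
    env_temp_sd: float = 0.10
    humidity_pct: float = 45.0
    humidity_sd: float = 0.5

    rates_hz: dict = field(default_factory=lambda: {
        "wrist_accel": 32.0, "ankle_accel": 32.0, "eda": 4.0,
        "body_temp": 4.0, "env_temp": 1.0, "humidity": 1.0, "hr": 1.0,
    })

    def validate(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.protocol is not None:
            for st, dur in self.protocol:
                if dur <= 0:
                    raise ConfigError(f"protocol duration for {st!r} must be positive")
        else:
            if self.transition is None or self.markov_states is None:
                raise ConfigError("need protocol or a semi-Markov specification")
            P = np.asarray(self.transition, float)
            if not np.allclose(P.sum(axis=1), 1.0):
                raise ConfigError("transition matrix rows must sum to 1")
            if np.any(np.asarray(self.mean_dwell_s) <= 0):
                raise ConfigError("mean dwell times must be positive")
            if not self.day_duration_s or self.day_duration_s <= 0:
                raise ConfigError("day_duration_s must be positive for semi-Markov")
        for k, r in self.rates_hz.items():
            if r <= 0:
                raise ConfigError(f"rate for {k!r} must be positive")
        for nm in ("hr_tau_s", "walk_lap_s", "run_lap_s", "burst_block_s", "eda_tau_s"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"{nm} must be positive")
        for nm in ("hr_noise_sd_bpm", "accel_noise_sd_g", "eda_noise_sd_uS",
                   "body_temp_sd", "env_temp_sd", "humidity_sd"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm} must be non-negative")

    @property
    def day_length_s(self) -> float:
        if self.protocol is not None:
            return float(sum(d for _, d in self.protocol))
        return float(self.day_duration_s)


def _expand_protocol(cfg: SimConfig, rng) -> list:
    """(state, start, duration, segment_index) pieces for one day."""
    pieces = []
    t = 0.0
    if cfg.protocol is not None:
        for seg_i, (st, dur) in enumerate(cfg.protocol):
            if st == "runwalk":
                left = dur
                phase = 0  # walk lap first
                while left > 1e-9:
                    lap = cfg.walk_lap_s if phase == 0 else cfg.run_lap_s
                    lap = min(lap, left)
                    pieces.append(("walk" if phase == 0 else "run", t, lap, seg_i))
                    t += lap
                    left -= lap
                    phase ^= 1
            else:
                pieces.append((st, t, dur, seg_i))
                t += dur
    else:
        states = list(cfg.markov_states)
        P = np.asarray(cfg.transition, float)
        dwell = np.asarray(cfg.mean_dwell_s, float)
        s = int(rng.integers(len(states)))
        seg_i = 0
        while t < cfg.day_duration_s:
            d = float(rng.exponential(dwell[s]))
            d = min(d, cfg.day_duration_s - t)
            if d > 1e-9:
                pieces.append((states[s], t, d, seg_i))
            t += d
            s = int(rng.choice(len(states), p=P[s]))
            seg_i += 1
    return pieces


def _state_at(pieces, times):
    """State name per time (day-local), plus segment index per time."""
    starts = np.array([p[1] for p in pieces])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(pieces) - 1)
    states = np.array([p[0] for p in pieces])
    segs = np.array([p[3] for p in pieces])
    return states[idx], segs[idx]


def _accel_day(cfg, pieces, rate, rng, wrist=False):
    T = cfg.day_length_s
    n = int(round(T * rate))
    t = np.arange(n) / rate
    states, _ = _state_at(pieces, t)
    amp = np.empty(n)
    freq = np.empty(n)
    for nm, sp in cfg.states.items():
        m = states == nm
        if not m.any():
            continue
        samp = sp.accel_amp_g * (sp.wrist_scale if wrist else 1.0)
        amp[m] = samp
        if sp.burst_freq_hz is None:
            freq[m] = sp.accel_freq_hz
        else:
            # rhythmic bursts alternating two frequencies: repetitions cycle
            # through a fixed amplitude profile (rep period 2.5 s, well
            # inside the analysis window) with a small random jitter, and
            # the secondary (faster) component is weaker so the spectral
            # peak stays at the primary movement frequency
            block = (t[m] // cfg.burst_block_s).astype(int)
            secondary = block % 2 == 1
            freq[m] = np.where(secondary, sp.burst_freq_hz, sp.accel_freq_hz)
            profile = np.array([1.0, 0.45, 0.8, 0.3, 0.65])
            env = (profile[block % len(profile)]
                   + 0.05 * rng.standard_normal(len(block)))
            amp[m] = samp * env * np.where(secondary, 0.5, 1.0)
    # slow AR(1) wander of movement intensity (~10 %) and cadence (~5 %):
    # human gait is not metronomic, every state is a diffuse blob
    n1 = int(math.ceil(T)) + 1
    ar = np.empty(n1)
    ar[0] = 0.0
    innov = rng.standard_normal(n1)
    for i in range(1, n1):
        ar[i] = 0.98 * ar[i - 1] + innov[i]
    ar = ar / max(ar.std(), 1e-9)
    wander = np.interp(t, np.arange(n1, dtype=float), ar)
    amp = amp * (1.0 + 0.10 * wander)
    freq = freq * (1.0 + 0.05 * wander)
    vals = np.empty((n, 3))
    # integrate the instantaneous frequency so state changes and cadence
    # wander are smooth frequency modulation, not phase jumps/chirps
    phi = 2 * np.pi * np.cumsum(freq) / rate
    # one gait phase per day with fixed per-axis lags: the axes stay
    # phase-locked, so inter-axis covariances are stable across days
    phase0 = rng.uniform(0, 2 * np.pi)
    for a, scale in enumerate(cfg.accel_axis_scale):
        vals[:, a] = (amp * scale * np.sin(phi + phase0 + (0.0, 1.0, 2.0)[a])
                      + rng.normal(0, cfg.accel_noise_sd_g, n))
    return t, vals


def simulate_recording(config: SimConfig, seed: int) -> MultimodalRecording:
    """Generate one multimodal recording (identical seed ⇒ identical output)."""
    config.validate()
    streams = {k: ([], []) for k in config.rates_hz if k != "hr"}
    hr_ts, hr_vals = [], []
    label_rows = []
    edges = [0.0]
    for day in range(config.n_days):
        rng = np.random.default_rng([int(seed), day])
        t0 = edges[-1]
        pieces = _expand_protocol(config, rng)
        T = (pieces[-1][1] + pieces[-1][2]) if config.protocol is None else config.day_length_s
        edges.append(t0 + T)

        for name in ("wrist_accel", "ankle_accel"):
            t, v = _accel_day(config, pieces, config.rates_hz[name], rng,
                              wrist=(name == "wrist_accel"))
            streams[name][0].append(t0 + t)
            streams[name][1].append(v)

        # 1 Hz state grid drives HR, EDA coupling and labels
        n1 = int(round(T))
        t1 = np.arange(n1, dtype=float)
        states1, segs1 = _state_at(pieces, t1)
        setp = np.array([config.states[s].hr_setpoint_bpm for s in states1])
        hr = np.empty(n1)
        hr[0] = setp[0]
        noise = rng.normal(0, config.hr_noise_sd_bpm, n1)
        a = 1.0 / config.hr_tau_s
        for i in range(1, n1):
            hr[i] = hr[i - 1] + a * (setp[i] - hr[i - 1]) + noise[i]
        hr_ts.append(t0 + t1)
        hr_vals.append(hr)
        label_rows.append(pd.DataFrame(
            {"timestamp_s": t0 + t1, "state": states1, "segment": segs1}
        ))

        # EDA: baseline + drift + first-order-smoothed state coupling + noise
        gain1 = np.array([config.states[s].eda_gain_uS for s in states1])
        sm = np.empty(n1)
        sm[0] = gain1[0]
        b = 1.0 / config.eda_tau_s
        for i in range(1, n1):
            sm[i] = sm[i - 1] + b * (gain1[i] - sm[i - 1])
        re = config.rates_hz["eda"]
        te = np.arange(int(round(T * re))) / re
        eda = (config.eda_baseline_uS + config.eda_drift_uS_per_s * te
               + np.interp(te, t1, sm)
               + rng.normal(0, config.eda_noise_sd_uS, len(te)))
        streams["eda"][0].append(t0 + te)
        streams["eda"][1].append(eda[:, None])

        for name, mean, sd in (
            ("body_temp", config.body_temp_C, config.body_temp_sd),
            ("env_temp", config.env_temp_C, config.env_temp_sd),
            ("humidity", config.humidity_pct, config.humidity_sd),
        ):
            r = config.rates_hz[name]
            ts = np.arange(int(round(T * r))) / r
            streams[name][0].append(t0 + ts)
            streams[name][1].append((mean + rng.normal(0, sd, len(ts)))[:, None])

    built = {}
    for name, (ts, vs) in streams.items():
        vals = np.vstack([v if v.ndim == 2 else v[:, None] for v in vs])
        built[name] = SensorStream(
            name, np.concatenate(ts), vals, config.rates_hz[name]
        )
    target = SensorStream(
        "hr", np.concatenate(hr_ts), np.concatenate(hr_vals)[:, None],
        config.rates_hz["hr"],
    )
    return MultimodalRecording(
        streams=built, target=target, day_edges=np.asarray(edges),
        labels=pd.concat(label_rows, ignore_index=True),
    )


@dataclass
class PlantedModel:
    """Known-truth linear response for support-recovery experiments.

    ``coef`` maps group name → coefficient vector applied to that group's
    raw features; groups absent from ``coef`` (or all-zero) are outside the
    true support.
    """

    coef: dict
    intercept: float = 70.0
    noise_sd: float = 1.0

    @property
    def support(self) -> tuple:
        return tuple(k for k, v in self.coef.items() if np.any(np.asarray(v) != 0))


def _planted_response(rec, model, delta_h, window, rng):
    """Recursively generate the target on the 1 Hz grid (per day)."""
    design = build_design(rec, delta_h=math.inf if "hr" not in model.coef
                          else delta_h, window=window)
    for g in model.coef:
        if g not in design.groups and g != "hr":
            raise ValueError(f"planted group {g!r} not in design")
    use_hr = "hr" in model.coef and not math.isinf(delta_h)
    lag = int(round(delta_h)) if not math.isinf(delta_h) else 0
    # exogenous part of the signal (everything except hr history)
    exo = np.full(design.n_rows, float(model.intercept))
    for g, beta in model.coef.items():
        if g == "hr":
            continue
        beta = np.asarray(beta, float)
        idx = design.groups[g]
        if len(beta) != len(idx):
            raise ValueError(f"coefficient length mismatch for group {g!r}")
        exo = exo + design.Z[:, idx] @ beta
    bhr = np.asarray(model.coef.get("hr", np.zeros(3)), float)

    new_ts, new_vals = [], []
    for d in range(rec.n_days):
        t0, t1 = rec.day_edges[d], rec.day_edges[d + 1]
        tgt = rec.target.slice_time(t0, t1)
        grid = tgt.timestamps  # 1 Hz by construction of the simulator
        ynew = np.full(len(grid), float(model.intercept))
        rows = design.day == d
        row_t = design.end_times[rows]
        row_exo = exo[rows]
        gi = np.searchsorted(grid, row_t - 1e-9)
        eps = rng.normal(0, model.noise_sd, len(grid))
        if use_hr:
            for r in range(len(row_t)):
                i = gi[r]
                j = i - lag
                hist = np.array([ynew[j], ynew[j] - ynew[j - 1],
                                 ynew[j] - 2 * ynew[j - 1] + ynew[j - 2]])
                ynew[i] = row_exo[r] + hist @ bhr + eps[i]
        else:
            ynew[gi] = row_exo + eps[gi]
        new_ts.append(grid)
        new_vals.append(ynew)
    return np.concatenate(new_ts), np.concatenate(new_vals)


def plant_linear_response(
    rec: MultimodalRecording,
    model: PlantedModel,
    seed: int,
    delta_h: float = 30.0,
    window: float = 5.0,
) -> MultimodalRecording:
    """Replace the target stream with ``Σ_k Z_k β_k + intercept + noise``.

    Features are the recording's raw windowed features; the heart-rate
    history group (if planted) is generated recursively so the downstream
    design reproduces the planted model exactly.  The true support is
    recorded on the returned recording for later recovery checks.
    """
    rng = np.random.default_rng(int(seed))
    ts, vals = _planted_response(rec, model, delta_h, window, rng)
    target = SensorStream("hr", ts, vals[:, None], rec.target.rate)
    return MultimodalRecording(
        streams=rec.streams, target=target, day_edges=rec.day_edges,
        context_sensors=rec.context_sensors, labels=rec.labels,
        planted_support=model.support,
    )


def calibrate_noise_sd(
    rec: MultimodalRecording,
    model: PlantedModel,
    snr: float,
    delta_h: float = 30.0,
    window: float = 5.0,
) -> PlantedModel:
    """Return a copy of ``model`` whose noise sd gives the requested SNR
    (signal variance of the noiseless planted response / noise variance)."""
    silent = replace(model, noise_sd=0.0)
    rng = np.random.default_rng(0)
    _, vals = _planted_response(rec, silent, delta_h, window, rng)
    # restrict to rows the design will actually contain
    design = build_design(rec, delta_h=delta_h, window=window)
    gi = np.searchsorted(rec.target.timestamps, design.end_times - 1e-9)
    sig_var = float(np.var(vals[gi]))
    return replace(model, noise_sd=math.sqrt(sig_var / snr))
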
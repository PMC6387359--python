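"""Canned synthetic experiments certifying the pipeline's machinery.

These are the package's standard self-checks: activity-clustering agreement
with ground-truth states, and exact sensor-support recovery on a
planted-truth recording. Both are deterministic given a seed and are shared
by the test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .activity import ActivityClusterModel
from .features import build_design
from .glasso import GroupLassoCV
from .simulate import (DEFAULT_PROTOCOL, DEFAULT_STATES, PlantedModel,
                       SimConfig, calibrate_noise_sd, plant_linear_response,
                       simulate_recording)

__all__ = [
    "scaled_protocol",
    "decoy_sim_config",
    "planted_sensor_model",
    "support_recovery_trial",
    "activity_clustering_trial",
]

PLANTED_SUPPORT = ("wrist_accel", "ankle_accel", "hr")


def scaled_protocol(factor: float):
    """The standard 8-segment day protocol with durations scaled."""
    return tuple((s, d * factor) for s, d in DEFAULT_PROTOCOL)


def decoy_sim_config(n_days: int = 3, rows_per_day: int = 2000) -> SimConfig:
    """Recording config whose non-planted sensors are true decoys.

    EDA's state coupling and drift are switched off: with them on, EDA
    legitimately proxies activity and time-of-day (the protocol repeats
    daily) and a correct selector *should* keep it. Day length is chosen so
    the design has about ``rows_per_day`` rows per day at δh = 30 s.
    """
    day_s = rows_per_day + 40.0
    factor = day_s / sum(d for _, d in DEFAULT_PROTOCOL)
    states = {k: dataclasses.replace(v, eda_gain_uS=0.0)
              for k, v in DEFAULT_STATES.items()}
    return SimConfig(n_days=n_days, protocol=scaled_protocol(factor),
                     states=states, eda_drift_uS_per_s=0.0)


def planted_sensor_model() -> PlantedModel:
    """Planted truth with distinct signals per group.

    Wrist carries movement intensity (window variances), ankle carries
    cadence (peak frequencies) and HR a mild autoregressive term — exact
    support recovery is only identifiable when no planted group is
    predictively redundant given the others.
    """
    wrist = np.zeros(21)
    wrist[1], wrist[7] = 20.0, 12.0        # var_x, var_y
    ankle = np.zeros(21)
    ankle[5], ankle[11] = 8.0, 5.0         # peak_freq_x, peak_freq_y
    return PlantedModel(coef={"wrist_accel": wrist, "ankle_accel": ankle,
                              "hr": [0.3, 0.15, 0.0]}, intercept=35.0)


def support_recovery_trial(seed: int, delta_h: float = 30.0,
                           snr: float = 10.0, rule: str = "1se",
                           relax: bool = True):
    """One planted-support trial; returns (selected set, planted set)."""
    cfg = decoy_sim_config()
    rec = simulate_recording(cfg, seed=seed)
    pm = calibrate_noise_sd(rec, planted_sensor_model(), snr=snr,
                            delta_h=delta_h)
    rec = plant_linear_response(rec, pm, seed=int(seed) + 10_000,
                                delta_h=delta_h)
    design = build_design(rec, delta_h=delta_h)
    m = GroupLassoCV(groups=design.groups, rule=rule, relax=relax)
    m.fit(design.Z, design.y, days=design.day)
    return frozenset(m.active_groups_), frozenset(rec.planted_support)


def activity_clustering_trial(seed: int, n_days: int = 4,
                              delta_h: float = 30.0):
    """Cluster the default protocol; returns (train ARI, test ARI).

    The activity model is fitted on all days but the last; the adjusted
    Rand index compares assigned clusters with the generator's ground-truth
    state labels.
    """
    rec = simulate_recording(SimConfig(n_days=n_days), seed=seed)
    design = build_design(rec, delta_h=delta_h)
    ctx = design.Z[:, design.groups["ankle_accel"]]
    truth = rec.labels.set_index("timestamp_s")["state"].reindex(
        design.end_times).to_numpy()
    train = design.day < (n_days - 1)
    model = ActivityClusterModel(random_state=0).fit(ctx[train])
    ari_train = adjusted_rand_score(truth[train], model.labels_)
    ari_test = adjusted_rand_score(truth[~train],
                                   model.predict(ctx[~train]))
    return ari_train, ari_test
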
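"""Current-reduction accounting and the accuracy–power trade-off.

A sensor whose feature group is inactive in the running cluster's model can
be duty-cycled (placed in idle mode, transmission stopped); the saving is
the sum of the disabled sensors' incremental current draws.  The default
:class:`PowerTable` is reconstructed from the published per-cluster
reduction accounting (see ``data/power_table.json``); the raw bench
measurements of the prototype platform ship alongside as
``power_table_measured.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PowerTable",
    "PowerReport",
    "default_power_table",
    "measured_power_table",
    "current_reduction",
    "average_reduction",
    "dropout_levels",
    "tradeoff_curve",
]

SENSORS = ("body_temp", "env_temp", "humidity", "wrist_accel",
           "ankle_accel", "eda", "hr")


@dataclass(frozen=True)
class PowerTable:
    """Per-sensor incremental currents (mA) and full-system baseline."""

    currents_mA: dict
    i_total_mA: float

    def __post_init__(self):
        if any(v < 0 for v in self.currents_mA.values()):
            raise ValueError("sensor currents must be non-negative")
        if sum(self.currents_mA.values()) > self.i_total_mA + 1e-9:
            raise ValueError("sum of increments exceeds the system total")

    @classmethod
    def from_json(cls, path) -> "PowerTable":
        d = json.loads(Path(path).read_text())
        return cls(currents_mA=dict(d["currents_mA"]),
                   i_total_mA=float(d["i_total_mA"]))


def _packaged(name):
    with resources.as_file(resources.files("actipred") / "data" / name) as p:
        return PowerTable.from_json(p)


def default_power_table() -> PowerTable:
    """Reconstructed per-sensor increments (the default accounting basis)."""
    return _packaged("power_table.json")


def measured_power_table() -> PowerTable:
    """Raw bench-measured increments of the prototype wrist/chest platform."""
    return _packaged("power_table_measured.json")


def current_reduction(active_sensors, table: PowerTable):
    """(ΔI mA, Δ%) from duty-cycling every sensor not in ``active_sensors``."""
    active = set(active_sensors)
    unknown = active - set(table.currents_mA)
    if unknown:
        raise KeyError(f"unknown sensor name(s): {sorted(unknown)}")
    delta = sum(v for k, v in table.currents_mA.items() if k not in active)
    return delta, 100.0 * delta / table.i_total_mA


def average_reduction(delta_by_cluster, n_by_cluster) -> float:
    """Cluster-size-weighted mean reduction ΔI_avg = Σ N_ci·ΔI_ci / Σ N_ci."""
    d = np.asarray(delta_by_cluster, float)
    n = np.asarray(n_by_cluster, float)
    if d.shape != n.shape:
        raise ValueError("cluster reduction and size lists differ in length")
    if np.any(n <= 0):
        raise ValueError("cluster sizes must be positive")
    return float((d * n).sum() / n.sum())


def dropout_levels(path) -> dict:
    """Largest λ at which each sensor group is still active (0 if never)."""
    levels = {}
    for lam, act in zip(path.lambdas, path.active_sets):
        for s in act:
            levels.setdefault(s, float(lam))
    all_groups = set().union(*map(set, path.active_sets)) if path.active_sets else set()
    return {s: levels.get(s, 0.0) for s in sorted(all_groups | set(levels))}


def tradeoff_curve(path, table: PowerTable, lambda_opt=None):
    """(λ, RMSE increase over the optimum, Δ% current) for each λ ≥ λ*.

    Requires ``path.test_rmse``; points are ordered by increasing λ, so the
    current saving is non-decreasing along the list when active sets nest.
    """
    if path.test_rmse is None:
        raise ValueError("path has no test RMSE; evaluate it first")
    lam0 = path.lambda_opt if lambda_opt is None else lambda_opt
    sel = [i for i, lam in enumerate(path.lambdas) if lam >= lam0 - 1e-12]
    sel = sorted(sel, key=lambda i: path.lambdas[i])  # ascending λ from λ*
    base = path.test_rmse[sel[0]]
    out = []
    for i in sel:
        _, pct = current_reduction(path.active_sets[i], table)
        out.append((float(path.lambdas[i]), float(path.test_rmse[i] - base), pct))
    return out


@dataclass
class PowerReport:
    """Per-cluster duty-cycling savings for one (δh, scheme) setting."""

    active_sets: dict               # cluster id -> tuple of active sensors
    delta_mA: dict                  # cluster id -> ΔI_ci (mA)
    delta_pct: dict
    cluster_sizes: dict             # cluster id -> N_ci
    avg_mA: float = 0.0
    avg_pct: float = 0.0
    nc_mA: float | None = None      # no-clustering variant
    nc_pct: float | None = None
    nc_active: tuple | None = None

    @classmethod
    def build(cls, active_sets, cluster_sizes, table, nc_active=None):
        delta_mA, delta_pct = {}, {}
        for c, act in active_sets.items():
            delta_mA[c], delta_pct[c] = current_reduction(act, table)
        ids = sorted(active_sets)
        avg = average_reduction([delta_mA[c] for c in ids],
                                [cluster_sizes[c] for c in ids])
        rep = cls(
            active_sets=dict(active_sets), delta_mA=delta_mA,
            delta_pct=delta_pct, cluster_sizes=dict(cluster_sizes),
            avg_mA=avg, avg_pct=100.0 * avg / table.i_total_mA,
        )
        if nc_active is not None:
            rep.nc_active = tuple(nc_active)
            rep.nc_mA, rep.nc_pct = current_reduction(nc_active, table)
        return rep

    def to_dict(self) -> dict:
        return {
            "clusters": {
                str(c): {
                    "active_sensors": sorted(self.active_sets[c]),
                    "delta_mA": self.delta_mA[c],
                    "delta_pct": self.delta_pct[c],
                    "n": int(self.cluster_sizes[c]),
                } for c in sorted(self.active_sets)
            },
            "avg_mA": self.avg_mA, "avg_pct": self.avg_pct,
            "nc_mA": self.nc_mA, "nc_pct": self.nc_pct,
            "nc_active_sensors": sorted(self.nc_active) if self.nc_active else None,
        }
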
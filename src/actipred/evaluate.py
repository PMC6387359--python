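"""Metrics, baselines and end-to-end pipeline orchestration.

``run_pipeline`` executes the full activity-aware workflow on a recording
(synthetic or loaded): featurize → fit the activity model on the training
days → assign clusters → per-cluster day-wise CV + group lasso fit →
evaluate on the held-out test day (clustered, unclustered and
constant-predictor variants) → power report and accuracy–power trade-off
curves.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import power as pw
from .activity import ActivityClusterModel
from .features import GroupedFeatureMatrix, build_design
from .glasso import GroupLassoCV
from .simulate import SimConfig, simulate_recording
from .streams import MultimodalRecording, read_recording

__all__ = [
    "MetricsReport",
    "PipelineConfig",
    "PipelineReport",
    "metrics",
    "constant_predictor",
    "run_pipeline",
]

SMALL_SAMPLE = 30


@dataclass
class MetricsReport:
    """MAE/RMSE/NRMSE/R² plus a response summary."""

    mae: float
    rmse: float
    nrmse: float
    r2: float
    n: int
    y_mean: float
    y_max: float
    y_min: float
    small_sample: bool = False

    def to_dict(self):
        return dataclasses.asdict(self)


def metrics(y, y_hat) -> MetricsReport:
    """MAE = mean |ŷ−y|; RMSE; NRMSE = RMSE/(y_max − y_min); R² = 1 − SSE/SST."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    ymax, ymin = float(y.max()), float(y.min())
    if ymax <= ymin:
        raise ValueError("NRMSE undefined for a constant response")
    e = y_hat - y
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((e ** 2).sum()) / sst
    return MetricsReport(
        mae=mae, rmse=rmse, nrmse=rmse / (ymax - ymin), r2=r2, n=y.size,
        y_mean=float(y.mean()), y_max=ymax, y_min=ymin,
        small_sample=y.size < SMALL_SAMPLE,
    )


def constant_predictor(design: GroupedFeatureMatrix, rows=None,
                       train_mean: float | None = None) -> np.ndarray:
    """Baseline ŷ(t) = y(t − δh), read off the raw lagged-HR column.

    With δh = ∞ there is no history and the baseline degrades to the
    training-mean predictor (flagged by requiring ``train_mean``).
    """
    rows = slice(None) if rows is None else rows
    if math.isinf(design.delta_h):
        if train_mean is None:
            raise ValueError("delta_h = inf: pass train_mean for the fallback")
        warnings.warn("delta_h = inf: constant predictor falls back to the "
                      "training mean")
        return np.full(np.sum(np.ones_like(design.y, bool)[rows]), train_mean)
    lag_col = design.groups["hr"][0]
    return design.Z[rows, lag_col]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (defaults mirror the study conditions)."""

    delta_h: float = 30.0
    scheme: str = "normalized"
    window_s: float = 5.0
    stride_s: float = 1.0
    n_clusters: int = 4
    lpp_components: int = 3
    lpp_neighbors: int = 10
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-4
    kmeans_restarts: int = 20
    power_table: str | None = None      # path; None → packaged default
    sim: SimConfig = field(default_factory=SimConfig)
    manifest: str | None = None         # load instead of simulating

    def load_power_table(self) -> pw.PowerTable:
        if self.power_table is None:
            return pw.default_power_table()
        return pw.PowerTable.from_json(self.power_table)


@dataclass
class PipelineReport:
    """Everything one (δh, scheme) run produces."""

    delta_h: float
    scheme: str
    lambda_opt: dict                # cluster id -> λ*
    active_sets: dict               # cluster id -> active sensors
    cluster_metrics: dict           # cluster id -> MetricsReport (test day)
    pooled: "MetricsReport"
    unclustered: "MetricsReport"
    cp_baseline: "MetricsReport"
    nc_lambda_opt: float
    nc_active: tuple
    power: pw.PowerReport
    tradeoff: dict                  # cluster id / "nc" -> list of points
    skipped_clusters: tuple = ()
    n_train: int = 0
    n_test: int = 0

    def to_dict(self):
        return {
            "delta_h": None if math.isinf(self.delta_h) else self.delta_h,
            "scheme": self.scheme,
            "lambda_opt": {str(k): v for k, v in self.lambda_opt.items()},
            "active_sets": {str(k): sorted(v) for k, v in self.active_sets.items()},
            "cluster_metrics": {str(k): m.to_dict()
                                for k, m in self.cluster_metrics.items()},
            "pooled": self.pooled.to_dict(),
            "unclustered": self.unclustered.to_dict(),
            "cp_baseline": self.cp_baseline.to_dict(),
            "nc_lambda_opt": self.nc_lambda_opt,
            "nc_active": sorted(self.nc_active),
            "power": self.power.to_dict(),
            "tradeoff": {str(k): v for k, v in self.tradeoff.items()},
            "skipped_clusters": list(self.skipped_clusters),
            "n_train": self.n_train, "n_test": self.n_test,
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _path_test_rmse(path, Z_test, y_test):
    preds = Z_test @ path.coef.T + path.intercepts
    return np.sqrt(((preds - y_test[:, None]) ** 2).mean(axis=0))


def run_pipeline(config: PipelineConfig, seed: int = 0,
                 recording: MultimodalRecording | None = None,
                 plugins: dict | None = None) -> PipelineReport:
    """Run the activity-aware prediction pipeline end to end.

    The last recording day is held out for testing; earlier days are
    training data and the CV folds.  Test-time cluster assignment uses the
    training-fitted activity model (no test-day refitting).
    """
    if recording is None:
        if config.manifest is not None:
            recording = read_recording(config.manifest)
        else:
            recording = simulate_recording(config.sim, seed)
    if recording.n_days < 3:
        raise ValueError("need >= 2 training days + 1 test day")
    table = config.load_power_table()
    powers = table.currents_mA if config.scheme == "weighted" else None

    design = build_design(recording, delta_h=config.delta_h,
                          window=config.window_s, stride=config.stride_s)
    test_day = recording.n_days - 1
    train = design.day < test_day
    test = ~train

    # --- activity model on training days, assignment everywhere -----------
    ctx = design.Z[:, design.groups["ankle_accel"]]
    act = ActivityClusterModel(
        n_clusters=config.n_clusters, n_components=config.lpp_components,
        n_neighbors=config.lpp_neighbors, n_init=config.kmeans_restarts,
        random_state=int(seed) % (2 ** 31),
    ).fit(ctx[train])
    cluster = np.empty(design.n_rows, int)
    cluster[train] = act.labels_
    cluster[test] = act.predict(ctx[test])
    design.cluster = cluster

    # --- per-cluster CV + fit ---------------------------------------------
    models, lambda_opt, active_sets, skipped = {}, {}, {}, []
    for c in range(config.n_clusters):
        rows = train & (cluster == c)
        if rows.sum() == 0:
            warnings.warn(f"cluster {c} absent from training data; skipped")
            skipped.append(c)
            continue
        m = GroupLassoCV(
            groups=design.groups, scheme=config.scheme, powers=powers,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        try:
            m.fit(design.Z[rows], design.y[rows], days=design.day[rows])
        except ValueError as exc:
            warnings.warn(f"cluster {c} model skipped ({exc}); the "
                          "unclustered model will cover its test rows")
            skipped.append(c)
            continue
        models[c] = m
        lambda_opt[c] = m.lambda_
        active_sets[c] = m.active_groups_

    # --- unclustered model -------------------------------------------------
    nc = GroupLassoCV(groups=design.groups, scheme=config.scheme,
                      powers=powers, n_lambdas=config.n_lambdas,
                      lambda_min_ratio=config.lambda_min_ratio)
    nc.fit(design.Z[train], design.y[train], days=design.day[train])

    # --- test-day evaluation ----------------------------------------------
    y_test = design.y[test]
    yhat = np.empty(test.sum())
    cl_test = cluster[test]
    Z_test = design.Z[test]
    cluster_metrics = {}
    for c in range(config.n_clusters):
        m_rows = cl_test == c
        if not m_rows.any():
            continue
        mdl = models.get(c, nc)  # skipped cluster falls back to NC model
        yhat[m_rows] = mdl.predict(Z_test[m_rows])
        if m_rows.sum() >= 2 and y_test[m_rows].max() > y_test[m_rows].min():
            cluster_metrics[c] = metrics(y_test[m_rows], yhat[m_rows])
    pooled = metrics(y_test, yhat)
    unclustered = metrics(y_test, nc.predict(Z_test))
    cp = constant_predictor(design, rows=test,
                            train_mean=float(design.y[train].mean()))
    cp_metrics = metrics(y_test, cp)

    # --- power accounting (test-day cluster occupancy as N_ci) ------------
    sizes = {c: int((cl_test == c).sum()) for c in active_sets}
    for c in list(active_sets):
        if sizes[c] == 0:
            sizes[c] = int((cluster[train] == c).sum())  # fallback weight
    report_power = pw.PowerReport.build(active_sets, sizes, table,
                                        nc_active=nc.active_groups_)

    # --- accuracy–power trade-off curves ----------------------------------
    tradeoff = {}
    for c, m in models.items():
        rows = cl_test == c
        if rows.sum() < 2:
            continue
        m.path_.test_rmse = _path_test_rmse(m.path_, Z_test[rows], y_test[rows])
        tradeoff[c] = pw.tradeoff_curve(m.path_, table)
    nc.path_.test_rmse = _path_test_rmse(nc.path_, Z_test, y_test)
    tradeoff["nc"] = pw.tradeoff_curve(nc.path_, table)

    rep = PipelineReport(
        delta_h=config.delta_h, scheme=config.scheme, lambda_opt=lambda_opt,
        active_sets=active_sets, cluster_metrics=cluster_metrics,
        pooled=pooled, unclustered=unclustered, cp_baseline=cp_metrics,
        nc_lambda_opt=nc.lambda_, nc_active=nc.active_groups_,
        power=report_power, tradeoff=tradeoff,
        skipped_clusters=tuple(skipped),
        n_train=int(train.sum()), n_test=int(test.sum()),
    )
    rep.models_ = models          # kept for callers; not serialized
    rep.nc_model_ = nc
    rep.activity_model_ = act
    rep.design_ = design
    if plugins:
        rep.plugin_metrics_ = {}
        for name, factory in plugins.items():
            try:
                rep.plugin_metrics_[name] = _eval_plugin(
                    factory, design, models, nc, train, test, cluster)
            except Exception as exc:  # noqa: BLE001 — plugin isolation
                warnings.warn(f"plugin {name!r} failed and was skipped: {exc}")
    return rep


def _eval_plugin(factory, design, models, nc, train, test, cluster):
    """Fit/predict a secondary regressor on each cluster's reduced feature
    set (the group-lasso-active columns) under the same protocol."""
    y_test = design.y[test]
    yhat = np.empty(test.sum())
    cl_test = cluster[test]
    for c in np.unique(cl_test):
        mdl = models.get(int(c), nc)
        cols = np.concatenate([
            design.groups[g] for g in mdl.active_groups_
        ]) if mdl.active_groups_ else np.arange(design.n_features)
        rows_tr = train & (cluster == c)
        if rows_tr.sum() == 0:
            rows_tr = train
        est = factory() if callable(factory) else dataclasses.replace(factory)
        mu = design.Z[rows_tr][:, cols].mean(axis=0)
        sd = design.Z[rows_tr][:, cols].std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        est.fit((design.Z[rows_tr][:, cols] - mu) / sd, design.y[rows_tr])
        rows_te = cl_test == c
        yhat[rows_te] = est.predict(
            (design.Z[test][rows_te][:, cols] - mu) / sd)
    return metrics(y_test, yhat)
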
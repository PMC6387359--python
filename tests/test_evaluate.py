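import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from actipred import (GroupedFeatureMatrix, PipelineConfig, SimConfig,
                      constant_predictor, metrics, run_pipeline)

from conftest import scaled_protocol


class TestMetrics:
    def test_hand_computed_three_point_example(self):
        m = metrics([60, 80, 100], [62, 77, 104])
        assert m.mae == pytest.approx(3.0, abs=1e-9)
        assert m.rmse == pytest.approx(math.sqrt(29 / 3), abs=1e-9)
        assert m.nrmse == pytest.approx(math.sqrt(29 / 3) / 40, abs=1e-9)
        assert m.r2 == pytest.approx(1 - 29 / 800, abs=1e-9)

    def test_perfect_prediction(self):
        m = metrics([60.0, 70, 80], [60.0, 70, 80])
        assert (m.mae, m.rmse, m.nrmse, m.r2) == (0, 0, 0, 1)

    def test_mean_predictor_has_zero_r2(self, rng):
        y = rng.normal(70, 10, 50)
        m = metrics(y, np.full(50, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metrics([70.0, 70.0], [69.0, 71.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0, 2.0], [1.0])


@given(
    hnp.arrays(np.float64, st.integers(3, 40),
               elements=st.floats(40, 200, allow_nan=False)),
    st.data(),
)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_metric_invariants_hold_on_arbitrary_traces(y, data):
    if y.max() - y.min() < 1e-6:
        y[0] += 1.0  # ensure a non-constant response
    yhat = data.draw(hnp.arrays(
        np.float64, y.size, elements=st.floats(40, 200, allow_nan=False)))
    m = metrics(y, yhat)
    assert m.rmse >= m.mae >= 0.0
    assert m.r2 <= 1.0
    assert m.nrmse == pytest.approx(m.rmse / (m.y_max - m.y_min))
    # shifting both series leaves every error metric unchanged
    m2 = metrics(y + 7.5, yhat + 7.5)
    assert m2.mae == pytest.approx(m.mae)
    assert m2.rmse == pytest.approx(m.rmse)


def _fake_design(delta_h=30.0):
    """Minimal design with an hr group whose lag column is y(t−δh)."""
    t = np.arange(100.0, 200.0)
    y = t.copy()                      # 1 bpm/s ramp
    lag = y - delta_h
    Z = np.column_stack([lag, np.ones_like(lag), np.zeros_like(lag)])
    return GroupedFeatureMatrix(
        Z=Z, y=y, feature_names=["hr__lag", "hr__diff1", "hr__diff2"],
        groups={"hr": np.arange(3)}, end_times=t,
        day=np.zeros(len(t), int), delta_h=delta_h, window=5.0, stride=1.0)


class TestConstantPredictor:
    def test_lagged_ramp_error_equals_horizon(self):
        d = _fake_design(delta_h=30.0)
        cp = constant_predictor(d)
        m = metrics(d.y, cp)
        assert m.mae == pytest.approx(30.0)

    def test_constant_response_is_predicted_perfectly(self):
        d = _fake_design()
        d.y = np.full(d.n_rows, 71.0)
        d.Z[:, 0] = 71.0
        assert np.all(constant_predictor(d) == 71.0)

    def test_infinite_horizon_falls_back_to_training_mean(self):
        d = _fake_design()
        d.delta_h = math.inf
        with pytest.warns(UserWarning, match="training mean"):
            cp = constant_predictor(d, train_mean=70.0)
        assert np.all(cp == 70.0)
        with pytest.raises(ValueError, match="train_mean"):
            constant_predictor(d)


@pytest.fixture(scope="module")
def pipeline_report():
    from sklearn.dummy import DummyRegressor
    cfg = PipelineConfig(
        delta_h=30.0, n_lambdas=12,
        sim=SimConfig(n_days=3, protocol=scaled_protocol(0.12)),
    )
    rep = run_pipeline(cfg, seed=5,
                       plugins={"mean": lambda: DummyRegressor()})
    return rep, cfg


class TestPipeline:
    def test_report_structure(self, pipeline_report):
        rep, cfg = pipeline_report
        assert set(rep.active_sets) | set(rep.skipped_clusters) == set(
            range(cfg.n_clusters))
        for act in rep.active_sets.values():
            assert set(act) <= {"body_temp", "env_temp", "humidity",
                                "wrist_accel", "ankle_accel", "eda", "hr"}
        assert rep.pooled.n == rep.n_test
        assert rep.cp_baseline.n == rep.n_test

    def test_power_average_lies_between_cluster_extremes(self, pipeline_report):
        rep, _ = pipeline_report
        vals = list(rep.power.delta_mA.values())
        assert min(vals) <= rep.power.avg_mA <= max(vals)

    def test_pooled_rmse_is_size_weighted_quadratic_mean(self, pipeline_report):
        rep, _ = pipeline_report
        tot = sum(m.n for m in rep.cluster_metrics.values())
        assert tot == rep.n_test
        mix = math.sqrt(sum(m.n * m.rmse ** 2
                            for m in rep.cluster_metrics.values()) / tot)
        assert rep.pooled.rmse == pytest.approx(mix, rel=1e-9)

    def test_tradeoff_curves_start_at_selected_lambda(self, pipeline_report):
        rep, _ = pipeline_report
        for key, pts in rep.tradeoff.items():
            assert pts[0][1] == 0.0
            lam_opt = rep.nc_lambda_opt if key == "nc" else rep.lambda_opt[key]
            assert pts[0][0] == pytest.approx(lam_opt)

    def test_deterministic_given_seed(self, pipeline_report):
        rep, cfg = pipeline_report
        rep2 = run_pipeline(cfg, seed=5)
        assert rep.to_dict() == rep2.to_dict()

    def test_single_cluster_reduces_to_unclustered_model(self):
        cfg = PipelineConfig(
            delta_h=30.0, n_clusters=1, n_lambdas=10,
            sim=SimConfig(n_days=3, protocol=scaled_protocol(0.1)),
        )
        rep = run_pipeline(cfg, seed=3)
        assert rep.pooled.rmse == pytest.approx(rep.unclustered.rmse,
                                                rel=1e-9)
        assert rep.active_sets[0] == rep.nc_active

    def test_too_few_days_rejected(self):
        cfg = PipelineConfig(sim=SimConfig(n_days=2,
                                           protocol=scaled_protocol(0.05)))
        with pytest.raises(ValueError, match="day"):
            run_pipeline(cfg, seed=0)


class TestHorizonDivergence:
    def test_constant_predictor_degrades_faster_than_model(self):
        """As the history horizon grows, the lag baseline decays quickly
        while the multimodal model holds up (HR dynamics are ~30 s)."""
        from actipred import GroupLassoCV, build_design, simulate_recording
        rec = simulate_recording(
            SimConfig(n_days=3, protocol=scaled_protocol(0.15)), seed=4)
        cp_rmse, model_rmse = [], []
        for dh in (10.0, 30.0, 90.0):
            d = build_design(rec, delta_h=dh)
            train = d.day < 2
            m = GroupLassoCV(groups=d.groups, n_lambdas=10)
            m.fit(d.Z[train], d.y[train], days=d.day[train])
            test = ~train
            model_rmse.append(metrics(d.y[test],
                                      m.predict(d.Z[test])).rmse)
            cp_rmse.append(metrics(d.y[test],
                                   constant_predictor(d, rows=test)).rmse)
        assert cp_rmse == sorted(cp_rmse)  # non-decreasing in delta_h
        for dh, mr, cr in zip((10.0, 30.0, 90.0), model_rmse, cp_rmse):
            if dh >= 30.0:
                assert mr < cr

    def test_planted_pipeline_excludes_decoys(self):
        """End to end on planted truth: no decoy sensor enters any cluster
        model and clustering does not cost accuracy."""
        from actipred import (build_design, calibrate_noise_sd,
                              plant_linear_response, simulate_recording)
        from actipred.experiments import decoy_sim_config, planted_sensor_model
        cfg = decoy_sim_config(n_days=3, rows_per_day=2000)
        rec = simulate_recording(cfg, seed=2)
        pm = calibrate_noise_sd(rec, planted_sensor_model(), snr=10.0,
                                delta_h=30.0)
        rec = plant_linear_response(rec, pm, seed=1002, delta_h=30.0)
        rep = run_pipeline(PipelineConfig(delta_h=30.0, n_lambdas=15),
                           seed=2, recording=rec)
        decoys = {"body_temp", "env_temp", "humidity", "eda"}
        for act in list(rep.active_sets.values()) + [rep.nc_active]:
            assert not (set(act) & decoys)
        assert rep.pooled.rmse <= rep.unclustered.rmse + 0.5


class TestRegressorPlugin:
    def test_mean_predictor_plugin_is_dominated_by_the_model(
            self, pipeline_report):
        # a cluster-wise mean predictor retains the skill clustering itself
        # provides (clusters track HR states) but none of the feature skill
        rep, _ = pipeline_report
        dummy = rep.plugin_metrics_["mean"]
        assert dummy.rmse > rep.pooled.rmse
        assert dummy.r2 < rep.pooled.r2

    def test_failing_plugin_is_skipped_with_warning(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        cfg = PipelineConfig(
            delta_h=30.0, n_lambdas=8,
            sim=SimConfig(n_days=3, protocol=scaled_protocol(0.06)),
        )
        with pytest.warns(UserWarning, match="skipped"):
            rep = run_pipeline(cfg, seed=2, plugins={"broken": Broken})
        assert "broken" not in rep.plugin_metrics_
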
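import math
import warnings

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from actipred import GroupLassoCV, GroupLassoRegressor, lasso_path
from actipred.glasso import fit_glasso
from actipred.glasso import _StdDesign, group_weights, kkt_check, lambda_max


# --- independent oracle: proximal gradient (FISTA) on the same objective ----

def fista_group_lasso(Z, y, blocks, thr, max_iter=20000, tol=1e-12):
    """Accelerated proximal gradient for ‖y − Zβ‖² + Σ_k thr_k‖β_k‖₂."""
    L = 2.0 * np.linalg.eigvalsh(Z.T @ Z).max() + 1e-12
    beta = np.zeros(Z.shape[1])
    v = beta.copy()
    tk = 1.0
    for _ in range(max_iter):
        grad = 2.0 * Z.T @ (Z @ v - y)
        u = v - grad / L
        new = np.empty_like(u)
        for idx, t in zip(blocks, thr):
            g = u[idx]
            nrm = np.linalg.norm(g)
            new[idx] = 0.0 if nrm <= t / L else (1 - (t / L) / nrm) * g
        tk1 = (1 + math.sqrt(1 + 4 * tk ** 2)) / 2
        v = new + ((tk - 1) / tk1) * (new - beta)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta, tk = new, tk1
    return beta


def objective(Z, y, beta, blocks, thr):
    r = y - Z @ beta
    return float(r @ r + sum(t * np.linalg.norm(beta[i])
                             for i, t in zip(blocks, thr)))


def random_instance(rng, n_max=40, p_max=12):
    n = int(rng.integers(15, n_max + 1))
    n_groups = int(rng.integers(2, 5))
    sizes = rng.integers(1, 5, size=n_groups)
    p = int(min(sizes.sum(), p_max))
    sizes = sizes[np.cumsum(sizes) <= p]
    if len(sizes) < 2:
        sizes = np.array([1, 1])
    idx = np.split(np.arange(sizes.sum()), np.cumsum(sizes)[:-1])
    Z = rng.normal(size=(n, int(sizes.sum())))
    beta_true = rng.normal(size=Z.shape[1]) * rng.integers(0, 2, Z.shape[1])
    y = Z @ beta_true + rng.normal(size=n)
    groups = {f"g{i}": j for i, j in enumerate(idx)}
    return Z, y, groups


class TestSolverAgainstOracles:
    def test_objective_matches_fista_on_random_instances(self, rng):
        worst = 0.0
        for _ in range(50):
            Z, y, groups = random_instance(rng)
            c = group_weights("normalized", groups)
            D = _StdDesign(Z, y, groups, standardize=True)
            lam = 0.3 * D.lambda_max(c)
            m = GroupLassoRegressor(groups=groups, lam=lam, tol=1e-10).fit(Z, y)
            thr = [lam * math.sqrt(c[n]) for n in D.group_names]
            beta_o = fista_group_lasso(D.Xs, D.ys, D.blocks, thr)
            f_m = objective(D.Xs, D.ys, m.beta_std_, D.blocks, thr)
            f_o = objective(D.Xs, D.ys, beta_o, D.blocks, thr)
            worst = max(worst, abs(f_m - f_o) / max(abs(f_o), 1e-12))
            assert kkt_check(m) < 1e-4
        assert worst < 1e-6

    def test_lambda_zero_reduces_to_least_squares(self, rng):
        Z = rng.normal(size=(40, 9))
        y = Z[:, 0] * 2 - Z[:, 4] + rng.normal(size=40)
        groups = {"a": np.arange(3), "b": np.arange(3, 6), "c": np.arange(6, 9)}
        m = GroupLassoRegressor(groups=groups, lam=0.0, tol=1e-10).fit(Z, y)
        Zc = np.column_stack([Z, np.ones(40)])
        b = np.linalg.lstsq(Zc, y, rcond=None)[0]
        np.testing.assert_allclose(m.coef_, b[:9], atol=1e-5)

    def test_lambda_at_or_above_max_gives_empty_model(self, rng):
        Z, y, groups = random_instance(rng)
        D = _StdDesign(Z, y, groups)
        c = D.weights("normalized", None)
        lmax = D.lambda_max(c)
        for lam in (lmax, 1.5 * lmax):
            m = GroupLassoRegressor(groups=groups, lam=lam).fit(Z, y)
            assert m.active_groups_ == ()
            assert np.all(m.coef_ == 0)

    def test_singleton_groups_match_standard_lasso(self, rng):
        Z = rng.normal(size=(20, 3))
        y = Z @ [1.5, 0.0, -0.7] + rng.normal(size=20)
        groups = {f"f{j}": [j] for j in range(3)}
        lam = 8.0
        m = GroupLassoRegressor(groups=groups, lam=lam, tol=1e-12).fit(Z, y)
        D = m.design_
        sk = Lasso(alpha=lam / (2 * len(y)), fit_intercept=False,
                   tol=1e-14, max_iter=200000).fit(D.Xs, D.ys)
        np.testing.assert_allclose(m.beta_std_, sk.coef_, atol=1e-8)

    def test_single_group_ridge_type_shrinkage_matches_fista(self, rng):
        Z = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        groups = {"all": np.arange(5)}
        c = group_weights("normalized", groups)
        D = _StdDesign(Z, y, groups)
        lam = 0.4 * D.lambda_max(c)
        m = GroupLassoRegressor(groups=groups, lam=lam, tol=1e-12).fit(Z, y)
        thr = [lam * math.sqrt(c["all"])]
        beta_o = fista_group_lasso(D.Xs, D.ys, D.blocks, thr)
        f_m = objective(D.Xs, D.ys, m.beta_std_, D.blocks, thr)
        f_o = objective(D.Xs, D.ys, beta_o, D.blocks, thr)
        assert abs(f_m - f_o) <= 1e-8 * max(1.0, abs(f_o))
        # shrinkage, not selection: whole group shrunk toward zero
        assert np.linalg.norm(m.beta_std_) < np.linalg.norm(
            np.linalg.lstsq(D.Xs, D.ys, rcond=None)[0])


class TestLambdaMax:
    def test_orthogonal_response_gives_zero(self):
        Z = np.eye(6)[:, :3]
        y = np.array([0, 0, 0, 1.0, -1, 0.5])
        assert lambda_max(Z, y, {"g": np.arange(3)}, {"g": 1.0}) == 0.0

    def test_single_orthonormal_group_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        got = lambda_max(q, y, {"g": np.arange(4)}, {"g": 1.0})
        assert got == pytest.approx(2 * np.linalg.norm(q.T @ y), rel=1e-12)

    def test_quadrupling_weight_halves_contribution(self, rng):
        Z = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        g = {"g": np.arange(4)}
        assert lambda_max(Z, y, g, {"g": 4.0}) == pytest.approx(
            lambda_max(Z, y, g, {"g": 1.0}) / 2, rel=1e-12)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lambda_max(np.eye(3), np.ones(3), {"g": [0, 1, 2]}, {"g": 1.0})


class TestPath:
    def test_first_grid_point_is_empty(self, rng):
        Z, y, groups = random_instance(rng)
        p = lasso_path(Z, y, groups, n_lambdas=12)
        assert p.active_sets[0] == ()
        assert np.all(np.diff(p.lambdas) < 0)

    def test_planted_groups_leave_the_path_last(self, rng):
        n = 200
        Z = rng.normal(size=(n, 8))
        groups = {"strong1": [0, 1], "strong2": [2, 3],
                  "noise1": [4, 5], "noise2": [6, 7]}
        y = Z[:, 0] * 3 + Z[:, 1] * 2 + Z[:, 2] * 2.5 + rng.normal(size=n)
        p = lasso_path(Z, y, groups, n_lambdas=25)
        from actipred import dropout_levels
        lv = dropout_levels(p)
        assert min(lv["strong1"], lv["strong2"]) > max(
            lv.get("noise1", 0), lv.get("noise2", 0))

    def test_warm_start_objective_not_worse_than_cold(self, rng):
        Z, y, groups = random_instance(rng)
        p = lasso_path(Z, y, groups, n_lambdas=10)
        for i, lam in enumerate(p.lambdas):
            cold = GroupLassoRegressor(groups=groups, lam=float(lam),
                                       tol=1e-10).fit(Z, y)
            assert p.objectives[i] <= cold.objective_ * (1 + 1e-6) + 1e-9


class TestInvariances:
    def test_within_group_column_permutation(self, rng):
        Z, y, groups = random_instance(rng)
        big = max(groups, key=lambda k: len(groups[k]))
        if len(groups[big]) < 2:
            pytest.skip("no multi-column group drawn")
        lam_ref = 0.3 * _StdDesign(Z, y, groups).lambda_max(
            group_weights("normalized", groups))
        m1 = GroupLassoRegressor(groups=groups, lam=lam_ref, tol=1e-10).fit(Z, y)
        perm = np.array(groups[big])[::-1]
        Z2 = Z.copy()
        Z2[:, groups[big]] = Z[:, perm]
        m2 = GroupLassoRegressor(groups=groups, lam=lam_ref, tol=1e-10).fit(Z2, y)
        np.testing.assert_allclose(m2.coef_[groups[big]],
                                   m1.coef_[perm], atol=1e-6)
        assert set(m1.active_groups_) == set(m2.active_groups_)

    def test_kkt_certificate_along_path(self, rng):
        Z, y, groups = random_instance(rng)
        D = _StdDesign(Z, y, groups)
        c = D.weights("normalized", None)
        lmax = D.lambda_max(c)
        for frac in (0.8, 0.3, 0.05, 0.01):
            m = GroupLassoRegressor(groups=groups, lam=frac * lmax,
                                    tol=1e-10).fit(Z, y)
            assert kkt_check(m) < 1e-4


class TestPredictContract:
    @pytest.fixture()
    def fitted(self, rng):
        Z = rng.normal(size=(60, 6))
        y = Z[:, 0] * 4 + Z[:, 1] * 3 + rng.normal(size=60) * 0.1 + 70
        groups = {"sig": [0, 1], "dud": [2, 3], "dud2": [4, 5]}
        D = _StdDesign(Z, y, groups)
        lam = 0.3 * D.lambda_max(D.weights("normalized", None))
        m = GroupLassoRegressor(groups=groups, lam=lam).fit(Z, y)
        assert m.active_groups_ == ("sig",)
        return m, Z, y

    def test_all_zero_standardized_features_predict_training_mean(self, fitted):
        m, Z, y = fitted
        x = Z.mean(axis=0, keepdims=True)  # zero in standardized units
        assert m.predict(x)[0] == pytest.approx(y.mean(), rel=1e-12)

    def test_training_rows_match_stored_fitted_values(self, fitted):
        m, Z, _ = fitted
        np.testing.assert_allclose(m.predict(Z), m.fitted_values_, atol=1e-9)

    def test_missing_inactive_sensor_changes_nothing(self, fitted):
        m, Z, _ = fitted
        Z2 = Z.copy()
        Z2[:, [2, 3]] = np.nan  # duty-cycled inactive group
        np.testing.assert_allclose(m.predict(Z2), m.predict(Z), atol=1e-12)

    def test_missing_active_sensor_is_an_error_naming_it(self, fitted):
        m, Z, _ = fitted
        Z2 = Z.copy()
        Z2[:, 0] = np.nan
        with pytest.raises(ValueError, match="sig"):
            m.predict(Z2)

    def test_nonfinite_training_inputs_rejected(self, rng):
        Z = rng.normal(size=(10, 4))
        Z[3, 2] = np.inf
        with pytest.raises(ValueError, match="finite"):
            GroupLassoRegressor(groups={"g": np.arange(4)}, lam=1.0).fit(
                Z, rng.normal(size=10))


class TestCrossValidation:
    def test_pure_noise_selects_near_empty_model(self, rng):
        n = 240
        Z = rng.normal(size=(n, 8))
        y = rng.normal(size=n)
        days = np.repeat([0, 1, 2], n // 3)
        groups = {f"g{i}": [2 * i, 2 * i + 1] for i in range(4)}
        m = GroupLassoCV(groups=groups, n_lambdas=20).fit(Z, y, days=days)
        # CV error of the chosen model within one null-sd of the empty model
        null_rmse = m.path_.cv_rmse[0]
        assert m.path_.cv_rmse.min() >= null_rmse - y.std() / math.sqrt(n / 3)
        assert len(m.active_groups_) <= 1

    def test_duplicating_rows_leaves_lambda_grid_position_unchanged(self, rng):
        n = 120
        Z = rng.normal(size=(n, 6))
        y = Z[:, 0] * 2 + rng.normal(size=n)
        days = np.repeat([0, 1, 2], n // 3)
        groups = {"a": [0, 1], "b": [2, 3], "c": [4, 5]}
        m1 = GroupLassoCV(groups=groups, n_lambdas=15).fit(Z, y, days=days)
        Z2, y2, d2 = np.vstack([Z, Z]), np.r_[y, y], np.r_[days, days]
        m2 = GroupLassoCV(groups=groups, n_lambdas=15).fit(Z2, y2, days=d2)
        i1 = int(np.argmin(np.abs(m1.path_.lambdas - m1.lambda_)))
        i2 = int(np.argmin(np.abs(m2.path_.lambdas - m2.lambda_)))
        assert i1 == i2  # grid is relative to lambda_max

    def test_single_day_rejected(self, rng):
        Z = rng.normal(size=(30, 4))
        with pytest.raises(ValueError, match="day"):
            GroupLassoCV(groups={"g": np.arange(4)}).fit(
                Z, rng.normal(size=30), days=np.zeros(30))


def test_fitted_model_json_roundtrip(rng, tmp_path):
    Z = rng.normal(size=(40, 6))
    y = Z[:, 0] * 3 + rng.normal(size=40) + 70
    groups = {"a": [0, 1], "b": [2, 3], "c": [4, 5]}
    m = fit_glasso(Z, y, groups, lam=5.0)
    m.to_json(tmp_path / "m.json")
    back = GroupLassoRegressor.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(back.predict(Z), m.predict(Z), atol=1e-12)
    assert back.active_groups_ == m.active_groups_


def test_weighted_scheme_prefers_cheap_sensors(rng):
    """Raising a group's power weight pushes it out of the model earlier."""
    n = 300
    Z = rng.normal(size=(n, 4))
    y = Z[:, 0] + Z[:, 2] + rng.normal(size=n) * 0.5
    groups = {"cheap": [0, 1], "dear": [2, 3]}
    from actipred import dropout_levels
    p_cheap = lasso_path(Z, y, groups, scheme="weighted",
                         powers={"cheap": 0.1, "dear": 5.0}, n_lambdas=25)
    lv = dropout_levels(p_cheap)
    assert lv["cheap"] > lv["dear"]
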
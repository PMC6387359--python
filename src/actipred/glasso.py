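"""Group lasso estimation with sensor-group penalties.

Minimizes, on standardized data,

    ‖Y − Σ_k Z_k β_k‖₂² + λ Σ_k √c_k ‖β_k‖₂

where the c_k implement the two weighting schemes: ``normalized``
(c_k = 1/M_k, each sensor weighted equally regardless of its feature count)
and ``weighted`` (c_k = P_k/M_k, power-hungry sensors penalized harder).
The penalty is not divided by N, so λ is data-size dependent; the grid is
always taken relative to λ_max, which makes this harmless.

The solver is block coordinate descent with exact block minimization: each
group subproblem (quadratic plus Euclidean-norm penalty) is solved in the
eigenbasis of its Gram block by a monotone scalar root-find, and the path
is warm-started.  The intercept is handled by centering and never
penalized.  Zero-variance columns (e.g. a constant humidity channel) are
dropped with a warning before fitting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GroupLassoRegressor",
    "GroupLassoCV",
    "LambdaPath",
    "group_weights",
    "lambda_max",
    "fit_glasso",
    "lasso_path",
    "kkt_check",
]

_EPS = 1e-12


class ConvergenceWarning(UserWarning):
    pass


def group_weights(scheme, groups, powers=None):
    """Per-group penalty scalars c_k.

    ``normalized``: c_k = 1/M_k.  ``weighted``: c_k = P_k/M_k with P_k the
    sensor's average current draw (mA) from ``powers``.
    """
    sizes = {k: len(v) for k, v in groups.items()}
    if scheme == "normalized":
        return {k: 1.0 / m for k, m in sizes.items()}
    if scheme == "weighted":
        if powers is None:
            raise ValueError("weighted scheme needs per-sensor powers")
        missing = [k for k in groups if k not in powers]
        if missing:
            raise ValueError(f"no power entry for groups {missing}")
        return {k: powers[k] / m for k, m in sizes.items()}
    if isinstance(scheme, dict):
        return {k: float(scheme[k]) for k in groups}
    raise ValueError(f"unknown penalty scheme {scheme!r}")


def lambda_max(Z, y, groups, c) -> float:
    """Smallest λ with an all-zero solution: max_k 2‖Z_k'Y‖₂ / √c_k."""
    y = np.asarray(y, float)
    if y.std() <= _EPS:
        raise ValueError("zero-variance response")
    best = 0.0
    for k, idx in groups.items():
        if len(idx) == 0:
            continue
        g = 2.0 * np.linalg.norm(Z[:, idx].T @ y) / math.sqrt(c[k])
        best = max(best, g)
    return best


def _solve_block(w, Q, z2, t):
    """Exact minimizer of β'Wβ − z2'β·... the block subproblem

        min_β  β'G_kk β − 2 b̃'β + t‖β‖₂

    in the eigenbasis ``G_kk = Q diag(w) Q'`` with ``z2 = 2 Q'b̃``.
    The norm s = ‖β‖ solves the monotone scalar equation
    s = ‖z2·s/(2ws + t)‖; solved by bisection.
    """
    nz2 = math.sqrt(float(z2 @ z2))
    if nz2 <= t:
        return None  # zero block
    # b̃ lies in range(G_kk); clean rounding noise in null directions
    live = w > 1e-12 * w[-1]
    z2 = np.where(live, z2, 0.0)
    z2sq = z2 * z2
    wmin = w[live & (z2sq > 0)].min(initial=w[-1])
    lo, hi = 0.0, nz2 / (2.0 * max(wmin, 1e-300)) + 1.0
    w2 = 2.0 * w
    for _ in range(60):
        s = 0.5 * (lo + hi)
        d = w2 * s + t
        h2 = s * s * float(z2sq @ (1.0 / (d * d)))
        if h2 > s * s:
            lo = s
        else:
            hi = s
    s = 0.5 * (lo + hi)
    return Q @ (z2 * s / (w2 * s + t))


def _bcd(G, b, blocks, thr, eigs, beta, tol, max_iter):
    """Block coordinate descent in Gram form with exact block minimization.

    G = Z'Z, b = Z'y; ``blocks`` are column index arrays, ``thr[k]`` the
    penalty λ√c_k and ``eigs[k] = (w, Q)`` the eigendecomposition of the
    block Gram G_kk.  Returns (beta, n_iter, converged).
    """
    for it in range(max_iter):
        delta = 0.0
        for k, idx in enumerate(blocks):
            bk = beta[idx]
            w, Q = eigs[k]
            # b̃_k = b_k - G_{k,-k} β_{-k}
            btilde = b[idx] - (G[idx] @ beta - G[np.ix_(idx, idx)] @ bk)
            new = _solve_block(w, Q, 2.0 * (Q.T @ btilde), thr[k])
            if new is None:
                new = np.zeros_like(bk)
            d = np.max(np.abs(new - bk))
            if d > 0:
                delta = max(delta, d)
                beta[idx] = new
        if delta < tol:
            return beta, it + 1, True
    return beta, max_iter, False


def _objective(Z, y, beta, blocks, thr):
    r = y - Z @ beta
    pen = sum(t * np.linalg.norm(beta[idx]) for t, idx in zip(thr, blocks))
    return float(r @ r + pen)


class _StdDesign:
    """Standardized design shared across warm-started fits."""

    def __init__(self, X, y, groups, standardize=True):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in design or response")
        self.x_mean = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
        sd = X.std(axis=0) if standardize else np.ones(X.shape[1])
        dead = sd <= _EPS
        if standardize and dead.any():
            warnings.warn(
                f"dropping {int(dead.sum())} zero-variance column(s) before fitting"
            )
        self.x_sd = np.where(dead, 1.0, sd)
        self.kept = ~dead if standardize else np.ones(X.shape[1], bool)
        self.y_mean = float(y.mean()) if standardize else 0.0
        ysd = float(y.std()) if standardize else 1.0
        if standardize and ysd <= _EPS:
            raise ValueError("zero-variance response")
        self.y_sd = ysd if standardize else 1.0
        self.Xs = ((X - self.x_mean) / self.x_sd)[:, self.kept]
        self.ys = (y - self.y_mean) / self.y_sd
        # group blocks in compact (kept) indexing
        pos = np.cumsum(self.kept) - 1
        self.group_names, self.blocks, self.orig_idx = [], [], []
        for name, idx in groups.items():
            idx = np.asarray(idx, int)
            live = idx[self.kept[idx]]
            if len(live) == 0:
                if len(idx):
                    warnings.warn(f"group {name!r} has no usable columns; excluded")
                continue
            self.group_names.append(name)
            self.blocks.append(pos[live])
            self.orig_idx.append(live)
        self.G = self.Xs.T @ self.Xs
        self.b = self.Xs.T @ self.ys
        self.eigs = []
        for i in self.blocks:
            w, Q = np.linalg.eigh(self.G[np.ix_(i, i)])
            self.eigs.append((np.maximum(w, 0.0), Q))
        self.p = X.shape[1]

    def weights(self, scheme, powers):
        groups = {n: i for n, i in zip(self.group_names, self.blocks)}
        return group_weights(scheme, groups, powers)

    def lambda_max(self, c):
        groups = {n: i for n, i in zip(self.group_names, self.blocks)}
        return lambda_max(self.Xs, self.ys, groups, c)

    def solve(self, lam, c, beta0=None, tol=1e-6, max_iter=10_000):
        thr = np.array([lam * math.sqrt(c[n]) for n in self.group_names])
        beta = np.zeros(self.Xs.shape[1]) if beta0 is None else beta0.copy()
        beta, n_iter, conv = _bcd(self.G, self.b, self.blocks, thr,
                                  self.eigs, beta, tol, max_iter)
        return beta, thr, n_iter, conv

    def raw_coef(self, beta):
        """Map compact standardized coefficients to raw-unit full-length coef."""
        full = np.zeros(self.p)
        for blk, orig in zip(self.blocks, self.orig_idx):
            full[orig] = beta[blk]
        coef = full / self.x_sd * self.y_sd
        intercept = self.y_mean - float(coef @ self.x_mean)
        return coef, intercept


class GroupLassoRegressor(RegressorMixin, BaseEstimator):
    """Group lasso heart-rate predictor for one activity cluster.

    Parameters
    ----------
    groups : dict
        Group name → column index array into X.
    lam : float
        Penalty weight λ (on the standardized, un-normalized objective).
    scheme : {"normalized", "weighted"} or dict
        Penalty weighting; ``weighted`` requires ``powers``.
    powers : dict or None
        Sensor name → average current draw (mA), for the weighted scheme.
    standardize : bool
        Center/scale features and response internally (the model is always
        affine in the raw features).

    Attributes
    ----------
    coef_ : ndarray (p,) raw-unit coefficients (0 for dropped columns).
    intercept_ : float
    active_groups_ : tuple of active group names (‖β_k‖₂ > 0).
    coef_std_ : dict group → standardized-unit coefficients.
    """

    def __init__(self, groups=None, lam=1.0, scheme="normalized", powers=None,
                 tol=1e-6, max_iter=10_000, standardize=True):
        self.groups = groups
        self.lam = lam
        self.scheme = scheme
        self.powers = powers
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    def fit(self, X, y):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        groups = self.groups
        if groups is None:  # single group holding everything (ridge-type)
            groups = {"all": np.arange(np.asarray(X).shape[1])}
        D = _StdDesign(X, y, groups, self.standardize)
        c = D.weights(self.scheme, self.powers)
        beta, thr, n_iter, conv = D.solve(self.lam, c, tol=self.tol,
                                          max_iter=self.max_iter)
        if not conv:
            warnings.warn("group lasso did not converge", ConvergenceWarning)
        self._finalize(D, beta, thr, n_iter, conv)
        return self

    def _finalize(self, D, beta, thr, n_iter, conv):
        self.design_ = D
        self.beta_std_ = beta
        self.coef_, self.intercept_ = D.raw_coef(beta)
        self.coef_std_ = {
            n: beta[blk].copy() for n, blk in zip(D.group_names, D.blocks)
        }
        self.active_groups_ = tuple(
            n for n, blk in zip(D.group_names, D.blocks)
            if np.linalg.norm(beta[blk]) > 0
        )
        self.group_index_ = {n: i for n, i in zip(D.group_names, D.orig_idx)}
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.objective_ = _objective(D.Xs, D.ys, beta, D.blocks, thr)
        self.fitted_values_ = (D.Xs @ beta) * D.y_sd + D.y_mean

    def to_json(self, path) -> None:
        """Persist the fitted predictor (enough to reload and predict)."""
        check_is_fitted(self, "coef_")
        payload = {
            "lam": self.lam,
            "scheme": self.scheme if isinstance(self.scheme, str) else dict(
                self.scheme),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "active_groups": list(self.active_groups_),
            "group_index": {k: np.asarray(v).tolist()
                            for k, v in self.group_index_.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroupLassoRegressor":
        d = json.loads(Path(path).read_text())
        m = cls(lam=d["lam"],
                scheme=d["scheme"] if isinstance(d["scheme"], str) else d["scheme"])
        m.coef_ = np.asarray(d["coef"], float)
        m.intercept_ = float(d["intercept"])
        m.active_groups_ = tuple(d["active_groups"])
        m.group_index_ = {k: np.asarray(v, int)
                          for k, v in d["group_index"].items()}
        return m

    def predict(self, X):
        """Predict in raw units.  Columns of *inactive* groups may be NaN
        (the sensor is duty-cycled off); NaN in an active group's columns is
        an error naming the sensor."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        Xv = X.copy()
        nan_cols = np.isnan(Xv).any(axis=0)
        if nan_cols.any():
            for name, idx in self.group_index_.items():
                if nan_cols[idx].any() and name in self.active_groups_:
                    raise ValueError(
                        f"missing features for active sensor {name!r}"
                    )
            Xv[:, nan_cols] = 0.0  # inactive ⇒ zero coefficient anyway
        return Xv @ self.coef_ + self.intercept_


def fit_glasso(Z, y, groups, lam, scheme="normalized", powers=None,
               **kw) -> GroupLassoRegressor:
    """Functional wrapper over :class:`GroupLassoRegressor`."""
    return GroupLassoRegressor(groups=groups, lam=lam, scheme=scheme,
                               powers=powers, **kw).fit(Z, y)


@dataclass
class LambdaPath:
    """Regularization path on a descending λ grid."""

    lambdas: np.ndarray
    active_sets: list                 # list of tuples of group names
    objectives: np.ndarray
    coef: np.ndarray                  # (n_lambda, p) raw-unit coefficients
    intercepts: np.ndarray
    lambda_max: float
    cv_rmse: np.ndarray | None = None     # mean validation RMSE per λ
    test_rmse: np.ndarray | None = None
    lambda_opt: float | None = None

    @property
    def n_active(self) -> np.ndarray:
        return np.array([len(a) for a in self.active_sets])

    def to_json(self, path) -> None:
        payload = {
            "lambdas": self.lambdas.tolist(),
            "active_sets": [list(a) for a in self.active_sets],
            "objectives": self.objectives.tolist(),
            "lambda_max": self.lambda_max,
            "lambda_opt": self.lambda_opt,
            "cv_rmse": None if self.cv_rmse is None else list(self.cv_rmse),
            "test_rmse": None if self.test_rmse is None else list(self.test_rmse),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def predict(self, i, X):
        return np.asarray(X, float) @ self.coef[i] + self.intercepts[i]


def _lambda_grid(lmax, n_lambdas, lambda_min_ratio):
    # nudge the top of the grid above λ_max so the boundary point is exactly
    # the all-zero solution despite floating-point rounding
    return np.geomspace(lmax * (1 + 1e-9), lmax * lambda_min_ratio, n_lambdas)


def lasso_path(Z, y, groups, scheme="normalized", powers=None, n_lambdas=30,
               lambda_min_ratio=1e-4, lambdas=None, tol=1e-6,
               max_iter=10_000) -> LambdaPath:
    """Warm-started path from λ_max down to λ_max·lambda_min_ratio."""
    if lambdas is None and n_lambdas < 2:
        raise ValueError("grid size must be >= 2")
    D = _StdDesign(Z, y, groups, True)
    c = D.weights(scheme, powers)
    lmax = D.lambda_max(c)
    grid = np.asarray(lambdas, float) if lambdas is not None else _lambda_grid(
        lmax, n_lambdas, lambda_min_ratio
    )
    beta = np.zeros(D.Xs.shape[1])
    acts, objs, coefs, icpts = [], [], [], []
    for lam in grid:
        beta, thr, _, conv = D.solve(lam, c, beta0=beta, tol=tol,
                                     max_iter=max_iter)
        if not conv:
            warnings.warn(f"path fit at λ={lam:.4g} did not converge",
                          ConvergenceWarning)
        acts.append(tuple(
            n for n, blk in zip(D.group_names, D.blocks)
            if np.linalg.norm(beta[blk]) > 0
        ))
        objs.append(_objective(D.Xs, D.ys, beta, D.blocks, thr))
        co, ic = D.raw_coef(beta)
        coefs.append(co)
        icpts.append(ic)
    return LambdaPath(
        lambdas=grid, active_sets=acts, objectives=np.asarray(objs),
        coef=np.asarray(coefs), intercepts=np.asarray(icpts), lambda_max=lmax,
    )


class GroupLassoCV(RegressorMixin, BaseEstimator):
    """Day-wise cross-validated λ selection + final refit.

    ``fit(X, y, days=...)`` permutes recording days as folds: each fold
    trains on the other days' rows and validates on the held-out day, on a
    common λ grid anchored at the full-training-set λ_max.  With the
    defaults, each λ is scored by an unpenalized refit on its active groups
    (``relax=True`` — the support is validated, not the shrunk fit) and λ*
    is the sparsest grid point within one standard error of the minimum
    mean RMSE (``rule="1se"``).  ``relax=False, rule="min"`` give the plain
    argmin of the penalized fits' validation RMSE.  The final model is the
    group-lasso fit on all training days at λ*.
    """

    def __init__(self, groups=None, scheme="normalized", powers=None,
                 n_lambdas=30, lambda_min_ratio=1e-4, rule="1se", relax=True,
                 tol=1e-6, max_iter=10_000):
        self.groups = groups
        self.scheme = scheme
        self.powers = powers
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.relax = relax
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, days=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if days is None:
            raise ValueError("day labels are required for day-wise CV")
        days = np.asarray(days)
        uniq = np.unique(days)
        if len(uniq) < 2:
            raise ValueError("need at least 2 training days for CV")
        groups = self.groups or {"all": np.arange(X.shape[1])}
        D_all = _StdDesign(X, y, groups, True)
        c = D_all.weights(self.scheme, self.powers)
        grid = _lambda_grid(D_all.lambda_max(c), self.n_lambdas,
                            self.lambda_min_ratio)

        fold_rmse = []
        for d in uniq:
            tr, va = days != d, days == d
            if va.sum() == 0 or tr.sum() < 2:
                warnings.warn(f"fold for day {d} skipped (empty split)")
                continue
            if y[tr].std() <= 1e-12:
                warnings.warn(f"fold for day {d} skipped "
                              "(constant training response)")
                continue
            path = lasso_path(X[tr], y[tr], groups, self.scheme, self.powers,
                              lambdas=grid, tol=self.tol,
                              max_iter=self.max_iter)
            if self.relax:
                # validate the *support*: unpenalized refit on each λ's
                # active groups, so shrinkage bias does not leak into the
                # model-size comparison
                fold_rmse.append(self._relaxed_rmse(X, y, tr, va, groups,
                                                    path.active_sets))
            else:
                preds = X[va] @ path.coef.T + path.intercepts
                fold_rmse.append(
                    np.sqrt(((preds - y[va][:, None]) ** 2).mean(axis=0)))
        if not fold_rmse:
            raise ValueError("no usable CV folds")
        F = np.vstack(fold_rmse)
        cv = F.mean(axis=0)
        se = F.std(axis=0, ddof=1) / math.sqrt(len(F)) if len(F) > 1 else \
            np.zeros_like(cv)
        best = int(np.argmin(cv))   # first = largest λ on ties
        if self.rule == "1se":
            # sparsest λ whose mean CV RMSE is within one standard error of
            # the minimum: the flat plateau around the minimum makes a plain
            # argmin statistically arbitrary
            best = int(np.flatnonzero(cv <= cv[best] + se[best])[0])
        elif self.rule != "min":
            raise ValueError(f"unknown selection rule {self.rule!r}")
        self.lambda_ = float(grid[best])
        self.cv_se_ = se
        final = GroupLassoRegressor(
            groups=groups, lam=self.lambda_, scheme=self.scheme,
            powers=self.powers, tol=self.tol, max_iter=self.max_iter,
        ).fit(X, y)
        self.model_ = final
        self.path_ = lasso_path(X, y, groups, self.scheme, self.powers,
                                lambdas=grid, tol=self.tol,
                                max_iter=self.max_iter)
        self.path_.cv_rmse = cv
        self.path_.lambda_opt = self.lambda_
        for attr in ("coef_", "intercept_", "active_groups_", "coef_std_",
                     "group_index_", "objective_", "converged_"):
            setattr(self, attr, getattr(final, attr))
        return self

    @staticmethod
    def _relaxed_rmse(X, y, tr, va, groups, active_sets):
        out = np.empty(len(active_sets))
        cache = {}
        for i, act in enumerate(active_sets):
            key = frozenset(act)
            if key not in cache:
                if act:
                    cols = np.concatenate([groups[g] for g in act])
                    A = np.column_stack([X[tr][:, cols],
                                         np.ones(int(tr.sum()))])
                    b, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                    Av = np.column_stack([X[va][:, cols],
                                          np.ones(int(va.sum()))])
                    pred = Av @ b
                else:
                    pred = np.full(int(va.sum()), y[tr].mean())
                cache[key] = math.sqrt(float(np.mean((pred - y[va]) ** 2)))
            out[i] = cache[key]
        return out

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)


def cv_select(Z, y, days, groups, scheme="normalized", powers=None, **kw):
    """Functional wrapper: returns (λ*, fitted :class:`GroupLassoCV`)."""
    m = GroupLassoCV(groups=groups, scheme=scheme, powers=powers, **kw)
    m.fit(Z, y, days=days)
    return m.lambda_, m


def kkt_check(model: GroupLassoRegressor, rtol_active=1e-4, rtol_inactive=1e-6):
    """Max relative KKT violation of a fitted model (0 = certified optimum).

    Active groups must satisfy ``2Z_k'r = λ√c_k β_k/‖β_k‖₂``; inactive groups
    ``‖2Z_k'r‖₂ ≤ λ√c_k``.  Violations are measured relative to λ√c_k.
    """
    D = model.design_
    beta = model.beta_std_
    r = D.ys - D.Xs @ beta
    c = D.weights(model.scheme, model.powers)
    worst = 0.0
    for name, blk in zip(D.group_names, D.blocks):
        g = 2.0 * D.Xs[:, blk].T @ r
        t = model.lam * math.sqrt(c[name])
        bk = beta[blk]
        nrm = np.linalg.norm(bk)
        if nrm > 0:
            v = np.linalg.norm(g - t * bk / nrm) / max(t, _EPS)
        else:
            v = max(0.0, np.linalg.norm(g) - t * (1 + rtol_inactive)) / max(t, _EPS)
        worst = max(worst, v)
    return worst
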
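"""Estimator wrappers, method registry, and the nested cross-validation
protocol: 10 outer folds, 5 inner folds selecting the hyperparameter grid
point with the lowest inner-validation nMSE, refit on the full outer
training fold, metrics on the outer test fold.  Z-scoring is fit inside
each training fold; predictions are mapped back to the original response
scale before computing metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .data import MultitaskDataset, make_folds, zscore
from .kernels import build_pool
from .l21lq import fit_l21lq, predict_l21lq
from .linear import fit_lq1_mtl, predict_linear
from .metrics import MetricsReport, nmse, rmse_per_task, weighted_r
from .mkmtl import fit_mkmtl, predict_mkmtl

__all__ = ["TuningGrid", "nested_cv", "compare_methods", "METHODS",
           "LinearMTLEstimator", "MKMTLEstimator", "L21LqEstimator",
           "RidgeEstimator", "LassoEstimator"]


@dataclass
class TuningGrid:
    """Hyperparameter grid: a geometric lam ladder and optional q values."""

    lam_values: Sequence[float] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    q_values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        lams = list(self.lam_values)
        if any(l <= 0 for l in lams) or sorted(lams) != lams:
            raise ValueError("lam_values must be positive and ascending")

    def points(self) -> list[dict]:
        if self.q_values is None:
            return [{"lam": l} for l in self.lam_values]
        return [{"lam": l, "q": q}
                for l, q in itertools.product(self.lam_values, self.q_values)]


class LinearMTLEstimator:
    """ℓq,1 linear multitask solver behind a fit/predict interface."""

    def __init__(self, q: float = 2.0, lam: float = 1.0, max_iter: int = 3000,
                 tol: float = 1e-8):
        self.q, self.lam, self.max_iter, self.tol = q, lam, max_iter, tol

    def fit(self, ds: MultitaskDataset) -> "LinearMTLEstimator":
        self.theta_, self.state_ = fit_lq1_mtl(
            ds, q=self.q, lam=self.lam, max_iter=self.max_iter, tol=self.tol)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_linear(self.theta_, X)


class MKMTLEstimator:
    """ℓq,1 multikernel multitask solver (pool built on the training fold)."""

    def __init__(self, q: float = 3.0, lam: float = 1.0, max_outer: int = 50,
                 tol: float = 1e-6, per_modality: bool = False,
                 pool_kwargs: dict | None = None):
        self.q, self.lam = q, lam
        self.max_outer, self.tol = max_outer, tol
        self.per_modality = per_modality
        self.pool_kwargs = pool_kwargs or {}

    def fit(self, ds: MultitaskDataset) -> "MKMTLEstimator":
        pool = build_pool(ds, per_modality=self.per_modality, **self.pool_kwargs)
        self.model_ = fit_mkmtl(ds, pool, q=self.q, lam=self.lam,
                                max_outer=self.max_outer, tol=self.tol)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_mkmtl(self.model_, X)


class L21LqEstimator:
    """ℓ2,1-ℓq multikernel multitask solver (PSD trace-constrained blocks)."""

    def __init__(self, q: float = 1.5, lam: float = 1.0, max_outer: int = 60,
                 tol: float = 1e-6, per_modality: bool = False,
                 pool_kwargs: dict | None = None):
        self.q, self.lam = q, lam
        self.max_outer, self.tol = max_outer, tol
        self.per_modality = per_modality
        self.pool_kwargs = pool_kwargs or {}

    def fit(self, ds: MultitaskDataset) -> "L21LqEstimator":
        pool = build_pool(ds, per_modality=self.per_modality, **self.pool_kwargs)
        self.model_ = fit_l21lq(ds, pool, q=self.q, lam=self.lam,
                                max_outer=self.max_outer, tol=self.tol)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_l21lq(self.model_, X)


class RidgeEstimator:
    """Independent per-task ridge, closed normal-equations form (baseline)."""

    def __init__(self, lam: float = 1.0, q: float | None = None):
        self.lam = lam

    def fit(self, ds: MultitaskDataset) -> "RidgeEstimator":
        X, Y = ds.X, ds.Y
        A = X.T @ X + self.lam * np.eye(ds.p)
        self.theta_ = np.linalg.solve(A, X.T @ Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.theta_


class LassoEstimator:
    """Independent per-task lasso via coordinate descent (baseline).

    alpha = lam / m converts the (1/2)||.||^2 + lam ||.||_1 objective to
    the scikit-learn per-sample parameterization.
    """

    def __init__(self, lam: float = 1.0, q: float | None = None):
        self.lam = lam

    def fit(self, ds: MultitaskDataset) -> "LassoEstimator":
        m = ds.m
        self.models_ = []
        for t in range(ds.T):
            mdl = Lasso(alpha=self.lam / m, fit_intercept=False, max_iter=10000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mdl.fit(ds.X, ds.Y[:, t])
            self.models_.append(mdl)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.models_])


METHODS = {
    "lq1-mtl": LinearMTLEstimator,
    "mkmtl-lq1": MKMTLEstimator,
    "mkmtl-l21lq": L21LqEstimator,
    "ridge": RidgeEstimator,
    "lasso": LassoEstimator,
}

DEFAULT_Q = {"lq1-mtl": 2.0, "mkmtl-lq1": 3.0, "mkmtl-l21lq": 1.5}


def _make_estimator(method: str, params: dict, estimator_kwargs: dict):
    cls = METHODS[method]
    kwargs = dict(estimator_kwargs)
    kwargs.update({k: v for k, v in params.items() if v is not None})
    return cls(**kwargs)


def _fit_eval(method, params, estimator_kwargs, ds, train_idx, test_idx,
              scale_y):
    """Fit on train rows (z-scored there), return raw-scale predictions on
    the test rows together with the matching ground truth and mask."""
    ds_train = ds.subset(train_idx)
    ds_scaled, scaler = zscore(ds_train, scale_y=scale_y)
    est = _make_estimator(method, params, estimator_kwargs)
    est.fit(ds_scaled)
    X_test = scaler.transform_x(ds.X[test_idx])
    pred = scaler.inverse_transform_y(est.predict(X_test))
    return pred, ds.Y[test_idx], ds.observed[test_idx]


def nested_cv(
    ds: MultitaskDataset,
    method: str,
    grid: TuningGrid | None = None,
    outer: int = 10,
    inner: int = 5,
    seed: int = 0,
    scale_y: bool = True,
    estimator_kwargs: dict | None = None,
) -> MetricsReport:
    """Nested cross-validation of one registered method.

    Inner folds select the grid point minimizing validation nMSE; the
    model is refit on the full outer-training fold and scored on the
    outer-test fold.  Deterministic given ``seed``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    grid = grid or TuningGrid()
    estimator_kwargs = estimator_kwargs or {}
    points = grid.points()
    if "q" not in (points[0] if points else {}) and method in DEFAULT_Q \
            and "q" not in estimator_kwargs:
        estimator_kwargs = {**estimator_kwargs, "q": DEFAULT_Q[method]}
    plan = make_folds(ds.m, outer=outer, inner=inner, seed=seed)
    T = ds.T
    fold_rmse = np.full((outer, T), np.nan)
    fold_cc = np.full((outer, T), np.nan)
    fold_nmse = np.full(outer, np.nan)
    fold_wr = np.full(outer, np.nan)
    selected, failed = [], []
    for k, (tr, te) in enumerate(plan.outer_folds):
        try:
            if len(points) == 1:
                best = points[0]
            else:
                scores = np.zeros(len(points))
                for itr, ite in plan.inner_folds_per_outer[k]:
                    for i, params in enumerate(points):
                        pred, y_true, mask = _fit_eval(
                            method, params, estimator_kwargs, ds, itr, ite, scale_y)
                        scores[i] += nmse(y_true, pred, mask)
                best = points[int(np.argmin(scores))]
            pred, y_true, mask = _fit_eval(
                method, best, estimator_kwargs, ds, tr, te, scale_y)
            fold_rmse[k] = rmse_per_task(y_true, pred, mask)
            fold_cc[k] = [
                float(np.corrcoef(y_true[mask[:, t], t], pred[mask[:, t], t])[0, 1])
                for t in range(T)
            ]
            fold_nmse[k] = nmse(y_true, pred, mask)
            fold_wr[k] = weighted_r(y_true, pred, mask)
            selected.append(best)
        except Exception as exc:   # noqa: BLE001 - fold-level containment
            warnings.warn(f"outer fold {k} failed for {method}: {exc}")
            failed.append(k)
            selected.append({})
            if len(failed) > 2:
                raise RuntimeError(
                    f"method {method!r} failed on {len(failed)} folds; aborting"
                ) from exc
    return MetricsReport(method=method, task_names=list(ds.task_names),
                         fold_rmse=fold_rmse, fold_cc=fold_cc,
                         fold_nmse=fold_nmse, fold_wr=fold_wr,
                         selected_params=selected, failed_folds=failed)


def compare_methods(
    ds: MultitaskDataset,
    methods: Sequence[str],
    grid_map: dict[str, TuningGrid] | None = None,
    seed: int = 0,
    outer: int = 10,
    inner: int = 5,
    estimator_kwargs: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Run nested CV for each method and stack the one-row summaries."""
    grid_map = grid_map or {}
    estimator_kwargs = estimator_kwargs or {}
    frames = []
    for method in methods:
        rep = nested_cv(ds, method, grid=grid_map.get(method), seed=seed,
                        outer=outer, inner=inner,
                        estimator_kwargs=estimator_kwargs.get(method))
        frames.append(rep.to_frame())
    return pd.concat(frames, ignore_index=True)
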
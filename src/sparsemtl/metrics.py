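"""Evaluation metrics for multitask score prediction.

Per task: root mean squared error (rMSE) and Pearson correlation (CC).
Overall, pooled across tasks with per-task observation counts m_t:

    nMSE(Y, Yhat) = sum_t ||Y_t - Yhat_t||^2 / sigma(Y_t)  /  sum_t m_t
    wR(Y, Yhat)   = sum_t Corr(Y_t, Yhat_t) m_t            /  sum_t m_t

``sigma`` is the variance of the ground-truth scores by default (the
convention of the multitask literature these metrics come from); a flag
switches to the standard deviation since the notation is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["rmse_per_task", "nmse", "weighted_r", "MetricsReport"]


def _masked_columns(Y, Yhat, observed):
    Y = np.asarray(Y, float)
    Yhat = np.asarray(Yhat, float)
    if Y.ndim == 1:
        Y, Yhat = Y[:, None], Yhat[:, None]
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    if observed is None:
        observed = np.ones(Y.shape, dtype=bool)
    observed = np.asarray(observed, bool)
    for t in range(Y.shape[1]):
        rows = observed[:, t]
        yield t, Y[rows, t], Yhat[rows, t]


def rmse_per_task(Y, Yhat, observed_mask=None) -> np.ndarray:
    """Per-task sqrt(mean squared error) over observed entries; NaN for
    tasks with no observations."""
    T = np.atleast_2d(np.asarray(Y, float).T).shape[0] if np.asarray(Y).ndim == 1 else np.asarray(Y).shape[1]
    out = np.full(T, np.nan)
    for t, yt, yh in _masked_columns(Y, Yhat, observed_mask):
        if yt.size:
            out[t] = float(np.sqrt(np.mean((yt - yh) ** 2)))
    return out


def nmse(Y, Yhat, observed_mask=None, spread: str = "variance") -> float:
    """Pooled normalized MSE; residual sums scaled by the ground-truth
    spread of each task, divided by the total observation count."""
    if spread not in {"variance", "std"}:
        raise ValueError("spread must be 'variance' or 'std'")
    num = 0.0
    total = 0
    for t, yt, yh in _masked_columns(Y, Yhat, observed_mask):
        s = float(np.var(yt, ddof=1)) if yt.size > 1 else 0.0
        if s == 0.0:
            raise ValueError(f"task {t} has zero spread in the ground truth")
        if spread == "std":
            s = np.sqrt(s)
        num += float(np.sum((yt - yh) ** 2)) / s
        total += yt.size
    return num / total


def weighted_r(Y, Yhat, observed_mask=None) -> float:
    """m_t-weighted mean of per-task Pearson correlations."""
    num = 0.0
    total = 0
    for t, yt, yh in _masked_columns(Y, Yhat, observed_mask):
        if np.std(yh) == 0.0 or np.std(yt) == 0.0:
            raise ValueError(f"task {t} has zero spread; correlation undefined")
        r = float(np.corrcoef(yt, yh)[0, 1])
        num += r * yt.size
        total += yt.size
    return num / total


@dataclass
class MetricsReport:
    """Cross-validation results: one row per outer fold, plus aggregates."""

    method: str
    task_names: list[str]
    fold_rmse: np.ndarray            # folds x T
    fold_cc: np.ndarray              # folds x T
    fold_nmse: np.ndarray            # folds
    fold_wr: np.ndarray              # folds
    selected_params: list[dict] = field(default_factory=list)
    failed_folds: list[int] = field(default_factory=list)

    @property
    def nmse_mean(self) -> float:
        return float(np.nanmean(self.fold_nmse))

    @property
    def nmse_std(self) -> float:
        return float(np.nanstd(self.fold_nmse, ddof=1))

    @property
    def wr_mean(self) -> float:
        return float(np.nanmean(self.fold_wr))

    @property
    def wr_std(self) -> float:
        return float(np.nanstd(self.fold_wr, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """One row per method with per-task rMSE/CC and overall nMSE/wR
        (mean ± sd across outer folds), mirroring the standard report layout."""
        row: dict[str, float | str] = {"method": self.method}
        for i, name in enumerate(self.task_names):
            row[f"rmse_{name}_mean"] = float(np.nanmean(self.fold_rmse[:, i]))
            row[f"rmse_{name}_std"] = float(np.nanstd(self.fold_rmse[:, i], ddof=1))
            row[f"cc_{name}_mean"] = float(np.nanmean(self.fold_cc[:, i]))
            row[f"cc_{name}_std"] = float(np.nanstd(self.fold_cc[:, i], ddof=1))
        row["nmse_mean"] = self.nmse_mean
        row["nmse_std"] = self.nmse_std
        row["wr_mean"] = self.wr_mean
        row["wr_std"] = self.wr_std
        row["failed_folds"] = len(self.failed_folds)
        return pd.DataFrame([row])
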
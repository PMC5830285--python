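"""Domain containers, table IO, z-scoring and fold construction.

The central object is :class:`MultitaskDataset`: a feature matrix ``X``
(samples x features, e.g. FreeSurfer ROI morphometry) paired with a
multitask response matrix ``Y`` (samples x tasks, e.g. cognitive scores).
Tasks may be partially observed via a boolean mask, and features may be
partitioned into named modality blocks (MRI / PET / demographics) for
multimodal kernel pooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MultitaskDataset",
    "ParameterMatrix",
    "FoldPlan",
    "Scaler",
    "load_dataset",
    "zscore",
    "make_folds",
]


@dataclass
class MultitaskDataset:
    """Features ``X`` (m x p) and responses ``Y`` (m x T) for T joint tasks.

    Parameters
    ----------
    X, Y
        Numeric matrices with equal row counts, no non-finite entries.
    task_names, feature_names
        Column labels; generated if omitted.
    modality_blocks
        Optional mapping of block name -> feature column indices.  When
        present the blocks must partition ``range(p)`` exactly.
    observed
        Optional boolean mask (m x T); ``observed[i, t]`` marks whether
        sample i has a response for task t.  Defaults to all-observed.
    """

    X: np.ndarray
    Y: np.ndarray
    task_names: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    modality_blocks: dict[str, np.ndarray] | None = None
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"row mismatch: X has {self.X.shape[0]} rows, Y has {self.Y.shape[0]}"
            )
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("need at least one feature and one task")
        if not np.isfinite(self.X).all() or not np.isfinite(self.Y).all():
            raise ValueError("non-finite entries in X or Y")
        if not self.task_names:
            self.task_names = [f"task_{t}" for t in range(self.T)]
        if not self.feature_names:
            self.feature_names = [f"feat_{h}" for h in range(self.p)]
        if len(self.task_names) != self.T or len(self.feature_names) != self.p:
            raise ValueError("label lengths do not match matrix shapes")
        if self.observed is None:
            self.observed = np.ones((self.m, self.T), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (self.m, self.T):
                raise ValueError("observed mask shape must be (m, T)")
        if self.modality_blocks is not None:
            blocks = {k: np.asarray(v, dtype=int) for k, v in self.modality_blocks.items()}
            concat = np.concatenate([v for v in blocks.values()]) if blocks else np.array([], int)
            if sorted(concat.tolist()) != list(range(self.p)):
                raise ValueError("modality blocks must partition the feature indices exactly")
            self.modality_blocks = blocks

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def m_t(self) -> np.ndarray:
        """Per-task observation counts (column sums of the mask)."""
        return self.observed.sum(axis=0)

    def task_rows(self, t: int) -> np.ndarray:
        """Row indices observed for task ``t``."""
        return np.flatnonzero(self.observed[:, t])

    def is_complete(self) -> bool:
        return bool(self.observed.all())

    def subset(self, rows: Sequence[int]) -> "MultitaskDataset":
        rows = np.asarray(rows, dtype=int)
        return MultitaskDataset(
            X=self.X[rows],
            Y=self.Y[rows],
            task_names=list(self.task_names),
            feature_names=list(self.feature_names),
            modality_blocks=None if self.modality_blocks is None
            else {k: v.copy() for k, v in self.modality_blocks.items()},
            observed=self.observed[rows],
        )


@dataclass
class ParameterMatrix:
    """Task coefficient matrix Theta (p x T); rows are per-feature weight
    profiles across tasks, columns are per-task weight vectors."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be 2-D")
        if not np.isfinite(self.theta).all():
            raise ValueError("theta has non-finite entries")

    def row(self, h: int) -> np.ndarray:
        return self.theta[h, :]

    def col(self, t: int) -> np.ndarray:
        return self.theta[:, t]

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


@dataclass
class FoldPlan:
    """Outer CV folds with nested inner folds for hyperparameter tuning."""

    outer_folds: list[tuple[np.ndarray, np.ndarray]]
    inner_folds_per_outer: list[list[tuple[np.ndarray, np.ndarray]]]

    def __post_init__(self) -> None:
        m = sum(len(te) for _, te in self.outer_folds)
        all_test = np.sort(np.concatenate([te for _, te in self.outer_folds]))
        if not np.array_equal(all_test, np.arange(m)):
            raise ValueError("outer test sets must partition the sample indices")
        for tr, te in self.outer_folds:
            if np.intersect1d(tr, te).size:
                raise ValueError("train and test overlap in an outer fold")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, header=0)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = np.argwhere(num.isna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at row {r + 1}, column '{df.columns[c]}' "
            f"(value {df.iloc[r, c]!r})"
        )
    return num


def _load_modality_map(modality_map: str | Path | dict | None) -> dict | None:
    if modality_map is None or isinstance(modality_map, dict):
        return modality_map
    path = Path(modality_map)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_dataset(
    features_path: str | Path,
    targets_path: str | Path,
    modality_map: str | Path | dict | None = None,
) -> MultitaskDataset:
    """Load a feature table and a target table into a :class:`MultitaskDataset`.

    Both files are delimited text tables with a header row (CSV, or TSV by
    extension).  ``modality_map`` may be a YAML/JSON file or dict mapping
    block name -> list of feature column names.
    """
    feats = _read_table(features_path)
    targs = _read_table(targets_path)
    if len(feats) != len(targs):
        raise ValueError(
            f"row count mismatch: {len(feats)} feature rows vs {len(targs)} target rows"
        )
    blocks = None
    mmap = _load_modality_map(modality_map)
    if mmap is not None:
        name_to_idx = {name: i for i, name in enumerate(feats.columns)}
        blocks = {}
        for block, cols in mmap.items():
            missing = [c for c in cols if c not in name_to_idx]
            if missing:
                raise ValueError(f"modality block {block!r} names unknown columns {missing}")
            blocks[block] = np.array([name_to_idx[c] for c in cols], dtype=int)
    return MultitaskDataset(
        X=feats.to_numpy(float),
        Y=targs.to_numpy(float),
        task_names=list(map(str, targs.columns)),
        feature_names=list(map(str, feats.columns)),
        modality_blocks=blocks,
    )


@dataclass
class Scaler:
    """Column-standardisation record fitted on training rows only.

    Standard deviations use the sample (n-1) convention.  Zero-variance
    columns are dropped (they carry no signal and break standardisation);
    ``kept_x`` records the surviving feature columns.
    """

    mean_x: np.ndarray
    sd_x: np.ndarray
    kept_x: np.ndarray
    mean_y: np.ndarray | None = None
    sd_y: np.ndarray | None = None

    @property
    def scales_y(self) -> bool:
        return self.mean_y is not None

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept_x] - self.mean_x) / self.sd_x

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        if not self.scales_y:
            return Y
        return (Y - self.mean_y) / self.sd_y

    def inverse_transform_y(self, Y: np.ndarray) -> np.ndarray:
        if not self.scales_y:
            return Y
        return Y * self.sd_y + self.mean_y

    def to_json(self) -> str:
        d = {
            "mean_x": self.mean_x.tolist(),
            "sd_x": self.sd_x.tolist(),
            "kept_x": self.kept_x.tolist(),
            "mean_y": None if self.mean_y is None else self.mean_y.tolist(),
            "sd_y": None if self.sd_y is None else self.sd_y.tolist(),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        d = json.loads(text)
        return cls(
            mean_x=np.asarray(d["mean_x"], float),
            sd_x=np.asarray(d["sd_x"], float),
            kept_x=np.asarray(d["kept_x"], int),
            mean_y=None if d["mean_y"] is None else np.asarray(d["mean_y"], float),
            sd_y=None if d["sd_y"] is None else np.asarray(d["sd_y"], float),
        )


def zscore(
    ds: MultitaskDataset,
    fit_index: Sequence[int] | None = None,
    scale_y: bool = False,
) -> tuple[MultitaskDataset, Scaler]:
    """Standardise columns to zero mean / unit sd using ``fit_index`` rows.

    All rows of ``ds`` are transformed with statistics computed on
    ``fit_index`` only, so held-out rows never leak into the scaling.
    Zero-variance columns (on the fit rows) are dropped with a warning.
    """
    fit_index = np.arange(ds.m) if fit_index is None else np.asarray(fit_index, int)
    if fit_index.size == 0:
        raise ValueError("fit_index must be nonempty")
    Xf = ds.X[fit_index]
    mean_x = Xf.mean(axis=0)
    sd_x = Xf.std(axis=0, ddof=1) if len(fit_index) > 1 else np.zeros(ds.p)
    kept = np.flatnonzero(sd_x > 0)
    if kept.size < ds.p:
        dropped = [ds.feature_names[i] for i in np.flatnonzero(sd_x == 0)]
        warnings.warn(f"dropping zero-variance feature columns: {dropped}")
    if kept.size == 0:
        raise ValueError("all feature columns have zero variance on the fit rows")
    mean_y = sd_y = None
    if scale_y:
        Yf = ds.Y[fit_index]
        mean_y = Yf.mean(axis=0)
        sd_y = Yf.std(axis=0, ddof=1) if len(fit_index) > 1 else np.ones(ds.T)
        if np.any(sd_y == 0):
            raise ValueError("zero-variance response column; cannot z-score Y")
    scaler = Scaler(mean_x=mean_x[kept], sd_x=sd_x[kept], kept_x=kept,
                    mean_y=mean_y, sd_y=sd_y)
    blocks = None
    if ds.modality_blocks is not None:
        pos = {old: new for new, old in enumerate(kept)}
        blocks = {
            k: np.array([pos[i] for i in v if i in pos], dtype=int)
            for k, v in ds.modality_blocks.items()
        }
        blocks = {k: v for k, v in blocks.items() if v.size}
    out = MultitaskDataset(
        X=scaler.transform_x(ds.X),
        Y=scaler.transform_y(ds.Y),
        task_names=list(ds.task_names),
        feature_names=[ds.feature_names[i] for i in kept],
        modality_blocks=blocks,
        observed=ds.observed.copy(),
    )
    return out, scaler


def make_folds(m: int, outer: int = 10, inner: int = 5, seed: int = 0) -> FoldPlan:
    """Random (unstratified) nested fold plan: ``outer`` outer folds, each
    training part further split into ``inner`` folds for tuning."""
    if outer < 2 or m < outer:
        raise ValueError(f"need m >= outer >= 2, got m={m}, outer={outer}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    test_sets = np.array_split(perm, outer)
    outer_folds = []
    inner_per_outer = []
    for k, te in enumerate(test_sets):
        tr = np.setdiff1d(perm, te, assume_unique=True)
        tr = rng.permutation(tr)
        outer_folds.append((np.sort(tr), np.sort(te)))
        n_inner = min(inner, len(tr))
        inner_tests = np.array_split(tr, n_inner)
        inner_folds = [
            (np.sort(np.setdiff1d(tr, ite, assume_unique=True)), np.sort(ite))
            for ite in inner_tests
        ]
        inner_per_outer.append(inner_folds)
    return FoldPlan(outer_folds=outer_folds, inner_folds_per_outer=inner_per_outer)
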
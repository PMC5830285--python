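"""Base-kernel pool construction and unit-trace Gram normalization.

The default pool follows the standard candidate set for this kind of
study: six Gaussian kernels with bandwidths 2^-2 .. 2^3, inhomogeneous
polynomial kernels of degrees 1-3, and a linear kernel — ten kernels in
total.  With modality blocks (MRI / PET / demographics) the same ten
kernels are built per block, each restricted to that block's columns.

Conventions (results depend on them, so they are fixed and documented):

* gaussian:    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)), sigma = bandwidth
* polynomial:  k(x, x') = (x^T x' + 1)^d   (so degree 1 differs from linear)
* linear:      k(x, x') = x^T x'

Training Gram matrices are normalized to unit trace; cross-kernel blocks
for prediction are divided by the same training trace so that train and
test embeddings stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import MultitaskDataset

__all__ = ["KernelSpec", "KernelPool", "gram_matrix", "unit_trace_normalize",
           "build_pool", "default_specs"]

_FAMILIES = {"gaussian", "polynomial", "linear"}


@dataclass(frozen=True)
class KernelSpec:
    """One base kernel: family plus its parameter (bandwidth or degree)."""

    family: str
    param: float | int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian" and (self.param is None or self.param <= 0):
            raise ValueError("gaussian kernel needs a positive bandwidth")
        if self.family == "polynomial" and self.param not in (1, 2, 3):
            raise ValueError("polynomial degree must be in {1, 2, 3}")

    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        if self.family == "gaussian":
            return f"gauss(sigma={self.param:g})"
        return f"poly(d={self.param})"


def gram_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kernel evaluations k(a_i, b_j) for all row pairs of A (n x p) and B (n' x p)."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"column mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.family == "linear":
        return A @ B.T
    if spec.family == "polynomial":
        return (A @ B.T + 1.0) ** int(spec.param)
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * float(spec.param) ** 2))


def unit_trace_normalize(K: np.ndarray) -> np.ndarray:
    """Divide a square Gram matrix by its trace (must be positive)."""
    K = np.asarray(K, float)
    tr = float(np.trace(K))
    if tr <= 0:
        raise ValueError(f"nonpositive trace {tr}; cannot normalize")
    return K / tr


def default_specs(
    bandwidths: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
    degrees: Sequence[int] = (1, 2, 3),
    include_linear: bool = True,
) -> list[KernelSpec]:
    specs = [KernelSpec("gaussian", b) for b in bandwidths]
    specs += [KernelSpec("polynomial", d) for d in degrees]
    if include_linear:
        specs.append(KernelSpec("linear"))
    return specs


@dataclass
class KernelPool:
    """Trained kernel collection: specs, unit-trace training Grams, and the
    training rows/columns needed to evaluate consistent cross-kernels."""

    specs: list[KernelSpec]
    gram_train: list[np.ndarray]
    traces: list[float]
    X_train: np.ndarray
    columns: list[np.ndarray]               # feature columns per kernel
    block: list[str | None] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.specs)

    @property
    def m(self) -> int:
        return self.X_train.shape[0]

    def gram_cross(self, X_new: np.ndarray) -> list[np.ndarray]:
        """Cross-kernel blocks [n_new x m], scaled by the training traces."""
        X_new = np.atleast_2d(np.asarray(X_new, float))
        return [
            gram_matrix(spec, X_new[:, cols], self.X_train[:, cols]) / tr
            for spec, cols, tr in zip(self.specs, self.columns, self.traces)
        ]

    def restrict(self, j: int, rows: np.ndarray, cols_rows: np.ndarray | None = None) -> np.ndarray:
        """Sub-block of training Gram j (used for per-task kernels)."""
        cols_rows = rows if cols_rows is None else cols_rows
        return self.gram_train[j][np.ix_(rows, cols_rows)]


def build_pool(
    data: MultitaskDataset | np.ndarray,
    bandwidths: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
    degrees: Sequence[int] = (1, 2, 3),
    include_linear: bool = True,
    per_modality: bool = False,
    psd_tol: float = 1e-8,
) -> KernelPool:
    """Build the training kernel pool on a (typically z-scored) dataset.

    With ``per_modality=True`` the dataset must carry modality blocks and
    each kernel is computed on one block's columns only, multiplying the
    pool size by the number of blocks.
    """
    if isinstance(data, MultitaskDataset):
        X = data.X
        blocks = data.modality_blocks
    else:
        X = np.asarray(data, float)
        blocks = None
    base = default_specs(bandwidths, degrees, include_linear)
    if per_modality:
        if not blocks:
            raise ValueError("per_modality=True requires modality blocks")
        for name, cols in blocks.items():
            if len(cols) == 0:
                raise ValueError(f"modality block {name!r} is empty")
        items = [(spec, cols, name) for name, cols in blocks.items() for spec in base]
    else:
        items = [(spec, np.arange(X.shape[1]), None) for spec in base]

    specs, grams, traces, columns, block_names = [], [], [], [], []
    for spec, cols, name in items:
        K = gram_matrix(spec, X[:, cols], X[:, cols])
        if np.max(np.abs(K - K.T)) > 1e-10 * max(1.0, np.max(np.abs(K))):
            raise ValueError(f"asymmetric Gram for {spec.label()}")
        K = 0.5 * (K + K.T)
        tr = float(np.trace(K))
        if tr <= 0:
            raise ValueError(f"nonpositive trace for {spec.label()}")
        Kn = K / tr
        lo = np.linalg.eigvalsh(Kn)[0]
        if lo < -psd_tol * max(1.0, np.abs(Kn).max()):
            raise ValueError(f"Gram for {spec.label()} is not PSD (min eig {lo:.3g})")
        specs.append(spec)
        grams.append(Kn)
        traces.append(tr)
        columns.append(np.asarray(cols, int))
        block_names.append(name)
    return KernelPool(specs=specs, gram_train=grams, traces=traces,
                      X_train=X.copy(), columns=columns, block=block_names)
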
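"""Synthetic multitask datasets with the structure the solvers assume.

Three generators:

* ``gen_linear`` — row-sparse shared-support linear model: X standard
  normal, Theta with s nonzero rows shared across tasks (entries uniform
  ±[0.5, 1.5]), Y = X Theta + Gaussian noise.  This is the regime the
  ℓq,1 regularizer targets.
* ``gen_kernel_nonlinear`` — responses drawn in the RKHS of a source
  kernel (f_t = K c_t with sparse shared-support coefficient vectors), so
  a kernel method using the source kernel can fit what a linear model
  cannot.
* ``gen_multimodal`` — features split into named blocks, each block
  carrying an independent share of the signal, emulating MRI / PET /
  demographic fusion where no single modality suffices.

All generators are deterministic given the seed.  ``snr`` (signal
variance over noise variance) may be given instead of ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MultitaskDataset, ParameterMatrix
from .kernels import KernelSpec, gram_matrix

__all__ = ["SyntheticSpec", "gen_linear", "gen_kernel_nonlinear",
           "gen_multimodal", "gen_linear_plus_kernel"]

# E[U^2] for U uniform on ±[0.5, 1.5]; fixes the implied signal variance
# of one active row: var(signal per task) = s * _COEF_VAR.
_COEF_VAR = (1.5 ** 3 - 0.5 ** 3) / 3.0     # = 13/12


@dataclass
class SyntheticSpec:
    """Generator configuration (sample size, dimensionality, sparsity,
    noise level or SNR, generation mode, seed)."""

    m: int = 200
    p: int = 50
    T: int = 5
    s: int = 5
    noise_sd: float = 1.0
    snr: float | None = None
    mode: str = "linear"
    kernel_source: KernelSpec | None = None
    block_sizes: list[int] | None = None
    support_overlap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s > self.p or self.s < 0:
            raise ValueError("need 0 <= s <= p")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in {"linear", "kernel-nonlinear", "multimodal"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.block_sizes is not None and sum(self.block_sizes) != self.p:
            raise ValueError("block_sizes must sum to p")
        if not (0.0 <= self.support_overlap <= 1.0):
            raise ValueError("support_overlap must lie in [0, 1]")


def _noise_sd(spec: SyntheticSpec, signal_var: float) -> float:
    if spec.snr is None:
        return spec.noise_sd
    if spec.snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.sqrt(signal_var / spec.snr))


def _sparse_theta(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Row-sparse Theta with (optionally partially) shared support."""
    theta = np.zeros((spec.p, spec.T))
    if spec.s == 0:
        return theta
    shared_n = int(round(spec.support_overlap * spec.s))
    shared = rng.choice(spec.p, size=shared_n, replace=False)
    for t in range(spec.T):
        extra_pool = np.setdiff1d(np.arange(spec.p), shared)
        extra = rng.choice(extra_pool, size=spec.s - shared_n, replace=False)
        rows = np.concatenate([shared, extra]).astype(int)
        vals = rng.uniform(0.5, 1.5, size=spec.s) * rng.choice([-1.0, 1.0], size=spec.s)
        theta[rows, t] = vals
    return theta


def gen_linear(spec: SyntheticSpec) -> tuple[MultitaskDataset, ParameterMatrix]:
    """Row-sparse linear multitask data; returns the dataset and true Theta."""
    if spec.mode != "linear":
        raise ValueError("spec.mode must be 'linear'")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.m, spec.p))
    theta = _sparse_theta(rng, spec)
    signal_var = spec.s * _COEF_VAR
    sd = _noise_sd(spec, signal_var) if spec.s else spec.noise_sd
    Y = X @ theta + sd * rng.standard_normal((spec.m, spec.T))
    return MultitaskDataset(X=X, Y=Y), ParameterMatrix(theta)


def gen_kernel_nonlinear(spec: SyntheticSpec) -> tuple[MultitaskDataset, dict]:
    """Kernel-generated responses f_t = K c_t with sparse shared support.

    Returns the dataset and a truth record (coefficients, support rows,
    the source kernel spec and noise level).
    """
    if spec.mode != "kernel-nonlinear":
        raise ValueError("spec.mode must be 'kernel-nonlinear'")
    if spec.kernel_source is None:
        raise ValueError("kernel-nonlinear mode requires kernel_source")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.m, spec.p))
    K = gram_matrix(spec.kernel_source, X, X)
    support = rng.choice(spec.m, size=min(spec.s if spec.s else 10, spec.m),
                         replace=False)
    C = np.zeros((spec.m, spec.T))
    C[support] = rng.standard_normal((len(support), spec.T))
    F = K @ C
    # rescale per task to unit signal variance, then apply noise_sd / snr
    F = F / np.maximum(F.std(axis=0, ddof=0), 1e-12)
    sd = _noise_sd(spec, 1.0)
    Y = F + sd * rng.standard_normal((spec.m, spec.T))
    ds = MultitaskDataset(X=X, Y=Y)
    return ds, {"coef": C, "support": support, "kernel": spec.kernel_source,
                "noise_sd": sd, "signal": F}


def gen_multimodal(spec: SyntheticSpec) -> tuple[MultitaskDataset, dict]:
    """Multimodal data: each feature block carries an independent signal
    component, so dropping any informative block loses predictive power."""
    if spec.mode != "multimodal":
        raise ValueError("spec.mode must be 'multimodal'")
    if not spec.block_sizes or len(spec.block_sizes) < 2:
        raise ValueError("multimodal mode requires >= 2 block_sizes")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.m, spec.p))
    starts = np.cumsum([0] + list(spec.block_sizes))
    blocks = {
        f"block_{b}": np.arange(starts[b], starts[b + 1])
        for b in range(len(spec.block_sizes))
    }
    theta = np.zeros((spec.p, spec.T))
    s_per_block = max(1, spec.s)
    for cols in blocks.values():
        rows = rng.choice(cols, size=min(s_per_block, len(cols)), replace=False)
        vals = rng.uniform(0.5, 1.5, size=(len(rows), spec.T)) \
            * rng.choice([-1.0, 1.0], size=(len(rows), spec.T))
        theta[rows] = vals
    signal_var = float(np.sum(theta ** 2, axis=0).mean())
    sd = _noise_sd(spec, signal_var)
    Y = X @ theta + sd * rng.standard_normal((spec.m, spec.T))
    ds = MultitaskDataset(X=X, Y=Y, modality_blocks=blocks)
    return ds, {"theta": theta, "noise_sd": sd, "blocks": blocks}


def gen_linear_plus_kernel(
    spec: SyntheticSpec,
    mix: float = 0.5,
    kernel_source: KernelSpec | None = None,
    n_centers: int = 10,
) -> tuple[MultitaskDataset, dict]:
    """Shared-support signal with a linear and a kernel-smooth component.

    The response is sqrt(1-mix) * L + sqrt(mix) * F + noise, where L is a
    row-sparse linear signal (as in :func:`gen_linear`) and F lives in the
    RKHS of ``kernel_source`` with ``n_centers`` shared support centers;
    both components are standardised to unit variance per task.  This is
    the structure the sparse linear and multikernel solvers respectively
    assume, with neither component alone sufficient - mirroring data where
    scores depend on a few features both linearly and smoothly.
    """
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    kernel_source = kernel_source or KernelSpec("gaussian", 8.0)
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.m, spec.p))
    rows = rng.choice(spec.p, size=spec.s, replace=False)
    theta = np.zeros((spec.p, spec.T))
    theta[rows] = rng.uniform(0.5, 1.5, (spec.s, spec.T)) \
        * rng.choice([-1.0, 1.0], (spec.s, spec.T))
    L = X @ theta
    L = L / np.maximum(L.std(axis=0), 1e-12)
    K = gram_matrix(kernel_source, X, X)
    centers = rng.choice(spec.m, size=min(n_centers, spec.m), replace=False)
    C = np.zeros((spec.m, spec.T))
    C[centers] = rng.standard_normal((len(centers), spec.T))
    F = K @ C
    F = F / np.maximum(F.std(axis=0), 1e-12)
    signal = np.sqrt(1.0 - mix) * L + np.sqrt(mix) * F
    sd = _noise_sd(spec, 1.0)
    Y = signal + sd * rng.standard_normal((spec.m, spec.T))
    ds = MultitaskDataset(X=X, Y=Y)
    return ds, {"theta": theta, "support": rows, "centers": centers,
                "kernel": kernel_source, "noise_sd": sd}
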
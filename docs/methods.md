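# Methods

This note records the models implemented in `sparsemtl`, the numerical
choices behind the solvers, what the synthetic data emulates, and the known
limitations.  Notation: `m` samples, `p` features, `T` tasks, `Θ ∈ ℝ^{p×T}`
with rows `θ_h·` (feature h across tasks) and columns `θ_·t` (task t).

## 1. The ℓq,1 linear solver

**Model.**  `min_Θ ½‖Y − XΘ‖²_F + λ Σ_h ‖θ_h·‖_q` with `q ≥ 1`.  `q = 1`
decouples into independent lasso problems; `q = 2` is the classic
group-row penalty; larger q pushes the within-row profile toward
uniformity, `q = ∞` penalizing only each row's largest entry.

**Proximal operator.**  The penalty's proximal map decouples over rows into
`argmin_θ ½‖θ − v‖² + λ‖θ‖_q`.  The solution is zero exactly when
`‖v‖_q̄ ≤ λ` with `q̄ = q/(q−1)` (dual exponent).  Closed forms:
soft-thresholding (q = 1), radial shrinkage `(‖v‖₂ − λ)/‖v‖₂ · v` (q = 2),
and `sign(v) ⊙ min(|v|, u*)` for q = ∞ where `u*` solves
`Σ_t max(|v_t| − u, 0) = λ`; that root is found exactly by scanning the
piecewise-linear segments of the sorted |v| (no bisection).  For other
`q ∈ (1, ∞)` the optimality system is `θ_i + c θ_i^{q−1} = |v_i|` on the
sign orthant with `c = λ‖θ‖_q^{1−q}`; we bisect on `c` (the map
`c ↦ c‖θ(c)‖_q^{q−1}` runs from 0 to `‖v‖_q̄` and crosses λ exactly once,
because the prox is unique), with an inner Brent root per component.
Tolerances: outer `root_tol = 1e−10` (relative), `max_bisect = 200`, inner
Brent at machine precision.  At the threshold boundary both branches give
the zero vector.

**Accelerated scheme.**  Momentum uses the standard sequence
`t_l = (1 + √(1+4t_{l−1}²))/2`, `β = (t_{l−1}−1)/t_l`; the step constant L
is found by doubling until the quadratic upper model majorizes the loss at
the prox point, and may shrink by ×0.9 between iterations.  We use the
*monotone* accelerated variant: the prox point drives the momentum
sequence, but the reported iterate keeps the better of {prox point,
previous iterate}, so the objective trace is non-increasing by
construction.  Plain acceleration can overshoot, and a monotone trace is
both a solver invariant we assert in every test run and a practical
debugging aid.  Convergence is declared when both the accepted-objective
change and the raw prox-sequence change fall below `tol` (default 1e−8)
relatively; requiring both avoids mistaking a rejected step for
convergence.  Θ starts at zero; the solver is fully deterministic.  The
solver requires a completely observed Y (the Frobenius loss is stated for
complete response matrices); partially observed tasks are the kernel
solvers' domain.

## 2. Kernel pool

Default pool: Gaussian kernels with bandwidths `2^−2 … 2^3`, inhomogeneous
polynomial kernels of degrees 1–3, and a linear kernel — 10 base kernels.
Two conventions matter and are fixed here:

* the Gaussian bandwidth enters as `k(x,x′) = exp(−‖x−x′‖²/(2σ²))` with σ
  the listed bandwidth (σ², or 1/(2σ²), would be defensible alternatives;
  results depend on the choice, so it is stated prominently);
* the polynomial kernel is `(xᵀx′ + 1)^d`, so degree 1 is affine and
  distinct from the linear kernel, keeping 10 distinct pool members.

Training Grams are normalized to unit trace; cross-kernel blocks for
prediction divide by the *training* trace so train/test embeddings agree.
With modality blocks (e.g. MRI / PET / demographics) the same pool is built
per block on that block's columns only, multiplying the pool size.

Note on scale: for standardized p-dimensional features, pairwise squared
distances concentrate near 2p, so for p ≈ 40 only the widest kernels of the
canonical ladder are informative; the simulation studies therefore use the
wide end of the ladder (σ ∈ {4, 8}) plus polynomial and linear kernels.

## 3. ℓq,1 multikernel solver

Dual variables per task solve `α_t = −(Σ_j μ_j ν_jt K_tj + I/λ)^{−1} y_t`
(Cholesky, never an explicit inverse; 1e−10 jitter with a warning if the
factorization fails).  `μ ∈ Δ_k` weights kernels; `ν_j ∈ Δ_{T,q̄}` with
`q̄ = q/(q−2)` couples tasks within kernel j.  That exponent is a valid
norm conjugate only for q > 2, so the solver admits `q ∈ (2, ∞)`, with
q → ∞ giving q̄ → 1 and q = 2 implemented as the degenerate limit ν ≡ 1
(uniform coupling).  Updates are the attainment conditions of the two
variational bounds:

* `ν_jt ∝ a_jt^{1/(q̄−1)}` normalized so `Σ_t ν_jt^q̄ = 1`, with
  `a_jt = α_tᵀ(μ_j K_tj)α_t`; an all-zero gain row falls back to the
  uniform boundary point.  For q̄ = 1 the maximizer is a vertex (mass on
  the argmax, ties split).
* `μ_j ∝ √b_j` with `b_j = Σ_t ν_jt α_tᵀ K_tj α_t` — the r = 1 closed form
  of the simplex lemma (`lemma1_minimizer`): over
  `Δ_{d,r} = {η ≥ 0, Σ η^r ≤ 1}`, `min Σ a_i/η_i` is attained at
  `η_i = a_i^{1/(r+1)} / (Σ a^{r/(r+1)})^{1/r}` with value
  `(Σ a^{r/(r+1)})^{(r+1)/r}` and the convention η_i = 0 where a_i = 0.

A generic mirror-descent path for μ exists in the literature for this
family of problems; since the μ-subproblem has the closed form above we use
it (deterministic, no step size), and keep an entropic mirror-descent
update behind `mu_update="mirror"` (with step/√l decay) as a fidelity
cross-check — the tests verify both paths select the same dominant kernel
and reach comparable objectives.

**Objective trace.**  The saddle value of the min–max formulation is not
guaranteed monotone under block alternation, so the recorded trace is the
*primal* objective `½(Σ_j (Σ_t ‖θ̃_tj‖₂^q)^{1/q})² + ‖α‖²/(2λ)`, evaluated
kernelized via `‖θ̃_tj‖₂² = μ_j² ν_jt² α_tᵀK_tjα_t` (the primal point is
feasible after every α-solve because ξ = α/λ satisfies the constraints).
Three consecutive increases trigger a convergence warning with the trace
attached; in practice the trace decreases.  Stopping: relative change
below `tol` (default 1e−7) or `max_outer`.

Predictions: `f_t(x) = −Σ_j μ_j ν_jt Σ_i α_ti k_j(x_ti, x)`; the sign
convention is pinned by the exact kernel-ridge reduction (single kernel,
single task), which the tests verify to 1e−8.

## 4. ℓ2,1-ℓq multikernel solver

Task coupling is learned in feature space: each kernel carries a symmetric
PSD matrix `Q_j` constrained by `Q_j ⪰ 0`, `Σ_j tr(Q_j)^q̄ ≤ 1` with
`q̄ = q/(2−q)`, `q ∈ [1, 2)` (q = 2 would give q̄ = ∞, a max-of-traces
constraint, and is excluded).  Orthogonal feature transforms and explicit
feature maps are eliminated: with the eigendecomposition
`G_j = V_j Σ_j² V_jᵀ` of the pooled unit-trace Gram, the maps
`M_tj = Σ_j^{−1} V_jᵀ G_j[:, rows_t]` satisfy `M_tjᵀM_t′j = G_j[rows_t,
rows_t′]`, so everything runs on Gram matrices.  Eigenvalues below
`rank_tol` (default 1e−10) times the largest are truncated to keep
`Σ_j^{−1}` well-conditioned.

The outer problem `min_Q f(Q)` with
`f = Σ_t [−α_tᵀy_t − ½α_tᵀ(Σ_j M_tjᵀQ_jM_tj)α_t − α_tᵀα_t/(2λ)]` at the
optimal α has subgradient blocks `−½B_j`, `B_j = Σ_t M_tjα_tα_tᵀM_tjᵀ`
(envelope theorem: α fixed at its optimum).  We run projected subgradient
— a Euclidean mirror-descent instance chosen because the projection has a
closed form here (an entropic/matrix-exponentiated variant would be the
other natural instance): step `η_l = step0/√l`, with `step0` picked by a
3-point probe on the first gradient when not given; Euclidean projection =
PSD eigenvalue clip followed by the closed-form trace rescale
`c = (Σ tr^q̄)^{−1/q̄}`; best-iterate tracking (the returned Q has the
lowest f seen, so the best-iterate curve is non-increasing by
construction).  Q is initialized block-diagonal uniform on the constraint
boundary.  Because a descent step *adds* a PSD matrix (`−η·(−½B_j)`), the
eigenvalue clip is a no-op along the trajectory; the projection certifies
this cheaply with a shifted Cholesky and only eigendecomposes when the
certificate fails.  Feasibility (PSD blocks, trace budget) is asserted
after every iteration.  When all tasks observe all samples the per-task
system matrices coincide and are assembled and factorized once per
evaluation.

Stopping: `max_outer` (default 200) or when the best objective improves by
less than `tol` relatively over a 10-iteration window — subgradient
methods do not descend monotonically, so a windowed criterion on the best
iterate is the stable choice.

## 5. Evaluation protocol and metrics

Nested cross-validation: 10 outer folds, 5 inner folds (unstratified
uniform random assignment; deterministic given the seed).  The inner loop
selects the grid point with the lowest summed validation nMSE; the model
is refit on the full outer-training fold; metrics are computed on the
outer-test fold and aggregated mean ± sd.  Z-scoring (sample n−1
standard deviations; zero-variance columns dropped with a warning) is fit
inside each training fold only — the tests verify held-out columns are
*not* centered, i.e. no leakage.  By default the harness also standardizes
Y on the training fold and inverse-transforms predictions, so metrics are
on the original response scale; the solvers have no intercepts, so
centering the responses is what makes unregularized ridge/lasso baselines
and the kernel methods comparable.  A failing fold is recorded and the
run aborts after more than two failures.

`nMSE` divides each task's residual sum of squares by `σ(Y_t)`, which this
package takes as the *variance* of the ground-truth test scores (the
convention of the multitask literature this metric family comes from; the
symbol is ambiguous between sd and variance, so `spread="std"` switches).
`wR` is the m_t-weighted mean Pearson correlation; zero-spread predictions
raise rather than being silently dropped.  Hyperparameter grids default to
the decade ladder `λ ∈ {10^{−1}, …, 10^3}`; for kernel solvers on
unit-trace Grams the effective ridge is `trace/λ`-scaled, so the studies
use `λ ∈ {10², 10³, 10⁴}`.  Whether q should be tuned per dataset or fixed
per method is open; the defaults fix q = 2 (linear), 3 (ℓq,1-MKMTL), 1.5
(ℓ2,1-ℓq) and the grid accepts q lists.

## 6. Synthetic data: what it emulates, and what it does not

* `gen_linear`: X i.i.d. standard normal; s active rows *shared across
  tasks* (the regime row-sparsity targets; `support_overlap < 1` relaxes
  it), coefficients uniform ±[0.5, 1.5]; homoscedastic Gaussian noise, with
  `snr` derivable (signal variance s·13/12 per task).
* `gen_kernel_nonlinear`: responses `f_t = K c_t` in a source kernel's
  RKHS with sparse shared centers, standardized per task.
* `gen_linear_plus_kernel`: equal-variance sum of the two structures —
  used for the method-comparison study because it contains both the sparse
  linear signal the ℓq,1 solver exploits and the smooth nonlinear signal
  the kernel solvers exploit, which is precisely the premise under which
  the multitask methods are expected to dominate a per-task linear ridge.
* `gen_multimodal`: feature blocks each carrying an independent signal
  component, so no single modality suffices — the fusion premise.

Not emulated: correlated ROI covariance structure, heteroscedastic or
bounded score distributions, site effects, missingness mechanisms.
Passing simulation studies therefore demonstrate algorithmic correctness
and the qualitative regime (multitask + sparsity + nonlinearity helps),
not clinical effect sizes.

## 7. Simulation-study design (sizes chosen for a single core)

* Support recovery: m = 200, p = 50, T = 5, s = 5, SNR 10; 20 seeds; λ on
  a 9-point decade grid; success = top-5 row norms equal the planted
  support at some λ.
* Method comparison: m = 150, p = 40, T = 5, s = 5, SNR 5, half linear /
  half kernel-smooth signal (Gaussian source σ = 8 ≈ √(2p)); 20 seeds of
  full nested CV (10 × 5); kernel pool σ ∈ {4, 8} + poly{1,2} + linear;
  win = lower mean outer-test nMSE than per-task ridge tuned on
  `{10^{−1},…,10^3}`.
* Multimodal fusion: m = 300, two 20-feature blocks, SNR 5; per seed a
  2/3–1/3 train/test split with a validation quarter for λ; win = the
  all-blocks pool beats *every* single-block fit.

## 8. Known limitations

* The general-q projection costs an outer bisection × T Brent solves per
  row; fine for T ≤ tens of tasks, not tuned for very large T.
* The ℓq,1-MKMTL alternation has no global convergence proof here; the
  primal trace is monitored and warned on, not proven monotone.
* `q̄ = q/(q−2)` restricts the MKMTL solver to q > 2 (q = 2 as a
  degenerate uniform limit); the ℓ2,1-ℓq solver requires q ∈ [1, 2).
  The two solvers intentionally cover complementary ranges.
* Squared loss only; no intercepts (standardization is the supported
  route); no restart schemes or adaptive momentum.
* The ℓ2,1-ℓq factorization is O(m³) per kernel per fit; nested CV over
  large pools and grids multiplies this, which is why the studies use
  compact pools and short λ grids.
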
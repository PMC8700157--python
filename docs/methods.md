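# Methods

## Model and estimator

Data are N rows x_i ∈ R^p with class labels y_i ∈ {1..K}; each class is
modeled as zero-mean Gaussian with covariance Σ(k) and precision
Θ(k) = Σ(k)⁻¹. The estimator minimizes F(Θ) = f(Θ) + g(Θ) with

    f(Θ) = −Σ_k n_k { logdet Θ(k) − tr(S(k) Θ(k)) },
    g(Θ) = λ1 Σ_k Σ_{i≠j} |θ_{k,i,j}| + P(Θ),

where S(k) = (1/n_k) Σ_{y_i=k} x_iᵀx_i and P is the fused or group coupling.
Conventions implemented exactly as defined:

* the likelihood weights are the **raw counts n_k**, not n_k/N. Consequence:
  penalties live on the scale λ ≈ (per-sample strength) × n_k. A λ1 that is
  tiny relative to n_k leaves the problem effectively unpenalized;
* the fused coupling sums over **all** entries including the diagonal; the
  ℓ1 term and the group coupling are off-diagonal only;
* μ = 0 is assumed by the model. For real data the covariance builder
  column-centers per class by default (`center=False` reproduces the raw
  second-moment formula verbatim); the generator draws exactly zero-mean
  data, so its covariances use `center=False`. Whether the original
  experiments centered is unknowable from the text; both paths are tested;
* S, gradients and prox outputs are symmetrized as (A+Aᵀ)/2 to suppress
  floating-point drift — all theory assumes symmetric matrices.

## Proximal operators

prox_{ηg} separates over matrix cells; each cell is a K-vector problem.

**Fused family.** For cell (i, j) minimize
½Σ_k(θ_k−a_k)² + α Σ|θ_k| + β Σ_{k<l}|θ_k−θ_l| with α = ηλ1·1[i≠j],
β = ηλ2. Solved exactly in three steps: (1) the minimizer preserves the
ordering of a (exchange argument), so sorting a turns the complete-graph
coupling into a chain whose r-th gap carries weight β·r(K−r) (the number of
pairs straddling it); (2) the weighted-chain fused lasso is solved by an
exact forward–backward dynamic program that propagates the piecewise-linear
derivative of the partial objective, clipping it at ±w_r (every piece keeps
slope ≥ 1, so all clip points are unique); (3) the ℓ1 part is applied as a
final soft threshold — the prox of the ℓ1 norm composes with the fusion
prox. The composition identity and the ordering argument are verified
against an independent numeric convex solver in the tests rather than
assumed. K = 2 uses the closed form (pull both values toward their mean by
at most β) vectorized over all cells; K = 1 is a plain soft threshold. Ties
in a are broken by class index (stable sort); at |x| = λ exactly the soft
threshold returns 0.

**Group family.** Off-diagonal cells use the closed form
θ = S_{ηλ1}(a)·(1 − ηλ2/‖S_{ηλ1}(a)‖₂)₊, with the zero vector returned
directly when the norm is ≤ ηλ2 (no 0/0); diagonals pass through.

## Solvers

Both solvers start from Θ0 = diag(1/(s_{k,i,i} + λ1)) — cheap, positive
definite, scale-aware — and initialize each step with the Barzilai–Borwein
estimate ⟨ΔΘ,ΔΘ⟩/⟨ΔΘ,Δ∇f⟩ (fallback: previous accepted step; clipped to
[1e-8, 1e8]). Gradient blocks n_k(S(k) − Θ(k)⁻¹) reuse the Cholesky factors
computed for logdet; the positive-definiteness test *is* the Cholesky
attempt, and in backtracking it runs before the majorization check because
f needs the factorization anyway.

**ISTA** accepts the first η ∈ {η0, cη0, c²η0, …} whose prox output is PD
and satisfies f(Θ₊) ≤ Q_η(Θ₊, Θ). Defaults c = 0.5, η0 = 1.0,
max_backtracks = 50 are package choices. If backtracking is exhausted the
solver falls back to the theoretically safe step a_l²/n_m with a_l taken
from the smallest eigenvalue among the current iterate and Θ0 (the
Proposition-based constant is too conservative and typographically
ambiguous), flagged in the trace.

**M-ISTA** computes d_t = prox_{η_t g}(Θ_t − η_t∇f) − Θ_t,
β_t = ‖d_t‖²_F/η_t, λ_t = (Σ_k n_k tr(Θ(k)⁻¹d(k)Θ(k)⁻¹d(k)))^{1/2}, and
α_t = β_t/(λ_t(λ_t+β_t)). Two deliberate choices:

* λ_t defaults to the exact Hessian quadratic form above (what the
  self-concordant step-size analysis requires); the flattened variant
  Σ_k n_k‖Θ(k)⁻¹d(k)‖_F is available as `lambda_form="printed"`;
* when α_t > 1 the step size is halved, but the halving loop exits early if
  α does not decrease: since d scales with η, α grows like 1/η, so halving
  cannot terminate once λ_t < 1 (confirmed numerically). In that case the
  solver takes α_t = 1, which the analysis admits — α_t > 1 at the formula
  forces λ_t < 1, hence α_t λ_t < 1 (the iterate stays inside the PD cone)
  and the descent estimate −β + ω*(λ) remains strictly negative.

α_t λ_t < 1 at every accepted step, so positive definiteness needs no line
search; a Cholesky assertion runs in debug mode, and the factorization of
the next iterate (needed for its gradient) would raise on any violation.

**Stopping.** Relative error Σ_k‖ΔΘ(k)‖_F / max{Σ_k‖Θ(k)‖_F, 1} ≤ ε
(default, ε = 1e-5, cap 1000 iterations), or objective error
F(Θ_t) − F(Θ*) ≤ ε, with F(Θ*) obtained from a relative-error solve at
ε/100 — used only for convergence-rate analysis. Caveat: the relative-error
rule certifies iterate agreement, not distance to the optimum; with linear
rate γ the solution error is ≈ ε·γ/(1−γ)·‖Θ‖, so on ill-conditioned
problems (e.g. n ≈ p with near-zero penalty) an ε = 1e-6 solve can still sit
~1e-3 from the optimum. Solver-comparison experiments should therefore use
penalties on the per-sample scale, where the problem is well conditioned.

**Diagnostics.** A fixed-point residual
‖Θ − prox_{ηg}(Θ − η∇f)‖_F/(1+‖Θ‖_F) (zero exactly at solutions) is recorded
per iteration for free from the accepted direction. The boundedness report
evaluates the solution/iterate norm bounds under one documented reading of
the flattened constants — λ_c = (√K λ1 + λ2)², upper bound
Np/λ1 + Σ_k Σ_i 1/s_{k,i,i}, M = ‖Θ0‖_F + 2Np/λ1 + 2Σ 1/s,
m = e^{−C1/n_m} M^{1−Kp} — exponent and division placement in the source
being ambiguous, these are diagnostics only and never drive the solvers
(the monotonicity of the upper bound in λ1 pins the Np/λ1 reading); with a
zero covariance diagonal or λ1 = 0 they are reported unavailable.

**ADMM reference.** The Danaher-style splitting (per-class eigendecomposition
for the Θ-update, prox_{g/ρ} for the Z-update, ρ = N) is included purely as a
cross-check oracle for the proximal solvers; it shares the prox code, whose
own correctness is established against an independent convex solver.

## Cross-validation

V-fold (default V = 6) over an explicit (λ1, λ2) grid, scored by the
predictive negative log-likelihood Σ_v Σ_k n_k{tr(S_v(k)Θ̂(k)) − logdet Θ̂(k)}.
Folds are stratified within class (sizes differ by ≤ 1) so every class
appears in every training set; the weight n_k is the **test-fold** class
count (the printed formula reuses n_k without qualification); fold
covariances follow the main fit's centering convention; non-converged grid
points score +∞ instead of aborting; everything is deterministic given the
seed.

## Synthetic generator

Emulates sparse multi-class Gaussian problems: a shared support of
`n_shared` off-diagonal pairs (Erdős–Rényi-style uniform pairs, or a chain)
plus `n_extra` class-specific pairs per class; signed magnitudes uniform on
±[0.2, 0.8], with shared edges reusing the same value in every class (the
regime the fused penalty targets); positive definiteness by diagonal
dominance (diagonal = absolute off-diagonal row sum + 0.1) followed by the
congruence D^{-1/2}ΘD^{-1/2}, which sets unit diagonals while preserving
definiteness and support; samples drawn via the Cholesky factor of
Σ(k) = Θ(k)⁻¹. Defaults (p = 50, K = 2, n_k = 100, p edges per class, 80%
shared) state a moderately sparse, mostly-shared world. What it does *not*
emulate: heavy tails, missing data, hub/scale-free topology, or unequal
variable scales — a green recovery test says the method works on
well-behaved Gaussian data with unit-scale variables, nothing more.

TP/FP counts run over off-diagonal unordered pairs i < j per class (the
printed sums over all i, j would double-count edges and include the
diagonal); selection means |θ̂| > 1e-6, a guard for float dust since the
prox produces exact zeros. MSE = 2/(Kp(p−1)) Σ_k Σ_{i<j}(θ̂−θ)², the unique
reading of the flattened formula that makes it a mean. ROC sweeps fix λ2,
sweep λ1 from sparse to dense with warm starts, and normalize by the true
edge/non-edge totals with (0,0) and (1,1) appended.

## Known limitations

* No missing-data handling, shrinkage covariance estimators, per-edge
  penalty weights, or proximal-Newton solver.
* The general-K fused prox loops over cells in Python; K ∈ {1, 2} (the
  common cases) are fully vectorized.
* The printed-constant bound diagnostics depend on one documented reading of
  ambiguous source typography and should not be quoted as sharp.
* With raw-count likelihood weights, penalty values quoted on a per-sample
  scale elsewhere must be multiplied by n_k to have the same effect here.
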
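# Methods

## Model

Paired longitudinal counts (Y_i1t, Y_i2t), i = 1..m subjects, t = 1..T_i
consecutive times, with covariates z_it (entering both series) and x_it
(entering only series 1). Three levels:

1. **Subject effects.** U_i > 0 i.i.d. with E(U_i) = 1, Var(U_i) = σ².
   No distributional family is assumed; σ² is the only thing estimation
   uses. U_i scales both series, inducing the positive cross association
   Cov(Y_i1t, Y_i2t) = σ² μ_i1t μ_i2t.
2. **Serial effects.** Conditionally on U_i, each series j has positive
   effects V_ijt with E(V_ijt | U_i) = U_i and Cov(V_ijt, V_ijt′ | U_i) =
   τ_j² ρ_j(t, t′) U_i. We implement the AR(1) pattern ρ_j(t, t′) =
   ρ_j^|t−t′| and, for balanced panels, an unstructured pattern with full
   correlation matrices R_j.
3. **Responses.** Given all effects, counts are independent Poisson with
   means V_i1t exp(z_it′α + x_it′β) and V_i2t exp(z_it′α).

Unconditionally, with Y_i the 2T_i-vector ordered series-major (series 1
for t = 1..T_i, then series 2):

    E(Y_i)   = μ_i,   μ_i1t = exp(z′α + x′β),  μ_i2t = exp(z′α)
    Var(V_i) = σ² J + blockdiag(τ₁² R₁, τ₂² R₂)          (J = ones)
    Var(Y_i) = diag(μ_i) + diag(μ_i) Var(V_i) diag(μ_i)
    Cov(U_i, Y_i) = σ² μ_i′,   Cov(V_i, Y_i) = Var(V_i) diag(μ_i)

Var(Y_i) is positive definite whenever μ_i > 0 (diag(μ) adds a strictly
positive diagonal to a PSD matrix), so the per-subject Cholesky
factorization succeeds without jitter on valid parameters; a single retry
with jitter 1e-8·mean(diag) guards pathological float inputs, and a failure
after that raises an error naming the subject.

The total N_it is conditionally Poisson, hence random and possibly zero,
and conditionally on (N_it, W) the success count is binomial with
logit(p_it) = log(V_i1t/V_i2t) + x_it′β; `binomial_probability` evaluates
this and requires strictly positive effect inputs.

## Estimation

An iterative scheme, all pieces requiring only the moments above.

**Regression (Newton scoring).** The two Poisson models stack into one,
Y_ijt | W ~ Poisson(V_ijt exp(x_ijt′γ)) with x_i1t = (z_it′, x_it′)′,
x_i2t = (z_it′, 0′)′ and γ = (α′, β′)′. Replacing the random effects in the
joint score by their BLUPs gives the unbiased estimating function
ψ(γ) = Σ_i X_i′(y_i − V̂_i ∘ μ_i), solved by γ* = γ − S⁻¹(γ) ψ(γ) with
sensitivity S(γ) = −Σ_i X_i′ diag(μ_i) Var⁻¹(Y_i) diag(μ_i) X_i. The
asymptotic covariance of γ̂ is (−S)⁻¹; Wald p-values are two-sided normal.

**Random effects (orthodox BLUPs).** Û_i = 1 + Cov(U_i, Y_i) Var⁻¹(Y_i)
(y_i − μ_i), and likewise V̂_i. These minimize mean squared prediction
error among linear functions of y_i, are exactly 1 at zero residual or
zero variance components, and may be non-positive in extreme cells (they
are used as-is in ψ; only the induced binomial probability requires
positivity).

**Dispersion (bias-corrected moments).** BLUPs shrink toward 1, so naive
squared-BLUP moments are biased low. Each update adds the exact correction
that restores the population identity at the current parameter values:

    σ²  ← (1/m) Σ_i [(Û_i − 1)² + c_i],              c_i = σ² − σ⁴ μ′V⁻¹μ
    τ_j² ← (1/ΣT_i) Σ_{i,t} [(V̂_ijt − Û_i)² + d_ijt]
    ρ_j  ← adjusted Pearson ratio over lag-1 pairs with corrections b

where c_i = E(U−1)² − E(Û−1)², d_ijt = E(V−U)² − E(V̂−Û)² and
b_ij,(t,t′) = E(V_t−U)(V_t′−U) − E(V̂_t−Û)(V̂_t′−Û), each expanded through
Cov(·, Y) Var⁻¹(Y) Cov(Y, ·) quadratic forms. We verified these closed
forms symbolically and against dense-inverse oracles to 1e−8 in the tests.
Under AR(1) only the lag-1 correlation is estimated; under the unstructured
pattern the full matrix of adjusted Pearson estimates is formed,
symmetrized and given a unit diagonal (balanced panels only, since pairwise
(t, t′) estimates need replication across subjects).

**Iteration.** Starting values: γ₀ from a plain Poisson regression on the
stacked design (iterated Newton scoring with variance components at zero —
identical to Fisher scoring/IRLS); σ̂₀² = (1/m)Σ_i[mean of subject i's
counts − 1]²; τ̂_{j,0}² = (1/T)Σ_t[mean over subjects of Y_ijt − 1]²;
ρ̂_{j,0} = average per-subject lag-1 Pearson autocorrelation of the series-j
counts (zero-variance subjects skipped, fallback 0 — pooling across
subjects would confound between-subject variation). Each iteration then
updates γ by one Newton step, recomputes the BLUPs once, and feeds that
single prediction pass to the σ², τ² and ρ updates together — the order in
which the corrections above are exact identities. Iteration stops when the
sum of absolute parameter changes falls below the tolerance. Convergence
is linear (contraction factor roughly 0.94 on typical panels), so
tolerances below ~1e-8 buy little.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `tolerance` | 1e-6 | stop when Σ|Δparam| drops below this; within the customary 1e-4..1e-7 range for moment algorithms |
| `max_iter` | 500 | non-convergence returns `converged=False` with a warning, never an exception |
| `fix_variance_components` | None | pin σ², τ² (and ρ = 0); value 0 reduces the fit to a Poisson GLM on the stacked design |
| dispersion floors | 0 | moment updates can go negative in small samples; raw negatives are floored and logged |
| ρ clip | ±0.99 | keeps the AR(1) matrix well-conditioned |
| jitter | 1e-8·mean diag | single Cholesky retry |

## Synthetic data generator

The generator realizes exactly the moments the estimator assumes:

* U_i ~ Gamma(1/σ², σ²), or a lognormal matched to mean 1 and variance σ²
  (`subject_effect_family`), so robustness to the random-effect family can
  be probed at identical moment parameters;
* V_ijt | U_i: a stationary gamma AR(1) by beta-thinning,
  V_t = B_t V_{t−1} + G_t with B_t ~ Beta(kρ, k(1−ρ)),
  G_t ~ Gamma(k(1−ρ), τ²), k = U_i/τ², which preserves the
  Gamma(U_i/τ², τ²) marginal (conditional mean U_i, variance τ²U_i) and has
  exact lag-h autocorrelation ρ^h;
* counts: Poisson(V_ijt μ_ijt), vectorized across subjects.

Each series is then a gamma-mixed Poisson — negative-binomial-like — so the
panels are overdispersed and produce zero totals with positive probability.
Default conditions: σ² = 0.3, τ² = (0.5, 0.8), ρ = (0.4, 0.3), covariates
i.i.d. N(0, 1) scaled by 0.1, γ with intercepts and one slope per
predictor; at these values roughly a quarter of the cells have zero totals,
comparable to heavily zero-inflated applications.

What the simulator does **not** emulate: negative serial correlation (the
thinning construction cannot represent ρ < 0, so the simulator rejects it —
the estimator itself has no such restriction); heavy-tailed or multimodal
random effects beyond the two families provided; covariates correlated with
the random effects; missing or non-consecutive observation times. Passing
tests therefore demonstrate correctness of the moment computations and
estimating equations under the model's own assumptions, not robustness to
violations of them (except the random-effect family, which is varied
deliberately).

## Verification design

Every formula is checked against an independent path: moment matrices
against entrywise scalar assembly with dense inverses; BLUPs against
brute-force linear algebra (1e-10); the zero-variance reduction against
statsmodels' Poisson IRLS (1e-6); the corrections c, d, b against their
moment-identity expansions (1e-8); the simulator and the analytic moments
against each other by Monte Carlo (3 SE bands); and the full pipeline by
parameter recovery on 20 simulated panels per random-effect family
(m = 100, T = 30, regression bias within 3 Monte-Carlo SEs, variance
parameters within 15% relative bias), with estimating-equation
unbiasedness checked at the truth over 500 panels (m = 50, T = 10). The
recovery fits use tolerance 1e-4 (within the customary range above);
reported sizes keep the whole suite at desk scale.

## Limitations

* Unstructured correlation requires balanced panels and the estimated R_j
  is not projected to positive definiteness; with short panels prefer AR(1).
* No standard errors for σ², τ², ρ (moment estimators; would require
  fourth-moment assumptions).
* Time gaps within a subject are rejected rather than modelled; relabel or
  split subjects upstream if observation is intermittent.
* BLUPs can be non-positive for extreme cells; the induced binomial
  probability is then undefined and reported as missing.
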
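# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Model

Individual level: `y_ijk ~ π_Ind(θ_ijk)` with
`g(θ_ijk) = η_jk(x) = μ_j + xᵀ(β₁ + β₂ₖ) + γ_k`. Supported likelihood/link
pairs: Bernoulli with probit or logit, normal with identity, Poisson with
log. The reference treatment has `γ₁ = 0`, `β₂₁ = 0`; covariates declared
only prognostic have their β₂ entries fixed at zero.

Aggregate level: each AgD arm's summary is modelled through
`θ·_jk = ∫ g⁻¹{η_jk(x)} f_jk(x) dx`, approximated by the average of
`g⁻¹(η)` over a fixed QMC point set representing `f_jk`. For the mean of
continuous outcomes the aggregate likelihood is `N(θ·, se²)` (a reported
SD is converted to an SE internally); for summed counts it is Poisson
with rate `N · mean(exp η)`; for event counts it is the two-parameter
binomial approximation to the Poisson-binomial:

- `p̄ = mean Φ(η)`, `p̄₂ = mean Φ(η)²` over the grid,
- `N′ = N p̄²/p̄₂`, `p′ = p̄₂/p̄`,

which matches the Poisson-binomial mean `N p̄` and variance `N(p̄ − p̄₂)`
exactly and never exceeds the naive `Bin(N, p̄)` variance. The binomial
pmf with real-valued `N′` is defined through log-gamma functions; in the
(extreme-heterogeneity) corner case `y > N′` the continuous extension is
evaluated and a warning raised, since no discrete pmf extension is
canonical. Moments are clamped to `p̄ ∈ (ε, 1−ε)` and
`p̄² ≤ p̄₂ ≤ p̄` with `ε = 1e-12` before use.

The key identifying assumption is conditional constancy of relative
effects: individual-level `γ_k` are constant across populations given the
modelled effect modifiers. Within a treatment class, interactions may be
`shared` (one β₂ vector for the class — required here, as in most sparse
networks, to identify interactions for treatments observed in a single
AgD study), `exchangeable` (`β₂ₖ;ₗ ~ N(m_l, σ_l²)` with hyperpriors;
rejected for classes of fewer than two treatments, where σ is
unidentifiable), or `independent`.

Random study effects replace `γ_k` by `δ_jk ~ N(γ_k, τ²)` with pairwise
correlation 0.5 among the non-reference arms of a multi-arm study — the
algebraic consequence of a common heterogeneity variance. Sampling uses
the non-centred form `δ_j = γ + τ L z_j` with `L` the Cholesky factor of
the 0.5-correlation matrix.

## Integration grids

- Sobol' points are Owen-scrambled with a user seed. Scrambling both
  randomizes reproducibly and removes the unscrambled first point at the
  origin, which would map to −∞ under the inverse-normal transform.
  Ñ = 10 000 by default, configurable; grids are generated once and are
  bit-identical under the same seed and inputs.
- Marginal families: `normal`; `gamma` moment-matched in closed form
  (shape = (mean/sd)², rate = mean/sd²) for right-skewed covariates such
  as weight (kg) or disease duration (years); scaled `logitnormal` on a
  bounded support (default [0, 100], for percentage covariates such as
  body surface area), with parameters found by least squares on the
  observed-scale mean/SD via 96-node Gauss–Hermite quadrature (optimizer
  tolerance 1e-12; a fit worse than 1e-2 relative on either moment is an
  error); `bernoulli` for proportions.
- The correlation structure is estimated from the pooled IPD as Spearman
  rank correlations, study-specific matrices weighted by sample size.
  Spearman (rather than Pearson) is used because it transforms exactly to
  the Gaussian-copula parameter for continuous marginals,
  ρ = 2 sin(π ρ_s/6), and remains meaningful for skewed covariates.
- Binary covariates enter the copula as latent standard normals
  thresholded at the (1 − proportion) quantile. Applying the same sin
  transform to their rank correlations is an approximation (the exact
  binary–continuous relationship differs); it is accepted and documented
  rather than solved, matching usual practice.
- Elementwise-transformed correlation matrices can lose positive
  semi-definiteness; eigenvalues are clipped at 1e-8 and the matrix
  renormalized to unit diagonal before the Cholesky step.
- The copula step permutes only the uniforms, so a column's marginal
  distribution is untouched (verified by Kolmogorov–Smirnov in the
  tests).

## Inference

The joint log-density is implemented fully vectorized over parameter
rows and sampled with an affine-invariant ensemble MCMC (`emcee`),
which the environment provides and which needs no gradients; `chains`
independent ensembles (default 4) of ~2·ndim walkers play the role of
chains for split-R̂, ESS and MCSE (via `arviz`). Each ensemble starts in
a small ball around a posterior mode found by L-BFGS-B (numerical
gradients, scale parameters bounded away from zero). Iteration counts
are ensemble steps; the flattened post-warmup draws are thinned to
`draws_per_chain` for storage. Defaults are 4 chains × 1000 warmup +
1000 sampling steps.

Covariates are centred at the pooled IPD mean inside the likelihood:
without centring, `γ_k`/`β₂ₖ` (and `μ_j`/`β₁`) ride a long ridge — the
data identify the effect at the population's covariate values, while
`γ_k` lives at x = 0 — and the ensemble mixes over it far too slowly
from a compact initialization. Reported draws are translated back
exactly (`μ_j = μ_j^c − x̄ᵀβ₁`, `γ_k = γ_k^c − x̄ᵀβ₂ₖ`), so the centring
is invisible in the output. τ and the interaction coefficients are
unaffected by the translation.

Priors: `N(0, 100²)` on all location parameters (μ, β₁, β₂, γ, class
means m), half-normal(2.5) on τ, σ_β₂ and the normal-outcome σ — a
weakly informative default on the probit/SMD scale, configurable through
`Priors`. Convergence is flagged at R̂ > 1.01 (stricter than the classic
1.05; cheap at this scale). An interaction group supported by no IPD
study and fewer than two AgD studies triggers an identifiability
warning, mirroring the data requirements of aggregate meta-regression.

## Prediction

Population-average contrasts are linear in x, so integration over a
population equals plugging in its mean effect-modifier vector; this
identity is exploited (and tested to 1e-10 against explicit grid
averaging). Absolute outcomes are genuinely non-linear and are averaged
point by point over the population's grid or IPD rows, chunked over
draws to bound memory. Under a shared class the interaction difference
cancels as an array identity, so within-class contrasts are bitwise
identical in every population.

Point estimates are posterior means with equal-tailed 2.5/97.5%
credible intervals (the common Stan-style summary; the median would be
an equally defensible choice). External target populations may supply
the baseline `μ_(P)` as a fixed value or a normal (mean, sd) sampled per
posterior draw; in-network populations borrow the study's own μ_j draws.
Populations given only as marginal summaries are turned into grids with
the same machinery as AgD studies, reusing the IPD-borrowed copula.

## Model criticism

Residual deviance is the posterior mean (over up to 500 thinned draws)
of `2(loglik_saturated − loglik)` per datapoint; datapoints are
individual rows plus aggregate arms. For aggregate binomial arms the
saturated term plugs `y/N′` into the *same* per-draw adjusted size `N′`,
keeping model and saturated terms on one scale. Note the Bernoulli
expectation of this deviance is twice the outcome entropy — typically
well below one per row — so "about one per datapoint" holds only for the
aggregate arms. DIC uses `pD = D̄ − D̂` with `D̂` at the posterior mean of
the parameter vector.

Heterogeneity is assessed by comparing FE and RE fits (identical data
enforced by hashing) and the posterior of τ; with few studies τ is
weakly identified and its posterior should be read against the prior
scale. Inconsistency uses an unrelated-mean-effects refit: one free
relative effect per observed (study-baseline treatment, treatment) pair,
shared across studies with the same pair, with the interaction structure
kept from the consistency model; it is compared by DIC and per-datapoint
deviance differences. Node splitting is not implemented. The UME model
is fitted with fixed effects.

## Synthetic data

The generator emulates the structure of the psoriasis evidence base: six
treatments in two mechanism classes (one anti-TNFα agent; four IL-17A
doses), three IPD trials and one aggregate trial, five covariates — two
binary (previous systemic therapy ~0.65, psoriatic arthritis ~0.22/0.15),
duration (gamma, mean ~18 y), body surface area (scaled logit-normal,
mean ~27–34%), weight (gamma, mean 83–92 kg) — joined by a Gaussian
copula with modest rank correlations. True effects are probit-scale SMDs
of 1.67–2.82 with small interactions (|β₂| ≤ 0.25 per unit), and study
baselines are solved so the placebo response is ~6% at each study's mean
covariates. Sample sizes default to 200 per arm. The covariate law is
expressible by the integration module's families, so the fitted model
can be exactly well specified — passing recovery tests therefore
demonstrate correctness of the machinery, not robustness to the marginal
misspecification, missing data, dropout or non-compliance present in
real trials.

Test problem sizes are the package's own reduced choices: unit-test fits
use 100/arm with Ñ = 512 and 2 × 400 + 400 ensemble steps; replicated
recovery runs use the full 200/arm scenario with Ñ = 1024 and
2 × 2000 + 2000 steps, the length at which the fits meet the package's
own R̂ ≤ ~1.01 standard.

## Known limitations

- Survival and multinomial outcomes, missing-data imputation, node
  splitting, and comparison-specific heterogeneity variances are out of
  scope.
- Single-arm studies are accepted as data but excluded from fitting;
  incorporating them needs much stronger assumptions than randomized
  comparisons.
- The Gaussian copula with sin-transformed rank correlations is
  approximate for binary covariates; alternative copulas are not
  offered.
- Uncertainty in the target population's covariate distribution is not
  propagated; grids are treated as known.
- The ensemble sampler needs materially more iterations than a
  gradient-based sampler would for the same effective sample size; the
  vectorized likelihood keeps this affordable at the intended scale
  (a few thousand individuals, Ñ ≈ 10⁴).
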
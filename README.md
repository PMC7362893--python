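# mlnmr — multilevel network meta-regression

Population-adjusted indirect treatment comparisons from networks of
randomized trials in which some studies provide individual patient data
(IPD) and others only published aggregate data (AgD). The motivating use
case is health-technology appraisal: e.g. comparing biologics for plaque
psoriasis where a sponsor holds IPD for its own trials (UNCOVER-style)
but only arm-level summaries for competitor trials (FIXTURE-style), and a
decision must be made for a specific target population.

## The model

Every individual *i* in study *j* on treatment *k* follows a generalized
linear model

```
y_ijk ~ π_Ind(θ_ijk),    g(θ_ijk) = η_jk(x_ijk) = μ_j + xᵀ(β₁ + β₂ₖ) + γ_k
```

with study baselines μ_j, prognostic coefficients β₁, treatment-specific
effect-modifier interactions β₂ₖ and individual-level relative effects
γ_k versus the network reference (γ₁ = 0, β₂₁ = 0). Aggregate studies
contribute through the *integrated* version of the same model,

```
θ·_jk = ∫ g⁻¹{η_jk(x)} f_jk(x) dx ,
```

which avoids the aggregation bias incurred by plugging mean covariates
into a non-linear link. The integral is evaluated by quasi-Monte-Carlo:
a scrambled Sobol' point set is transformed to each AgD study's joint
covariate distribution — parametric marginals moment-matched to the
published summaries, joined by a Gaussian copula whose correlations are
borrowed from the pooled IPD on the Spearman rank scale — and held fixed
across all posterior iterations.

For binary outcomes the exact aggregate likelihood of an event count is
Poisson-binomial; it is approximated by a binomial with both parameters
adjusted to match its mean and variance:

```
y·_jk ~ Bin(N′, p′),   N′ = N p̄²/p̄₂,   p′ = p̄₂/p̄,
```

where p̄ and p̄₂ are the integrals of the event probability and its
square. Fixed- or random-study-effects structures are supported (random
effects are multivariate normal with pairwise correlation ½ in multi-arm
trials under a common heterogeneity variance τ²), as are shared or
exchangeable effect-modifier interactions within treatment classes. The
posterior is sampled with an affine-invariant ensemble MCMC; model fit is
assessed by residual deviance, DIC, the posterior of τ, and an
unrelated-mean-effects refit for inconsistency.

Fitted models yield population-average contrasts d_ab(P) and absolute
outcomes on any treatment in *any* target population P with covariate
information — in-network trial populations or external ones.

## Worked example

A synthetic six-treatment network shaped like the psoriasis evidence base
(three IPD trials, one aggregate trial, five correlated covariates, a
probit PASI-75-style response, shared interactions within the two drug
classes) ships with the package:

```python
from mlnmr import (ScenarioConfig, build_scenario_data, FitConfig, fit,
                   diagnostics, TargetPopulation, all_pairwise, full_report)

scenario = ScenarioConfig()                       # 3 IPD + 1 AgD trials, 6 treatments
network, grids, truth = build_scenario_data(scenario, seed=1,
                                            n_integration_points=2048)
spec = scenario.model_spec()                      # probit, shared EMs within class
draws = fit(network, spec, grids,
            FitConfig(chains=2, warmup=800, samples=800, seed=1))

print(diagnostics(draws)["rhat"].max())

pop = TargetPopulation.from_grid(grids["STUDY-4"], baseline=("study", "STUDY-4"))
table = all_pairwise(draws, pop)
print(table[table.label.isin(["IXE_Q2W vs PBO", "SEC_300 vs IXE_Q2W",
                              "IXE_Q2W"])].round(3).to_string(index=False))

rep = full_report(draws)
print(f"residual deviance {rep.total_residual_deviance:.1f} "
      f"on {rep.n_datapoints} data points; DIC {rep.dic:.1f}")
```

prints (a couple of minutes on one core):

```
1.0164007579156402
population     kind              label   mean    sd   2.5%  97.5%
   STUDY-4 contrast     IXE_Q2W vs PBO  3.137 0.125  2.884  3.381
   STUDY-4 contrast SEC_300 vs IXE_Q2W -0.594 0.169 -0.940 -0.270
   STUDY-4 absolute            IXE_Q2W  0.925 0.018  0.885  0.954
residual deviance 1622.5 on 2204 data points; DIC 1666.6
```

All parameters converge (max R̂ = 1.016). The contrast rows are
standardized mean differences on the latent probit scale in the aggregate
study's population, with 95% credible intervals; the generating value for
the IXE_Q2W individual-level effect was γ = 2.82 (the population-average
contrast also includes its effect-modifier terms). The absolute row is
the predicted response proportion on IXE_Q2W in that population. The
residual deviance is well below one per Bernoulli data point, as expected
when the outcome entropy is moderate.

The same workflow is available from the shell:

```sh
mlnmr simulate --seed 3 --outdir data
mlnmr fit --config data/config.yaml --seed 5 --outdir fit
mlnmr predict --fit-dir fit --out estimates.csv
mlnmr check --fit-dir fit --out check.json
```

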
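"""Core model operations: linear predictor, aggregate moments, likelihoods."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from mlnmr.data import Treatment
from mlnmr.integration import IntegrationGrid, MarginalSpec, build_grid
from mlnmr.model import (
    AggregateMoments,
    ModelSpec,
    Parameters,
    aggregate_loglik,
    aggregate_moments,
    consistency_expand,
    effect_modifier_structure,
    individual_loglik,
    linear_predictor,
    moments_from_eta,
    random_effects_cov,
    two_param_binomial,
)


def _params(**kw):
    base = dict(
        mu={"S1": -1.0},
        beta1=np.array([0.5]),
        beta2={"B": np.array([0.2])},
        gamma={"B": 2.0},
    )
    base.update(kw)
    return Parameters(**base)


SPEC1 = ModelSpec(prognostic=("x",), effect_modifiers=("x",))


class TestLinearPredictor:
    def test_reference_at_zero_covariates_is_mu(self):
        p = _params()
        assert linear_predictor([0.0], "S1", "A", p, SPEC1) == pytest.approx(-1.0)

    def test_direct_arithmetic(self):
        # mu=-1, beta1=0.5, beta2=0.2, gamma=2, x=1 -> -1 + 0.7 + 2 = 1.7
        p = _params()
        assert linear_predictor([1.0], "S1", "B", p, SPEC1) == pytest.approx(1.7)

    def test_prognostic_only_cancels_in_contrasts(self):
        spec = ModelSpec(prognostic=("x",), effect_modifiers=())
        for b1 in (0.0, 0.5, -2.0):
            p = _params(beta1=np.array([b1]), beta2={})
            diff = linear_predictor([3.0], "S1", "B", p, spec) - linear_predictor(
                [3.0], "S1", "A", p, spec
            )
            assert diff == pytest.approx(2.0, abs=1e-12)

    def test_unknown_study_raises(self):
        with pytest.raises(KeyError):
            linear_predictor([0.0], "NOPE", "A", _params(), SPEC1)

    def test_random_effects_use_delta(self):
        p = _params(delta={("S1", "B"): 1.5})
        # mu + delta = -1 + 1.5; gamma is ignored once delta is present
        assert linear_predictor([0.0], "S1", "B", p, SPEC1) == pytest.approx(0.5)


class TestAggregateMoments:
    def test_constant_eta_degenerate(self):
        m = moments_from_eta(np.full(100, 0.7), "probit")
        assert m.pbar == pytest.approx(stats.norm.cdf(0.7), abs=1e-12)
        assert m.p2bar == pytest.approx(stats.norm.cdf(0.7) ** 2, abs=1e-12)

    def test_probit_normal_closed_form(self):
        # E Phi(mu + b X), X ~ N(0,1), equals Phi(mu / sqrt(1 + b^2))
        grid = build_grid("s", [MarginalSpec.normal("x", 0, 1)], None, 10_000, seed=1)
        p = _params(mu={"S": 1.0}, beta1=np.array([1.0]), beta2={}, gamma={})
        m = aggregate_moments(grid, "S", "A", p, SPEC1)
        assert abs(m.pbar - stats.norm.cdf(1 / np.sqrt(2))) < 1e-3

    def test_squared_probability_against_quadrature(self):
        grid = build_grid("s", [MarginalSpec.normal("x", 0, 1)], None, 10_000, seed=1)
        p = _params(mu={"S": 1.0}, beta1=np.array([1.0]), beta2={}, gamma={})
        m = aggregate_moments(grid, "S", "A", p, SPEC1)
        oracle, _ = integrate.quad(
            lambda x: stats.norm.cdf(1 + x) ** 2 * stats.norm.pdf(x), -10, 10
        )
        assert abs(m.p2bar - oracle) < 1e-3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            moments_from_eta(np.array([]), "probit")

    def test_moment_invariants_enforced(self):
        m = AggregateMoments(0.5, 0.1)  # below pbar^2: clamped up
        assert m.pbar**2 <= m.p2bar <= m.pbar

    def test_aggregation_bias_strict(self):
        # plugging in the mean covariate differs from integrating whenever
        # the coefficient is nonzero and the covariate varies
        grid = build_grid("s", [MarginalSpec.normal("x", 0, 1)], None, 4096, seed=2)
        p = _params(mu={"S": 1.0}, beta1=np.array([1.0]), beta2={}, gamma={})
        m = aggregate_moments(grid, "S", "A", p, SPEC1)
        plug_in = stats.norm.cdf(1.0 + 1.0 * grid.points.mean())
        assert abs(m.pbar - plug_in) > 0.01


def _poisbin_moments_bruteforce(probs):
    """Mean/variance of a Poisson-binomial by full pmf convolution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    k = np.arange(len(pmf))
    mean = float((k * pmf).sum())
    var = float(((k - mean) ** 2 * pmf).sum())
    return mean, var


class TestTwoParamBinomial:
    def test_homogeneous_reduces_to_simple_binomial(self):
        n_prime, p_prime = two_param_binomial(50, AggregateMoments(0.3, 0.09))
        assert n_prime == pytest.approx(50.0, abs=1e-9)
        assert p_prime == pytest.approx(0.3, abs=1e-12)

    def test_worked_example(self):
        # p = (0.2, 0.5, 0.8): pbar = 0.5, p2bar = 0.31
        n_prime, p_prime = two_param_binomial(3, AggregateMoments(0.5, 0.31))
        assert n_prime == pytest.approx(3 * 0.25 / 0.31, abs=1e-12)
        assert p_prime == pytest.approx(0.62, abs=1e-12)
        mean, var = _poisbin_moments_bruteforce([0.2, 0.5, 0.8])
        assert n_prime * p_prime == pytest.approx(mean, abs=1e-12)
        assert n_prime * p_prime * (1 - p_prime) == pytest.approx(var, abs=1e-12)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=9))
    def test_matches_poisson_binomial_and_shrinks_variance(self, probs):
        probs = np.array(probs)
        n = len(probs)
        m = AggregateMoments(probs.mean(), (probs**2).mean())
        n_prime, p_prime = two_param_binomial(n, m)
        mean, var = _poisbin_moments_bruteforce(probs)
        assert n_prime * p_prime == pytest.approx(mean, abs=1e-10)
        assert n_prime * p_prime * (1 - p_prime) == pytest.approx(var, abs=1e-10)
        naive_var = n * probs.mean() * (1 - probs.mean())
        assert n_prime * p_prime * (1 - p_prime) <= naive_var + 1e-12
        assert n_prime <= n + 1e-12


class TestLikelihoods:
    def test_bernoulli_closed_forms(self):
        assert individual_loglik(1, 1 - 1e-12, "bernoulli") == pytest.approx(0.0, abs=1e-9)
        assert individual_loglik(1, 0.5, "bernoulli") == pytest.approx(np.log(0.5))
        assert individual_loglik(0, 0.5, "bernoulli") == pytest.approx(np.log(0.5))

    def test_bernoulli_rejects_degenerate_probability(self):
        with pytest.raises(ValueError):
            individual_loglik(1, 1.0, "bernoulli")

    def test_normal_and_poisson_match_scipy(self):
        assert individual_loglik(1.3, 1.0, "normal", sigma=2.0) == pytest.approx(
            stats.norm.logpdf(1.3, 1.0, 2.0)
        )
        assert individual_loglik(4, 2.5, "poisson") == pytest.approx(
            stats.poisson.logpmf(4, 2.5)
        )

    def test_aggregate_homogeneous_equals_binomial_pmf(self):
        ll = aggregate_loglik(5, 10, AggregateMoments(0.5, 0.25), "bernoulli")
        assert ll == pytest.approx(stats.binom.logpmf(5, 10, 0.5), abs=1e-12)
        assert ll == pytest.approx(np.log(0.24609375), abs=1e-9)

    def test_two_parameter_differs_under_heterogeneity(self):
        hetero = AggregateMoments(0.5, 0.31)
        ll_two = aggregate_loglik(5, 10, hetero, "bernoulli")
        ll_naive = stats.binom.logpmf(5, 10, 0.5)
        assert ll_two != pytest.approx(ll_naive, abs=1e-6)

    def test_aggregate_normal_and_poisson(self):
        assert aggregate_loglik(1.2, 100, None, "normal", se=0.1, theta=1.0) == pytest.approx(
            stats.norm.logpdf(1.2, 1.0, 0.1)
        )
        assert aggregate_loglik(7, 100, None, "poisson", theta=6.0) == pytest.approx(
            stats.poisson.logpmf(7, 6.0)
        )


class TestRandomEffectsCov:
    def test_two_arm_structure(self):
        np.testing.assert_allclose(
            random_effects_cov(1.0, 2), [[1.0, 0.5], [0.5, 1.0]]
        )

    def test_fixed_effect_limit(self):
        np.testing.assert_allclose(random_effects_cov(0.0, 3), np.zeros((3, 3)))

    @pytest.mark.parametrize("dim", [1, 2, 5, 10])
    def test_positive_definite(self, dim):
        m = random_effects_cov(0.7, dim)
        assert np.linalg.eigvalsh(m).min() > 0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            random_effects_cov(-1.0, 2)
        with pytest.raises(ValueError):
            random_effects_cov(1.0, 0)


class TestEffectModifierStructure:
    def _treatments(self):
        return [
            Treatment("PBO", is_reference=True),
            Treatment("IXE_Q2W", "IL17"),
            Treatment("IXE_Q4W", "IL17"),
            Treatment("SEC_150", "IL17"),
            Treatment("SEC_300", "IL17"),
            Treatment("ETN", "TNF"),
        ]

    def test_shared_class_collapses_to_one_vector(self):
        em = effect_modifier_structure(
            self._treatments(), {"IL17": "shared", "TNF": "shared"}
        )
        assert em.n_groups == 2
        il17 = em.groups[em.group_of["IXE_Q2W"]]
        assert set(il17) == {"IXE_Q2W", "IXE_Q4W", "SEC_150", "SEC_300"}

    def test_independent_gives_one_vector_per_treatment(self):
        em = effect_modifier_structure(self._treatments(), {})
        assert em.n_groups == 5
        assert len({em.group_of[t] for t in em.group_of}) == 5

    def test_exchangeable_requires_two_members(self):
        trts = [Treatment("A", is_reference=True), Treatment("B", "solo")]
        with pytest.raises(ValueError, match="unidentifiable"):
            effect_modifier_structure(trts, {"solo": "exchangeable"})

    def test_exchangeable_class_tracks_groups(self):
        em = effect_modifier_structure(
            self._treatments(), {"IL17": "exchangeable", "TNF": "shared"}
        )
        assert len(em.exchangeable["IL17"]) == 4


class TestConsistency:
    def test_subtraction(self):
        table = consistency_expand({"a": 0.0, "b": 1.0, "c": 3.0})
        assert table[("b", "c")]["gamma"] == pytest.approx(2.0)

    def test_antisymmetry_and_triangle(self):
        rng = np.random.default_rng(0)
        gamma = {f"t{i}": float(g) for i, g in enumerate(rng.normal(size=6))}
        table = consistency_expand(gamma)
        trts = list(gamma)
        assert len(table) == 30  # ordered pairs; 15 unordered
        for a in trts:
            for b in trts:
                if a == b:
                    continue
                assert table[(a, b)]["gamma"] == pytest.approx(
                    -table[(b, a)]["gamma"], abs=1e-12
                )
                assert table[(a, b)]["gamma"] == pytest.approx(
                    gamma[b] - gamma[a], abs=1e-12
                )
        for c in trts[:3]:
            for a in trts[:3]:
                for b in trts[:3]:
                    if len({a, b, c}) == 3:
                        assert table[(a, b)]["gamma"] + table[(b, c)][
                            "gamma"
                        ] == pytest.approx(table[(a, c)]["gamma"], abs=1e-12)

    def test_beta2_differences(self):
        beta2 = {"a": np.zeros(2), "b": np.array([0.1, 0.2]), "c": np.array([0.3, -0.1])}
        gamma = {"a": 0.0, "b": 1.0, "c": 2.0}
        table = consistency_expand(gamma, beta2)
        np.testing.assert_allclose(table[("b", "c")]["beta2"], [0.2, -0.3])
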
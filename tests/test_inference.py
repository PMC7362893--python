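"""Posterior sampling: identities, recovery, diagnostics, determinism."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from conftest import pack_theta
from mlnmr.data import AgDStudy, IPDStudy, build_network
from mlnmr.inference import FitConfig, PosteriorDraws, diagnostics, fit
from mlnmr.model import (
    LogPosterior,
    ModelSpec,
    Parameters,
    individual_loglik,
    linear_predictor,
)


def _two_ipd_studies(seed=0, n=60):
    rng = np.random.default_rng(seed)
    studies = []
    for sid, trts, mu in [("S1", ["A", "B"], -0.3), ("S2", ["B", "C"], 0.1)]:
        frames = []
        for t in trts:
            x = rng.normal(0.5, 1.0, size=(n, 2))
            eta = mu + x @ [0.4, -0.2] + {"A": 0.0, "B": 0.8, "C": 1.2}[t]
            if t != "A":
                eta = eta + x @ [0.1, 0.05]
            y = rng.binomial(1, special.ndtr(eta))
            df = pd.DataFrame(x, columns=["x1", "x2"])
            df.insert(0, "y", y)
            df.insert(0, "treatment", t)
            frames.append(df)
        studies.append(IPDStudy(sid, pd.concat(frames, ignore_index=True), ("x1", "x2")))
    return studies


def _spec():
    return ModelSpec(prognostic=("x1", "x2"), effect_modifiers=("x1", "x2"))


def test_all_ipd_loglik_identical_to_direct_meta_regression():
    """With every study IPD, the joint likelihood equals a directly coded
    individual-level network meta-regression, term by term, to 1e-10."""
    studies = _two_ipd_studies()
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    spec = _spec()
    lp = LogPosterior(net, spec, center=False)

    params = Parameters(
        mu={"S1": -0.4, "S2": 0.2},
        beta1=np.array([0.3, -0.1]),
        beta2={"B": np.array([0.15, 0.02]), "C": np.array([-0.1, 0.2])},
        gamma={"B": 0.7, "C": 1.1},
    )
    naive = 0.0
    for s in studies:
        for _, row in s.data.iterrows():
            eta = linear_predictor(
                row[["x1", "x2"]].to_numpy(float), s.study_id, row["treatment"],
                params, spec,
            )
            naive += individual_loglik(row["y"], stats.norm.cdf(eta), "bernoulli")

    theta = pack_theta(
        lp,
        {
            "mu[S1]": -0.4,
            "mu[S2]": 0.2,
            "beta1[x1]": 0.3,
            "beta1[x2]": -0.1,
            "beta2[B;x1]": 0.15,
            "beta2[B;x2]": 0.02,
            "beta2[C;x1]": -0.1,
            "beta2[C;x2]": 0.2,
            "gamma[B]": 0.7,
            "gamma[C]": 1.1,
        },
    )
    assert lp.log_likelihood(theta[None, :])[0] == pytest.approx(naive, abs=1e-10)


def test_pointwise_loglik_sums_to_total():
    studies = _two_ipd_studies()
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    lp = LogPosterior(net, _spec())
    theta = lp.initial_point()[None, :] + 0.05
    total = lp.log_likelihood(theta)
    pointwise = lp.pointwise_loglik(theta)
    assert pointwise.shape[1] == sum(s.n for s in studies)
    np.testing.assert_allclose(pointwise.sum(axis=1), total, atol=1e-8)


def test_fixed_effects_spec_has_no_delta_parameters():
    studies = _two_ipd_studies()
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    fe = LogPosterior(net, _spec())
    re = LogPosterior(net, ModelSpec(prognostic=("x1", "x2"),
                                     effect_modifiers=("x1", "x2"),
                                     effects="random"))
    assert not any(n.startswith(("tau", "z_re")) for n in fe.names)
    assert any(n.startswith("tau") for n in re.names)
    assert sum(n.startswith("z_re") for n in re.names) == 3  # one per non-ref arm


def test_parameter_recovery_two_study_network():
    """On a small simulated 2-study network the posterior mean of each
    treatment effect lies within 3 posterior SDs of the truth."""
    studies = _two_ipd_studies(seed=3, n=250)
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    cfg = FitConfig(chains=2, warmup=400, samples=400, seed=5, draws_per_chain=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(net, _spec(), config=cfg)
    gamma = draws.gamma_draws()
    for t, truth in [("B", 0.8), ("C", 1.2)]:
        z = (gamma[t].mean() - truth) / gamma[t].std(ddof=1)
        assert abs(z) < 3


def test_seed_determinism():
    studies = _two_ipd_studies(seed=1, n=40)
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    spec = ModelSpec(prognostic=("x1",), effect_modifiers=())
    cfg = FitConfig(chains=2, warmup=60, samples=60, seed=42, draws_per_chain=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d1 = fit(net, spec, config=cfg)
        d2 = fit(net, spec, config=cfg)
    np.testing.assert_array_equal(d1.params, d2.params)


def test_prior_predictive_recovers_prior():
    """With the likelihood dropped, sampled moments match the prior."""
    studies = _two_ipd_studies(seed=2, n=30)
    net = build_network(studies, reference="A", covariates=("x1", "x2"))
    spec = ModelSpec(prognostic=("x1",), effect_modifiers=())
    cfg = FitConfig(chains=2, warmup=300, samples=1500, seed=8, draws_per_chain=3000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(net, spec, config=cfg, prior_only=True)
    g = draws.block("gamma")
    # prior is N(0, 100^2); allow 3 MCSE on the mean
    diag = diagnostics(draws)
    for i, name in enumerate(["gamma[B]", "gamma[C]"]):
        mcse = diag.loc[name, "mcse"]
        assert abs(g[:, i].mean()) < 3 * mcse + 1.0
        assert g[:, i].std(ddof=1) == pytest.approx(100.0, rel=0.25)


class TestDiagnostics:
    def _fake_draws(self, arr):
        studies = _two_ipd_studies(seed=4, n=20)
        net = build_network(studies, reference="A", covariates=("x1", "x2"))
        lp = LogPosterior(net, ModelSpec(prognostic=(), effect_modifiers=()))
        cfg = FitConfig(chains=arr.shape[0], warmup=1, samples=1, seed=0)
        full = np.zeros((arr.shape[0], arr.shape[1], lp.ndim))
        full[:, :, : arr.shape[2]] = arr
        full += 1e-6 * np.random.default_rng(0).standard_normal(full.shape)
        return PosteriorDraws(full, lp, cfg)

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        draws = self._fake_draws(rng.standard_normal((2, 800, 2)))
        diag = diagnostics(draws)
        assert (diag["rhat"] <= 1.01).all()
        assert not diag["flagged"].any()

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 400, 2))
        arr[1, :, 0] += 5.0
        diag = diagnostics(self._fake_draws(arr))
        assert diag.iloc[0]["rhat"] > 1.2
        assert diag.iloc[0]["flagged"]

    def test_ess_bounded_by_total_draws(self):
        rng = np.random.default_rng(2)
        draws = self._fake_draws(rng.standard_normal((2, 300, 2)))
        diag = diagnostics(draws)
        assert (diag["ess"] <= draws.n_draws + 1e-6).all()

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(3)
        draws = self._fake_draws(rng.standard_normal((1, 300, 2)))
        diag = diagnostics(draws)
        assert diag["rhat"].isna().all()


def test_no_covariate_mlnmr_matches_direct_nma():
    """With no covariates the model collapses to a standard aggregate NMA:
    posterior means agree with an independently coded binomial NMA."""
    arms = {
        "T1": [("A", 40, 120), ("B", 70, 120)],
        "T2": [("B", 55, 110), ("C", 80, 110)],
        "T3": [("A", 30, 100), ("C", 66, 100)],
    }
    studies = [
        AgDStudy(sid, pd.DataFrame(rows, columns=["treatment", "y", "n"]))
        for sid, rows in arms.items()
    ]
    net = build_network(studies, reference="A")
    spec = ModelSpec(prognostic=(), effect_modifiers=())
    cfg = FitConfig(chains=2, warmup=500, samples=500, seed=13, draws_per_chain=800)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(net, spec, config=cfg)

    # independent oracle: direct binomial NMA, probit link
    import emcee

    order = ["T1", "T2", "T3"]
    flat = [(order.index(s), t, y, n) for s in order for (t, y, n) in arms[s]]
    gidx = {"B": 0, "C": 1}

    def logp(th):
        th = np.atleast_2d(th)
        mu, gam = th[:, :3], th[:, 3:]
        out = stats.norm.logpdf(th, scale=100.0).sum(axis=1)
        for j, t, y, n in flat:
            eta = mu[:, j] + (gam[:, gidx[t]] if t in gidx else 0.0)
            p = np.clip(special.ndtr(eta), 1e-12, 1 - 1e-12)
            out += stats.binom.logpmf(y, n, p)
        return out

    sampler = emcee.EnsembleSampler(32, 5, logp, vectorize=True)
    rng = np.random.RandomState(99)
    p0 = 0.1 * rng.standard_normal((32, 5))
    state = emcee.State(p0, random_state=rng.get_state())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(state, 1500, progress=False)
    ref = sampler.get_chain(discard=500, flat=True)

    gamma = draws.gamma_draws()
    diag = diagnostics(draws)
    for t, col in gidx.items():
        ref_mean = ref[:, 3 + col].mean()
        ref_mcse = ref[:, 3 + col].std(ddof=1) / np.sqrt(
            len(ref) / (1 + 2 * 20)  # conservative autocorrelation allowance
        )
        mcse = diag.loc[f"gamma[{t}]", "mcse"]
        tol = 4 * np.hypot(mcse, ref_mcse) + 0.01
        assert gamma[t].mean() == pytest.approx(ref_mean, abs=tol)
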
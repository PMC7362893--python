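"""Bayesian posterior sampling of the ML-NMR model.

Sampling uses an affine-invariant ensemble sampler (emcee): the model's
joint log-density is fully vectorized over parameter rows, so moving a
whole ensemble costs little more than a single evaluation.  Because the
ensemble moves are invariant to affine reparameterizations, no centring or
QR rotation of the design is needed for mixing; chains are initialized in
a small ball around a posterior mode found by L-BFGS.  Independent
ensembles play the role of chains for the potential scale reduction
factor R-hat.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import emcee
import numpy as np
import pandas as pd
from scipy import optimize

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

from .data import Network
from .integration import IntegrationGrid
from .model import LogPosterior, ModelSpec


@dataclass
class FitConfig:
    """Sampler settings.

    ``warmup`` and ``samples`` count ensemble steps; each step advances
    every walker, so a chain yields ``samples * walkers`` correlated draws,
    thinned down to ``draws_per_chain`` for storage.
    """

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    walkers: int | None = None
    draws_per_chain: int = 1000
    n_integration_points: int = 10_000

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.warmup < 0 or self.samples <= 0:
            raise ValueError("iteration counts must be positive")


class PosteriorDraws:
    """Posterior draws plus access to the model structure that produced them.

    ``params`` has shape (chains, draws, ndim); parameter names follow the
    layout of the joint log-density.
    """

    def __init__(self, params: np.ndarray, logpost: LogPosterior, config: FitConfig):
        self.params = np.asarray(params, dtype=float)
        if self.params.ndim != 3:
            raise ValueError("params must be (chains, draws, ndim)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite posterior draws")
        self.logpost = logpost
        self.config = config
        self.names = list(logpost.names)

    # -- shapes ------------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[0] * self.params.shape[1]

    @property
    def stacked(self) -> np.ndarray:
        """(total draws, ndim) with chains concatenated."""
        return self.params.reshape(-1, self.params.shape[-1])

    # -- named access ------------------------------------------------------
    def block(self, name: str) -> np.ndarray:
        """(total draws, width) slice of a named parameter block."""
        sl = self.logpost._slices.get(name)
        if sl is None:
            raise KeyError(f"no parameter block {name!r}")
        return self.stacked[:, sl]

    def mu_draws(self) -> dict[str, np.ndarray]:
        """Study baselines on the natural covariate scale.

        Sampling runs on covariates centred at the pooled mean xbar, so the
        sampled baseline is mu_j + xbar' beta1; it is translated back here.
        """
        block = self.block("mu")
        shift = 0.0
        if self.logpost.d1:
            xbar_prog = self.logpost.xbar[self.logpost._prog_cols]
            shift = self.beta1_draws() @ xbar_prog
        return {
            s.study_id: block[:, j] - shift
            for j, s in enumerate(self.logpost.studies)
        }

    def beta1_draws(self) -> np.ndarray:
        if "beta1" not in self.logpost._slices:
            return np.zeros((self.n_draws, 0))
        return self.block("beta1")

    def gamma_draws(self) -> dict[str, np.ndarray]:
        """Individual-level relative effects per treatment (reference = 0).

        Translated from the centred sampling scale: the sampled effect is
        gamma_k + xbar' beta2_k, so xbar' beta2_k is subtracted back out.
        """
        out = {self.logpost.network.reference.id: np.zeros(self.n_draws)}
        if "gamma" in self.logpost._slices:
            block = self.block("gamma")
            beta2 = self.beta2_draws()
            xbar_em = self.logpost.xbar[self.logpost._em_cols]
            for t, i in self.logpost._gamma_idx.items():
                shift = beta2[t] @ xbar_em if self.logpost.d2 else 0.0
                out[t] = block[:, i] - shift
        return out

    def beta2_draws(self) -> dict[str, np.ndarray]:
        """Interaction vectors per treatment, (draws, d2); reference = 0.

        Treatments sharing a group map to the *same* array object, so
        shared-class contrasts cancel exactly.
        """
        d2 = self.logpost.d2
        out = {self.logpost.network.reference.id: np.zeros((self.n_draws, d2))}
        em = self.logpost.em
        if d2 and em.n_groups:
            block = self.block("beta2").reshape(self.n_draws, em.n_groups, d2)
            group_arrays = [block[:, g, :] for g in range(em.n_groups)]
            for t, g in em.group_of.items():
                out[t] = group_arrays[g]
        else:
            for t in em.group_of:
                out[t] = np.zeros((self.n_draws, d2))
        return out

    def tau_draws(self) -> np.ndarray | None:
        if "tau" not in self.logpost._slices:
            return None
        return self.block("tau")[:, 0]

    # -- interop -----------------------------------------------------------
    def to_inference_data(self) -> "az.InferenceData":
        posterior = {
            name: self.params[:, :, i] for i, name in enumerate(self.names)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.from_dict(posterior=posterior)

    def summary(self) -> pd.DataFrame:
        flat = self.stacked
        qs = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "2.5%": qs[0],
                "median": qs[1],
                "97.5%": qs[2],
            },
            index=self.names,
        )

    # -- persistence ---------------------------------------------------------
    def save(self, outdir, manifest_extra: Mapping | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            pd.DataFrame(self.params[c], columns=self.names).to_csv(
                outdir / f"chain_{c}.csv", index=False
            )
        manifest = {
            "chains": self.n_chains,
            "config": asdict(self.config),
            "parameters": self.names,
        }
        manifest.update(manifest_extra or {})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, outdir, logpost: LogPosterior) -> "PosteriorDraws":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        chains = [
            pd.read_csv(outdir / f"chain_{c}.csv").to_numpy()
            for c in range(manifest["chains"])
        ]
        config = FitConfig(**manifest["config"])
        return cls(np.stack(chains), logpost, config)


def _sample_prior(logpost: LogPosterior, rng: np.random.RandomState, n: int) -> np.ndarray:
    """Draw ensemble starting points directly from the prior."""
    p = logpost.spec.priors
    x = np.zeros((n, logpost.ndim))
    for name, sl in logpost._slices.items():
        w = sl.stop - sl.start
        if name in ("mu", "beta1", "beta2", "gamma", "d_ume") or name.startswith("m_beta2["):
            x[:, sl] = rng.normal(0.0, p.effect_sd, (n, w))
        elif name == "z_re":
            x[:, sl] = rng.normal(0.0, 1.0, (n, w))
        elif name == "tau":
            x[:, sl] = np.abs(rng.normal(0.0, p.tau_sd, (n, w)))
        elif name.startswith("sigma_beta2["):
            x[:, sl] = np.abs(rng.normal(0.0, p.sigma_beta2_sd, (n, w)))
        elif name == "sigma":
            x[:, sl] = np.abs(rng.normal(0.0, p.sigma_sd, (n, w)))
    # hierarchical classes: redraw beta2 from its class-level normal
    for cls, gidx in logpost.em.exchangeable.items():
        m = x[:, logpost._slices[f"m_beta2[{cls}]"]]
        s = x[:, logpost._slices[f"sigma_beta2[{cls}]"]]
        b2 = x[:, logpost._slices["beta2"]].reshape(n, logpost.em.n_groups, logpost.d2)
        for g in gidx:
            b2[:, g, :] = rng.normal(m, s)
        x[:, logpost._slices["beta2"]] = b2.reshape(n, -1)
    return x


def _map_estimate(logpost: LogPosterior) -> np.ndarray:
    """Posterior mode by L-BFGS-B with numerical gradients.

    Scale parameters are kept away from their boundary at zero; a failed
    optimization falls back to the data-informed initial point.
    """
    x0 = logpost.initial_point()
    bounds = [(None, None)] * logpost.ndim
    for name, sl in logpost._slices.items():
        if name == "tau" or name == "sigma" or name.startswith("sigma_beta2"):
            for i in range(sl.start, sl.stop):
                bounds[i] = (1e-3, None)
                x0[i] = max(x0[i], 0.1)

    def neg(x):
        val = logpost(x[None, :])[0]
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500})
    x = res.x if np.isfinite(logpost(res.x[None, :])[0]) else x0
    return x


def fit(
    network: Network,
    spec: ModelSpec,
    grids: Mapping[str, IntegrationGrid] | None = None,
    config: FitConfig | None = None,
    ume: bool = False,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the joint posterior of the ML-NMR model.

    Integration grids must be supplied for every aggregate study with
    covariates in the model; they are held fixed across all iterations.
    ``prior_only=True`` drops the likelihood (prior-predictive check).
    """
    config = config or FitConfig()
    logpost = LogPosterior(network, spec, grids, ume=ume)
    _check_identifiability(logpost)
    target = (lambda th: logpost.log_prior(np.atleast_2d(th))) if prior_only else logpost

    ndim = logpost.ndim
    nwalkers = config.walkers or max(2 * ndim + 2, 32)
    if nwalkers % 2:
        nwalkers += 1
    x_map = logpost.initial_point() if prior_only else _map_estimate(logpost)

    chains = []
    for c in range(config.chains):
        rng = np.random.RandomState((config.seed + 7919 * c) % (2**31 - 1))
        if prior_only:
            p0 = _sample_prior(logpost, rng, nwalkers)
        else:
            p0 = x_map[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
        # keep constrained coordinates inside their support
        for name, sl in logpost._slices.items():
            if name == "tau" or name == "sigma" or name.startswith("sigma_beta2"):
                p0[:, sl] = np.abs(p0[:, sl]) + 1e-3
        lp0 = target(p0)
        bad = ~np.isfinite(np.atleast_1d(lp0))
        tries = 0
        while bad.any() and tries < 50:
            p0[bad] = x_map[None, :] + 0.01 * rng.standard_normal((bad.sum(), ndim))
            for name, sl in logpost._slices.items():
                if name == "tau" or name == "sigma" or name.startswith("sigma_beta2"):
                    p0[bad, sl] = np.abs(p0[bad, sl]) + 1e-3
            bad = ~np.isfinite(np.atleast_1d(target(p0)))
            tries += 1
        sampler = emcee.EnsembleSampler(nwalkers, ndim, target, vectorize=True)
        state = emcee.State(p0, random_state=np.random.RandomState(
            (config.seed + 104729 * (c + 1)) % (2**31 - 1)).get_state())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(state, config.warmup + config.samples, progress=False)
        flat = sampler.get_chain(discard=config.warmup, flat=True)
        if len(flat) > config.draws_per_chain:
            idx = np.linspace(0, len(flat) - 1, config.draws_per_chain).astype(int)
            flat = flat[idx]
        chains.append(flat)
        acc = float(np.mean(sampler.acceptance_fraction))
        if acc < 0.05:
            warnings.warn(
                f"chain {c}: low ensemble acceptance fraction {acc:.3f}",
                stacklevel=2,
            )
    return PosteriorDraws(np.stack(chains), logpost, config)


def _check_identifiability(logpost: LogPosterior) -> None:
    """Warn when an interaction group is supported by no IPD study and
    fewer than two aggregate studies (meta-regression requirement)."""
    if logpost.d2 == 0 or logpost.ume:
        return
    for g, members in enumerate(logpost.em.groups):
        ipd = {a.study_id for a in logpost.ipd_arms if a.group == g}
        agd = {a.study_id for a in logpost.agd_arms if a.group == g}
        if not ipd and len(agd) < 2:
            warnings.warn(
                f"interaction coefficients for treatment group {members} are "
                "informed by no IPD study and fewer than two aggregate studies; "
                "the model may be weakly identified",
                stacklevel=3,
            )


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.01) -> pd.DataFrame:
    """Convergence report: split R-hat, effective sample size, MC standard error.

    With a single chain R-hat is unavailable and reported as NaN.
    """
    idata = draws.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
        mcse = az.mcse(idata)
        if draws.n_chains >= 2:
            rhat = az.rhat(idata)
            rhat_vals = {v: float(rhat[v].values) for v in rhat.data_vars}
        else:
            rhat_vals = {v: np.nan for v in ess.data_vars}
    rows = []
    for name in draws.names:
        r = rhat_vals.get(name, np.nan)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess": float(ess[name].values),
                "mcse": float(mcse[name].values),
                "flagged": bool(r > rhat_threshold) if np.isfinite(r) else False,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
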
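"""Population-average estimates in arbitrary target populations.

Any functional h(x, xi) of the covariates and model parameters can be
averaged over a target population P, either by QMC integration over a
covariate grid or by averaging over the individuals of an IPD sample.
Population-average contrasts d_ab(P) are linear in x, so integration
reduces exactly to plugging in the population's mean effect-modifier
values; absolute outcome probabilities are genuinely non-linear and are
averaged point by point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import IPDStudy
from .inference import PosteriorDraws
from .integration import IntegrationGrid
from .model import inverse_link

_CHUNK = 256


@dataclass
class TargetPopulation:
    """A named population with full covariate representation.

    ``points`` holds either QMC integration points (marginals + copula) or
    IPD covariate rows, one column per name in ``covariates``.  ``baseline``
    locates the individual-level reference effect mu_(P): a study in the
    network (``("study", id)``), a fixed external value (``("fixed", v)``)
    or an external normal distribution (``("normal", mean, sd)``) sampled
    once per posterior draw.
    """

    name: str
    covariates: tuple[str, ...]
    points: np.ndarray
    baseline: tuple | None = None

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != len(self.covariates):
            raise ValueError("points must have one column per covariate")

    @classmethod
    def from_grid(cls, grid: IntegrationGrid, baseline=None, name=None):
        return cls(name or grid.study_id, grid.names, grid.points, baseline)

    @classmethod
    def from_ipd_study(cls, study: IPDStudy, covariates: Sequence[str], baseline="self"):
        if baseline == "self":
            baseline = ("study", study.study_id)
        pts = study.data[list(covariates)].to_numpy(dtype=float)
        return cls(study.study_id, tuple(covariates), pts, baseline)

    def column_means(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.covariates.index(n) for n in names]
        return self.points[:, idx].mean(axis=0)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.covariates.index(n) for n in names]
        return self.points[:, idx]


@dataclass
class PopulationEstimate:
    """Posterior draws and summary of one population-average quantity."""

    kind: str  # "contrast" | "absolute" | "custom"
    treatments: tuple[str, ...]
    population: str
    draws: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1)) if self.draws.size > 1 else 0.0

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws, [a, 100 - a])
        return float(lo), float(hi)

    def summary_row(self) -> dict:
        lo, hi = self.interval()
        return {
            "population": self.population,
            "kind": self.kind,
            "label": self.label,
            "mean": self.mean,
            "sd": self.sd,
            "2.5%": lo,
            "97.5%": hi,
        }


def _effect_modifier_means(draws: PosteriorDraws, population: TargetPopulation):
    ems = draws.logpost.spec.effect_modifiers
    missing = [c for c in ems if c not in population.covariates]
    if missing:
        raise ValueError(
            f"population {population.name!r} lacks effect modifiers {missing}"
        )
    return population.column_means(ems) if ems else np.zeros(0)


def population_contrast(
    draws: PosteriorDraws, population: TargetPopulation, a: str, b: str
) -> PopulationEstimate:
    """Population-average relative effect d_ab(P) of b versus a.

    Per draw, h-bar(P) = xbar' (beta2_b - beta2_a) + gamma_b - gamma_a,
    with xbar the mean effect-modifier vector in P.  Within a shared
    effect-modifier class the interaction difference cancels exactly, so
    the contrast is identical in every population.
    """
    for t in (a, b):
        draws.logpost.network.treatment_index(t)
    gamma = draws.gamma_draws()
    beta2 = draws.beta2_draws()
    xbar = _effect_modifier_means(draws, population)
    h = gamma[b] - gamma[a]
    if xbar.size:
        h = h + (beta2[b] - beta2[a]) @ xbar
    return PopulationEstimate(
        "contrast", (a, b), population.name, h, label=f"{b} vs {a}"
    )


def _baseline_draws(draws: PosteriorDraws, population: TargetPopulation):
    base = population.baseline
    if base is None:
        raise ValueError(
            f"population {population.name!r} has no baseline source for "
            "absolute predictions"
        )
    if base[0] == "study":
        mu = draws.mu_draws()
        if base[1] not in mu:
            raise KeyError(f"baseline study {base[1]!r} not in the fitted network")
        return mu[base[1]]
    if base[0] == "fixed":
        return np.full(draws.n_draws, float(base[1]))
    if base[0] == "normal":
        _, mean, sd = base
        rng = np.random.default_rng(draws.config.seed + 424243)
        return rng.normal(mean, sd, size=draws.n_draws)
    raise ValueError(f"unknown baseline source {base!r}")


def population_absolute(
    draws: PosteriorDraws, population: TargetPopulation, treatment: str
) -> PopulationEstimate:
    """Population-average absolute outcome on one treatment in P.

    Per draw, averages g^{-1}(mu_(P) + x'(beta1 + beta2_k) + gamma_k) over
    the population's covariate points (grid or individuals).
    """
    spec = draws.logpost.spec
    draws.logpost.network.treatment_index(treatment)
    needed = list(dict.fromkeys(spec.covariates))
    missing = [c for c in needed if c not in population.covariates]
    if missing:
        raise ValueError(
            f"population {population.name!r} lacks covariates {missing} needed "
            "for absolute predictions"
        )
    mu = _baseline_draws(draws, population)
    gamma = draws.gamma_draws()[treatment]
    beta2 = draws.beta2_draws()[treatment]
    beta1 = draws.beta1_draws()

    X_prog = population.matrix(spec.prognostic)  # (N, d1)
    X_em = population.matrix(spec.effect_modifiers)  # (N, d2)
    n = draws.n_draws
    link = spec.link if spec.likelihood == "bernoulli" else {
        "normal": "identity", "poisson": "log"
    }[spec.likelihood]
    out = np.empty(n)
    for start in range(0, n, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n))
        eta = mu[sl, None] + gamma[sl, None]
        if X_prog.shape[1]:
            eta = eta + beta1[sl] @ X_prog.T
        if X_em.shape[1]:
            eta = eta + beta2[sl] @ X_em.T
        out[sl] = inverse_link(eta, link).mean(axis=1)
    return PopulationEstimate("absolute", (treatment,), population.name, out,
                              label=treatment)


def all_pairwise(
    draws: PosteriorDraws,
    population: TargetPopulation,
    include_absolute: bool | None = None,
) -> pd.DataFrame:
    """Contrast table for every treatment pair, plus absolute outcomes.

    Returns a tidy frame (population, kind, label, mean, sd, 2.5%, 97.5%);
    the K(K-1)/2 contrasts satisfy d_ab + d_bc = d_ac exactly per draw by
    construction.  Absolute outcomes are included when the population has a
    baseline source (or ``include_absolute=True``).
    """
    trts = [t.id for t in draws.logpost.network.treatments]
    rows = []
    for i, a in enumerate(trts):
        for b in trts[i + 1:]:
            rows.append(population_contrast(draws, population, a, b).summary_row())
    if include_absolute is None:
        include_absolute = population.baseline is not None
    if include_absolute:
        for t in trts:
            rows.append(population_absolute(draws, population, t).summary_row())
    return pd.DataFrame(rows)
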
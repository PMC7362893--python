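"""Fixed quasi-Monte-Carlo integration grids for aggregate-data studies.

An aggregate study reports only marginal covariate summaries (mean/SD or a
proportion).  To evaluate the aggregate-level model we need the joint
covariate distribution, so each marginal is given a parametric family
(moment matched to the published summaries), the missing correlation
structure is borrowed from the pooled IPD studies on the Spearman rank
scale, and a Gaussian copula combines the two.  A scrambled Sobol'
sequence in the unit hypercube is pushed through inverse-normal transform,
Cholesky correlation, normal CDF and finally each marginal's quantile
function.  The resulting point set is generated once per study and held
fixed across every posterior evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import qmc

from .data import IPDStudy

_EIG_FLOOR = 1e-8


@dataclass
class MarginalSpec:
    """A parametric marginal distribution matched to published summaries.

    Families
    --------
    ``normal``
        mean/sd as given.
    ``gamma``
        moment matched: shape = (mean/sd)^2, rate = mean/sd^2; for
        right-skewed covariates such as weight or disease duration.
    ``logitnormal``
        scaled logit-normal on ``support`` (default [0, 100]); for bounded
        percentage covariates.  Parameters are found by numerically
        matching the declared mean and sd on the observed scale.
    ``bernoulli``
        a proportion in [0, 1].
    """

    name: str
    family: str
    params: dict[str, float]
    support: tuple[float, float] | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def normal(cls, name: str, mean: float, sd: float) -> "MarginalSpec":
        if sd <= 0:
            raise ValueError(f"{name}: normal marginal requires sd > 0")
        return cls(name, "normal", {"mean": float(mean), "sd": float(sd)})

    @classmethod
    def gamma(cls, name: str, mean: float, sd: float) -> "MarginalSpec":
        if mean <= 0 or sd <= 0:
            raise ValueError(f"{name}: gamma marginal requires mean > 0 and sd > 0")
        shape = (mean / sd) ** 2
        rate = mean / sd**2
        return cls(name, "gamma", {"shape": shape, "rate": rate})

    @classmethod
    def bernoulli(cls, name: str, prop: float) -> "MarginalSpec":
        if not 0.0 <= prop <= 1.0:
            raise ValueError(f"{name}: proportion {prop} outside [0, 1]")
        return cls(name, "bernoulli", {"prop": float(prop)})

    @classmethod
    def logitnormal(
        cls,
        name: str,
        mean: float,
        sd: float,
        support: tuple[float, float] = (0.0, 100.0),
    ) -> "MarginalSpec":
        lo, hi = support
        if not lo < mean < hi:
            raise ValueError(f"{name}: mean {mean} outside support {support}")
        mu, sigma = _match_logitnormal(mean, sd, lo, hi)
        return cls(name, "logitnormal", {"mu": mu, "sigma": sigma}, support=(lo, hi))

    # -- distribution interface -------------------------------------------
    def ppf(self, u: np.ndarray) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return stats.norm.ppf(u, loc=p["mean"], scale=p["sd"])
        if self.family == "gamma":
            return stats.gamma.ppf(u, a=p["shape"], scale=1.0 / p["rate"])
        if self.family == "bernoulli":
            # latent normal thresholded at the (1 - prop) quantile
            return (u > 1.0 - p["prop"]).astype(float)
        if self.family == "logitnormal":
            lo, hi = self.support
            return lo + (hi - lo) * special.expit(
                p["mu"] + p["sigma"] * stats.norm.ppf(u)
            )
        raise ValueError(f"unknown marginal family {self.family!r}")

    def cdf(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return stats.norm.cdf(x, loc=p["mean"], scale=p["sd"])
        if self.family == "gamma":
            return stats.gamma.cdf(x, a=p["shape"], scale=1.0 / p["rate"])
        if self.family == "logitnormal":
            lo, hi = self.support
            z = (special.logit((np.asarray(x) - lo) / (hi - lo)) - p["mu"]) / p["sigma"]
            return stats.norm.cdf(z)
        raise ValueError(f"cdf not defined for family {self.family!r}")

    def mean(self) -> float:
        p = self.params
        if self.family == "normal":
            return p["mean"]
        if self.family == "gamma":
            return p["shape"] / p["rate"]
        if self.family == "bernoulli":
            return p["prop"]
        if self.family == "logitnormal":
            m, _ = _logitnormal_moments(p["mu"], p["sigma"], *self.support)
            return m
        raise ValueError(self.family)

    def sd(self) -> float:
        p = self.params
        if self.family == "normal":
            return p["sd"]
        if self.family == "gamma":
            return np.sqrt(p["shape"]) / p["rate"]
        if self.family == "bernoulli":
            return float(np.sqrt(p["prop"] * (1 - p["prop"])))
        if self.family == "logitnormal":
            _, s = _logitnormal_moments(p["mu"], p["sigma"], *self.support)
            return s
        raise ValueError(self.family)

    def to_dict(self) -> dict:
        d = {"name": self.name, "family": self.family, "params": self.params}
        if self.support is not None:
            d["support"] = list(self.support)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalSpec":
        support = tuple(d["support"]) if d.get("support") else None
        return cls(d["name"], d["family"], dict(d["params"]), support)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(96)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)


def _logitnormal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean/sd of lo + (hi-lo)*expit(Z), Z ~ N(mu, sigma^2), by Gauss-Hermite."""
    vals = lo + (hi - lo) * special.expit(mu + sigma * _GH_NODES)
    m = float(np.sum(_GH_WEIGHTS * vals))
    v = float(np.sum(_GH_WEIGHTS * (vals - m) ** 2))
    return m, np.sqrt(v)


def _match_logitnormal(mean: float, sd: float, lo: float, hi: float):
    target = np.array([mean, sd])

    def resid(theta):
        m, s = _logitnormal_moments(theta[0], np.exp(theta[1]), lo, hi)
        return np.array([m, s]) - target

    x0 = np.array([special.logit((mean - lo) / (hi - lo)), np.log(4 * sd / (hi - lo))])
    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    m, s = _logitnormal_moments(sol.x[0], np.exp(sol.x[1]), lo, hi)
    if abs(m - mean) > 1e-2 * max(1.0, abs(mean)) or abs(s - sd) > 1e-2 * max(1.0, sd):
        raise ValueError(
            f"logit-normal moment matching failed: target ({mean}, {sd}) vs ({m}, {s})"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def marginals_from_summaries(
    summaries: Mapping[str, Mapping[str, float]],
    families: Mapping[str, str],
    supports: Mapping[str, tuple[float, float]] | None = None,
) -> list[MarginalSpec]:
    """Build marginal specs for an AgD study from its covariate summaries."""
    supports = supports or {}
    out = []
    for name, family in families.items():
        if name not in summaries:
            raise KeyError(f"no covariate summary for {name!r}")
        summ = summaries[name]
        if family == "bernoulli":
            out.append(MarginalSpec.bernoulli(name, summ["prop"]))
        elif family == "normal":
            out.append(MarginalSpec.normal(name, summ["mean"], summ["sd"]))
        elif family == "gamma":
            out.append(MarginalSpec.gamma(name, summ["mean"], summ["sd"]))
        elif family == "logitnormal":
            out.append(
                MarginalSpec.logitnormal(
                    name, summ["mean"], summ["sd"], supports.get(name, (0.0, 100.0))
                )
            )
        else:
            raise ValueError(f"unknown family {family!r} for covariate {name!r}")
    return out


def sobol_unit_points(n_points: int, dim: int, seed: int) -> np.ndarray:
    """Scrambled Sobol' points in [0, 1)^dim; deterministic given the seed.

    Scrambling (Owen) both randomizes the sequence reproducibly and avoids
    the unscrambled first point at the origin, which would map to -inf
    under the inverse normal CDF.
    """
    if n_points < 1 or dim < 1:
        raise ValueError("n_points and dim must be >= 1")
    engine = qmc.Sobol(d=dim, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # balance warning for sample sizes that are not powers of two
        warnings.simplefilter("ignore", UserWarning)
        return engine.random(n_points)


def spearman_to_copula(rho_s):
    """Latent Gaussian correlation implied by a Spearman rank correlation.

    For a bivariate Gaussian copula, rho_s = (6/pi) arcsin(rho/2), inverted
    here as rho = 2 sin(pi rho_s / 6).  Monotone and odd on [-1, 1].
    """
    rho_s = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(rho_s) > 1.0):
        raise ValueError("Spearman correlation outside [-1, 1]")
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def nearest_psd(mat: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CorrelationModel:
    """Rank correlations pooled from IPD plus the implied copula matrix."""

    names: tuple[str, ...]
    spearman: np.ndarray
    copula: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        s = np.asarray(self.spearman, dtype=float)
        if s.shape != (len(self.names), len(self.names)):
            raise ValueError("correlation matrix shape does not match names")
        if not np.allclose(s, s.T) or not np.allclose(np.diag(s), 1.0):
            raise ValueError("Spearman matrix must be symmetric with unit diagonal")
        self.spearman = s
        self.copula = nearest_psd(spearman_to_copula(s))

    @classmethod
    def independent(cls, names: Sequence[str]) -> "CorrelationModel":
        return cls(tuple(names), np.eye(len(names)))

    def subset(self, names: Sequence[str]) -> "CorrelationModel":
        idx = [self.names.index(n) for n in names]
        return CorrelationModel(tuple(names), self.spearman[np.ix_(idx, idx)])


def estimate_ipd_correlation(
    ipd_studies: Sequence[IPDStudy], covariates: Sequence[str]
) -> CorrelationModel:
    """Pool Spearman rank correlations across IPD studies, weighting by size.

    Study-specific matrices are combined with weights proportional to the
    study sample sizes; the copula matrix follows elementwise via the sin
    transform with a PSD repair.
    """
    covariates = tuple(covariates)
    if len(covariates) < 2:
        raise ValueError("need at least two covariates to estimate correlations")
    total_n = sum(s.n for s in ipd_studies)
    if total_n < 3:
        raise ValueError("need at least three pooled individuals")
    acc = np.zeros((len(covariates), len(covariates)))
    for s in ipd_studies:
        block = s.data[list(covariates)].to_numpy(dtype=float)
        sds = block.std(axis=0)
        if np.any(sds == 0):
            bad = covariates[int(np.flatnonzero(sds == 0)[0])]
            raise ValueError(
                f"covariate {bad!r} is constant in study {s.study_id!r}; "
                "its rank correlation is undefined"
            )
        rho = stats.spearmanr(block).statistic
        rho = np.atleast_2d(rho)
        acc += (s.n / total_n) * rho
    np.fill_diagonal(acc, 1.0)
    return CorrelationModel(covariates, acc)


@dataclass
class IntegrationGrid:
    """A fixed matrix of integration points for one aggregate study."""

    study_id: str
    names: tuple[str, ...]
    points: np.ndarray  # shape (n_points, d)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != len(self.names):
            raise ValueError("points must be (n_points, n_covariates)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.points[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=list(self.names))

    def save(self, csv_path, meta: dict | None = None) -> None:
        """Write the grid as CSV plus a JSON provenance sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {"study_id": self.study_id, "n_points": self.n_points}
        sidecar.update(meta or {})
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, csv_path) -> "IntegrationGrid":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(meta["study_id"], tuple(df.columns), df.to_numpy())


def build_grid(
    study_id: str,
    marginals: Sequence[MarginalSpec],
    corr: CorrelationModel | None = None,
    n_points: int = 10_000,
    seed: int = 0,
) -> IntegrationGrid:
    """Generate the fixed QMC point set for one aggregate study.

    Unit-cube Sobol' points are mapped to correlated standard normals via
    the Cholesky factor of the copula correlation matrix, back to
    correlated uniforms via the normal CDF, and finally through each
    marginal's quantile function.  The copula step never alters a column's
    marginal distribution.
    """
    names = tuple(m.name for m in marginals)
    d = len(marginals)
    u = sobol_unit_points(n_points, d, seed)
    if corr is not None:
        order = [corr.names.index(n) for n in names]
        cop = corr.copula[np.ix_(order, order)]
        try:
            chol = np.linalg.cholesky(cop)
        except np.linalg.LinAlgError:
            cop = nearest_psd(cop)
            chol = np.linalg.cholesky(cop + 1e-10 * np.eye(d))
        z = special.ndtri(u) @ chol.T
        u = special.ndtr(z)
    cols = [m.ppf(u[:, i]) for i, m in enumerate(marginals)]
    return IntegrationGrid(study_id, names, np.column_stack(cols))


def degenerate_grid(study_id: str, names: Sequence[str] = ()) -> IntegrationGrid:
    """A single-point, zero-covariate grid (no-covariate special case)."""
    return IntegrationGrid(study_id, tuple(names), np.zeros((1, len(names))))
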
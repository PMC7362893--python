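"""Individual- and aggregate-level model for multilevel network meta-regression.

The individual-level model is a generalized linear model

    g(theta_ijk) = eta_jk(x_ijk) = mu_j + x' (beta1 + beta2_k) + gamma_k

with study baselines mu_j, prognostic coefficients beta1, treatment-specific
effect-modifier interactions beta2_k and individual-level relative effects
gamma_k (gamma_1 = 0 and beta2_1 = 0 at the network reference).  The
aggregate-level model integrates g^{-1}(eta) over a study's joint covariate
distribution, evaluated here as an average over a fixed QMC grid.

For binary outcomes the exact aggregate likelihood of an event count is
Poisson-binomial; it is approximated by a binomial whose two parameters are
adjusted to match the Poisson-binomial mean and variance:

    N' = N pbar^2 / p2bar,   p' = p2bar / pbar,

where pbar and p2bar are the integrals of the probability and the squared
probability over the covariate distribution.

Random study effects replace gamma_k by delta_jk ~ N(gamma_k, tau^2) with
pairwise correlation 0.5 among the non-reference arms of a multi-arm study
(common heterogeneity variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .data import AgDStudy, IPDStudy, Network, Treatment
from .integration import IntegrationGrid

_EPS = 1e-12

# ---------------------------------------------------------------------------
# links and likelihood atoms
# ---------------------------------------------------------------------------

_LINKS = {
    "probit": {"inv": special.ndtr, "log_inv": special.log_ndtr},
    "logit": {"inv": special.expit, "log_inv": special.log_expit},
    "identity": {"inv": lambda x: x, "log_inv": None},
    "log": {"inv": np.exp, "log_inv": None},
}

_VALID_LINKS = {
    "bernoulli": {"probit", "logit"},
    "normal": {"identity"},
    "poisson": {"log"},
}


def inverse_link(eta, link: str):
    return _LINKS[link]["inv"](np.asarray(eta, dtype=float))


@dataclass
class Priors:
    """Prior scales.  Location parameters get N(0, effect_sd^2); scale
    parameters get half-normal priors."""

    effect_sd: float = 100.0
    tau_sd: float = 2.5
    sigma_beta2_sd: float = 2.5
    sigma_sd: float = 2.5


@dataclass
class ModelSpec:
    """Likelihood, link and effect-structure choices.

    ``em_structure`` maps a treatment class id to one of ``independent``,
    ``shared`` or ``exchangeable``; treatments without a class (or classes
    not listed) get independent interactions.
    """

    likelihood: str = "bernoulli"
    link: str = "probit"
    prognostic: tuple[str, ...] = ()
    effect_modifiers: tuple[str, ...] = ()
    em_structure: dict[str, str] = field(default_factory=dict)
    effects: str = "fixed"
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        self.prognostic = tuple(self.prognostic)
        self.effect_modifiers = tuple(self.effect_modifiers)
        if self.likelihood not in _VALID_LINKS:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.link not in _VALID_LINKS[self.likelihood]:
            raise ValueError(
                f"link {self.link!r} is not valid with a {self.likelihood} likelihood"
            )
        if self.effects not in {"fixed", "random"}:
            raise ValueError("effects must be 'fixed' or 'random'")
        for cls, s in self.em_structure.items():
            if s not in {"independent", "shared", "exchangeable"}:
                raise ValueError(f"unknown effect-modifier structure {s!r} for {cls!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.prognostic + self.effect_modifiers:
            seen.setdefault(c)
        return tuple(seen)


# ---------------------------------------------------------------------------
# simple parameter container + elementary operations
# ---------------------------------------------------------------------------


@dataclass
class Parameters:
    """Named parameter values for direct evaluation of the model.

    ``beta2`` maps treatment id to its interaction vector (reference
    treatment implicitly zero); ``delta`` maps (study_id, treatment_id) to
    study-specific relative effects when random effects are used.
    """

    mu: dict[str, float]
    beta1: np.ndarray
    beta2: dict[str, np.ndarray]
    gamma: dict[str, float]
    delta: dict[tuple[str, str], float] | None = None
    tau: float = 0.0
    sigma: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


def linear_predictor(
    x: np.ndarray, study_id: str, treatment_id: str, params: Parameters, spec: ModelSpec
):
    """eta_jk(x) for covariate row(s) ``x`` aligned with ``spec.covariates``.

    Uses delta_jk when random study effects are present, gamma_k otherwise;
    the reference treatment contributes zero interaction and zero effect.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(spec.covariates):
        raise ValueError(
            f"covariate vector has {x.shape[1]} entries, expected {len(spec.covariates)}"
        )
    if study_id not in params.mu:
        raise KeyError(f"unknown study {study_id!r}")
    cov_idx = {c: i for i, c in enumerate(spec.covariates)}
    coef = np.zeros(x.shape[1])
    for b, c in zip(params.beta1, spec.prognostic):
        coef[cov_idx[c]] += b
    b2 = params.beta2.get(treatment_id)
    if b2 is not None:
        for b, c in zip(b2, spec.effect_modifiers):
            coef[cov_idx[c]] += b
    if params.delta is not None:
        effect = params.delta.get((study_id, treatment_id), 0.0)
    else:
        effect = params.gamma.get(treatment_id, 0.0)
    eta = params.mu[study_id] + x @ coef + effect
    return eta if eta.size > 1 else float(eta[0])


@dataclass
class AggregateMoments:
    """Mean probability and mean squared probability over a population."""

    pbar: float
    p2bar: float

    def __post_init__(self) -> None:
        self.pbar = float(np.clip(self.pbar, _EPS, 1.0 - _EPS))
        self.p2bar = float(np.clip(self.p2bar, self.pbar**2, self.pbar))


def moments_from_eta(eta: np.ndarray, link: str) -> AggregateMoments:
    """pbar and p2bar by averaging g^{-1}(eta) and its square over the grid."""
    if link not in {"probit", "logit"}:
        raise ValueError("aggregate outcome moments require a probit or logit link")
    eta = np.asarray(eta, dtype=float)
    if eta.size == 0:
        raise ValueError("empty integration grid")
    p = inverse_link(eta, link)
    return AggregateMoments(float(p.mean()), float((p**2).mean()))


def aggregate_moments(
    grid: IntegrationGrid,
    study_id: str,
    treatment_id: str,
    params: Parameters,
    spec: ModelSpec,
) -> AggregateMoments:
    """Integrate the individual model over a study's covariate grid."""
    order = [grid.names.index(c) for c in spec.covariates]
    x = grid.points[:, order]
    eta = linear_predictor(x, study_id, treatment_id, params, spec)
    return moments_from_eta(np.atleast_1d(eta), spec.link)


def two_param_binomial(n: float, moments: AggregateMoments) -> tuple[float, float]:
    """Binomial (N', p') matching the Poisson-binomial mean and variance.

    N' = N pbar^2 / p2bar and p' = p2bar / pbar, so that N'p' = N pbar and
    N'p'(1-p') = N (pbar - p2bar) = sum_i p_i (1 - p_i).  N' <= N always,
    with equality iff the individual probabilities are homogeneous.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    pbar, p2bar = moments.pbar, moments.p2bar
    if not (pbar**2 - 1e-9 <= p2bar <= pbar + 1e-9):
        raise ValueError(f"invalid moments: pbar={pbar}, p2bar={p2bar}")
    return n * pbar**2 / p2bar, float(np.clip(p2bar / pbar, _EPS, 1 - _EPS))


def individual_loglik(y, theta, likelihood: str, sigma: float | None = None):
    """Log-likelihood of one individual outcome given its conditional mean."""
    if likelihood == "bernoulli":
        theta = np.asarray(theta, dtype=float)
        if np.any((theta <= 0) | (theta >= 1)):
            raise ValueError("Bernoulli probability must lie strictly in (0, 1)")
        return y * np.log(theta) + (1 - y) * np.log1p(-theta)
    if likelihood == "normal":
        if sigma is None or sigma <= 0:
            raise ValueError("normal likelihood requires sigma > 0")
        return stats.norm.logpdf(y, loc=theta, scale=sigma)
    if likelihood == "poisson":
        return stats.poisson.logpmf(y, theta)
    raise ValueError(f"unknown likelihood {likelihood!r}")


def _binom_logpmf_real_n(y, n_prime, p):
    """Binomial log-pmf generalized to real-valued size via log-gamma."""
    y = np.asarray(y, dtype=float)
    n_prime = np.asarray(n_prime, dtype=float)
    if np.any(y > n_prime):
        warnings.warn(
            "event count exceeds adjusted binomial size N'; using the "
            "continuous log-gamma extension",
            stacklevel=3,
        )
    return (
        special.gammaln(n_prime + 1)
        - special.gammaln(y + 1)
        - special.gammaln(np.abs(n_prime - y) + 1)
        + y * np.log(p)
        + (n_prime - y) * np.log1p(-p)
    )


def aggregate_loglik(
    y,
    n,
    moments: AggregateMoments | None,
    likelihood: str,
    se: float | None = None,
    theta: float | None = None,
):
    """Log-likelihood of one aggregate arm summary.

    Binary arms use the two-parameter-adjusted binomial; continuous arms
    use N(theta, se^2); count arms use Poisson with the summed rate.
    """
    if likelihood == "bernoulli":
        if moments is None:
            raise ValueError("binary aggregate likelihood requires outcome moments")
        n_prime, p_prime = two_param_binomial(n, moments)
        return float(_binom_logpmf_real_n(y, n_prime, p_prime))
    if likelihood == "normal":
        if se is None or se <= 0:
            raise ValueError("normal aggregate likelihood requires a standard error")
        return float(stats.norm.logpdf(y, loc=theta, scale=se))
    if likelihood == "poisson":
        return float(stats.poisson.logpmf(y, theta))
    raise ValueError(f"unknown likelihood {likelihood!r}")


def random_effects_cov(tau: float, n_nonref_arms: int) -> np.ndarray:
    """Covariance of the study random effects: tau^2 diagonal, tau^2/2 off it.

    The 0.5 correlation between arms of a multi-arm study follows from the
    common heterogeneity variance assumption.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if n_nonref_arms < 1:
        raise ValueError("need at least one non-reference arm")
    m = np.full((n_nonref_arms, n_nonref_arms), tau**2 / 2.0)
    np.fill_diagonal(m, tau**2)
    return m


def consistency_expand(
    gamma: Mapping[str, float], beta2: Mapping[str, np.ndarray] | None = None
):
    """All pairwise contrasts from reference-indexed effects.

    gamma_ab = gamma_b - gamma_a and beta2_ab = beta2_b - beta2_a; the
    resulting tables are antisymmetric and satisfy the triangle identity
    gamma_ab + gamma_bc = gamma_ac exactly.
    """
    trts = list(gamma)
    out = {}
    for a in trts:
        for b in trts:
            if a == b:
                continue
            entry = {"gamma": gamma[b] - gamma[a]}
            if beta2 is not None:
                entry["beta2"] = np.asarray(beta2[b]) - np.asarray(beta2[a])
            out[(a, b)] = entry
    return out


# ---------------------------------------------------------------------------
# effect-modifier tying structure
# ---------------------------------------------------------------------------


@dataclass
class EMStructure:
    """How interaction vectors are tied across treatments.

    ``groups`` lists the treatments sharing each beta2 vector (one group per
    treatment under independent/exchangeable structures, one per class under
    sharing); ``group_of`` maps non-reference treatment id to group index;
    ``exchangeable`` maps class id to the group indices drawn from that
    class-level normal.
    """

    groups: list[tuple[str, ...]]
    group_of: dict[str, int]
    exchangeable: dict[str, list[int]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def effect_modifier_structure(
    treatments: Sequence[Treatment], em_structure: Mapping[str, str]
) -> EMStructure:
    """Build the beta2 tying map from treatment classes.

    Unclassed treatments (and classes declared ``independent``) each get
    their own interaction vector; ``shared`` classes get a single vector;
    ``exchangeable`` classes get per-treatment vectors drawn from a
    class-level normal (at least two members required, otherwise the
    class-level variance is unidentifiable).
    """
    nonref = [t for t in treatments if not t.is_reference]
    groups: list[tuple[str, ...]] = []
    group_of: dict[str, int] = {}
    exchangeable: dict[str, list[int]] = {}

    by_class: dict[str | None, list[str]] = {}
    for t in nonref:
        by_class.setdefault(t.class_id, []).append(t.id)

    for cls, members in by_class.items():
        structure = "independent" if cls is None else em_structure.get(cls, "independent")
        if structure == "shared":
            idx = len(groups)
            groups.append(tuple(members))
            for m in members:
                group_of[m] = idx
        elif structure == "exchangeable":
            if len(members) < 2:
                raise ValueError(
                    f"exchangeable class {cls!r} has {len(members)} treatment(s); "
                    "the class-level variance is unidentifiable with fewer than two"
                )
            exchangeable[cls] = []
            for m in members:
                idx = len(groups)
                groups.append((m,))
                group_of[m] = idx
                exchangeable[cls].append(idx)
        else:
            for m in members:
                idx = len(groups)
                groups.append((m,))
                group_of[m] = idx
    return EMStructure(groups, group_of, exchangeable)


# ---------------------------------------------------------------------------
# packed parameter layout and vectorized joint log-density
# ---------------------------------------------------------------------------


def _re_chol(n: int) -> np.ndarray:
    """Cholesky factor of the unit-variance 0.5-correlation matrix."""
    c = np.full((n, n), 0.5)
    np.fill_diagonal(c, 1.0)
    return np.linalg.cholesky(c)


@dataclass
class _IPDArm:
    j: int
    study_id: str
    treatment_id: str
    trt_idx: int
    group: int | None  # beta2 group, None for reference
    X: np.ndarray  # (n, d_all) covariate block
    y: np.ndarray
    effect_col: int | None  # column into the per-study effect table


@dataclass
class _AgDArm:
    j: int
    study_id: str
    treatment_id: str
    trt_idx: int
    group: int | None
    X: np.ndarray  # (n_points, d_all) integration grid
    y: float
    n: float
    se: float | None
    effect_col: int | None


class LogPosterior:
    """Joint log-density of the ML-NMR model, vectorized over parameter rows.

    Calling the object with a ``(m, ndim)`` array returns ``m`` log posterior
    densities; the integration grids are fixed at construction and reused at
    every evaluation.  ``ume=True`` swaps the consistency-constrained
    relative effects for independent per-design baseline contrasts
    (unrelated mean effects model) while keeping the interaction structure.
    """

    def __init__(
        self,
        network: Network,
        spec: ModelSpec,
        grids: Mapping[str, IntegrationGrid] | None = None,
        ume: bool = False,
        center: bool = True,
    ):
        self.network = network
        self.spec = spec
        self.ume = ume
        self.center = center
        grids = grids or {}
        self.studies = network.fit_studies
        if not self.studies:
            raise ValueError("no multi-arm studies available for fitting")
        self.J = len(self.studies)
        self._study_idx = {s.study_id: j for j, s in enumerate(self.studies)}
        self.em = effect_modifier_structure(network.treatments, spec.em_structure)
        self.d1 = len(spec.prognostic)
        self.d2 = len(spec.effect_modifiers)
        self.d_all = len(spec.covariates)
        cov_idx = {c: i for i, c in enumerate(spec.covariates)}
        self._prog_cols = np.array([cov_idx[c] for c in spec.prognostic], dtype=int)
        self._em_cols = np.array([cov_idx[c] for c in spec.effect_modifiers], dtype=int)

        # Centring point: pooled IPD covariate mean (grid means if no IPD).
        # The likelihood is evaluated on x - xbar, which removes the near
        # collinearity between the treatment effects and the interactions;
        # reported draws are translated back to the natural scale exactly.
        self.xbar = np.zeros(self.d_all)
        if center and self.d_all:
            blocks = [
                s.data[list(spec.covariates)].to_numpy(dtype=float)
                for s in self.studies
                if isinstance(s, IPDStudy)
            ]
            if blocks:
                pooled = np.concatenate(blocks, axis=0)
                self.xbar = pooled.mean(axis=0)
            else:
                gs = [grids[s.study_id] for s in self.studies
                      if isinstance(s, AgDStudy) and s.study_id in grids]
                if gs:
                    self.xbar = np.mean(
                        [g.points[:, [g.names.index(c) for c in spec.covariates]].mean(axis=0)
                         for g in gs],
                        axis=0,
                    )

        nonref = [t.id for t in network.treatments[1:]]
        self._gamma_idx = {t: i for i, t in enumerate(nonref)}

        # UME: one free effect per observed (study-baseline treatment, treatment)
        # pair, shared across studies with the same baseline.
        self._ume_pairs: dict[tuple[str, str], int] = {}

        self.ipd_arms: list[_IPDArm] = []
        self.agd_arms: list[_AgDArm] = []
        self._re_blocks: list[tuple[int, list[int], np.ndarray]] = []
        n_z = 0

        for j, s in enumerate(self.studies):
            if isinstance(s, IPDStudy):
                arm_keys = list(dict.fromkeys(s.data["treatment"]))
            else:
                arm_keys = list(s.arms["treatment"])
            baseline = min(arm_keys, key=network.treatment_index)
            effect_cols: dict[str, int | None] = {}
            re_cols: list[int] = []
            for t in arm_keys:
                k = network.treatment_index(t)
                if ume:
                    if t == baseline:
                        effect_cols[t] = None
                    else:
                        pair = (baseline, t)
                        if pair not in self._ume_pairs:
                            self._ume_pairs[pair] = len(self._ume_pairs)
                        effect_cols[t] = self._ume_pairs[pair]
                else:
                    effect_cols[t] = None if k == 0 else self._gamma_idx[t]
            if spec.effects == "random" and not ume:
                arms_with_effect = [t for t in arm_keys if effect_cols[t] is not None]
                for t in arms_with_effect:
                    re_cols.append(n_z)
                    n_z += 1
                if arms_with_effect:
                    self._re_blocks.append(
                        (j, re_cols, _re_chol(len(arms_with_effect)))
                    )

            re_map = {}
            if spec.effects == "random" and not ume:
                arms_with_effect = [t for t in arm_keys if effect_cols[t] is not None]
                re_map = {t: c for t, c in zip(arms_with_effect, re_cols)}

            for t in arm_keys:
                k = network.treatment_index(t)
                group = None if k == 0 else self.em.group_of.get(t)
                ecol = re_map.get(t, effect_cols[t]) if (
                    spec.effects == "random" and not ume
                ) else effect_cols[t]
                if isinstance(s, IPDStudy):
                    rows = s.data[s.data["treatment"] == t]
                    X = rows[list(spec.covariates)].to_numpy(dtype=float) - self.xbar if self.d_all else np.zeros((len(rows), 0))
                    self.ipd_arms.append(
                        _IPDArm(j, s.study_id, t, k, group, X,
                                rows["y"].to_numpy(dtype=float), ecol)
                    )
                else:
                    if s.study_id in grids:
                        g = grids[s.study_id]
                        order = [g.names.index(c) for c in spec.covariates]
                        X = g.points[:, order] - self.xbar
                    elif self.d_all == 0:
                        X = np.zeros((1, 0))
                    else:
                        raise ValueError(
                            f"no integration grid supplied for AgD study {s.study_id!r}"
                        )
                    row = s.arms[s.arms["treatment"] == t].iloc[0]
                    se = float(row["se"]) if "se" in s.arms.columns else None
                    self.agd_arms.append(
                        _AgDArm(j, s.study_id, t, k, group, X, float(row["y"]),
                                float(row["n"]), se, ecol)
                    )

        # --- flat layout ---------------------------------------------------
        self.names: list[str] = []
        self._slices: dict[str, slice] = {}

        def add(name: str, labels: list[str]) -> None:
            start = len(self.names)
            self.names.extend(f"{name}[{lab}]" if lab else name for lab in labels)
            self._slices[name] = slice(start, len(self.names))

        add("mu", [s.study_id for s in self.studies])
        if self.d1:
            add("beta1", list(spec.prognostic))
        if self.d2 and self.em.n_groups:
            add(
                "beta2",
                [
                    f"{'+'.join(g)};{c}"
                    for g in self.em.groups
                    for c in spec.effect_modifiers
                ],
            )
        if ume:
            add("d_ume", [f"{a}:{b}" for a, b in self._ume_pairs])
        else:
            add("gamma", nonref)
        if spec.effects == "random" and not ume:
            add("tau", [""])
            if n_z:
                add("z_re", [str(i) for i in range(n_z)])
        self._n_z = n_z
        for cls, gidx in self.em.exchangeable.items():
            add(f"m_beta2[{cls}]", list(spec.effect_modifiers))
            add(f"sigma_beta2[{cls}]", list(spec.effect_modifiers))
        if spec.likelihood == "normal":
            add("sigma", [s.study_id for s in self.studies if isinstance(s, IPDStudy)])
        self.ndim = len(self.names)

    # -- unpacking ---------------------------------------------------------
    def _get(self, theta: np.ndarray, name: str) -> np.ndarray:
        sl = self._slices.get(name)
        if sl is None:
            return np.zeros((theta.shape[0], 0))
        return theta[:, sl]

    def _effects_table(self, theta: np.ndarray) -> np.ndarray:
        """Per-row table of arm effects: gamma, UME contrasts, or delta."""
        if self.ume:
            return self._get(theta, "d_ume")
        gamma = self._get(theta, "gamma")
        if self.spec.effects == "fixed":
            return gamma
        tau = self._get(theta, "tau")[:, 0]
        z = self._get(theta, "z_re")
        # non-centred: delta_jk = gamma_k + tau * (L z_j)_k, with the 0.5
        # correlation structure entering through L; gamma_k is added
        # arm-wise in _arm_effect.
        delta = np.empty((theta.shape[0], self._n_z))
        for j, cols, chol in self._re_blocks:
            zj = z[:, cols]
            delta[:, cols] = (zj @ chol.T) * tau[:, None]
        return delta

    def _arm_effect(self, theta, effects, arm) -> np.ndarray:
        if arm.effect_col is None:
            return np.zeros(theta.shape[0])
        e = effects[:, arm.effect_col]
        if self.spec.effects == "random" and not self.ume and arm.trt_idx != 0:
            e = e + self._get(theta, "gamma")[:, self._gamma_idx[arm.treatment_id]]
        return e

    def _beta2_rows(self, theta: np.ndarray) -> np.ndarray:
        """(m, n_groups, d2) interaction vectors."""
        m = theta.shape[0]
        if not (self.d2 and self.em.n_groups):
            return np.zeros((m, 0, self.d2))
        return self._get(theta, "beta2").reshape(m, self.em.n_groups, self.d2)

    def _eta(self, theta, arm, effects, beta2) -> np.ndarray:
        """(m, n_rows) linear predictor for one arm."""
        m = theta.shape[0]
        mu = self._get(theta, "mu")[:, arm.j]
        coef = np.zeros((m, self.d_all))
        if self.d1:
            coef[:, self._prog_cols] += self._get(theta, "beta1")
        if arm.group is not None and self.d2:
            coef[:, self._em_cols] += beta2[:, arm.group, :]
        eta = mu[:, None] + coef @ arm.X.T
        return eta + self._arm_effect(theta, effects, arm)[:, None]

    # -- densities -----------------------------------------------------------
    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        p = self.spec.priors
        m = theta.shape[0]
        out = np.zeros(m)
        loc_names = ["mu", "beta1", "gamma", "d_ume"]
        for name in loc_names:
            block = self._get(theta, name)
            if block.size:
                out += stats.norm.logpdf(block, scale=p.effect_sd).sum(axis=1)
        beta2 = self._get(theta, "beta2")
        if beta2.size:
            if self.em.exchangeable:
                # exchangeable groups get their class-level normal below;
                # remaining groups get the fixed prior
                exch_groups = {g for gs in self.em.exchangeable.values() for g in gs}
                b2 = beta2.reshape(m, self.em.n_groups, self.d2)
                for g in range(self.em.n_groups):
                    if g not in exch_groups:
                        out += stats.norm.logpdf(b2[:, g, :], scale=p.effect_sd).sum(axis=1)
                for cls, gidx in self.em.exchangeable.items():
                    mb = self._get(theta, f"m_beta2[{cls}]")
                    sb = self._get(theta, f"sigma_beta2[{cls}]")
                    bad = (sb <= 0).any(axis=1)
                    out = np.where(bad, -np.inf, out)
                    sb_safe = np.where(sb > 0, sb, 1.0)
                    out += stats.norm.logpdf(mb, scale=p.effect_sd).sum(axis=1)
                    out += stats.halfnorm.logpdf(sb_safe, scale=p.sigma_beta2_sd).sum(axis=1)
                    for g in gidx:
                        out += stats.norm.logpdf(
                            b2[:, g, :], loc=mb, scale=sb_safe
                        ).sum(axis=1)
            else:
                out += stats.norm.logpdf(beta2, scale=p.effect_sd).sum(axis=1)
        if self.spec.effects == "random" and not self.ume:
            tau = self._get(theta, "tau")[:, 0]
            out = np.where(tau < 0, -np.inf, out)
            tau_safe = np.where(tau >= 0, tau, 0.0)
            out += stats.halfnorm.logpdf(tau_safe, scale=p.tau_sd)
            z = self._get(theta, "z_re")
            if z.size:
                out += stats.norm.logpdf(z).sum(axis=1)
        sig = self._get(theta, "sigma")
        if sig.size:
            bad = (sig <= 0).any(axis=1)
            out = np.where(bad, -np.inf, out)
            sig_safe = np.where(sig > 0, sig, 1.0)
            out += stats.halfnorm.logpdf(sig_safe, scale=p.sigma_sd).sum(axis=1)
        return out

    def _arm_loglik(self, theta, arm, effects, beta2) -> np.ndarray:
        """(m,) log-likelihood of one arm (summed over individuals for IPD)."""
        lik = self.spec.likelihood
        eta = self._eta(theta, arm, effects, beta2)
        if isinstance(arm, _IPDArm):
            if lik == "bernoulli":
                # y log g^{-1}(eta) + (1-y) log g^{-1}(-eta) = log g^{-1}((2y-1) eta)
                # for symmetric links (probit, logit)
                log_inv = _LINKS[self.spec.link]["log_inv"]
                return log_inv((2.0 * arm.y - 1.0)[None, :] * eta).sum(axis=1)
            if lik == "normal":
                sig_ids = [s.study_id for s in self.studies if isinstance(s, IPDStudy)]
                sig = self._get(theta, "sigma")[:, sig_ids.index(arm.study_id)]
                resid2 = ((arm.y[None, :] - eta) ** 2).sum(axis=1)
                n = arm.y.size
                return -0.5 * resid2 / sig**2 - n * np.log(sig) - 0.5 * n * np.log(2 * np.pi)
            if lik == "poisson":
                lam = np.exp(eta)
                return (arm.y[None, :] * eta - lam).sum(axis=1) - special.gammaln(
                    arm.y + 1
                ).sum()
        else:
            if lik == "bernoulli":
                p = inverse_link(eta, self.spec.link)
                pbar = np.clip(p.mean(axis=1), _EPS, 1 - _EPS)
                p2bar = np.clip((p**2).mean(axis=1), pbar**2, pbar)
                n_prime = arm.n * pbar**2 / p2bar
                p_prime = np.clip(p2bar / pbar, _EPS, 1 - _EPS)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    return _binom_logpmf_real_n(arm.y, n_prime, p_prime)
            if lik == "normal":
                theta_bar = eta.mean(axis=1)
                se = arm.se if arm.se is not None else 1.0 / np.sqrt(arm.n)
                return stats.norm.logpdf(arm.y, loc=theta_bar, scale=se)
            if lik == "poisson":
                rate = arm.n * np.exp(eta).mean(axis=1)
                return arm.y * np.log(rate) - rate - special.gammaln(arm.y + 1)
        raise ValueError(lik)

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        effects = self._effects_table(theta)
        beta2 = self._beta2_rows(theta)
        out = np.zeros(theta.shape[0])
        for arm in self.ipd_arms:
            out += self._arm_loglik(theta, arm, effects, beta2)
        for arm in self.agd_arms:
            out += self._arm_loglik(theta, arm, effects, beta2)
        return out

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.log_prior(theta)
        ok = np.isfinite(lp)
        if ok.any():
            lp[ok] = lp[ok] + self.log_likelihood(theta[ok])
        return lp

    # -- pointwise contributions (for deviance / DIC) ------------------------
    @property
    def datapoint_labels(self) -> list[tuple[str, str, str]]:
        labels = []
        for arm in self.ipd_arms:
            labels.extend(
                ("ipd", arm.study_id, f"{arm.treatment_id}#{i}")
                for i in range(arm.y.size)
            )
        labels.extend(("agd", a.study_id, a.treatment_id) for a in self.agd_arms)
        return labels

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """(m, n_datapoints): IPD rows first (study/arm order), then AgD arms."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        effects = self._effects_table(theta)
        beta2 = self._beta2_rows(theta)
        cols = []
        for arm in self.ipd_arms:
            eta = self._eta(theta, arm, effects, beta2)
            lik = self.spec.likelihood
            if lik == "bernoulli":
                log_inv = _LINKS[self.spec.link]["log_inv"]
                cols.append(log_inv((2.0 * arm.y - 1.0)[None, :] * eta))
            elif lik == "normal":
                sig_ids = [s.study_id for s in self.studies if isinstance(s, IPDStudy)]
                sig = self._get(theta, "sigma")[:, [sig_ids.index(arm.study_id)]]
                cols.append(stats.norm.logpdf(arm.y[None, :], loc=eta, scale=sig))
            else:
                lam = np.exp(eta)
                cols.append(
                    arm.y[None, :] * eta - lam - special.gammaln(arm.y + 1)[None, :]
                )
        for arm in self.agd_arms:
            cols.append(self._arm_loglik(theta, arm, effects, beta2)[:, None])
        return np.concatenate(cols, axis=1)

    def saturated_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Pointwise log-likelihood of the saturated model (theta_i = y_i).

        For AgD binomial arms the saturated term plugs y/N' into the same
        adjusted size N', so it varies by draw; Bernoulli rows have
        saturated log-likelihood zero.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        m = theta.shape[0]
        effects = self._effects_table(theta)
        beta2 = self._beta2_rows(theta)
        cols = []
        lik = self.spec.likelihood
        for arm in self.ipd_arms:
            n = arm.y.size
            if lik == "bernoulli":
                cols.append(np.zeros((m, n)))
            elif lik == "normal":
                sig_ids = [s.study_id for s in self.studies if isinstance(s, IPDStudy)]
                sig = self._get(theta, "sigma")[:, [sig_ids.index(arm.study_id)]]
                cols.append(np.broadcast_to(-np.log(sig) - 0.5 * np.log(2 * np.pi), (m, n)).copy())
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    sat = np.where(
                        arm.y > 0,
                        arm.y * np.log(np.where(arm.y > 0, arm.y, 1.0)) - arm.y,
                        0.0,
                    ) - special.gammaln(arm.y + 1)
                cols.append(np.broadcast_to(sat, (m, n)).copy())
        for arm in self.agd_arms:
            if lik == "bernoulli":
                eta = self._eta(theta, arm, effects, beta2)
                p = inverse_link(eta, self.spec.link)
                pbar = np.clip(p.mean(axis=1), _EPS, 1 - _EPS)
                p2bar = np.clip((p**2).mean(axis=1), pbar**2, pbar)
                n_prime = arm.n * pbar**2 / p2bar
                p_sat = np.clip(arm.y / n_prime, _EPS, 1 - _EPS)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    cols.append(_binom_logpmf_real_n(arm.y, n_prime, p_sat)[:, None])
            elif lik == "normal":
                se = arm.se if arm.se is not None else 1.0 / np.sqrt(arm.n)
                cols.append(np.full((m, 1), stats.norm.logpdf(0.0, scale=se)))
            else:
                sat = (arm.y * np.log(arm.y) - arm.y if arm.y > 0 else 0.0) - float(
                    special.gammaln(arm.y + 1)
                )
                cols.append(np.full((m, 1), sat))
        return np.concatenate(cols, axis=1)

    # -- initialization ------------------------------------------------------
    def initial_point(self) -> np.ndarray:
        """A crude data-informed starting point for optimization/sampling."""
        x0 = np.zeros(self.ndim)
        mu_sl = self._slices["mu"]
        for j, s in enumerate(self.studies):
            if self.spec.likelihood == "bernoulli":
                if isinstance(s, IPDStudy):
                    rate = float(np.clip(s.data["y"].mean(), 0.02, 0.98))
                else:
                    rate = float(
                        np.clip(s.arms["y"].sum() / s.arms["n"].sum(), 0.02, 0.98)
                    )
                x0[mu_sl.start + j] = (
                    stats.norm.ppf(rate) if self.spec.link == "probit" else special.logit(rate)
                )
            elif self.spec.likelihood == "normal":
                if isinstance(s, IPDStudy):
                    x0[mu_sl.start + j] = float(s.data["y"].mean())
                else:
                    x0[mu_sl.start + j] = float(s.arms["y"].mean())
            else:
                if isinstance(s, IPDStudy):
                    x0[mu_sl.start + j] = float(np.log(s.data["y"].mean() + 0.5))
                else:
                    x0[mu_sl.start + j] = float(
                        np.log(s.arms["y"].sum() / s.arms["n"].sum() + 1e-3)
                    )
        if "tau" in self._slices:
            x0[self._slices["tau"]] = 0.1
        for name, sl in self._slices.items():
            if name.startswith("sigma_beta2"):
                x0[sl] = 0.5
            elif name == "sigma":
                x0[sl] = 1.0
        return x0
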
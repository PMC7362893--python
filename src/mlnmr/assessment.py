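"""Model criticism: residual deviance, DIC, heterogeneity and inconsistency.

Residual deviance compares each datapoint's fitted log-likelihood to the
saturated model; an adequate model contributes about one unit per
datapoint.  The deviance information criterion DIC = Dbar + pD (with
pD = Dbar - Dhat) compares non-nested evidence-synthesis models.  Residual
heterogeneity is assessed by comparing fixed- and random-effects fits and
the posterior of the heterogeneity standard deviation tau; inconsistency
by refitting with unrelated mean effects (one free baseline contrast per
observed design) and comparing fit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import Network
from .inference import FitConfig, PosteriorDraws, fit
from .integration import IntegrationGrid
from .model import ModelSpec

_MAX_DEV_DRAWS = 500


@dataclass
class FitReport:
    """Residual deviance decomposition and information criterion."""

    total_residual_deviance: float
    ipd_deviance: float
    agd_deviance: float
    n_datapoints: int
    n_ipd: int
    n_agd: int
    per_point: pd.DataFrame = field(repr=False, default=None)
    dbar: float = np.nan
    dhat: float = np.nan
    p_d: float = np.nan
    dic: float = np.nan


def _dev_draws(draws: PosteriorDraws, max_draws: int = _MAX_DEV_DRAWS) -> np.ndarray:
    theta = draws.stacked
    if len(theta) > max_draws:
        idx = np.linspace(0, len(theta) - 1, max_draws).astype(int)
        theta = theta[idx]
    return theta


def residual_deviance(draws: PosteriorDraws, max_draws: int = _MAX_DEV_DRAWS) -> FitReport:
    """Posterior-mean residual deviance, per datapoint and in total.

    Bernoulli rows use the Bernoulli deviance (saturated log-likelihood 0);
    aggregate binomial arms use the two-parameter-adjusted binomial with
    the observed count plugged into the same adjusted size N'.
    """
    lp = draws.logpost
    theta = _dev_draws(draws, max_draws)
    dev = 2.0 * (lp.saturated_loglik(theta) - lp.pointwise_loglik(theta))
    dev_point = dev.mean(axis=0)
    labels = lp.datapoint_labels
    per_point = pd.DataFrame(labels, columns=["level", "study", "datapoint"])
    per_point["deviance"] = dev_point
    is_ipd = per_point["level"] == "ipd"
    return FitReport(
        total_residual_deviance=float(dev_point.sum()),
        ipd_deviance=float(dev_point[is_ipd.to_numpy()].sum()),
        agd_deviance=float(dev_point[~is_ipd.to_numpy()].sum()),
        n_datapoints=len(labels),
        n_ipd=int(is_ipd.sum()),
        n_agd=int((~is_ipd).sum()),
        per_point=per_point,
    )


def dic(draws: PosteriorDraws, max_draws: int = _MAX_DEV_DRAWS):
    """(Dbar, Dhat, pD, DIC) from per-draw and plug-in total deviances.

    Dbar is the posterior mean of -2 log L; Dhat evaluates -2 log L at the
    posterior mean of the parameters; pD = Dbar - Dhat and DIC = Dbar + pD.
    """
    lp = draws.logpost
    theta = _dev_draws(draws, max_draws)
    per_draw = -2.0 * lp.log_likelihood(theta)
    if not np.all(np.isfinite(per_draw)):
        raise ValueError("non-finite deviance encountered")
    dbar = float(per_draw.mean())
    theta_bar = draws.stacked.mean(axis=0)
    dhat = float(-2.0 * lp.log_likelihood(theta_bar[None, :])[0])
    p_d = dbar - dhat
    return dbar, dhat, p_d, dbar + p_d


def full_report(draws: PosteriorDraws) -> FitReport:
    """Residual deviance plus DIC in one report."""
    rep = residual_deviance(draws)
    rep.dbar, rep.dhat, rep.p_d, rep.dic = dic(draws)
    return rep


def _data_hash(draws: PosteriorDraws) -> str:
    lp = draws.logpost
    payload = []
    for arm in lp.ipd_arms:
        payload.append([arm.study_id, arm.treatment_id, arm.y.tolist()])
    for arm in lp.agd_arms:
        payload.append([arm.study_id, arm.treatment_id, arm.y, arm.n])
    return hashlib.sha1(json.dumps(payload).encode()).hexdigest()


def heterogeneity_check(fe_draws: PosteriorDraws, re_draws: PosteriorDraws) -> dict:
    """Compare fixed- and random-effects fits on identical data.

    Returns DIC for both models and the posterior median and 95% credible
    interval of the residual heterogeneity SD tau.
    """
    if _data_hash(fe_draws) != _data_hash(re_draws):
        raise ValueError("fixed- and random-effects fits use different data")
    tau = re_draws.tau_draws()
    if tau is None:
        raise ValueError("second fit has no heterogeneity parameter")
    lo, med, hi = np.percentile(tau, [2.5, 50.0, 97.5])
    return {
        "dic_fixed": dic(fe_draws)[3],
        "dic_random": dic(re_draws)[3],
        "tau_median": float(med),
        "tau_2.5%": float(lo),
        "tau_97.5%": float(hi),
    }


def ume_fit(
    network: Network,
    spec: ModelSpec,
    grids: Mapping[str, IntegrationGrid] | None,
    config: FitConfig,
    consistency_draws: PosteriorDraws | None = None,
):
    """Fit the unrelated-mean-effects model and compare with consistency.

    The consistency-constrained relative effects are replaced by one free
    contrast per observed (study-baseline, treatment) design pair; a large
    DIC improvement or concentrated per-datapoint deviance reductions
    indicate inconsistency.  Returns ``(ume_draws, comparison)`` where the
    comparison is ``None`` unless a consistency fit is supplied.
    """
    ume_draws = fit(network, spec, grids, config, ume=True)
    comparison = None
    if consistency_draws is not None:
        if _data_hash(ume_draws) != _data_hash(consistency_draws):
            raise ValueError("UME and consistency fits use different data")
        rep_c = residual_deviance(consistency_draws)
        rep_u = residual_deviance(ume_draws)
        per = rep_c.per_point.copy()
        per = per.rename(columns={"deviance": "deviance_consistency"})
        per["deviance_ume"] = rep_u.per_point["deviance"].to_numpy()
        per["difference"] = per["deviance_consistency"] - per["deviance_ume"]
        comparison = {
            "dic_consistency": dic(consistency_draws)[3],
            "dic_ume": dic(ume_draws)[3],
            "per_point": per,
        }
    return ume_draws, comparison
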
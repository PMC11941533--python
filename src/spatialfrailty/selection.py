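"""Bayesian model comparison: CPO/LPML, DIC and WAIC, plus a consensus rank.

All three indices are computed from posterior draws; lower is better for
every reported column (the LPML is reported negated as ``neg_lpml`` so the
"lowest wins" selection rule applies uniformly; the raw LPML is exposed as
well).

* CPO_i is the harmonic-mean estimator of the leave-one-out predictive
  density, ``CPO_i = [mean_m exp(-l_im)]^{-1}``, stabilized via
  log-sum-exp; ``neg_lpml = -sum_i log CPO_i``.
* DIC uses the plug-in deviance at the posterior mean of the parameters on
  the sampler's unconstrained scale (invariant to the working
  parameterization): ``p_D = mean(D_m) - D(theta_bar)``,
  ``DIC = mean(D_m) + p_D``.
* WAIC uses the pointwise-variance penalty ("WAIC-2"):
  ``p_waic = sum_i var_m(l_im)`` with the M-1 denominator,
  ``WAIC = -2 (lppd - p_waic)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort
from .likelihood import loglik
from .mcmc import PosteriorSamples

__all__ = [
    "FitIndices",
    "cpo",
    "neg_lpml",
    "dic",
    "waic",
    "fit_indices",
    "compare_models",
]


@dataclass(frozen=True)
class FitIndices:
    neg_lpml: float
    dic: float
    p_d: float
    waic: float
    p_waic: float

    @property
    def lpml(self) -> float:
        return -self.neg_lpml


def _check_ll(pointwise_ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be a (draws x records) matrix")
    bad = np.argwhere(~np.isfinite(ll))
    if bad.size:
        m, i = bad[0]
        raise ValueError(
            f"non-finite pointwise log-likelihood at draw {m}, record {i}"
        )
    return ll


def cpo(pointwise_ll: np.ndarray) -> np.ndarray:
    """Conditional predictive ordinate per record (harmonic-mean estimator)."""
    ll = _check_ll(pointwise_ll)
    M = ll.shape[0]
    # log CPO_i = log M - logsumexp_m(-l_im)
    log_cpo = np.log(M) - logsumexp(-ll, axis=0)
    return np.exp(log_cpo)


def neg_lpml(cpo_values: np.ndarray) -> float:
    """Negated log pseudo-marginal likelihood, -sum_i log CPO_i (lower is better)."""
    cpo_values = np.asarray(cpo_values, dtype=float)
    if np.any(cpo_values <= 0):
        raise ValueError("CPO values must be positive")
    return float(-np.sum(np.log(cpo_values)))


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """(DIC, p_D) from deviance draws and the plug-in deviance.

    ``p_D = mean(D_m) - D(theta_bar)``; ``DIC = mean(D_m) + p_D``.
    """
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one deviance draw")
    dbar = float(np.mean(d))
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d


def waic(pointwise_ll: np.ndarray) -> tuple[float, float]:
    """(WAIC, p_waic) from the pointwise log-likelihood matrix."""
    ll = _check_ll(pointwise_ll)
    M = ll.shape[0]
    if M < 2:
        raise ValueError("WAIC needs at least 2 draws for the variance penalty")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(M)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def fit_indices(samples: PosteriorSamples, cohort: Cohort) -> FitIndices:
    """All three fit indices for one fitted model."""
    ll = samples.pointwise_ll
    nl = neg_lpml(cpo(ll))
    dev_draws = -2.0 * ll.sum(axis=1)
    dev_at_mean = -2.0 * loglik(cohort, samples.posterior_mean_state())
    dic_val, p_d = dic(dev_draws, dev_at_mean)
    waic_val, p_waic = waic(ll)
    return FitIndices(neg_lpml=nl, dic=dic_val, p_d=p_d, waic=waic_val, p_waic=p_waic)


def compare_models(models: list[tuple[str, FitIndices]]) -> pd.DataFrame:
    """Rank candidate models on neg_lpml, DIC and WAIC.

    The consensus winner is the model that is lowest on a majority of the
    three criteria; ties are broken by neg_lpml.  Returns one row per model
    with per-criterion ranks, a ``consensus_winner`` flag and a ``tie``
    flag when two models share identical indices.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    df = pd.DataFrame(
        {
            "model": [name for name, _ in models],
            "neg_lpml": [fi.neg_lpml for _, fi in models],
            "dic": [fi.dic for _, fi in models],
            "p_d": [fi.p_d for _, fi in models],
            "waic": [fi.waic for _, fi in models],
            "p_waic": [fi.p_waic for _, fi in models],
        }
    )
    for crit in ("neg_lpml", "dic", "waic"):
        df[f"rank_{crit}"] = df[crit].rank(method="min").astype(int)
    wins = sum((df[f"rank_{c}"] == 1).astype(int) for c in ("neg_lpml", "dic", "waic"))
    df["criteria_won"] = wins
    best = df.sort_values(
        ["criteria_won", "neg_lpml"], ascending=[False, True], kind="stable"
    ).index[0]
    df["consensus_winner"] = False
    df.loc[best, "consensus_winner"] = True
    df["tie"] = df.duplicated(subset=["neg_lpml", "dic", "waic"], keep=False)
    return df
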
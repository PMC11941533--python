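"""Parametric proportional-hazards baselines and the right-censored frailty likelihood.

Three baseline families are supported, in the standard shape/scale
parameterizations:

* Weibull:        ``Lambda0(t) = (t/scale)**shape``
* Log-logistic:   ``S0(t) = 1 / (1 + (t/scale)**shape)``,
                  i.e. ``Lambda0(t) = log(1 + (t/scale)**shape)``
* Log-normal:     ``Lambda0(t) = -log(1 - Phi((log t - mu)/sigma0))``

All three enter a proportional-hazards (PH) model — the covariates and the
block frailty multiply the baseline hazard:

    h(t | x, g) = h0(t) * exp(x'beta + w_g)

so the survival function is ``S(t|x,g) = exp(-exp(eta) * Lambda0(t))`` with
linear predictor ``eta = x'beta + w_g``.  Note the log-normal and
log-logistic baselines are used as PH models, not as accelerated-failure-time
models.  There is no intercept in ``beta``: the baseline scale parameter
plays that role.

The right-censored log-likelihood decomposes into per-record contributions

    l_i = delta_i * (log h0(t_i) + eta_i) - exp(eta_i) * Lambda0(t_i)

which is what CPO/LPML and WAIC need pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm

from .cohort import Cohort, encode_design

FAMILIES = ("weibull", "lognormal", "loglogistic")

__all__ = [
    "FAMILIES",
    "BaselineParams",
    "ParameterState",
    "baseline_cumhaz",
    "baseline_loghaz",
    "baseline_logsurv",
    "linear_predictor",
    "loglik",
    "pointwise_loglik",
]


@dataclass(frozen=True)
class BaselineParams:
    """Baseline-hazard parameters for one family.

    Weibull and log-logistic use (shape, scale) with both positive; the
    log-normal uses (mu, sigma0) with sigma0 positive.  Use the family
    constructors rather than the raw dataclass.
    """

    family: str
    shape: float | None = None
    scale: float | None = None
    mu: float | None = None
    sigma0: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "lognormal":
            if self.mu is None or self.sigma0 is None:
                raise ValueError("lognormal baseline requires mu and sigma0")
            if not self.sigma0 > 0:
                raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        else:
            if self.shape is None or self.scale is None:
                raise ValueError(f"{self.family} baseline requires shape and scale")
            if not (self.shape > 0 and self.scale > 0):
                raise ValueError(
                    f"shape and scale must be positive, got ({self.shape}, {self.scale})"
                )

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "BaselineParams":
        return cls("weibull", shape=shape, scale=scale)

    @classmethod
    def loglogistic(cls, shape: float, scale: float) -> "BaselineParams":
        return cls("loglogistic", shape=shape, scale=scale)

    @classmethod
    def lognormal(cls, mu: float, sigma0: float) -> "BaselineParams":
        return cls("lognormal", mu=mu, sigma0=sigma0)


@dataclass
class ParameterState:
    """One full parameter configuration of the spatial-frailty PH model.

    Attributes
    ----------
    baseline : BaselineParams
    beta : (5,) coefficients in the cohort covariate order.
    frailty : (G,) additive block effects w_g on the log-hazard scale.
    frailty_sd : prior standard deviation sigma of the frailties.
    """

    baseline: BaselineParams
    beta: np.ndarray
    frailty: np.ndarray
    frailty_sd: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.frailty = np.asarray(self.frailty, dtype=float)
        if not self.frailty_sd > 0:
            raise ValueError(f"frailty_sd must be positive, got {self.frailty_sd}")


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    return t


def baseline_cumhaz(baseline: BaselineParams, t):
    """Cumulative baseline hazard Lambda0(t); vectorized over ``t``."""
    t = _check_times(t)
    if baseline.family == "weibull":
        return np.exp(baseline.shape * (np.log(t) - np.log(baseline.scale)))
    if baseline.family == "loglogistic":
        u = baseline.shape * (np.log(t) - np.log(baseline.scale))
        # log(1 + e^u) computed stably for large |u|
        return np.logaddexp(0.0, u)
    z = (np.log(t) - baseline.mu) / baseline.sigma0
    # -log S0(t) with S0 = Phi(-z); log_ndtr avoids cancellation for large t
    return -log_ndtr(-z)


def baseline_logsurv(baseline: BaselineParams, t):
    """log S0(t) = -Lambda0(t)."""
    return -baseline_cumhaz(baseline, t)


def baseline_loghaz(baseline: BaselineParams, t):
    """Log baseline hazard log h0(t); vectorized over ``t``."""
    t = _check_times(t)
    logt = np.log(t)
    if baseline.family == "weibull":
        a, s = baseline.shape, baseline.scale
        return np.log(a) - logt + a * (logt - np.log(s))
    if baseline.family == "loglogistic":
        a, s = baseline.shape, baseline.scale
        u = a * (logt - np.log(s))
        return np.log(a) - logt + u - np.logaddexp(0.0, u)
    z = (logt - baseline.mu) / baseline.sigma0
    # h0 = f0/S0 with f0 the log-normal density
    return norm.logpdf(z) - logt - np.log(baseline.sigma0) - log_ndtr(-z)


def linear_predictor(cohort: Cohort, state: ParameterState) -> np.ndarray:
    """eta_i = x_i'beta + w_{g(i)} for every record."""
    X, block_idx = encode_design(cohort)
    if state.beta.shape != (X.shape[1],):
        raise ValueError(
            f"beta has length {state.beta.shape[0]}, expected {X.shape[1]}"
        )
    if state.frailty.shape != (len(cohort.blocks),):
        raise ValueError(
            f"frailty has length {state.frailty.shape[0]}, expected {len(cohort.blocks)}"
        )
    return X @ state.beta + state.frailty[block_idx]


def pointwise_loglik(cohort: Cohort, state: ParameterState) -> np.ndarray:
    """Per-record log-likelihood contributions l_i (right-censored PH)."""
    eta = linear_predictor(cohort, state)
    t = cohort.time
    delta = cohort.status
    with np.errstate(over="ignore", invalid="ignore"):
        ll = delta * (baseline_loghaz(state.baseline, t) + eta) - np.exp(
            eta
        ) * baseline_cumhaz(state.baseline, t)
    return ll


def loglik(cohort: Cohort, state: ParameterState) -> float:
    """Total right-censored frailty log-likelihood (sum of pointwise terms)."""
    return float(np.sum(pointwise_loglik(cohort, state)))
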
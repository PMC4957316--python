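"""Concordance-index estimators for right-censored data.

The concordance index (C-index) of a risk score eta is the probability
that, of two random subjects, the one with the shorter survival time has
the larger score,

    C = P(eta_j > eta_i | T_j < T_i),

so C = 1 means perfect discrimination and C = 0.5 an uninformative
marker.  Under right censoring the naive pair count is biased; the
estimators here follow the inverse-probability-of-censoring-weighting
(IPCW) approach of Uno et al.: each usable pair (j, i) with observed
event at the smaller time T~_j is weighted by 1 / G(T~_j-)^2, where G is
the Kaplan-Meier estimate of the censoring survival function.

Four quantities are provided:

* :func:`concordance_uno` -- the IPCW estimator with hard indicators,
* :func:`concordance_truncated` -- the unweighted estimator restricted
  to event-event pairs with the smaller time below a horizon ``tau``,
* :func:`concordance_smooth` -- the IPCW estimator with the score
  indicator replaced by a sigmoid of bandwidth ``sigma`` (differentiable
  in eta, hence usable as a boosting loss), and
* :func:`smooth_gradient` -- its analytic gradient (ascent direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import SurvivalSample

logger = logging.getLogger(__name__)

__all__ = [
    "CensoringKM",
    "ConcordanceQuery",
    "km_censoring",
    "ipcw_weights",
    "concordance_uno",
    "concordance_truncated",
    "concordance_smooth",
    "smooth_gradient",
    "evaluate",
]

#: default sigmoid bandwidth for the smoothed estimator
DEFAULT_SIGMA = 0.1


class CensoringKM:
    """Kaplan-Meier estimate of the censoring survival function G.

    The product-limit estimator is applied with *censoring* (status 0)
    as the event of interest, so G(t) = P(T_cens > t).  The step
    function is right-continuous; ``evaluate_left`` returns the left
    limit G(t-), the convention used for IPCW weights so that a
    subject's own censoring jump does not deflate its weight.
    """

    def __init__(self, jump_times: np.ndarray, values: np.ndarray,
                 left_limit: bool = True):
        jump_times = np.asarray(jump_times, dtype=float)
        values = np.asarray(values, dtype=float)
        if jump_times.shape != values.shape:
            raise ValueError("jump_times and values must have equal length")
        if np.any(np.diff(jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(values < 0) or np.any(values > 1) or np.any(np.diff(values) > 0):
            raise ValueError("values must be non-increasing in [0, 1]")
        self.jump_times = jump_times
        self.values = values
        #: evaluation convention used by :func:`ipcw_weights`
        self.left_limit = left_limit

    @classmethod
    def fit(cls, sample: SurvivalSample, left_limit: bool = True) -> "CensoringKM":
        t, d = sample.times, sample.status
        order = np.argsort(t, kind="stable")
        ts, ds = t[order], d[order]
        uniq, start = np.unique(ts, return_index=True)
        n = len(ts)
        # number at risk just before each distinct time; censorings at it
        at_risk = n - start
        n_cens = np.add.reduceat(1 - ds, start)
        keep = n_cens > 0
        if not keep.any():  # no censoring: G identically 1
            return cls(np.empty(0), np.empty(0), left_limit)
        surv = np.cumprod(1.0 - n_cens[keep] / at_risk[keep])
        return cls(uniq[keep], surv, left_limit)

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous value G(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        return np.concatenate(([1.0], self.values))[idx]

    def evaluate_left(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left")
        return np.concatenate(([1.0], self.values))[idx]

    def __call__(self, t) -> np.ndarray:
        return self.evaluate_left(t) if self.left_limit else self.evaluate(t)


def km_censoring(sample: SurvivalSample, left_limit: bool = True) -> CensoringKM:
    """Fit the censoring Kaplan-Meier G on a sample."""
    return CensoringKM.fit(sample, left_limit=left_limit)


def ipcw_weights(sample: SurvivalSample, G: CensoringKM) -> np.ndarray:
    """Per-subject IPCW weights w_j = Delta_j / G(T~_j-)^2.

    Censored subjects get weight 0.  Subjects whose evaluation point has
    G = 0 would yield an infinite weight; they get weight 0 and a logged
    warning instead.
    """
    g = G(sample.times)
    w = np.zeros(sample.n)
    ev = sample.status == 1
    zero = ev & (g <= 0.0)
    if zero.any():
        logger.warning(
            "%d event(s) with zero censoring-survival estimate; their IPCW "
            "weight is set to 0", int(zero.sum()),
        )
    ok = ev & (g > 0.0)
    w[ok] = 1.0 / g[ok] ** 2
    return w


@dataclass(frozen=True)
class ConcordanceQuery:
    """Evaluation request: scores plus optional horizon/bandwidth."""

    eta: np.ndarray
    tau: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))
        if self.eta.ndim != 1:
            raise ValueError("eta must be one-dimensional")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _check_eta(sample: SurvivalSample, eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (sample.n,):
        raise ValueError(
            f"eta has length {eta.shape[0]}, sample has {sample.n} subjects"
        )
    return eta


def pair_weight_matrix(sample: SurvivalSample,
                       G: CensoringKM | None = None) -> tuple[np.ndarray, float]:
    """IPCW pair weights W[j, i] = w_j * I(T~_j < T~_i) and their sum D.

    These depend only on (times, status), not on eta; boosting computes
    them once per training sample and holds them fixed.
    """
    if G is None:
        G = km_censoring(sample)
    w = ipcw_weights(sample, G)
    t = sample.times
    WM = w[:, None] * (t[:, None] < t[None, :])
    return WM, float(WM.sum())


def concordance_uno(sample: SurvivalSample, eta,
                    G: CensoringKM | None = None) -> float:
    """Uno's IPCW estimator of the C-index.

    Strict inequalities throughout: tied times form no pair, tied scores
    contribute nothing to the numerator.
    """
    eta = _check_eta(sample, eta)
    WM, D = pair_weight_matrix(sample, G)
    if D <= 0:
        raise ValueError(
            "no usable pair: need an observed event time strictly smaller "
            "than another follow-up time with positive IPCW weight"
        )
    num = (WM * (eta[:, None] > eta[None, :])).sum()
    return float(num / D)


def concordance_truncated(sample: SurvivalSample, eta, tau: float) -> float:
    """Truncated C-index restricted to event-event pairs with T~_j <= tau.

    Unlike the Uno estimator this uses no censoring weights: both pair
    members must be observed events and the smaller time must not exceed
    the horizon tau.
    """
    eta = _check_eta(sample, eta)
    if tau is None or tau <= 0:
        raise ValueError("tau must be a positive horizon")
    t, d = sample.times, sample.status
    elig = (
        (d[:, None] * d[None, :])
        * (t[:, None] < t[None, :])
        * (t[:, None] <= tau)
    )
    D = elig.sum()
    if D <= 0:
        raise ValueError(
            f"no event-event pair with the smaller event time <= tau={tau}"
        )
    num = (elig * (eta[:, None] > eta[None, :])).sum()
    return float(num / D)


def concordance_smooth(sample: SurvivalSample, eta,
                       sigma: float = DEFAULT_SIGMA,
                       G: CensoringKM | None = None) -> float:
    """Smoothed Uno estimator: the score indicator I(eta_j > eta_i) is
    replaced by the sigmoid K(u) = 1 / (1 + exp(-u / sigma)).
    """
    eta = _check_eta(sample, eta)
    if sigma is None or sigma <= 0:
        raise ValueError("sigma must be positive")
    WM, D = pair_weight_matrix(sample, G)
    if D <= 0:
        raise ValueError("no usable pair for the smoothed estimator")
    K = expit((eta[:, None] - eta[None, :]) / sigma)
    return float((WM * K).sum() / D)


def smooth_gradient(sample: SurvivalSample, eta,
                    sigma: float = DEFAULT_SIGMA,
                    G: CensoringKM | None = None) -> np.ndarray:
    """Analytic gradient of :func:`concordance_smooth` w.r.t. eta.

    This is the ascent direction for the smoothed C-index.  Each pair
    contributes equal and opposite amounts to its two members, so the
    components always sum to zero.
    """
    eta = _check_eta(sample, eta)
    if sigma is None or sigma <= 0:
        raise ValueError("sigma must be positive")
    WM, D = pair_weight_matrix(sample, G)
    if D <= 0:
        raise ValueError("no usable pair for the smoothed estimator")
    K = expit((eta[:, None] - eta[None, :]) / sigma)
    A = WM * (K * (1.0 - K) / sigma)
    return (A.sum(axis=1) - A.sum(axis=0)) / D


def evaluate(sample: SurvivalSample, query: ConcordanceQuery,
             estimator: str = "uno") -> float:
    """Dispatch on the estimator name (used by the CLI)."""
    if estimator == "uno":
        return concordance_uno(sample, query.eta)
    if estimator == "truncated":
        if query.tau is None:
            raise ValueError("the truncated estimator requires tau")
        return concordance_truncated(sample, query.eta, query.tau)
    if estimator == "smooth":
        sigma = DEFAULT_SIGMA if query.sigma is None else query.sigma
        return concordance_smooth(sample, query.eta, sigma)
    raise ValueError(f"unknown estimator {estimator!r}")
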
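"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every estimator from its definition with plain
Python loops (product-limit by hand, exhaustive pair enumeration) so the
vectorised implementations are checked against a genuinely independent
path.
"""

import math

import numpy as np
import pytest

from cindexboost import SurvivalSample


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_censoring_km(times, status):
    """Product-limit estimate of the censoring survival function,
    computed by explicit looping; returns a plain step-function closure
    evaluating the left limit G(t-)."""
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    jumps = []
    for t in sorted(set(times)):
        d = int(((times == t) & (status == 0)).sum())
        if d:
            at_risk = int((times >= t).sum())
            jumps.append((t, 1.0 - d / at_risk))

    def G_left(t):
        g = 1.0
        for jt, factor in jumps:
            if jt < t:
                g *= factor
        return g

    def G_right(t):
        g = 1.0
        for jt, factor in jumps:
            if jt <= t:
                g *= factor
        return g

    return G_left, G_right


def brute_weights(times, status):
    G_left, _ = brute_censoring_km(times, status)
    return np.array([
        (1.0 / G_left(t) ** 2 if G_left(t) > 0 else 0.0) if d == 1 else 0.0
        for t, d in zip(times, status)
    ])


def brute_uno(times, status, eta):
    w = brute_weights(times, status)
    num = den = 0.0
    n = len(times)
    for j in range(n):
        for i in range(n):
            if times[j] < times[i]:
                den += w[j]
                if eta[j] > eta[i]:
                    num += w[j]
    if den == 0:
        raise ZeroDivisionError
    return num / den


def brute_truncated(times, status, eta, tau):
    num = den = 0.0
    n = len(times)
    for j in range(n):
        for i in range(n):
            if status[j] and status[i] and times[j] < times[i] and times[j] <= tau:
                den += 1.0
                if eta[j] > eta[i]:
                    num += 1.0
    return num / den


def brute_smooth(times, status, eta, sigma):
    w = brute_weights(times, status)
    num = den = 0.0
    n = len(times)
    for j in range(n):
        for i in range(n):
            if times[j] < times[i]:
                den += w[j]
                num += w[j] / (1.0 + math.exp(-(eta[j] - eta[i]) / sigma))
    return num / den


def random_censored_sample(rng, n, p=0, cens=0.4):
    """Tie-free random right-censored sample."""
    t = rng.exponential(2.0, n) + 1e-3
    c = rng.exponential(2.0 * (1 - cens) / cens, n) + 1e-3
    obs = np.minimum(t, c)
    status = (t <= c).astype(int)
    if status.sum() == 0:
        status[int(np.argmin(obs))] = 1  # keep at least one usable pair
    X = rng.standard_normal((n, p)) if p else None
    return SurvivalSample(obs, status, X)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_sample():
    """T~ = (1,2,3,4), events except the censored subject at t=2."""
    return SurvivalSample([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])


@pytest.fixture
def toy_eta():
    return np.array([4.0, 3.0, 1.0, 2.0])


@pytest.fixture
def informative_sample():
    """n=120, p=8 with two strong AFT effects; moderate censoring."""
    rng = np.random.default_rng(2024)
    X = rng.standard_normal((120, 8))
    t = np.exp(1.0 * X[:, 0] - 1.0 * X[:, 1] + 0.4 * rng.logistic(size=120))
    c = rng.exponential(np.median(t) * 1.5, 120)
    return SurvivalSample(np.minimum(t, c), (t <= c).astype(int), X)
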
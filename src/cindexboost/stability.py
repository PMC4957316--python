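"""Complementary-pairs stability selection with per-family error control.

Stability selection wraps a base variable-selection procedure -- here
:meth:`cindexboost.boosting.CIndexBoost.fit_until_q`, which boosts until
q distinct covariates have entered -- around repeated subsampling: B
random partitions of the data yield 2B half-samples (each subsample and
its complement), the base procedure runs on each, and the selection
frequency pi_j of every covariate is the fraction of the 2B runs that
picked it.  Covariates with pi_j >= pi_thr form the *stable set*.

The appeal is error control: the expected number V of falsely selected
covariates (the per-family error rate, PFER) is bounded by

    E(V) <= q^2 / ((2 pi_thr - 1) p)

under exchangeability (Meinshausen & Buhlmann), and by substantially
tighter bounds under unimodality or r-concavity of the selection-
frequency distribution (Shah & Samworth complementary-pairs scheme);
the r-concave bound requires numerical extremisation over r-concave
tail distributions and is implemented in :func:`max_tail_rconcave`.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .boosting import CIndexBoost, CIndexBoostResults
from .concordance import DEFAULT_SIGMA
from .data import SurvivalSample

logger = logging.getLogger(__name__)

__all__ = [
    "complementary_pairs",
    "pfer_bound_mb",
    "pfer_bound_unimodal",
    "pfer_bound_rconcave",
    "pfer_bound_shah_samworth",
    "max_tail_rconcave",
    "StabilitySelection",
    "StabilityResults",
]


def complementary_pairs(n: int, B: int, seed=None) -> list[np.ndarray]:
    """Draw B random partitions of range(n) into complementary halves.

    Returns 2B index arrays: for each partition, a floor(n/2)-subset and
    its complement (which absorbs the extra subject when n is odd).
    Reproducible under ``seed`` (an int or a Generator).
    """
    if n < 4:
        raise ValueError("need n >= 4 for complementary-pairs subsampling")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    half = n // 2
    out = []
    for _ in range(B):
        perm = rng.permutation(n)
        out.append(np.sort(perm[:half]))
        out.append(np.sort(perm[half:]))
    return out


# ---------------------------------------------------------------------------
# PFER bounds
# ---------------------------------------------------------------------------

def _check_pi(pi_thr: float, allow_half: bool = False) -> None:
    lo_ok = pi_thr >= 0.5 if allow_half else pi_thr > 0.5
    if not (lo_ok and pi_thr <= 1.0):
        rng = "[0.5, 1]" if allow_half else "(0.5, 1]"
        raise ValueError(f"pi_thr must lie in {rng}, got {pi_thr}")


def pfer_bound_mb(q: int, p: int, pi_thr: float) -> float:
    """Meinshausen-Buhlmann bound E(V) <= q^2 / ((2 pi_thr - 1) p)."""
    _check_pi(pi_thr)
    return q * q / ((2.0 * pi_thr - 1.0) * p)


def _mean_trunc(a: float, k: int, s: float, etaB: float) -> float:
    i = np.arange(k + 1)
    g = (a + i) ** (-s)
    return float((i * g).sum() / g.sum()) - etaB


@lru_cache(maxsize=256)
def max_tail_rconcave(eta: float, B: int, s: float) -> tuple[float, ...]:
    """Extremal tails of an r-concave variable on {0, 1/B, ..., 1}.

    Returns the vector (P(X >= 1/B), ..., P(X >= 1)) maximised over all
    distributions with mean ``eta`` whose probability mass function f
    satisfies f^r convex with r = -1/s.  The extremal family consists of
    f(i) proportional to (a + i)^(-s) truncated at some support point k,
    plus a point mass at k + 1 absorbing the mean constraint; the tail
    is maximised over k and the shape parameter a (grid over k, bounded
    scalar optimisation in a between consecutive exact-mean roots).
    """
    etaB = eta * B
    out = np.ones(B)
    k_start = int(np.ceil(2.0 * etaB)) + 1
    if k_start > B:
        return tuple(out)
    min_a, max_a = 1e-5, 1e5
    a_vec = np.full(B + 2, max_a)
    for k in range(k_start, B + 1):
        a_vec[k] = brentq(_mean_trunc, min_a, a_vec[k - 1],
                          args=(k, s, etaB), xtol=1e-12, rtol=1e-12)

    def neg_tail(a: float, k: int, t: int) -> float:
        i = np.arange(k + 1)
        g = (a + i) ** (-s)
        num = (k + 1 - etaB) * g[:t].sum()
        den = ((k + 1 - i) * g).sum()
        return num / den - 1.0

    prev_k = k_start
    for t in range(k_start, B + 1):
        cur = np.zeros(B + 1)
        for k in range(prev_k, B):
            res = minimize_scalar(neg_tail, args=(k, t),
                                  bounds=(a_vec[k + 1], a_vec[k]),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            cur[k] = -res.fun
        out[t - 1] = cur.max()
        prev_k = int(cur.argmax())
    return tuple(out)


def pfer_bound_unimodal(q: int, p: int, pi_thr: float, B: int) -> float:
    """Closed-form complementary-pairs bound under unimodality."""
    _check_pi(pi_thr)
    if B < 1:
        raise ValueError("B must be >= 1")
    if pi_thr <= 0.5 + 1.0 / (2 * B):
        # the closed form is vacuous this close to 1/2; fall back to MB
        return pfer_bound_mb(q, p, pi_thr)
    theta2 = (q / p) ** 2
    if pi_thr <= 0.75:
        c = 1.0 / (2.0 * (2.0 * pi_thr - 1.0 - 1.0 / (2 * B)))
    else:
        c = 4.0 * (1.0 - pi_thr + 1.0 / (2 * B)) / (1.0 + 1.0 / B)
    return min(p * c * theta2, pfer_bound_mb(q, p, pi_thr))


def pfer_bound_rconcave(q: int, p: int, pi_thr: float, B: int) -> float:
    """Complementary-pairs bound under r-concavity (the tightest).

    Combines the extremal tail of the simultaneous-selection proportion
    over the B pairs (mean q^2/p^2, grid 1/B, r = -1/2, evaluated at
    2 pi_thr - 1) with that of the plain 2B-fold selection frequency
    (mean q/p, grid 1/(2B), r = -1/4, evaluated at pi_thr), takes the
    smaller, and scales by p.  The threshold is rounded down to the
    nearest attainable grid point, matching how frequencies that are
    exact multiples of 1/(2B) are thresholded inclusively.
    """
    _check_pi(pi_thr, allow_half=True)
    if B < 1:
        raise ValueError("B must be >= 1")
    eps = 1e-9
    k1 = int(np.floor(B * (2.0 * pi_thr - 1.0) + eps))
    k2 = int(np.floor(2 * B * pi_thr + eps))
    v1 = (max_tail_rconcave(q * q / (p * p), B, 2.0)[k1 - 1]
          if k1 >= 1 else 1.0)
    v2 = max_tail_rconcave(q / p, 2 * B, 4.0)[k2 - 1] if k2 >= 1 else 1.0
    return p * min(1.0, v1, v2)


def pfer_bound_shah_samworth(q: int, p: int, pi_thr: float, B: int,
                             assumption: str = "r-concave") -> float:
    """Shah-Samworth complementary-pairs PFER bound."""
    if assumption == "unimodal":
        return pfer_bound_unimodal(q, p, pi_thr, B)
    if assumption == "r-concave":
        return pfer_bound_rconcave(q, p, pi_thr, B)
    raise ValueError(
        f"assumption must be 'unimodal' or 'r-concave', got {assumption!r}"
    )


# ---------------------------------------------------------------------------
# the selection procedure
# ---------------------------------------------------------------------------

class StabilitySelection:
    """Complementary-pairs stability selection for C-index boosting.

    Parameters
    ----------
    sample : SurvivalSample
        Full training data (n subjects, p covariates).
    q : int
        Per-subsample selection budget: boosting on each half-sample
        runs until q distinct covariates have entered.
    B : int
        Number of complementary pairs; 2B half-samples in total.
    nu, sigma : float
        Boosting step length and loss bandwidth.
    max_iter : int, optional
        Iteration cap per subsample (default ``500 * q``).
    """

    def __init__(self, sample: SurvivalSample, q: int, B: int = 50,
                 nu: float = 0.1, sigma: float = DEFAULT_SIGMA,
                 max_iter: int | None = None):
        if sample.covariates is None:
            raise ValueError("stability selection requires covariates")
        if q < 1 or q > sample.p:
            raise ValueError(f"q must lie in [1, p={sample.p}]")
        self.sample = sample
        self.q = int(q)
        self.B = int(B)
        self.nu = float(nu)
        self.sigma = float(sigma)
        self.max_iter = max_iter

    def fit(self, seed=None, max_redraws: int = 20) -> "StabilityResults":
        """Run the 2B subsample fits and tally selection frequencies.

        A half-sample on which the boosting loss is degenerate (no
        usable comparable pair, e.g. all subjects censored) is redrawn
        from a child RNG with a logged warning.
        """
        sample = self.sample
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        pair_seed, redraw_seed = ss.spawn(2)
        subsamples = complementary_pairs(
            sample.n, self.B, np.random.default_rng(pair_seed))
        redraw_rng = np.random.default_rng(redraw_seed)
        half = sample.n // 2

        counts = np.zeros(sample.p)
        sets: list[frozenset[int]] = []
        n_warn = 0
        for idx in subsamples:
            res = None
            for _ in range(max_redraws):
                try:
                    model = CIndexBoost(sample.subset(idx), sigma=self.sigma)
                except ValueError:
                    n_warn += 1
                    logger.warning(
                        "degenerate half-sample (no comparable pair); "
                        "redrawing")
                    idx = np.sort(redraw_rng.permutation(sample.n)[:half])
                    continue
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    res = model.fit_until_q(self.q, nu=self.nu,
                                            max_iter=self.max_iter)
                n_warn += sum(1 for w in caught if w.category is not None
                              and issubclass(w.category, UserWarning))
                break
            if res is None:
                raise ValueError(
                    "could not draw a usable half-sample after "
                    f"{max_redraws} attempts"
                )
            sel = res.selected_set
            sets.append(sel)
            counts[list(sel)] += 1.0

        return StabilityResults(
            frequencies=counts / (2 * self.B),
            q=self.q, B=self.B, nu=self.nu, sigma=self.sigma,
            subsample_sets=sets, n_warnings=n_warn,
            var_names=sample.var_names, sample=sample, seed=seed,
        )


class StabilityResults:
    """Selection frequencies and everything derived from them.

    ``frequencies[j]`` is the fraction of the 2B half-samples whose
    boosting run (stopped after q distinct selections) picked covariate
    j; all frequencies are exact multiples of 1/(2B).
    """

    def __init__(self, frequencies, q, B, nu, sigma, subsample_sets,
                 n_warnings, var_names=None, sample=None, seed=None):
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.q = int(q)
        self.B = int(B)
        self.nu = float(nu)
        self.sigma = float(sigma)
        self.subsample_sets = list(subsample_sets)
        self.n_warnings = int(n_warnings)
        self.var_names = (tuple(var_names) if var_names is not None else
                          tuple(f"x{j+1}" for j in range(self.frequencies.size)))
        self.sample = sample
        self.seed = seed

    @property
    def p(self) -> int:
        return self.frequencies.size

    def stable_set(self, pi_thr: float) -> frozenset[int]:
        """Covariates with selection frequency >= pi_thr.

        The comparison is inclusive so that frequencies landing exactly
        on the threshold (always multiples of 1/(2B)) are kept.  An
        empty stable set is a legal outcome.
        """
        _check_pi(pi_thr)
        return frozenset(int(j) for j in np.flatnonzero(
            self.frequencies >= pi_thr - 1e-12))

    def pfer_bound(self, pi_thr: float, assumption: str = "r-concave") -> float:
        """Upper bound on the expected number of false positives."""
        if assumption == "MB":
            return pfer_bound_mb(self.q, self.p, pi_thr)
        return pfer_bound_shah_samworth(self.q, self.p, pi_thr, self.B,
                                        assumption)

    def refit(self, pi_thr: float | None = None, stable_set=None,
              m_stop: int = 1000, nu: float | None = None) -> CIndexBoostResults:
        """Refit boosting on the full sample, restricted to the stable set.

        The final model uses a fixed ``m_stop`` (default 1000) and
        reports coefficients in full-p indexing, zeros elsewhere.
        """
        if self.sample is None:
            raise ValueError("results carry no sample; refit manually")
        if stable_set is None:
            if pi_thr is None:
                raise ValueError("give pi_thr or an explicit stable_set")
            stable_set = self.stable_set(pi_thr)
        stable_set = sorted(int(j) for j in stable_set)
        if not stable_set:
            raise ValueError(
                "no stable variables at this threshold; nothing to refit"
            )
        model = CIndexBoost(self.sample, sigma=self.sigma)
        return model.fit(m_stop=m_stop, nu=self.nu if nu is None else nu,
                         columns=stable_set)

    def summary(self, pi_thr: float = 0.7,
                assumption: str = "r-concave") -> str:
        stable = self.stable_set(pi_thr)
        lines = [
            "Complementary-pairs stability selection",
            "=" * 50,
            f"covariates (p):        {self.p}",
            f"per-subsample q:       {self.q}",
            f"subsamples (2B):       {2 * self.B}",
            f"threshold pi_thr:      {pi_thr}",
            f"PFER bound ({assumption}): "
            f"{self.pfer_bound(pi_thr, assumption):.3f}",
            f"stable covariates:     {len(stable)}",
            f"degenerate redraws:    {self.n_warnings}",
            "-" * 50,
            f"{'covariate':<20}{'frequency':>10}{'stable':>8}",
        ]
        order = np.argsort(-self.frequencies, kind="stable")
        for j in order[:max(len(stable), self.q)]:
            lines.append(
                f"{self.var_names[j]:<20}{self.frequencies[j]:>10.2f}"
                f"{'  *' if j in stable else '':>8}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies.tolist(),
            "q": self.q,
            "B": self.B,
            "nu": self.nu,
            "sigma": self.sigma,
            "subsample_sets": [sorted(s) for s in self.subsample_sets],
            "n_warnings": self.n_warnings,
            "var_names": list(self.var_names),
            "seed": self.seed if isinstance(self.seed, (int, type(None)))
                    else str(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityResults":
        return cls(
            d["frequencies"], d["q"], d["B"], d["nu"], d["sigma"],
            [frozenset(s) for s in d["subsample_sets"]],
            d["n_warnings"], d.get("var_names"), None, d.get("seed"),
        )
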
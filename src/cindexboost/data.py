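"""Container for right-censored survival samples."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SurvivalSample:
    """A right-censored survival sample.

    Parameters
    ----------
    times : array-like, shape (n,)
        Observed follow-up times ``min(T, T_cens)``; strictly positive.
    status : array-like, shape (n,)
        Event indicators: 1 if the event was observed, 0 if censored.
    covariates : array-like, shape (n, p), optional
        Covariate matrix. May be omitted for evaluation-only samples
        (e.g. when scoring an externally computed predictor).
    var_names : sequence of str, optional
        Covariate column names; defaults to ``x1 .. xp``.
    """

    times: np.ndarray
    status: np.ndarray
    covariates: np.ndarray | None = None
    var_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        status = np.asarray(self.status)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        n = times.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("times must be strictly positive and finite")
        if status.shape != (n,):
            raise ValueError("status must have the same length as times")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must be coded 0 (censored) / 1 (event)")
        status = status.astype(np.int8)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)
        if self.covariates is not None:
            X = np.asarray(self.covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[0] != n:
                raise ValueError(
                    f"covariates have {X.shape[0]} rows for {n} subjects"
                )
            if not np.all(np.isfinite(X)):
                raise ValueError("covariates contain missing/non-finite values")
            object.__setattr__(self, "covariates", X)
            names = self.var_names
            if names is None:
                names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
            else:
                names = tuple(str(v) for v in names)
                if len(names) != X.shape[1]:
                    raise ValueError("var_names length does not match covariates")
            object.__setattr__(self, "var_names", names)
        elif self.var_names is not None:
            raise ValueError("var_names given without covariates")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - self.status.mean()

    def subset(self, idx) -> "SurvivalSample":
        """Row subset (used by subsampling schemes)."""
        idx = np.asarray(idx)
        X = None if self.covariates is None else self.covariates[idx]
        return SurvivalSample(self.times[idx], self.status[idx], X,
                              self.var_names)
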
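"""Reading survival tables and writing run reports.

Survival data are delimited text with a header row, a ``time`` column
(strictly positive), a ``status`` column (1 = event, 0 = censored) and
any number of numeric covariate columns, whose order is preserved.
Reports are JSON (models, stability results) or CSV (scores, replication
summaries), each stamped with a schema version, the seed used and a hash
of the generating configuration so any reported number is regenerable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import CIndexBoostResults
from .data import SurvivalSample
from .stability import StabilityResults

SCHEMA_VERSION = 1

__all__ = [
    "read_survival_csv",
    "read_scores",
    "write_report",
    "read_model_json",
    "read_stability_json",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_survival_csv(path, time_col: str = "time",
                      status_col: str = "status") -> SurvivalSample:
    """Load and validate a survival table.

    Raises ``ValueError`` naming the offending row (1-based, excluding
    the header) and column for missing values, non-positive times or
    status codes outside {0, 1}.  A file with only time/status columns
    yields an evaluation-only sample without covariates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    na = df.isna()
    if na.to_numpy().any():
        row = int(na.any(axis=1).idxmax())
        col = na.loc[row].idxmax()
        raise ValueError(f"{path}: missing value at row {row + 1}, "
                         f"column {col!r}")
    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        bad = times.isna() | (times <= 0)
        raise ValueError(
            f"{path}: non-positive or non-numeric time at row "
            f"{int(bad.idxmax()) + 1}"
        )
    status = pd.to_numeric(df[status_col], errors="coerce")
    if status.isna().any() or (~status.isin((0, 1))).any():
        bad = status.isna() | ~status.isin((0, 1))
        raise ValueError(
            f"{path}: status outside {{0, 1}} at row {int(bad.idxmax()) + 1}"
        )
    cov_cols = [c for c in df.columns if c not in (time_col, status_col)]
    X = None
    if cov_cols:
        X = df[cov_cols].apply(pd.to_numeric, errors="coerce")
        if X.isna().to_numpy().any():
            na = X.isna()
            row = int(na.any(axis=1).idxmax())
            col = na.loc[row].idxmax()
            raise ValueError(
                f"{path}: non-numeric covariate at row {row + 1}, "
                f"column {col!r}"
            )
        X = X.to_numpy(float)
    return SurvivalSample(times.to_numpy(float), status.to_numpy(),
                          X, tuple(cov_cols) if cov_cols else None)


def read_scores(path, column: str = "score") -> np.ndarray:
    """Read a one-column score file (CSV with header)."""
    df = pd.read_csv(path)
    if column in df.columns:
        return df[column].to_numpy(float)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(float)
    raise ValueError(f"{path}: no {column!r} column found")


def write_report(obj, path, seed=None, config: dict | None = None) -> None:
    """Serialise a result object.

    * :class:`CIndexBoostResults` and :class:`StabilityResults` -> JSON
    * DataFrames and score arrays -> CSV
    """
    path = Path(path)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }
    if isinstance(obj, CIndexBoostResults):
        payload = {"kind": "boost_model", **meta, "model": obj.to_dict()}
        path.write_text(json.dumps(payload, indent=1))
    elif isinstance(obj, StabilityResults):
        payload = {"kind": "stability", **meta, "result": obj.to_dict()}
        path.write_text(json.dumps(payload, indent=1))
    elif isinstance(obj, pd.DataFrame):
        obj.assign(seed=seed, config_hash=meta["config_hash"]).to_csv(
            path, index=False)
    elif isinstance(obj, np.ndarray):
        pd.DataFrame({"score": obj}).to_csv(path, index=False)
    else:
        raise TypeError(f"cannot serialise object of type {type(obj)!r}")


def read_model_json(path) -> CIndexBoostResults:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "boost_model":
        raise ValueError(f"{path}: not a boosting model report")
    return CIndexBoostResults.from_dict(payload["model"])


def read_stability_json(path) -> StabilityResults:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "stability":
        raise ValueError(f"{path}: not a stability report")
    return StabilityResults.from_dict(payload["result"])
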
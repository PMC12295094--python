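"""Delimited-text and JSON readers/writers.

Data files are plain CSV/TSV with a header row: feature columns plus one
target column.  Results (hyperparameters, fit summaries) are JSON with a
``schema_version`` field; optimization traces are CSV with one row per
evidence evaluation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .em import FitResult
from .errors import ParseError
from .posterior import Hyperparameters

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_fit_result",
    "write_trace",
    "load_hyperparameters",
    "save_hyperparameters",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def read_dataset(
    path: str | Path, target_column: str | int, delimiter: str = ","
) -> tuple[np.ndarray, np.ndarray]:
    """Read features X and targets T from a delimited text file.

    The header row names the columns; ``target_column`` may be a name or a
    positional index.  All remaining columns become features, in file
    order.  Raises :class:`ParseError` on empty files, missing target
    columns or non-numeric cells, naming the offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows below the header")

    if isinstance(target_column, int) and target_column not in df.columns:
        try:
            target_column = df.columns[target_column]
        except IndexError as exc:
            raise ParseError(
                f"{path}: target column index {target_column} out of range "
                f"for {df.shape[1]} columns"
            ) from exc
    if target_column not in df.columns:
        raise ParseError(
            f"{path}: target column {target_column!r} not found among {list(df.columns)}"
        )

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        col = bad.any(axis=0).idxmax()
        row = int(bad[col].idxmax())
        raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")

    T = numeric[target_column].to_numpy(dtype=float)
    X = numeric.drop(columns=[target_column]).to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ParseError(f"{path}: no feature columns besides the target")
    return X, T


def write_dataset(
    path: str | Path,
    X: np.ndarray,
    T: np.ndarray,
    target_column: str = "t",
    delimiter: str = ",",
) -> None:
    """Write features and targets as delimited text (inverse of
    :func:`read_dataset`)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = {f"x{i + 1}": X[:, i] for i in range(X.shape[1])}
    cols[target_column] = np.asarray(T, dtype=float).ravel()
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


def save_hyperparameters(path: str | Path, hp: Hyperparameters) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **hp.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_hyperparameters(path: str | Path) -> Hyperparameters:
    d = json.loads(Path(path).read_text())
    return Hyperparameters.from_dict(d)


def write_fit_result(path: str | Path, result: FitResult) -> None:
    """Serialize a fit summary (final hyperparameters, posterior moments,
    status) as JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "status": result.status,
        "n_restarts": result.n_restarts,
        "n_iterations": result.n_iterations,
        "log_evidence": result.log_evidence,
        "hyperparameters": result.hyperparameters.to_dict(),
        "posterior": {
            "m": result.posterior.m.tolist(),
            "C": result.posterior.C.tolist(),
            "rcond": result.posterior.rcond,
            "used_pseudo_inverse": result.posterior.used_pseudo_inverse,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_trace(path: str | Path, result: FitResult) -> None:
    """Write the per-iteration log-evidence trace as CSV."""
    rows = pd.DataFrame(
        {
            "iteration": [r.iteration for r in result.trace],
            "log_evidence": [r.log_evidence for r in result.trace],
            "pinv_flag": [int(r.used_pseudo_inverse) for r in result.trace],
        }
    )
    rows.to_csv(path, index=False)
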
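"""Response-matrix container, CSV round-trip, and extreme-score screening.

The analysis data structure is a persons × items matrix of dichotomous
responses (NaN = not administered) together with three per-person categorical
covariates: gender, school-age group, and CARS-classified symptom severity.
Joint maximum-likelihood Rasch estimation cannot locate persons or items with
perfect (all-1) or zero (all-0) observed scores, so screening removes them
iteratively before calibration and reports what was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "DataError",
    "GENDER_LEVELS",
    "AGE_LEVELS",
    "SYMPTOM_LEVELS",
    "read_responses",
    "write_responses",
    "screen_extremes",
]

GENDER_LEVELS = ("male", "female")
AGE_LEVELS = ("infant", "kindergarten", "primary", "junior_high", "high")
SYMPTOM_LEVELS = ("non_autism", "mild_moderate", "severe")

_COVARIATE_LEVELS = {
    "gender": GENDER_LEVELS,
    "age_group": AGE_LEVELS,
    "symptom_level": SYMPTOM_LEVELS,
}


class DataError(ValueError):
    """Raised on malformed response or covariate data."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Dichotomous responses plus per-person covariates.

    ``X`` is a persons × items DataFrame of float 0.0/1.0 with NaN for
    missing cells; index holds person ids, columns item ids (both strings,
    kept in file order).  ``covariates`` is indexed by the same person ids
    with columns gender / age_group / symptom_level.
    """

    X: pd.DataFrame
    covariates: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        X = self.X
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise DataError(f"need at least 2 persons and 2 items, got {X.shape}")
        values = X.to_numpy(dtype=float)
        obs = ~np.isnan(values)
        if not np.isin(values[obs], (0.0, 1.0)).all():
            bad = values[obs][~np.isin(values[obs], (0.0, 1.0))][0]
            raise DataError(f"non-dichotomous cell value {bad:g}; cells must be 0, 1 or missing")
        if X.index.has_duplicates:
            raise DataError("duplicate person ids")
        if X.columns.has_duplicates:
            raise DataError("duplicate item ids")
        if self.covariates is not None:
            cov = self.covariates
            if not X.index.equals(cov.index):
                raise DataError("covariate person ids do not match the response matrix")
            for col, levels in _COVARIATE_LEVELS.items():
                if col not in cov.columns:
                    raise DataError(f"covariates missing column {col!r}")
                unknown = set(cov[col].astype(str)) - set(levels)
                if unknown:
                    raise DataError(
                        f"unknown {col} level(s) {sorted(unknown)}; allowed: {list(levels)}"
                    )

    @property
    def n_persons(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def subset(self, persons=None, items=None) -> "ResponseMatrix":
        X = self.X
        if persons is not None:
            X = X.loc[persons]
        if items is not None:
            X = X[items]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[X.index]
        return ResponseMatrix(X=X, covariates=cov)


def read_responses(
    matrix_path: str | Path, covariates_path: str | Path | None = None
) -> ResponseMatrix:
    """Read a wide response CSV (person_id, item_*) and optional covariate CSV.

    Row and column order are preserved from file; empty cells are missing.
    Person ids must match exactly between the two files.
    """
    X = pd.read_csv(matrix_path, index_col=0, dtype={0: str})
    X.index = X.index.astype(str)
    X.columns = X.columns.astype(str)
    X = X.astype(float)
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, index_col="person_id", dtype=str)
        cov.index = cov.index.astype(str)
        missing = X.index.difference(cov.index)
        extra = cov.index.difference(X.index)
        if len(missing) or len(extra):
            raise DataError(
                "person ids do not match between responses and covariates "
                f"(missing from covariates: {list(missing[:5])}, "
                f"extra in covariates: {list(extra[:5])})"
            )
        cov = cov.loc[X.index]
    return ResponseMatrix(X=X, covariates=cov)


def write_responses(
    data: ResponseMatrix,
    matrix_path: str | Path,
    covariates_path: str | Path | None = None,
) -> None:
    """Write the CSV pair :func:`read_responses` consumes; missing cells stay empty."""
    out = data.X.copy()
    out.index.name = "person_id"
    # integers in the file, empty string for missing
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(matrix_path)
    if covariates_path is not None:
        if data.covariates is None:
            raise DataError("no covariates to write")
        cov = data.covariates.copy()
        cov.index.name = "person_id"
        cov.to_csv(covariates_path)


def screen_extremes(
    data: ResponseMatrix,
) -> tuple[ResponseMatrix, list[str], list[str]]:
    """Iteratively drop persons and items with all-0 or all-1 observed responses.

    Removing an extreme item can create a newly extreme person (and vice
    versa), so passes alternate until the matrix is stable.  Returns the kept
    matrix plus the removed person and item ids in removal order.
    """
    X = data.X
    dropped_persons: list[str] = []
    dropped_items: list[str] = []
    while True:
        values = X.to_numpy(dtype=float)
        obs = ~np.isnan(values)
        with np.errstate(invalid="ignore"):
            row_sum = np.nansum(values, axis=1)
            row_n = obs.sum(axis=1)
            col_sum = np.nansum(values, axis=0)
            col_n = obs.sum(axis=0)
        extreme_rows = (row_sum == 0) | (row_sum == row_n)
        extreme_cols = (col_sum == 0) | (col_sum == col_n)
        if not extreme_rows.any() and not extreme_cols.any():
            break
        dropped_persons.extend(X.index[extreme_rows])
        dropped_items.extend(X.columns[extreme_cols])
        X = X.loc[~extreme_rows, ~extreme_cols]
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise DataError(
                "extreme-score screening removed too much data; "
                "fewer than 2 persons or items remain"
            )
    cov = None if data.covariates is None else data.covariates.loc[X.index]
    return ResponseMatrix(X=X, covariates=cov), dropped_persons, dropped_items
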
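"""Data model for competing-risk samples and step-function machinery.

A competing-risk sample holds, per subject, a strictly positive follow-up
time, a status code (0 = censored, 1 = primary event, 2 = competing event)
and optional real-valued covariates.  A single competing cause is assumed;
multiple competing causes must be collapsed to code 2 before loading.

Step functions are right-continuous piecewise-constant functions of time and
represent every nonparametric estimate in the package: the censoring survival
function G, cumulative incidence functions, and the Breslow baseline
cumulative subdistribution hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    MissingColumnError,
    MissingValueError,
    NonNumericTimeError,
    NonPositiveTimeError,
    StatusCodeError,
)

VALID_STATUS = (0, 1, 2)


@dataclass
class CompetingRiskDataset:
    """Subject-level competing-risk data.

    Parameters
    ----------
    subject_id : array-like
        Unique subject identifiers (row order is preserved throughout).
    time : array-like of float
        Strictly positive follow-up times, all in the same (uninterpreted)
        unit; prediction horizons must use the same unit.
    status : array-like of int
        0 censored, 1 primary event, 2 competing event.
    covariates : pandas.DataFrame, optional
        Named real-valued columns, no missing values.
    """

    subject_id: np.ndarray
    time: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        self.covariates = self.covariates.reset_index(drop=True)
        self._validate()

    def _validate(self):
        n = len(self.time)
        if len(self.subject_id) != n or len(self.status) != n:
            raise ValueError("subject_id, time and status must have equal length")
        if not np.all(np.isfinite(self.time)):
            raise NonNumericTimeError("follow-up times must be finite numbers")
        bad = np.nonzero(self.time <= 0)[0]
        if bad.size:
            raise NonPositiveTimeError(
                f"follow-up time must be > 0; offending row(s): {bad[:5].tolist()}"
            )
        status_arr = np.asarray(self.status)
        if status_arr.dtype.kind not in "iu":
            as_float = np.asarray(status_arr, dtype=float)
            as_int = as_float.astype(int)
            if not np.all(as_float == as_int):
                raise StatusCodeError("status codes must be integers in {0, 1, 2}")
            status_arr = as_int
        self.status = status_arr.astype(int)
        bad = np.nonzero(~np.isin(self.status, VALID_STATUS))[0]
        if bad.size:
            raise StatusCodeError(
                f"status must be in {{0, 1, 2}}; offending row(s): {bad[:5].tolist()} "
                f"with value(s) {self.status[bad[:5]].tolist()}"
            )
        uniq, counts = np.unique(self.subject_id, return_counts=True)
        if np.any(counts > 1):
            raise DuplicateIdError(
                f"duplicated subject_id value(s): {uniq[counts > 1][:5].tolist()}"
            )
        if len(self.covariates) not in (0, n):
            raise ValueError("covariates must have one row per subject")
        if len(self.covariates) and self.covariates.isna().any().any():
            cols = self.covariates.columns[self.covariates.isna().any()].tolist()
            raise MissingValueError(f"missing values in covariate column(s): {cols}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = self.covariate_names if names is None else names
        return self.covariates[names].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "time": self.time, "status": self.status}
        )
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def subset(self, mask_or_index) -> "CompetingRiskDataset":
        """Row subset (boolean mask or integer index), preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        cov = self.covariates.iloc[idx] if len(self.covariates) else pd.DataFrame()
        return CompetingRiskDataset(
            self.subject_id[idx], self.time[idx], self.status[idx], cov
        )

    def administratively_censored(self, t0: float) -> "CompetingRiskDataset":
        """Recode subjects still under follow-up after ``t0`` as censored at ``t0``."""
        time = self.time.copy()
        status = self.status.copy()
        late = time > t0
        time[late] = t0
        status[late] = 0
        return CompetingRiskDataset(self.subject_id, time, status, self.covariates)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompetingRiskDataset):
            return NotImplemented
        return (
            np.array_equal(self.subject_id, other.subject_id)
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.status, other.status)
            and list(self.covariates.columns) == list(other.covariates.columns)
            and (
                self.covariates.empty
                or np.array_equal(
                    self.covariates.to_numpy(), other.covariates.to_numpy()
                )
            )
        )


@dataclass
class StepFunction:
    """Right-continuous piecewise-constant function of time.

    The function equals ``initial_value`` on ``[0, jump_times[0])`` and
    ``values[i]`` on ``[jump_times[i], jump_times[i+1])``.
    """

    jump_times: np.ndarray
    values: np.ndarray
    initial_value: float = 1.0

    def __post_init__(self):
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_times.size != self.values.size:
            raise ValueError("jump_times and values must have equal length")
        if self.jump_times.size:
            if np.any(self.jump_times <= 0):
                raise ValueError("jump times must be strictly positive")
            if np.any(np.diff(self.jump_times) <= 0):
                raise ValueError("jump times must be strictly increasing")

    def __call__(self, t, side: str = "right"):
        """Evaluate at ``t`` (scalar or array).

        ``side="right"`` gives f(t); ``side="left"`` gives the limit from
        below, f(t-).  Both equal ``initial_value`` before the first jump.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("evaluation time must be nonnegative")
        if side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        idx = np.searchsorted(self.jump_times, t, side="right" if side == "right" else "left")
        padded = np.concatenate(([self.initial_value], self.values))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "value": self.values})

    def write_csv(self, path) -> None:
        """Serialize as two-column CSV, with ``initial_value`` on a comment line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# initial_value={self.initial_value!r}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "StepFunction":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip()
            if not header.startswith("# initial_value="):
                raise ValueError("missing initial_value header comment")
            initial = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        return cls(df["time"].to_numpy(), df["value"].to_numpy(), initial)


def evaluate_step(f: StepFunction, t, side: str = "right"):
    """Functional alias for :meth:`StepFunction.__call__`."""
    return f(t, side=side)


@dataclass
class RiskPredictionSet:
    """Predicted cumulative incidence at a fixed horizon, aligned to a dataset.

    ``predicted[i]`` is the predicted probability that subject ``i``
    experiences the primary event before ``horizon_t0``, produced by whatever
    prediction model is under assessment.
    """

    horizon_t0: float
    predicted: np.ndarray

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.horizon_t0 <= 0:
            raise ValueError("horizon_t0 must be positive")
        if np.any((self.predicted < 0) | (self.predicted > 1)) or np.any(
            ~np.isfinite(self.predicted)
        ):
            raise ValueError("predicted risks must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.predicted)


def read_dataset(
    path,
    id_col: str = "id",
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: list[str] | None = None,
) -> CompetingRiskDataset:
    """Read a competing-risk dataset from a comma-separated text file.

    The file must have a header row; times use '.' as the decimal separator.
    If ``covariate_cols`` is None, every column other than the id, time and
    status columns is treated as a covariate.
    """
    df = pd.read_csv(path, sep=",")
    needed = [id_col, time_col, status_col] + (covariate_cols or [])
    for col in needed:
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} not found in {path}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (id_col, time_col, status_col)]
    time = pd.to_numeric(df[time_col], errors="coerce")
    if time.isna().any():
        rows = df.index[time.isna()].tolist()[:5]
        raise NonNumericTimeError(f"non-numeric time value(s) at row(s) {rows}")
    cov = df[covariate_cols].apply(pd.to_numeric, errors="coerce")
    return CompetingRiskDataset(
        df[id_col].to_numpy(), time.to_numpy(), df[status_col].to_numpy(), cov
    )


def write_dataset(dataset: CompetingRiskDataset, path, id_col: str = "id",
                  time_col: str = "time", status_col: str = "status") -> None:
    """Write a dataset as comma-separated text (round-trips with read_dataset)."""
    df = dataset.to_frame().rename(
        columns={"subject_id": id_col, "time": time_col, "status": status_col}
    )
    df.to_csv(path, index=False)
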
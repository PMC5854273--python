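"""Domain types and registry I/O.

A *registry* is a tabular cohort: one row per patient, covariates described
by a :class:`VariableSchema` list, a follow-up time in days and an event
indicator (1 = death observed, 0 = right-censored at that time).  Raw
registries are held as pandas DataFrames with explicit missing values
(``NaN``); the modelling modules consume the fully-encoded, complete
:class:`SurvivalDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VARIABLE_KINDS = ("continuous", "binary", "categorical")

#: Values treated as missing in registry CSV cells.
MISSING_MARKERS = ("", "NA")


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one registry variable.

    Parameters
    ----------
    name : str
        Column name in the registry CSV.
    kind : {"continuous", "binary", "categorical"}
    categories : tuple of str
        Category labels (categorical only, >= 2); the first is the
        reference level under dummy coding.
    unit : str
        Free-text unit, for reports only.
    """

    name: str
    kind: str
    categories: tuple = ()
    unit: str = ""

    def __post_init__(self):
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if len(self.categories) < 2:
                raise ValueError(f"categorical variable {self.name!r} needs >= 2 categories")
        elif self.categories:
            raise ValueError(f"{self.kind} variable {self.name!r} must not declare categories")
        object.__setattr__(self, "categories", tuple(self.categories))


def check_schema(schema: Sequence[VariableSchema]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names in schema: {dup}")


@dataclass
class SurvivalDataset:
    """Encoded, complete survival data: the universal model input.

    ``X`` is the n x p covariate matrix after encoding (dummies for
    categoricals), ``time`` the follow-up in days (> 0), ``event`` the
    death indicator, ``center`` optional center labels for grouped
    cross-validation.
    """

    X: np.ndarray
    variable_names: list
    time: np.ndarray
    event: np.ndarray
    center: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.variable_names = list(self.variable_names)
        n, p = self.X.shape
        if len(self.variable_names) != p:
            raise ValueError("variable_names length does not match X columns")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match X rows")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all follow-up times must be finite and > 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; run preprocessing first")
        if self.center is not None:
            self.center = np.asarray(self.center)
            if self.center.shape != (n,):
                raise ValueError("center length does not match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            X=self.X[idx],
            variable_names=list(self.variable_names),
            time=self.time[idx],
            event=self.event[idx],
            center=None if self.center is None else self.center[idx],
        )

    def select_variables(self, names: Sequence[str]) -> "SurvivalDataset":
        cols = [self.variable_names.index(n) for n in names]
        return SurvivalDataset(
            X=self.X[:, cols],
            variable_names=list(names),
            time=self.time,
            event=self.event,
            center=self.center,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variable_names)
        df["time"] = self.time
        df["event"] = self.event
        return df


@dataclass
class CalibrationResult:
    """Binned observed-vs-expected comparison with its chi-square test.

    Shared output type of single-time (Hosmer-Lemeshow) calibration and
    distributional (D-)calibration.  ``observed`` may be fractional:
    censored patients contribute fractional mass in the D-calibration
    construction.
    """

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    dof: int
    p_value: float
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.statistic < 0 or self.dof < 1:
            raise ValueError("invalid chi-square statistic or dof")
        expected_p = float(stats.chi2.sf(self.statistic, self.dof))
        if abs(self.p_value - expected_p) > 1e-10:
            raise ValueError("p_value inconsistent with statistic and dof")


def read_registry_csv(
    path,
    schema: Sequence[VariableSchema],
    time_col: str = "time",
    event_col: str = "event",
    center_col: Optional[str] = None,
) -> pd.DataFrame:
    """Read a registry CSV into a typed DataFrame with explicit missingness.

    Missing cells (empty or ``NA``) become NaN.  Numeric columns that fail
    to parse, nonpositive times and event values outside {0, 1} raise
    ``ValueError`` naming the offending row (1-based, excluding the header)
    and column.
    """
    check_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=list(MISSING_MARKERS))
    for col in (time_col, event_col):
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} not found in {path}")

    out = pd.DataFrame(index=raw.index)

    def _numeric(col: str) -> pd.Series:
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"unparseable numeric value {raw[col][bad.idxmax()]!r} in column {col!r}, row {row}")
        return series

    time = _numeric(time_col)
    if time.isna().any():
        row = int(time.isna().idxmax()) + 1
        raise ValueError(f"missing follow-up time in row {row}")
    if (time <= 0).any():
        row = int((time <= 0).idxmax()) + 1
        raise ValueError(f"nonpositive follow-up time in row {row}")
    event = _numeric(event_col)
    if event.isna().any() or not event.isin([0, 1]).all():
        bad = event.isna() | ~event.isin([0, 1])
        row = int(bad.idxmax()) + 1
        raise ValueError(f"event indicator outside {{0,1}} in row {row}")

    for var in schema:
        if var.name not in raw.columns:
            raise ValueError(f"schema variable {var.name!r} not found in {path}")
        if var.kind in ("continuous", "binary"):
            col = _numeric(var.name)
            if var.kind == "binary":
                bad = col.notna() & ~col.isin([0, 1])
                if bad.any():
                    row = int(bad.idxmax()) + 1
                    raise ValueError(f"binary variable {var.name!r} outside {{0,1}} in row {row}")
            out[var.name] = col
        else:
            col = raw[var.name].astype("string")
            bad = col.notna() & ~col.isin(var.categories)
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise ValueError(
                    f"categorical variable {var.name!r} has unknown level "
                    f"{col[bad.idxmax()]!r} in row {row}"
                )
            out[var.name] = col

    out[time_col] = time
    out[event_col] = event.astype(int)
    if center_col is not None:
        if center_col not in raw.columns:
            raise ValueError(f"center column {center_col!r} not found in {path}")
        out[center_col] = raw[center_col]
    return out


def encoded_variable_names(schema: Sequence[VariableSchema]) -> list:
    """Column names of the design matrix: dummies drop the reference level."""
    names = []
    for var in schema:
        if var.kind == "categorical":
            names.extend(f"{var.name}[{cat}]" for cat in var.categories[1:])
        else:
            names.append(var.name)
    return names


def encode_records(records: pd.DataFrame, schema: Sequence[VariableSchema]) -> pd.DataFrame:
    """Dummy-code categoricals; pass continuous/binary columns through.

    Requires complete records (no NaN among schema columns).
    """
    check_schema(schema)
    cols = {}
    for var in schema:
        series = records[var.name]
        if series.isna().any():
            raise ValueError(f"variable {var.name!r} still has missing values; impute first")
        if var.kind == "categorical":
            for cat in var.categories[1:]:
                cols[f"{var.name}[{cat}]"] = (series == cat).astype(float)
        else:
            cols[var.name] = series.astype(float)
    return pd.DataFrame(cols, index=records.index)


def make_dataset(
    records: pd.DataFrame,
    schema: Sequence[VariableSchema],
    time_col: str = "time",
    event_col: str = "event",
    center_col: Optional[str] = None,
) -> SurvivalDataset:
    """Encode complete records into a :class:`SurvivalDataset`."""
    design = encode_records(records, schema)
    center = records[center_col].to_numpy() if center_col else None
    return SurvivalDataset(
        X=design.to_numpy(),
        variable_names=list(design.columns),
        time=records[time_col].to_numpy(dtype=float),
        event=records[event_col].to_numpy(),
        center=center,
    )
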
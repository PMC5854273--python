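"""Registry preprocessing and Cox-based variable selection.

The transplant-registry conventions implemented here: laboratory values are
capped at clinically meaningful ceilings (INR at 5, MELD at 40), creatinine
is set to 4.0 mg/dL for patients dialyzed within the week before transplant,
selected laboratory variables enter both in natural and log form, variables
missing in more than 40% of cases are excluded, and remaining gaps are
filled by mean imputation (mode for binary/categorical variables).

Variable selection is the standard two-stage Cox filter: a univariate
proportional-hazards screen retaining variables with Wald p <= 0.1, then
multivariate backward elimination removing the least significant variable
one at a time until all remaining have p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coxkp import fit_cox_partial_likelihood
from .data import SurvivalDataset, VariableSchema

logger = logging.getLogger(__name__)

DEFAULT_CAPS = {"INR": 5.0, "MELD": 40.0}
DEFAULT_DIALYSIS_RULE = ("creatinine", "dialysis", 4.0)
DEFAULT_LOG_VARIABLES = ("INR", "bilirubin", "creatinine")


@dataclass
class SelectionResult:
    """Outcome of the two-stage Cox variable-selection filter."""

    considered: list
    univariate_p: dict
    retained_after_univariate: list
    final_variables: list
    multivariate_hr: dict = field(default_factory=dict)

    def __post_init__(self):
        if not set(self.final_variables) <= set(self.retained_after_univariate):
            raise ValueError("final variables must come from the univariate survivors")
        if not set(self.retained_after_univariate) <= set(self.considered):
            raise ValueError("univariate survivors must come from the considered set")


def apply_clinical_caps(
    records: pd.DataFrame,
    caps: Optional[dict] = None,
    dialysis_rule: Optional[tuple] = DEFAULT_DIALYSIS_RULE,
) -> pd.DataFrame:
    """Cap laboratory values and apply the dialysis-creatinine override.

    ``caps`` maps column -> ceiling (default INR at 5, MELD at 40);
    ``dialysis_rule = (target, flag, value)`` sets ``target`` to ``value``
    wherever the binary ``flag`` column is 1.  Columns absent from the
    records are skipped with a logged notice; missing cells are untouched.
    """
    caps = DEFAULT_CAPS if caps is None else caps
    out = records.copy()
    for col, ceiling in caps.items():
        if col not in out.columns:
            logger.info("cap for %r skipped: column not present", col)
            continue
        out[col] = out[col].clip(upper=ceiling)
    if dialysis_rule is not None:
        target, flag, value = dialysis_rule
        if target in out.columns and flag in out.columns:
            mask = out[flag] == 1
            out.loc[mask, target] = value
        else:
            logger.info("dialysis rule (%r <- %s when %r) skipped: column not present", target, value, flag)
    return out


def add_log_transforms(records: pd.DataFrame, variables: Sequence[str] = DEFAULT_LOG_VARIABLES) -> pd.DataFrame:
    """Append natural-log columns ``log_<v>``; missing propagates to missing."""
    out = records.copy()
    for var in variables:
        if var not in out.columns:
            logger.info("log transform for %r skipped: column not present", var)
            continue
        series = out[var]
        bad = series.notna() & (series <= 0)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"nonpositive value in {var!r} (row {row}) cannot be log-transformed")
        out[f"log_{var}"] = np.log(series)
    return out


def log_schema(variables: Sequence[str] = DEFAULT_LOG_VARIABLES) -> list:
    return [VariableSchema(f"log_{v}", "continuous") for v in variables]


def drop_sparse_variables(
    records: pd.DataFrame,
    threshold: float = 0.40,
    protect: Sequence[str] = ("time", "event", "center"),
):
    """Remove variables missing in strictly more than ``threshold`` of rows.

    Returns ``(records, dropped)`` where ``dropped`` maps each removed
    variable to its missing fraction.
    """
    if not 0 < threshold < 1:
        raise ValueError("sparsity threshold must lie in (0, 1)")
    frac = records.isna().mean()
    dropped = {
        col: float(f)
        for col, f in frac.items()
        if f > threshold and col not in protect
    }
    return records.drop(columns=list(dropped)), dropped


def mean_impute(records: pd.DataFrame, schema: Sequence[VariableSchema]):
    """Fill missing values: mean for continuous, mode for binary/categorical.

    Returns ``(records, report)`` with ``report[var] = (imputed_value, count)``.
    A variable that is entirely missing raises (it should have been dropped
    as sparse).  Mode ties break toward the smaller value for determinism.
    """
    out = records.copy()
    report = {}
    for var in schema:
        if var.name not in out.columns:
            continue
        series = out[var.name]
        missing = series.isna()
        if not missing.any():
            continue
        if missing.all():
            raise ValueError(f"variable {var.name!r} has no observed values")
        if var.kind == "continuous":
            value = float(series.mean())
        else:
            counts = series.value_counts()
            top = counts[counts == counts.max()]
            value = sorted(top.index)[0]
        out.loc[missing, var.name] = value
        report[var.name] = (value, int(missing.sum()))
    return out, report


def univariate_cox_filter(dataset: SurvivalDataset, alpha: float = 0.1):
    """Single-covariate proportional-hazards screen.

    Retains variables whose Wald p-value is <= ``alpha`` (the boundary is
    kept).  Variables whose fit fails to converge are excluded with a
    logged warning.  Returns ``(retained_names, p_values)``.
    """
    if dataset.n_events < 2:
        raise ValueError("univariate Cox screen requires at least 2 events")
    retained, p_values = [], {}
    for name in dataset.variable_names:
        try:
            fit = fit_cox_partial_likelihood(dataset, variables=[name])
        except ValueError as exc:
            logger.warning("univariate Cox fit failed for %r: %s", name, exc)
            continue
        p = float(fit.p_values[0])
        p_values[name] = p
        if p <= alpha:
            retained.append(name)
    return retained, p_values


def backward_elimination(
    dataset: SurvivalDataset,
    variables: Sequence[str],
    alpha: float = 0.05,
    univariate_p: Optional[dict] = None,
) -> SelectionResult:
    """Multivariate Cox backward elimination at Wald level ``alpha``.

    One variable (the largest p among those above ``alpha``) is removed per
    refit; correlated covariates are therefore re-assessed after each
    removal.  An empty final set is a valid outcome, not an error.
    """
    variables = list(variables)
    unknown = set(variables) - set(dataset.variable_names)
    if unknown:
        raise ValueError(f"variables not in dataset: {sorted(unknown)}")

    current = list(variables)
    fit = None
    while current:
        fit = fit_cox_partial_likelihood(dataset, variables=current)
        worst_idx = int(np.argmax(fit.p_values))
        if fit.p_values[worst_idx] <= alpha:
            break
        removed = current.pop(worst_idx)
        logger.info("backward elimination removed %r (p=%.3g)", removed, fit.p_values[worst_idx])
        fit = None

    multivariate_hr = {}
    if current and fit is not None:
        for i, name in enumerate(fit.variable_names):
            multivariate_hr[name] = (
                float(fit.hazard_ratios[i]),
                float(fit.ci_lower[i]),
                float(fit.ci_upper[i]),
                float(fit.p_values[i]),
            )
    return SelectionResult(
        considered=list(variables),
        univariate_p=dict(univariate_p or {}),
        retained_after_univariate=list(variables),
        final_variables=current,
        multivariate_hr=multivariate_hr,
    )


def select_variables(
    dataset: SurvivalDataset,
    univariate_alpha: float = 0.1,
    multivariate_alpha: float = 0.05,
    skip_univariate: bool = False,
) -> SelectionResult:
    """Full two-stage filter: univariate screen then backward elimination."""
    if skip_univariate:
        retained, p_values = list(dataset.variable_names), {}
    else:
        retained, p_values = univariate_cox_filter(dataset, alpha=univariate_alpha)
    result = backward_elimination(dataset, retained, alpha=multivariate_alpha, univariate_p=p_values)
    return SelectionResult(
        considered=list(dataset.variable_names),
        univariate_p=p_values,
        retained_after_univariate=retained,
        final_variables=result.final_variables,
        multivariate_hr=result.multivariate_hr,
    )
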
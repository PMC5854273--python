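"""End-to-end modelling pipeline: preprocessing state + fitted model.

Couples the clinical preprocessing (caps, log transforms, sparse-variable
drop, mean imputation), in-sample Cox variable selection and either
survival learner into one serializable object, so that a model trained by
``pssp-surv train`` can be applied to new patients by ``pssp-surv predict``
with the *training* imputation values and variable set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coxkp, pssp
from .curves import SurvivalCurve
from .data import SurvivalDataset, VariableSchema, encode_records, make_dataset
from .preprocessing import (
    DEFAULT_CAPS,
    DEFAULT_DIALYSIS_RULE,
    DEFAULT_LOG_VARIABLES,
    SelectionResult,
    add_log_transforms,
    apply_clinical_caps,
    drop_sparse_variables,
    log_schema,
    mean_impute,
    select_variables,
)


@dataclass
class PreprocessingConfig:
    """Tunable preprocessing rules; defaults follow the clinical conventions."""

    caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))
    dialysis_rule: bool = True
    log_variables: tuple = DEFAULT_LOG_VARIABLES
    sparsity_threshold: float = 0.40
    univariate_alpha: float = 0.10
    multivariate_alpha: float = 0.05
    skip_univariate: bool = False


def preprocess_records(
    records: pd.DataFrame,
    schema: Sequence[VariableSchema],
    config: Optional[PreprocessingConfig] = None,
    impute_values: Optional[dict] = None,
):
    """Run caps -> logs -> sparse-drop -> imputation.

    Returns ``(records, schema, state)`` where ``state`` carries everything
    needed to replay the transform on new patients (training imputation
    values, dropped variables).  Passing ``impute_values`` replays a stored
    state instead of refitting it (sparse-drop then removes exactly the
    stored variables).
    """
    config = config or PreprocessingConfig()
    schema = list(schema)
    rule = DEFAULT_DIALYSIS_RULE if config.dialysis_rule else None
    out = apply_clinical_caps(records, caps=config.caps, dialysis_rule=rule)
    present_logs = [v for v in config.log_variables if v in out.columns]
    out = add_log_transforms(out, present_logs)
    schema = schema + log_schema(present_logs)

    if impute_values is None:
        out, dropped = drop_sparse_variables(out, threshold=config.sparsity_threshold)
        schema = [v for v in schema if v.name not in dropped]
        out, impute_report = mean_impute(out, schema)
        state = {
            "dropped": sorted(dropped),
            "impute_values": {k: v for k, (v, _) in impute_report.items()},
            "impute_counts": {k: c for k, (_, c) in impute_report.items()},
        }
        # variables observed complete in training still need a stored value
        for var in schema:
            if var.name not in state["impute_values"] and var.kind == "continuous":
                state["impute_values"][var.name] = float(out[var.name].mean())
    else:
        dropped = impute_values.get("dropped", [])
        out = out.drop(columns=[c for c in dropped if c in out.columns])
        schema = [v for v in schema if v.name not in dropped]
        for name, value in impute_values.get("impute_values", {}).items():
            if name in out.columns:
                out[name] = out[name].fillna(value)
        for var in schema:  # binary/categorical gaps on new patients: refuse
            if out[var.name].isna().any():
                raise ValueError(f"variable {var.name!r} missing and no stored imputation value")
        state = impute_values
    return out, schema, state


@dataclass
class FittedPipeline:
    """Preprocessing state, selected variables and the fitted learner."""

    model_kind: str  # "pssp" | "cox_kp"
    schema: list
    preprocessing_state: dict
    selection: Optional[SelectionResult]
    final_variables: list
    model: object
    config: PreprocessingConfig = field(default_factory=PreprocessingConfig)


def fit_pipeline(
    records: pd.DataFrame,
    schema: Sequence[VariableSchema],
    model_kind: str = "pssp",
    config: Optional[PreprocessingConfig] = None,
    run_selection: bool = True,
    grid_k: int = 10,
    regularization="cv",
    time_col: str = "time",
    event_col: str = "event",
    center_col: Optional[str] = None,
) -> FittedPipeline:
    """Preprocess, select variables in-sample, and fit the chosen learner."""
    if model_kind not in ("pssp", "cox_kp"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    config = config or PreprocessingConfig()
    clean, schema2, state = preprocess_records(records, schema, config)
    clean[time_col] = records[time_col]
    clean[event_col] = records[event_col]
    if center_col and center_col in records.columns:
        clean[center_col] = records[center_col]
    dataset = make_dataset(clean, schema2, time_col, event_col, center_col if center_col in clean.columns else None)

    selection = None
    final = list(dataset.variable_names)
    if run_selection:
        selection = select_variables(
            dataset,
            univariate_alpha=config.univariate_alpha,
            multivariate_alpha=config.multivariate_alpha,
            skip_univariate=config.skip_univariate,
        )
        final = list(selection.final_variables)
    model_ds = dataset.select_variables(final)

    if model_kind == "pssp":
        model = pssp.fit_pssp(model_ds, k=grid_k, regularization=regularization)
    else:
        model = coxkp.fit_cox_kp(model_ds)
    return FittedPipeline(
        model_kind=model_kind,
        schema=list(schema2),
        preprocessing_state=state,
        selection=selection,
        final_variables=final,
        model=model,
        config=config,
    )


def pipeline_predict(fp: FittedPipeline, records: pd.DataFrame):
    """Curves for new patients after replaying the stored preprocessing."""
    base_schema = [v for v in fp.schema if not v.name.startswith("log_")]
    clean, schema, _ = preprocess_records(records, base_schema, fp.config, impute_values=fp.preprocessing_state)
    design = encode_records(clean, schema)
    missing = [v for v in fp.final_variables if v not in design.columns]
    if missing:
        raise ValueError(f"patient records lack model variables: {missing}")
    X = design[fp.final_variables].to_numpy()
    if fp.model_kind == "pssp":
        return [pssp.predict_curve(fp.model, x) for x in X]
    return [coxkp.predict_cox_curve(fp.model, x) for x in X]


# ---------------------------------------------------------------------------
# serialization


def save_pipeline(fp: FittedPipeline, path) -> None:
    if fp.model_kind == "pssp":
        model_payload = pssp.pssp_model_to_dict(fp.model)
    else:
        model_payload = coxkp.cox_model_to_dict(fp.model)
    payload = {
        "kind": fp.model_kind,
        "schema": [asdict(v) for v in fp.schema],
        "preprocessing_state": fp.preprocessing_state,
        "config": asdict(fp.config),
        "final_variables": list(fp.final_variables),
        "selection": None
        if fp.selection is None
        else {
            "considered": fp.selection.considered,
            "univariate_p": fp.selection.univariate_p,
            "retained_after_univariate": fp.selection.retained_after_univariate,
            "final_variables": fp.selection.final_variables,
            "multivariate_hr": {k: list(v) for k, v in fp.selection.multivariate_hr.items()},
        },
        "model": model_payload,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_pipeline(path) -> FittedPipeline:
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload["kind"]
    model = (
        pssp.pssp_model_from_dict(payload["model"])
        if kind == "pssp"
        else coxkp.cox_model_from_dict(payload["model"])
    )
    sel = payload.get("selection")
    selection = None
    if sel is not None:
        selection = SelectionResult(
            considered=sel["considered"],
            univariate_p=sel["univariate_p"],
            retained_after_univariate=sel["retained_after_univariate"],
            final_variables=sel["final_variables"],
            multivariate_hr={k: tuple(v) for k, v in sel["multivariate_hr"].items()},
        )
    cfg = payload.get("config", {})
    cfg["log_variables"] = tuple(cfg.get("log_variables", DEFAULT_LOG_VARIABLES))
    return FittedPipeline(
        model_kind=kind,
        schema=[
            VariableSchema(v["name"], v["kind"], tuple(v.get("categories") or ()), v.get("unit", ""))
            for v in payload["schema"]
        ],
        preprocessing_state=payload["preprocessing_state"],
        selection=selection,
        final_variables=list(payload["final_variables"]),
        model=model,
        config=PreprocessingConfig(**cfg),
    )


def read_schema_yaml(path) -> list:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        VariableSchema(e["name"], e["kind"], tuple(e.get("categories") or ()), e.get("unit", ""))
        for e in entries
    ]


def write_schema_yaml(schema: Sequence[VariableSchema], path) -> None:
    entries = [
        {"name": v.name, "kind": v.kind, "categories": list(v.categories), "unit": v.unit}
        for v in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
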
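"""Cox proportional-hazards comparator with Kalbfleisch-Prentice baseline.

The Cox model supplies a single risk score exp(beta' x) per patient; to turn
it into an individual survival curve we estimate the baseline survival S0 by
the Kalbfleisch-Prentice discrete self-consistency construction and raise it
to the patient's hazard ratio:

    S(t | x) = S0(t) ** exp(beta' (x - x_bar)).

At each distinct event time t_i the interval survival factor alpha_i solves

    sum_{j in D_i} e^{eta_j} / (1 - alpha_i^{e^{eta_j}}) = sum_{k in R_i} e^{eta_k}

over the death set D_i and risk set R_i (eta = centered linear predictor).
With a single death the equation has the closed form
alpha_i = (1 - e^{eta_i} / sum_{R_i} e^{eta_k}) ** e^{-eta_i}; under ties it
is solved numerically.  With beta = 0 every alpha_i reduces to
1 - d_i / n_i, i.e. the Kaplan-Meier product-limit factor, so the whole
pipeline collapses to KM — a useful correctness oracle.

Partial-likelihood maximization itself is standard and is delegated to
lifelines (Efron tie handling); this module owns the baseline construction
and the curve assembly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.optimize import brentq

from .curves import SurvivalCurve
from .data import SurvivalDataset


@dataclass
class CoxFit:
    """Partial-likelihood estimates: coefficients, covariance, Wald tests."""

    beta: np.ndarray
    covariance: np.ndarray
    variable_names: list
    standard_errors: np.ndarray
    p_values: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    log_likelihood: float


@dataclass
class CoxModel:
    """Fitted Cox-KP model producing individual survival step curves."""

    beta: np.ndarray
    variable_names: list
    baseline_times: np.ndarray
    baseline_survival: np.ndarray
    covariate_means: np.ndarray
    ties_method: str = "efron"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_survival = np.asarray(self.baseline_survival, dtype=float)
        self.covariate_means = np.asarray(self.covariate_means, dtype=float)
        if self.baseline_times.shape != self.baseline_survival.shape:
            raise ValueError("baseline times/survival length mismatch")
        if np.any(np.diff(self.baseline_survival) > 1e-12):
            raise ValueError("baseline survival must be non-increasing")
        if np.any(self.baseline_survival < 0) or np.any(self.baseline_survival > 1):
            raise ValueError("baseline survival must lie in [0, 1]")


def fit_cox_partial_likelihood(
    dataset: SurvivalDataset,
    variables: Optional[Sequence[str]] = None,
    ties_method: str = "efron",
    penalizer: float = 0.0,
) -> CoxFit:
    """Maximize the Cox partial likelihood; Wald inference per covariate.

    Raises ``ValueError`` on < 2 events, constant covariates, or
    non-convergence (including separation).
    """
    if ties_method != "efron":
        raise NotImplementedError("only Efron tie handling is supported")
    if variables is not None:
        dataset = dataset.select_variables(variables)
    if dataset.n_events < 2:
        raise ValueError("Cox fit requires at least 2 events")
    spread = dataset.X.max(axis=0) - dataset.X.min(axis=0)
    if np.any(spread == 0):
        bad = [n for n, s in zip(dataset.variable_names, spread) if s == 0]
        raise ValueError(f"constant covariates cannot enter a Cox model: {bad}")

    df = dataset.to_frame()
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox partial likelihood did not converge: {exc}") from exc

    summary = cph.summary.loc[dataset.variable_names]
    return CoxFit(
        beta=summary["coef"].to_numpy(),
        covariance=cph.variance_matrix_.loc[dataset.variable_names, dataset.variable_names].to_numpy(),
        variable_names=list(dataset.variable_names),
        standard_errors=summary["se(coef)"].to_numpy(),
        p_values=summary["p"].to_numpy(),
        hazard_ratios=summary["exp(coef)"].to_numpy(),
        ci_lower=summary["exp(coef) lower 95%"].to_numpy(),
        ci_upper=summary["exp(coef) upper 95%"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
    )


def _kp_alpha(eta_deaths: np.ndarray, risk_total: float) -> float:
    """Solve the KP self-consistency equation for one event time."""
    if eta_deaths.size == 1:
        eta = float(eta_deaths[0])
        w = np.exp(eta)
        inner = 1.0 - w / risk_total
        if inner <= 0.0:
            return 0.0
        return float(inner ** np.exp(-eta))

    w = np.exp(eta_deaths)
    death_total = float(w.sum())
    if risk_total - death_total <= 1e-12 * risk_total:
        return 0.0  # everyone at risk dies: survival factor hits zero

    def f(alpha: float) -> float:
        return float(np.sum(w / (1.0 - alpha**w)) - risk_total)

    # f is increasing in alpha with f(0+) = death_total - risk_total < 0
    lo, hi = 1e-15, 1.0 - 1e-15
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def kp_baseline_survival(dataset: SurvivalDataset, beta: np.ndarray, covariate_means=None):
    """Kalbfleisch-Prentice baseline survival S0 as a step function.

    Returns ``(event_times, survival)`` where ``survival[i]`` is S0 at (and
    beyond) the i-th distinct event time.  Covariates are centered at the
    training means (``covariate_means``, default the dataset means) so the
    baseline refers to an average patient.
    """
    beta = np.asarray(beta, dtype=float)
    if covariate_means is None:
        covariate_means = dataset.X.mean(axis=0)
    eta = (dataset.X - covariate_means) @ beta
    w = np.exp(eta)

    event_times = np.unique(dataset.time[dataset.event == 1])
    alphas = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        at_risk = dataset.time >= t
        deaths = at_risk & (dataset.event == 1) & (dataset.time == t)
        alphas[i] = _kp_alpha(eta[deaths], float(w[at_risk].sum()))
    return event_times, np.cumprod(alphas)


def fit_cox_kp(
    dataset: SurvivalDataset,
    variables: Optional[Sequence[str]] = None,
    ties_method: str = "efron",
    penalizer: float = 0.0,
) -> CoxModel:
    """Fit the full Cox-KP pipeline: partial likelihood then KP baseline."""
    if variables is not None:
        dataset = dataset.select_variables(variables)
    if dataset.p == 0:
        beta = np.zeros(0)
        means = np.zeros(0)
        meta = {"n": dataset.n, "events": dataset.n_events, "null_model": True}
    else:
        fit = fit_cox_partial_likelihood(dataset, ties_method=ties_method, penalizer=penalizer)
        beta = fit.beta
        means = dataset.X.mean(axis=0)
        meta = {"n": dataset.n, "events": dataset.n_events}
    times, surv = kp_baseline_survival(dataset, beta, means)
    return CoxModel(
        beta=beta,
        variable_names=list(dataset.variable_names),
        baseline_times=times,
        baseline_survival=surv,
        covariate_means=means,
        ties_method=ties_method,
        training_meta=meta,
    )


def predict_cox_curve(model: CoxModel, x) -> SurvivalCurve:
    """Individual curve S(t|x) = S0(t)^exp(beta'(x - x_bar)), step-valued."""
    x = np.asarray(x, dtype=float)
    if x.shape != model.beta.shape:
        raise ValueError(
            f"covariate vector length {x.size} does not match model ({model.beta.size})"
        )
    if np.isnan(x).any():
        missing = [n for n, v in zip(model.variable_names, x) if np.isnan(v)]
        raise ValueError(f"missing covariate values: {missing}")
    hr = np.exp(float(model.beta @ (x - model.covariate_means)))
    times = np.concatenate(([0.0], model.baseline_times))
    probs = np.concatenate(([1.0], model.baseline_survival**hr))
    return SurvivalCurve(times, probs, interpolation="step")


def cox_risk_score(model: CoxModel, X: np.ndarray) -> np.ndarray:
    """Linear predictor beta'(x - x_bar); higher = earlier expected death."""
    X = np.asarray(X, dtype=float)
    return (X - model.covariate_means) @ model.beta


def cox_model_to_dict(model: CoxModel) -> dict:
    return {
        "kind": "cox_kp",
        "variable_names": list(model.variable_names),
        "beta": model.beta.tolist(),
        "baseline_times": model.baseline_times.tolist(),
        "baseline_survival": model.baseline_survival.tolist(),
        "covariate_means": model.covariate_means.tolist(),
        "ties_method": model.ties_method,
        "training_meta": model.training_meta,
    }


def cox_model_from_dict(payload: dict) -> CoxModel:
    if payload.get("kind") != "cox_kp":
        raise ValueError(f"not a cox_kp model payload: kind={payload.get('kind')!r}")
    return CoxModel(
        beta=np.asarray(payload["beta"], dtype=float),
        variable_names=list(payload["variable_names"]),
        baseline_times=np.asarray(payload["baseline_times"], dtype=float),
        baseline_survival=np.asarray(payload["baseline_survival"], dtype=float),
        covariate_means=np.asarray(payload["covariate_means"], dtype=float),
        ties_method=payload.get("ties_method", "efron"),
        training_meta=payload.get("training_meta", {}),
    )


def save_cox_model(model: CoxModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(cox_model_to_dict(model), fh, indent=1)


def load_cox_model(path) -> CoxModel:
    with open(path) as fh:
        return cox_model_from_dict(json.load(fh))
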
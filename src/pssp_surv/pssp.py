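"""Patient-specific survival prediction (PSSP).

The learner discretizes follow-up into a small time grid t_1 < ... < t_k
(event-time quantiles by default) and fits one L2-regularized logistic
classifier per interval (t_{j-1}, t_j], modelling the *conditional*
probability q_j(x) that a patient at risk at t_{j-1} dies within the
interval.  A patient enters interval j's fit only when their status at t_j
is determined: dead by t_j, or followed beyond t_j.  Patients censored
inside an interval are dropped from that and all later intervals, which is
unbiased when censoring is independent of the event within the interval.

An individual survival curve is the telescoping product

    S(t_j | x) = prod_{l <= j} (1 - q_l(x)),

anchored at S(0) = 1 and linearly interpolated between grid points.  The
product of values in [0, 1] makes the curve monotone non-increasing by
construction — no post-hoc isotonic correction is needed.  Because each
interval has its own coefficient vector, a covariate may matter early and
not late (or vice versa), in contrast to the constant relative hazard of a
Cox model.

Continuous covariates are standardized internally (means/SDs stored in the
model and re-applied at prediction); binary 0/1 columns are left on their
natural scale so the ridge penalty treats indicator contrasts sensibly.
The ridge strength defaults to an internal cross-validated choice.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .curves import SurvivalCurve
from .data import SurvivalDataset

logger = logging.getLogger(__name__)

#: Ridge strengths scanned when ``regularization="cv"``.
CV_ALPHA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
#: Seed for the internal CV fold assignment (deterministic fits).
CV_FOLD_SEED = 20180315


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing positive time points t_1 < ... < t_k (days)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("time grid needs at least one point")
        if np.any(pts <= 0) or np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be positive and strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def k(self) -> int:
        return self.points.size


@dataclass
class PSSPModel:
    """Time grid plus one (intercept, weights) pair per interval."""

    grid: TimeGrid
    coefficients: np.ndarray  # k x (p + 1); column 0 is the intercept
    variable_names: list
    standardize_mean: np.ndarray
    standardize_scale: np.ndarray
    regularization: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k, width = self.coefficients.shape
        if k != self.grid.k or width != len(self.variable_names) + 1:
            raise ValueError("coefficient matrix shape does not match grid/variables")


def choose_time_grid(
    dataset: SurvivalDataset,
    k: int = 10,
    include: Optional[Sequence[float]] = None,
) -> TimeGrid:
    """Grid at the j/k quantiles (j = 1..k) of the observed event times.

    Duplicate quantiles (heavily tied event times) are collapsed, shrinking
    the grid with a warning.  ``include`` merges extra points — typically
    the horizons at which the curves will be read off, so those
    predictions come from a fitted grid point rather than interpolation;
    points beyond the largest event time are ignored.
    """
    if k < 1:
        raise ValueError("grid size k must be >= 1")
    event_times = dataset.time[dataset.event == 1]
    if event_times.size == 0:
        raise ValueError("cannot place a time grid without observed events")
    qs = np.arange(1, k + 1) / k
    points = np.unique(np.quantile(event_times, qs))
    if points.size < k:
        logger.warning("time grid collapsed from %d to %d points (tied event times)", k, points.size)
    if include is not None:
        extra = np.asarray(include, dtype=float)
        extra = extra[(extra > 0) & (extra < points.max())]
        points = np.unique(np.concatenate([points, extra]))
    return TimeGrid(points)


def build_interval_targets(dataset: SurvivalDataset, grid: TimeGrid):
    """Per-interval (inclusion mask, binary death label) pairs.

    Interval j is (t_{j-1}, t_j] with t_0 = 0.  A patient is included iff
    at risk at t_{j-1} (time > t_{j-1}) and their status at t_j is
    determined; the label is 1 for a death within the interval.  Patients
    censored inside the interval are excluded from it and, being no longer
    at risk with known status, from all later intervals too.
    """
    time, event = dataset.time, dataset.event
    edges = np.concatenate(([0.0], grid.points))
    targets = []
    for j in range(grid.k):
        t_lo, t_hi = edges[j], edges[j + 1]
        at_risk = time > t_lo
        died_by = (event == 1) & (time <= t_hi)
        followed_past = time >= t_hi  # censored exactly at t_hi is known alive at t_hi
        include = at_risk & (died_by | followed_past)
        label = (died_by & include).astype(int)
        targets.append((include, label))
    return targets


def _split_scale(X: np.ndarray):
    """Standardization constants: continuous columns only; binary untouched."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    is_binary = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in X.T])
    mean[is_binary] = 0.0
    scale[is_binary] = 1.0
    scale[scale == 0] = 1.0
    return mean, scale


def _fit_interval(Z: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """One interval's logistic fit; returns (intercept, weights)."""
    if Z.shape[1] == 0:  # intercept-only model: MLE is the logit of the rate
        rate = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return np.array([np.log(rate / (1 - rate))])
    if y.min() == y.max():
        # constant outcome (e.g. the final interval of an uncensored cohort):
        # covariates carry no information, so use a shrunken intercept only
        rate = (y.sum() + 0.5) / (y.size + 1.0)
        return np.concatenate(([np.log(rate / (1 - rate))], np.zeros(Z.shape[1])))
    if alpha > 0:
        clf = LogisticRegression(C=1.0 / alpha, solver="lbfgs", max_iter=10000, tol=1e-12)
    else:
        if y.min() == y.max():
            raise ValueError("unpenalized logistic fit impossible on constant labels")
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=10000, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    return np.concatenate((clf.intercept_, clf.coef_[0]))


def _cv_log_loss(targets, Z: np.ndarray, alpha: float, folds: int = 5) -> float:
    total = 0.0
    kf = KFold(n_splits=folds, shuffle=True, random_state=CV_FOLD_SEED)
    for include, label in targets:
        idx = np.flatnonzero(include)
        y = label[idx]
        if y.min() == y.max() or idx.size < folds:
            continue
        for train, test in kf.split(idx):
            tr, te = idx[train], idx[test]
            if label[tr].min() == label[tr].max():
                continue
            coef = _fit_interval(Z[tr], label[tr], alpha)
            q = expit(coef[0] + Z[te] @ coef[1:])
            q = np.clip(q, 1e-12, 1 - 1e-12)
            yt = label[te]
            total -= float(np.sum(yt * np.log(q) + (1 - yt) * np.log(1 - q)))
    return total


def fit_pssp(
    dataset: SurvivalDataset,
    grid: Optional[TimeGrid] = None,
    k: int = 10,
    regularization="cv",
    min_interval_n: int = 10,
    grid_include: Optional[Sequence[float]] = None,
) -> PSSPModel:
    """Fit the bank of per-interval conditional-death classifiers.

    ``regularization`` is the ridge strength (0 = unpenalized MLE) or
    ``"cv"`` to pick it by internal 5-fold cross-validated log-loss over
    :data:`CV_ALPHA_GRID` (deterministic folds).  Every interval must
    retain at least ``min_interval_n`` patients and at least one event;
    otherwise the error advises a smaller k.
    """
    if grid is None:
        grid = choose_time_grid(dataset, k=k, include=grid_include)
    targets = build_interval_targets(dataset, grid)

    for j, (include, label) in enumerate(targets):
        n_inc, n_evt = int(include.sum()), int(label.sum())
        if n_inc < min_interval_n or n_evt < 1:
            raise ValueError(
                f"interval {j + 1} of {grid.k} retains {n_inc} patients and {n_evt} events; "
                "use a smaller grid (k)"
            )

    mean, scale = _split_scale(dataset.X)
    Z = (dataset.X - mean) / scale

    if regularization == "cv":
        losses = {a: _cv_log_loss(targets, Z, a) for a in CV_ALPHA_GRID}
        alpha = min(losses, key=lambda a: (losses[a], a))
        logger.info("ridge strength chosen by CV: %g", alpha)
    else:
        alpha = float(regularization)
        if alpha < 0:
            raise ValueError("regularization strength must be >= 0")

    coefficients = np.empty((grid.k, dataset.p + 1))
    for j, (include, label) in enumerate(targets):
        coefficients[j] = _fit_interval(Z[include], label[include], alpha)

    return PSSPModel(
        grid=grid,
        coefficients=coefficients,
        variable_names=list(dataset.variable_names),
        standardize_mean=mean,
        standardize_scale=scale,
        regularization=alpha,
        training_meta={"n": dataset.n, "events": dataset.n_events},
    )


def interval_death_probabilities(model: PSSPModel, x: np.ndarray) -> np.ndarray:
    """Conditional death probabilities q_j(x), one per grid interval."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.variable_names),):
        raise ValueError(
            f"covariate vector length {x.size} does not match model ({len(model.variable_names)})"
        )
    if np.isnan(x).any():
        missing = [n for n, v in zip(model.variable_names, x) if np.isnan(v)]
        raise ValueError(f"missing covariate values: {missing}")
    z = (x - model.standardize_mean) / model.standardize_scale
    return expit(model.coefficients[:, 0] + model.coefficients[:, 1:] @ z)


def predict_curve(model: PSSPModel, x) -> SurvivalCurve:
    """Monotone individual curve via the telescoping product of (1 - q_j)."""
    q = interval_death_probabilities(model, np.asarray(x, dtype=float))
    probs = np.concatenate(([1.0], np.cumprod(1.0 - q)))
    times = np.concatenate(([0.0], model.grid.points))
    return SurvivalCurve(times, probs, interpolation="linear")


def predict_population_km(dataset: SurvivalDataset) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve of the whole cohort (step-valued)."""
    if dataset.n_events == 0:
        logger.warning("no events observed; population curve is flat at 1")
        return SurvivalCurve(np.array([0.0]), np.array([1.0]), interpolation="step")
    km = KaplanMeierFitter()
    km.fit(dataset.time, dataset.event)
    event_times = np.unique(dataset.time[dataset.event == 1])
    surv = km.survival_function_at_times(event_times).to_numpy()
    times = np.concatenate(([0.0], event_times))
    probs = np.concatenate(([1.0], surv))
    return SurvivalCurve(times, probs, interpolation="step")


def pssp_model_to_dict(model: PSSPModel) -> dict:
    return {
        "kind": "pssp",
        "grid": model.grid.points.tolist(),
        "coefficients": model.coefficients.tolist(),
        "variable_names": list(model.variable_names),
        "standardize_mean": model.standardize_mean.tolist(),
        "standardize_scale": model.standardize_scale.tolist(),
        "regularization": model.regularization,
        "training_meta": model.training_meta,
    }


def pssp_model_from_dict(payload: dict) -> PSSPModel:
    if payload.get("kind") != "pssp":
        raise ValueError(f"not a pssp model payload: kind={payload.get('kind')!r}")
    return PSSPModel(
        grid=TimeGrid(np.asarray(payload["grid"], dtype=float)),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        variable_names=list(payload["variable_names"]),
        standardize_mean=np.asarray(payload["standardize_mean"], dtype=float),
        standardize_scale=np.asarray(payload["standardize_scale"], dtype=float),
        regularization=float(payload["regularization"]),
        training_meta=payload.get("training_meta", {}),
    )


def save_pssp_model(model: PSSPModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(pssp_model_to_dict(model), fh, indent=1)


def load_pssp_model(path) -> PSSPModel:
    with open(path) as fh:
        return pssp_model_from_dict(json.load(fh))
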
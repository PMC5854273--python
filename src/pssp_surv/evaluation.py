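"""Discrimination and calibration testing for individual survival curves.

Three complementary checks:

* **Concordance (c-index)** — over comparable patient pairs, does a higher
  risk score go with the earlier observed death?  Purely discriminative.
* **1-calibration** — a Hosmer-Lemeshow test at a fixed horizon t: patients
  are cut into equal-count deciles of predicted death probability by t and
  observed deaths are compared with the summed predictions per decile.
* **D-calibration** — the distributional test for whole curves.  If each
  patient's curve were their true survival function, the probability
  integral transform makes S_i(d_i) uniform on [0, 1] over deaths d_i, so
  the decile histogram of predicted-survival-at-death values should be
  flat; a chi-square test over the 10 bins quantifies the departure.
  Censored patients are known only to have S_i(T_i) below S_i(c_i), so
  each contributes one unit of mass spread uniformly over [0, S_i(c_i)].

The cross-validation harness runs variable selection and model fitting
inside each training fold and pools out-of-fold curves, optionally
partitioning by treatment center rather than by patient to probe for
center-coding effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

from .curves import SurvivalCurve, quantile_time, survival_at
from .data import CalibrationResult, SurvivalDataset

logger = logging.getLogger(__name__)

DEFAULT_EVAL_YEARS = (0.25, 1.0, 5.0, 10.0)
DAYS_PER_YEAR = 365.25


def concordance_index(risk_scores, dataset: SurvivalDataset) -> float:
    """C-index with the convention HIGHER score = earlier expected death.

    Comparable pairs: i died and i's time precedes j's; tied scores count
    half.  Raises ``ValueError`` when no pair is comparable.
    """
    scores = np.asarray(risk_scores, dtype=float)
    if scores.shape != dataset.time.shape:
        raise ValueError("risk_scores length does not match dataset")
    events = dataset.time[dataset.event == 1]
    comparable = events.size and (
        (dataset.time > events.min()).any() or (dataset.time == events.min()).sum() > 1
    )
    if not comparable:
        raise ValueError("no comparable pairs: need an event preceding another follow-up")
    # lifelines counts concordance for higher score = longer survival
    return float(_lifelines_cindex(dataset.time, -scores, dataset.event))


def _chi2_result(bin_edges, observed, expected, dof, warnings_list=None) -> CalibrationResult:
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return CalibrationResult(
        bin_edges=np.asarray(bin_edges, dtype=float),
        observed=observed,
        expected=expected,
        statistic=statistic,
        dof=int(dof),
        p_value=float(stats.chi2.sf(statistic, dof)),
        warnings=list(warnings_list or []),
    )


def one_calibration_hl(
    curves: Sequence[SurvivalCurve],
    dataset: SurvivalDataset,
    t: float,
    bins: int = 10,
    dof_convention: str = "development",
) -> CalibrationResult:
    """Hosmer-Lemeshow single-time calibration at horizon ``t`` (days).

    Patients censored before ``t`` carry no observable status there and are
    excluded.  The rest are sorted by predicted death probability by ``t``
    and cut into ``bins`` equal-count groups; the statistic is
    sum (O - E)^2 / (E (1 - E/n_g)) with dof = groups - 2 under the
    development-sample convention (``dof_convention="validation"`` uses
    groups).  Degenerate groups (E = 0 or E = n_g) merge with a neighbor.
    """
    if t <= 0:
        raise ValueError("horizon t must be > 0")
    if len(curves) != dataset.n:
        raise ValueError("one curve per patient required")

    notes = []
    time, event = dataset.time, dataset.event
    known = (time >= t) | (event == 1) & (time <= t)
    if known.sum() < bins * 5:
        notes.append(f"only {int(known.sum())} patients with known status at t={t:g}")
        logger.warning(notes[-1])
    observed_death = ((event == 1) & (time <= t) & known).astype(float)
    predicted = np.array([1.0 - survival_at(c, t) for c in curves])

    idx = np.flatnonzero(known)
    order = idx[np.argsort(predicted[idx], kind="stable")]
    groups = [g for g in np.array_split(order, bins) if g.size]

    O = np.array([observed_death[g].sum() for g in groups])
    E = np.array([predicted[g].sum() for g in groups])
    n_g = np.array([float(g.size) for g in groups], dtype=float)

    # merge groups whose variance term degenerates
    while len(O) > 1:
        bad = np.flatnonzero((E <= 0) | (E >= n_g))
        if bad.size == 0:
            break
        i = int(bad[0])
        j = i - 1 if i > 0 else i + 1
        keep = [m for m in range(len(O)) if m not in (i, j)]
        O = np.concatenate(([O[i] + O[j]], O[keep]))
        E = np.concatenate(([E[i] + E[j]], E[keep]))
        n_g = np.concatenate(([n_g[i] + n_g[j]], n_g[keep]))
        notes.append("merged a degenerate decile group")
    if len(O) == 1 and (E[0] <= 0 or E[0] >= n_g[0]):
        raise ValueError("calibration groups degenerate even after merging")

    variance = E * (1.0 - E / n_g)
    statistic = float(np.sum((O - E) ** 2 / variance))
    dof = len(O) - (2 if dof_convention == "development" else 0)
    dof = max(dof, 1)
    if notes:
        logger.warning("; ".join(notes))
    return CalibrationResult(
        bin_edges=np.arange(len(O) + 1, dtype=float),
        observed=O,
        expected=E,
        statistic=statistic,
        dof=dof,
        p_value=float(stats.chi2.sf(statistic, dof)),
        warnings=notes,
    )


def d_calibration(
    curves: Sequence[SurvivalCurve],
    dataset: SurvivalDataset,
    bins: int = 10,
) -> CalibrationResult:
    """Distributional calibration chi-square over survival-probability deciles.

    Each death at d_i adds one count to the decile bin holding
    p_i = S_i(d_i) (top bin [0.9, 1.0] right-closed; a boundary value such
    as 0.1 belongs to the bin above it).  Each censored patient at c_i
    spreads one unit of mass uniformly over [0, S_i(c_i)].  Expected counts
    are total/bins per bin; dof = bins - 1.
    """
    if len(curves) != dataset.n:
        raise ValueError("one curve per patient required")
    if dataset.n_events < 1:
        raise ValueError("D-calibration requires at least one event")

    edges = np.linspace(0.0, 1.0, bins + 1)
    observed = np.zeros(bins)
    for curve, t, ev in zip(curves, dataset.time, dataset.event):
        p = survival_at(curve, t)
        if ev == 1:
            b = min(int(np.floor(p * bins + 1e-12)), bins - 1)
            observed[b] += 1.0
        else:
            if p <= 0.0:
                observed[0] += 1.0
                continue
            overlap = np.clip(np.minimum(edges[1:], p) - edges[:-1], 0.0, None)
            observed += overlap / p
    expected = np.full(bins, observed.sum() / bins)
    assert abs(observed.sum() - expected.sum()) < 1e-8  # mass conservation
    return _chi2_result(edges, observed, expected, dof=bins - 1)


def fraction_dead_before_median(curves: Sequence[SurvivalCurve], dataset: SurvivalDataset) -> float:
    """Fraction of observed deaths occurring strictly before the patient's
    predicted median survival time; 0.5 under perfect D-calibration.

    Patients whose curve never reaches 0.5 are excluded with a warning.
    """
    if len(curves) != dataset.n:
        raise ValueError("one curve per patient required")
    hits, total = 0, 0
    skipped = 0
    for curve, t, ev in zip(curves, dataset.time, dataset.event):
        if ev != 1:
            continue
        med = quantile_time(curve, 0.5)
        if med is None:
            skipped += 1
            continue
        total += 1
        hits += int(t < med)
    if skipped:
        logger.warning("%d death curves never reach 0.5; excluded from the median check", skipped)
    if total == 0:
        raise ValueError("no deaths with a defined predicted median")
    return hits / total


@dataclass
class EvaluationReport:
    """Pooled out-of-fold evaluation: discrimination plus both calibrations."""

    c_index: float
    one_cal: dict  # horizon (days) -> CalibrationResult
    d_cal: CalibrationResult
    n: int
    events: int
    folds: int
    fold_selections: list = field(default_factory=list)
    fold_d_cal_p: list = field(default_factory=list)
    fraction_dead_before_median: Optional[float] = None

    def to_dict(self) -> dict:
        def _cal(c: CalibrationResult) -> dict:
            return {
                "observed": c.observed.tolist(),
                "expected": c.expected.tolist(),
                "statistic": c.statistic,
                "dof": c.dof,
                "p_value": c.p_value,
            }

        return {
            "c_index": self.c_index,
            "one_calibration": {f"{t:g}": _cal(c) for t, c in self.one_cal.items()},
            "d_calibration": _cal(self.d_cal),
            "fraction_dead_before_median": self.fraction_dead_before_median,
            "n": self.n,
            "events": self.events,
            "folds": self.folds,
            "fold_selections": self.fold_selections,
            "fold_d_calibration_p": self.fold_d_cal_p,
        }

    def to_markdown(self) -> str:
        lines = [
            "# Evaluation report",
            "",
            f"- patients: {self.n} ({self.events} deaths), {self.folds}-fold cross-validation",
            f"- concordance index: {self.c_index:.3f}",
            f"- D-calibration: chi2 = {self.d_cal.statistic:.2f} "
            f"(dof {self.d_cal.dof}), p = {self.d_cal.p_value:.3f}",
        ]
        if self.fraction_dead_before_median is not None:
            lines.append(
                f"- deaths before predicted median: {self.fraction_dead_before_median:.3f}"
            )
        lines += ["", "## 1-calibration (Hosmer-Lemeshow)", "", "| horizon (days) | chi2 | dof | p |", "|---|---|---|---|"]
        for t, c in sorted(self.one_cal.items()):
            lines.append(f"| {t:g} | {c.statistic:.2f} | {c.dof} | {c.p_value:.3f} |")
        if self.fold_selections:
            lines += ["", "## Per-fold selected variables", ""]
            for i, sel in enumerate(self.fold_selections, 1):
                lines.append(f"- fold {i}: {', '.join(sel) if sel else '(none)'}")
        return "\n".join(lines) + "\n"


def make_folds(
    dataset: SurvivalDataset,
    folds: int = 5,
    group_by: str = "patient",
    seed: int = 0,
):
    """Deterministic fold assignment; ``group_by="center"`` keeps each
    center's patients in a single test fold."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    if group_by == "patient":
        order = rng.permutation(dataset.n)
        return [np.sort(chunk) for chunk in np.array_split(order, folds)]
    if group_by == "center":
        if dataset.center is None:
            raise ValueError("dataset has no center labels")
        centers = np.unique(dataset.center)
        if centers.size < folds:
            raise ValueError(f"need >= {folds} distinct centers, found {centers.size}")
        shuffled = rng.permutation(centers)
        return [
            np.flatnonzero(np.isin(dataset.center, chunk))
            for chunk in np.array_split(shuffled, folds)
        ]
    raise ValueError(f"unknown group_by {group_by!r}")


def cross_validate(
    dataset: SurvivalDataset,
    fit_predict: Callable,
    folds: int = 5,
    group_by: str = "patient",
    seed: int = 0,
    eval_times: Optional[Sequence[float]] = None,
    risk_time: float = 5 * DAYS_PER_YEAR,
    select: Optional[Callable] = None,
) -> EvaluationReport:
    """Pooled out-of-fold evaluation of a survival-curve learner.

    ``fit_predict(train_dataset, test_dataset) -> list[SurvivalCurve]``
    trains on the fold's training split and returns one curve per test
    patient.  If ``select`` is given it runs *inside* each training fold
    (``select(train_dataset) -> list of variable names``) and both splits
    are restricted to the selected variables before fitting.  Risk scores
    for the c-index are 1 - S(risk_time | x) from the pooled curves.
    """
    eval_days = (
        [y * DAYS_PER_YEAR for y in DEFAULT_EVAL_YEARS] if eval_times is None else list(eval_times)
    )
    fold_idx = make_folds(dataset, folds=folds, group_by=group_by, seed=seed)
    all_idx = np.arange(dataset.n)

    pooled: list = [None] * dataset.n
    fold_selections, fold_d_cal_p = [], []
    for test in fold_idx:
        train = np.setdiff1d(all_idx, test)
        train_ds, test_ds = dataset.subset(train), dataset.subset(test)
        if train_ds.n_events == 0 or test_ds.n_events == 0:
            raise ValueError("a fold has no events; use fewer folds")
        if select is not None:
            chosen = list(select(train_ds))
            fold_selections.append(chosen)
            train_ds = train_ds.select_variables(chosen)
            test_ds = test_ds.select_variables(chosen)
        curves = fit_predict(train_ds, test_ds)
        if len(curves) != test_ds.n:
            raise ValueError("fit_predict returned a wrong number of curves")
        for i, c in zip(test, curves):
            pooled[i] = c
        fold_d_cal_p.append(d_calibration(curves, test_ds).p_value)

    risk = np.array([1.0 - survival_at(c, risk_time) for c in pooled])
    one_cal = {t: one_calibration_hl(pooled, dataset, t) for t in eval_days}
    try:
        frac = fraction_dead_before_median(pooled, dataset)
    except ValueError:
        frac = None
    return EvaluationReport(
        c_index=concordance_index(risk, dataset),
        one_cal=one_cal,
        d_cal=d_calibration(pooled, dataset),
        n=dataset.n,
        events=dataset.n_events,
        folds=folds,
        fold_selections=fold_selections,
        fold_d_cal_p=fold_d_cal_p,
        fraction_dead_before_median=frac,
    )
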
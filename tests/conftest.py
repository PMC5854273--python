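import numpy as np
import pytest

from pssp_surv import SurvivalCurve, SurvivalDataset


@pytest.fixture
def line_curve():
    """Linear curve dropping from 1 at t=0 to 0 at t=200."""
    return SurvivalCurve(np.array([0.0, 200.0]), np.array([1.0, 0.0]), "linear")


@pytest.fixture
def toy_cox_dataset():
    """Five patients, all deaths at distinct times, one binary covariate.

    The covariate alternates with the death order so the partial
    likelihood has an interior maximum (no separation).
    """
    return SurvivalDataset(
        X=np.array([[1.0], [0.0], [1.0], [0.0], [0.0]]),
        variable_names=["x"],
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        event=np.array([1, 1, 1, 1, 1]),
    )


@pytest.fixture
def km_hand_dataset():
    """Deaths at days 10 and 20, censoring at 15 and 25."""
    return SurvivalDataset(
        X=np.zeros((4, 1)),
        variable_names=["x"],
        time=np.array([10.0, 15.0, 20.0, 25.0]),
        event=np.array([1, 0, 1, 0]),
    )


def exact_truth_curve(truth, x, times_of_interest, horizon):
    """Curve whose knots include the query times, so linear interpolation
    reproduces the analytic Weibull-PH survival exactly at those times."""
    from pssp_surv import true_survival

    knots = np.unique(np.concatenate(([0.0, horizon], np.asarray(times_of_interest, dtype=float))))
    return SurvivalCurve(knots, true_survival(truth, x, knots), "linear")
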
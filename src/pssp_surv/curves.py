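"""Individual survival curves: querying, quantiles, serialization.

A :class:`SurvivalCurve` is a monotone non-increasing map t -> P(T > t)
for a single patient (or a population), anchored at S(0) = 1.  Curves are
evaluated either with linear interpolation between grid points (model
output on a time grid) or as right-continuous steps (product-limit style
estimators).  Beyond the last grid time the curve extends flat: it is
never extrapolated toward zero, so queries far past follow-up return the
last estimated probability rather than an invented one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

INTERPOLATIONS = ("linear", "step")

#: Sentinel for quantiles the curve never reaches (flat extension).
UNDEFINED_TIME = None

_CURVE_CSV_HEADER = "time_days,survival_prob"


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival function estimate on a finite time grid (days)."""

    times: np.ndarray
    probs: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if times.ndim != 1 or times.shape != probs.shape or times.size == 0:
            raise ValueError("times and probs must be equal-length 1-D arrays")
        if times[0] != 0.0:
            raise ValueError("curve must start at time 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if probs[0] != 1.0:
            raise ValueError("curve must start at probability 1")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        # tolerate float rounding from products of probabilities
        increments = np.diff(probs)
        if np.any(increments > 1e-9):
            raise ValueError("probabilities must be non-increasing")
        probs = np.minimum.accumulate(np.clip(probs, 0.0, 1.0))
        if self.interpolation not in INTERPOLATIONS:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "probs", probs)


def survival_at(curve: SurvivalCurve, t) -> float:
    """P(T > t) under the curve's interpolation rule; flat beyond the grid.

    Accepts a scalar or array of times; negative times raise ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    if curve.interpolation == "linear":
        out = np.interp(t_arr, curve.times, curve.probs)
    else:
        idx = np.searchsorted(curve.times, t_arr, side="right") - 1
        out = curve.probs[np.clip(idx, 0, curve.probs.size - 1)]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def quantile_time(curve: SurvivalCurve, q: float):
    """Smallest t with P(T > t) <= q; ``None`` if the curve never reaches q.

    ``quantile_time(curve, 0.5)`` is the predicted median survival time.
    """
    if not 0 < q < 1:
        raise ValueError("quantile level q must lie strictly in (0, 1)")
    probs, times = curve.probs, curve.times
    below = probs <= q
    if not below.any():
        return UNDEFINED_TIME
    i = int(np.argmax(below))
    if i == 0:  # q >= 1 is excluded, so probs[0]=1 > q; defensive only
        return float(times[0])
    if curve.interpolation == "step":
        return float(times[i])
    p_hi, p_lo = probs[i - 1], probs[i]
    if p_hi == p_lo:  # defensive: argmax already picks the first index
        return float(times[i])
    frac = (p_hi - q) / (p_hi - p_lo)
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def write_curve(curve: SurvivalCurve, path, format: str = "csv") -> None:
    """Serialize a curve; ``read_curve`` round-trips times/probs bit-exactly."""
    if format == "csv":
        lines = [_CURVE_CSV_HEADER]
        lines += [f"{float(t)!r},{float(p)!r}" for t, p in zip(curve.times, curve.probs)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "times": [float(t) for t in curve.times],
            "probs": [float(p) for p in curve.probs],
            "interpolation": curve.interpolation,
            "extension": "flat",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown curve format {format!r}")


def read_curve(path, format: str = "csv", interpolation: str = "linear") -> SurvivalCurve:
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().strip()
            if header != _CURVE_CSV_HEADER:
                raise ValueError(f"unexpected curve CSV header {header!r}")
            rows = [line.strip().split(",") for line in fh if line.strip()]
        times = np.array([float(r[0]) for r in rows])
        probs = np.array([float(r[1]) for r in rows])
        return SurvivalCurve(times, probs, interpolation)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return SurvivalCurve(
            np.asarray(payload["times"], dtype=float),
            np.asarray(payload["probs"], dtype=float),
            payload["interpolation"],
        )
    raise ValueError(f"unknown curve format {format!r}")
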
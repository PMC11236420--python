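"""Participant-specific input transforms and model-naive RMSE performance.

Stimulus intensities are discrete levels 1..13 while ratings live on a 0-100
visual-analogue scale, so each participant's perception ratings are regressed
on the raw input to obtain a linear map onto the response scale.  If the
fitted line sends any observed input below 0, the fit is repeated with the
intercept constrained to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "InputTransform",
    "fit_input_transform",
    "apply_transform",
    "rmse_perception",
    "rmse_prediction",
]


@dataclass(frozen=True)
class InputTransform:
    """Linear map from intensity level to the 0-100 response scale."""

    slope: float        # response units per intensity level
    intercept: float    # response units
    constrained: bool = False   # True if refit with intercept >= 0

    def __call__(self, x):
        return apply_transform(self, x)


def fit_input_transform(inputs, responses) -> InputTransform:
    """Least-squares line mapping perception-trial inputs to ratings.

    Ordinary least squares first; if any observed input is then mapped below
    zero, a constrained refit (intercept >= 0) replaces it.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.unique(x).size < 2:
        raise ValueError("all inputs identical; slope undefined")

    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if np.min(slope * x + intercept) >= 0:
        return InputTransform(slope=slope, intercept=intercept)

    (slope, intercept), _ = optimize.curve_fit(
        lambda x_, a, b: a * x_ + b, x, y,
        p0=[max(slope, 1e-3), max(intercept, 0.0)],
        bounds=([-np.inf, 0.0], [np.inf, np.inf]),
    )
    return InputTransform(slope=float(slope), intercept=float(intercept), constrained=True)


def apply_transform(transform: InputTransform, values):
    """Elementwise ``slope * x + intercept``."""
    return transform.slope * np.asarray(values, dtype=float) + transform.intercept


def _rmse(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("inputs must be non-empty and aligned")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_perception(responses, transformed_inputs) -> float:
    """Root-mean-square error of perception ratings vs the current
    (transformed) input, over perception trials."""
    return _rmse(transformed_inputs, responses)


def rmse_prediction(responses, next_inputs) -> float:
    """RMSE of prediction ratings at trial ``t`` vs the transformed input at
    ``t+1``.  Callers drop final-trial predictions with no successor."""
    return _rmse(next_inputs, responses)
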
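"""Mapping of log fold changes to bounded interaction targets.

Raw logFC values are squashed into (-1, 1) by a three-interval "step
function" SF: a modified tanh that damps the biologically uninteresting band
|logFC| < t (default t = 1) and saturates toward +/-1 beyond it, so the
regression target emphasises genuinely up-/down-regulated genes.

The concrete parameterisation used here is

    SF(x) = w * tanh(s1 * x)                                   for |x| <= t
    SF(x) = sign(x) * [ w*tanh(s1*t)
                        + (1 - w*tanh(s1*t)) * tanh(s2*(|x|-t)) ]  otherwise

which is odd, continuous, strictly increasing and bounded in (-1, 1).  The
inner weight w < 1 controls how flat the dead zone is; s1 and s2 are the
inner/outer gains.  All four parameters are configurable.

Class labels use the conventional thresholds: Up iff logFC > t, Down iff
logFC < -t, None otherwise (strict inequalities; ties at +/-t are None).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class ExpressionLabel(enum.Enum):
    UP = "Up"
    DOWN = "Down"
    NONE = "None"


@dataclass(frozen=True)
class StepFunctionParams:
    inner_gain: float = 1.0   # s1
    inner_weight: float = 0.1  # w
    outer_gain: float = 1.0   # s2
    threshold: float = 1.0    # t, in logFC units

    def __post_init__(self):
        if self.inner_gain <= 0 or self.outer_gain <= 0:
            raise ValueError("gains must be > 0")
        if not 0.0 < self.inner_weight < 1.0:
            raise ValueError("inner_weight must be in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @property
    def knee(self) -> float:
        """SF value at the threshold, SF(t)."""
        return self.inner_weight * np.tanh(self.inner_gain * self.threshold)


DEFAULT_SF = StepFunctionParams()


def step_function(x, params: StepFunctionParams = DEFAULT_SF):
    """Apply SF elementwise; accepts scalars or arrays, returns the same shape."""
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("step_function requires finite input")
    w, s1, s2, t = params.inner_weight, params.inner_gain, params.outer_gain, params.threshold
    knee = w * np.tanh(s1 * t)
    inner = w * np.tanh(s1 * arr)
    outer = np.sign(arr) * (knee + (1.0 - knee) * np.tanh(s2 * (np.abs(arr) - t)))
    out = np.where(np.abs(arr) <= t, inner, outer)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def label(x: float, threshold: float = 1.0) -> ExpressionLabel:
    """True class of a logFC value: Up (> t), Down (< -t) or None."""
    if not np.isfinite(x):
        raise ValueError("label requires finite logFC")
    if x > threshold:
        return ExpressionLabel.UP
    if x < -threshold:
        return ExpressionLabel.DOWN
    return ExpressionLabel.NONE


def predicted_label(s_hat: float, params: StepFunctionParams = DEFAULT_SF) -> ExpressionLabel:
    """Class of a predicted score, thresholded consistently with SF targets.

    Up iff s_hat > SF(t), Down iff s_hat < SF(-t), None otherwise — so that
    label(x) == predicted_label(SF(x)) away from the exact thresholds.
    """
    if not np.isfinite(s_hat):
        raise ValueError("predicted_label requires finite input")
    knee = params.knee
    if s_hat > knee:
        return ExpressionLabel.UP
    if s_hat < -knee:
        return ExpressionLabel.DOWN
    return ExpressionLabel.NONE
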
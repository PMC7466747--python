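"""Confal quality scores.

The per-parameter confal is a Gaussian in the displacement from the class
mean, calibrated so that it is 100 exactly at the mean and 1 exactly at the
allowed border nearer to the mean; outside the allowed borders it is 0.  A
step score is the harmonic mean of its 12 per-parameter values (0 as soon as
any of them is 0), and a structure score is the arithmetic mean of its
assigned steps' scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import circular_difference, signed_circular_difference

__all__ = [
    "parameter_confal",
    "step_confal",
    "structure_confal",
    "structure_percentile",
    "ConfalBreakdown",
    "confal_breakdown",
]

_LN100 = np.log(100.0)
_N_CIRCULAR = 10


@dataclass
class ConfalBreakdown:
    """Per-parameter confals, the step score and the signed deviations."""

    per_parameter: np.ndarray  # 12 values in [0, 100]
    step_score: float
    deviations: np.ndarray     # signed differences from the class mean (circular for torsions)


def parameter_confal(x: float, mean: float, lower_border: float,
                     upper_border: float, circular: bool = True) -> float:
    """Confal value of one parameter, in [0, 100].

    ``f(x) = 100 * exp(-ln(100) * (d(x, mean) / d(b_near, mean))^2)`` inside
    the allowed borders and 0 outside, where ``d`` is the circular difference
    for angular parameters and ``b_near`` is the border nearer to the mean.
    The Gaussian width is calibrated on the nearer border only, so with
    asymmetric borders the value approaches something below 1 at the farther
    border before the clamp to 0.
    """
    if circular:
        lo = float(signed_circular_difference(lower_border, mean))
        up = float(signed_circular_difference(upper_border, mean))
        dev = float(signed_circular_difference(x, mean))
    else:
        lo = lower_border - mean
        up = upper_border - mean
        dev = x - mean
    if not (lo < 0 < up):
        raise ValueError("borders must bracket the mean strictly")
    if dev < lo or dev > up:
        return 0.0
    d_near = min(-lo, up)
    return float(100.0 * np.exp(-_LN100 * (abs(dev) / d_near) ** 2))


def step_confal(per_parameter) -> float:
    """Harmonic mean of the 12 per-parameter confal values; 0 if any is 0."""
    v = np.asarray(per_parameter, dtype=float)
    if v.shape != (12,):
        raise ValueError(f"expected 12 confal values, got shape {v.shape}")
    if np.any(v < 0) or np.any(v > 100):
        raise ValueError("confal values must lie in [0, 100]")
    if np.any(v == 0):
        return 0.0
    return float(len(v) / np.sum(1.0 / v))


def structure_confal(step_scores) -> float:
    """Arithmetic mean of step confal scores."""
    scores = np.asarray(list(step_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("structure confal is undefined without assigned steps")
    return float(scores.mean())


def structure_percentile(score: float, distribution) -> float:
    """Percent of an empirical score distribution strictly below ``score``."""
    dist = np.asarray(list(distribution), dtype=float)
    if dist.size == 0:
        raise ValueError("empty score distribution")
    return float(100.0 * np.mean(dist < score))


def confal_breakdown(params, ntc_class) -> ConfalBreakdown:
    """Score one step's 12 parameters against a reference class."""
    from .geometry import StepParameters

    x = params.as_array() if isinstance(params, StepParameters) else np.asarray(params, float)
    per = np.empty(12)
    dev = np.empty(12)
    for i in range(12):
        circ = i < _N_CIRCULAR
        per[i] = parameter_confal(x[i], ntc_class.means[i], ntc_class.lower[i],
                                  ntc_class.upper[i], circular=circ)
        dev[i] = signed_circular_difference(x[i], ntc_class.means[i]) if circ \
            else x[i] - ntc_class.means[i]
    return ConfalBreakdown(per_parameter=per, step_score=step_confal(per), deviations=dev)
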
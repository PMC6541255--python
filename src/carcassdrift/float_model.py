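"""Logistic carcass float/sink model.

A drifting carcass stays afloat for a limited time before sinking.  The
proportion still afloat after ``f`` hours follows a reversed logistic

    p(f) = eta1 - eta1 / (1 + exp(-eta2 * (f - eta3)))

with ``eta1`` the initially-afloat asymptote, ``eta2`` (per hour) the
steepness, and ``eta3`` (hours) the midpoint where p = eta1/2.  Beyond the
14-day cap (336 h) p is defined as zero: a particle still at sea then is
treated as sunk.

The shape parameters are not observable directly; they are calibrated to
a target *median* float duration (field observations from cold Alaskan
waters support medians of 7 and 9 days) together with a near-total sink
by the cap, operationalised as p(336 h) = tail_prob * eta1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FloatParams", "float_prob", "calibrate", "FLOAT_CAP_H"]

FLOAT_CAP_H = 336.0


@dataclass(frozen=True)
class FloatParams:
    """Shape parameters of the float function."""

    eta1: float = 1.0
    eta2: float = 0.0274
    eta3: float = 168.0
    cutoff: float = FLOAT_CAP_H

    def __post_init__(self) -> None:
        if not 0.0 < self.eta1 <= 1.0:
            raise ValueError("eta1 must be in (0, 1]")
        if self.eta2 <= 0 or self.eta3 <= 0:
            raise ValueError("eta2 and eta3 must be positive")

    @property
    def median_hours(self) -> float:
        """Float duration at which p drops to eta1/2 (= eta3 by design)."""
        return self.eta3


def float_prob(f, params: FloatParams):
    """Probability a carcass is still afloat after ``f`` hours.

    Accepts scalars or arrays; f must be non-negative.  Values at or past
    the cutoff return exactly 0.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("float duration must be non-negative")
    p = params.eta1 - params.eta1 / (1.0 + np.exp(-params.eta2 * (f_arr - params.eta3)))
    p = np.where(f_arr >= params.cutoff, 0.0, p)
    if np.isscalar(f) or f_arr.ndim == 0:
        return float(p)
    return p


def calibrate(
    median_days: float,
    eta1: float = 1.0,
    tail_prob: float = 0.01,
    cutoff: float = FLOAT_CAP_H,
) -> FloatParams:
    """Solve the float-function shape from a target median float duration.

    The midpoint is the median in hours (p(eta3) = eta1/2) and the
    steepness is set so the function has decayed to ``tail_prob * eta1``
    at the cap:  eta2 = ln((1 - tail_prob)/tail_prob) / (cutoff - eta3).
    """
    if not 0.0 < tail_prob < 0.5:
        raise ValueError("tail_prob must be in (0, 0.5)")
    eta3 = median_days * 24.0
    if not 0.0 < eta3 < cutoff:
        raise ValueError(
            f"median of {median_days} days is not calibratable below the "
            f"{cutoff / 24:.0f}-day cap"
        )
    eta2 = np.log((1.0 - tail_prob) / tail_prob) / (cutoff - eta3)
    return FloatParams(eta1=eta1, eta2=float(eta2), eta3=float(eta3), cutoff=cutoff)
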
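"""Combination of replicate uncalibrated radiocarbon measurements.

Two AMS measurements of the same sample (e.g. from different collagen
fractions) are combined into a single age.  The arithmetic method averages
the ages (truncating the mean toward zero) and propagates the one-sigma
uncertainties as sqrt(sum sigma_i^2)/n, rounded half-up — the convention
under which 32,316 +/- 215 and 32,623 +/- 200 BP combine to
32,469 +/- 147 BP.  The inverse-variance method is the standard weighted
mean, reported with the chi-square consistency statistic
T = sum((x_i - xbar)/sigma_i)^2.

Calibration to calendar years requires an external calibration curve and
is out of scope; :func:`calibrate` accepts a user-supplied curve but the
package ships none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .types import RadiocarbonDate

ARITHMETIC = "arithmetic"
INVERSE_VARIANCE = "inverse_variance"


@dataclass(frozen=True)
class CombinedDate:
    date: RadiocarbonDate
    method: str
    n: int
    consistency_t: float | None = None


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def combine_dates(dates: list[RadiocarbonDate], method: str = ARITHMETIC) -> CombinedDate:
    """Combine replicate measurements of one sample into a single date.

    Permutation-invariant; requires at least two dates.
    """
    if len(dates) < 2:
        raise ParameterError("need at least two dates to combine")
    ages = np.array([d.age for d in dates], dtype=float)
    sigmas = np.array([d.sigma for d in dates], dtype=float)
    n = len(dates)
    if method == ARITHMETIC:
        age = math.trunc(ages.mean())
        sigma = _round_half_up(math.sqrt(float((sigmas**2).sum())) / n)
        return CombinedDate(RadiocarbonDate(age, sigma, "combined"), method, n)
    if method == INVERSE_VARIANCE:
        w = 1.0 / sigmas**2
        xbar = float((w * ages).sum() / w.sum())
        sigma = float(1.0 / math.sqrt(w.sum()))
        t = float((((ages - xbar) / sigmas) ** 2).sum())
        return CombinedDate(
            RadiocarbonDate(xbar, sigma, "combined"), method, n, consistency_t=t
        )
    raise ParameterError(f"unknown combination method {method!r}")


def calibrate(date: RadiocarbonDate, curve=None):
    """Hook for age calibration against a user-supplied calibration curve.

    No curve is bundled; passing ``curve=None`` raises.
    """
    if curve is None:
        raise ParameterError(
            "calibration requires a calibration curve (none is bundled with this package)"
        )
    raise NotImplementedError("user-supplied curve calibration is not implemented")
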
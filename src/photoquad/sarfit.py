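"""Gleason species-area model fitting and Molinier-point minimal sampling areas.

The semilog (Gleason) species-area relationship

    S = a * ln(A) + b

is fitted by ordinary least squares of mean richness on the natural log
of area (cm^2).  Two derived quantities drive survey design:

* ``k = exp(-b / a)`` — the area scale of the curve, i.e. the area at
  which the fitted curve crosses S = 0.  The more dispersed the species,
  the larger k, and the larger the sample needed.
* the Molinier point ``M dA/d'S`` — the area beyond which a dA% increase
  in area buys less than a d'S% increase in species.  Under the Gleason
  model the condition "increasing A by dA% increases S by exactly d'S%"
  is met at a single area proportional to k, with multiplier

      (1 + dA/100) ** (100 / d'S)

  using finite relative increments.  For the conventional M 20/5
  criterion the multiplier is 1.2**20 = 38.34 (38.3 at 3 significant
  figures), so A_min = 38.3 * k.

The finite-increment form, not the derivative form, is used throughout:
it is the form under which A_min/k is a pure constant of (dA, d'S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .accumulation import SpeciesAreaCurve
from .incidence import ValidationError

DEFAULT_DA = 20.0
DEFAULT_DS = 5.0


def fit_gleason(
    curve: SpeciesAreaCurve | tuple[Sequence[float], Sequence[float]],
    min_n: int = 1,
) -> tuple[float, float, float]:
    """OLS fit of mean richness on ln(area); returns ``(a, b, r2)``.

    ``min_n`` drops curve points below that sample size (sensitivity
    checks; the default keeps every point including n = 1).  A flat
    curve fits with a = 0 and r2 reported as 0.
    """
    if isinstance(curve, SpeciesAreaCurve):
        mask = curve.n >= min_n
        areas = curve.area_cm2[mask]
        s = curve.mean_s[mask]
    else:
        areas = np.asarray(curve[0], dtype=float)
        s = np.asarray(curve[1], dtype=float)
    if np.any(areas <= 0):
        raise ValidationError("areas must be positive for the log fit")
    if len(np.unique(areas)) < 3:
        raise ValidationError("need >= 3 distinct areas to fit the Gleason model")
    x = np.log(areas)
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in ln(area)")
    if np.ptp(s) == 0:
        return 0.0, float(s[0]), 0.0
    res = stats.linregress(x, s)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def k_param(a: float, b: float) -> float:
    """Curve-shape parameter ``k = exp(-b/a)`` (area units, cm^2).

    Defined only for rising curves (a > 0); k is the area where the
    fitted Gleason line crosses S = 0.
    """
    if a <= 0:
        raise ValidationError(
            f"k requires a positive Gleason slope (got a={a}); "
            "a non-increasing curve has no minimal sampling area"
        )
    return math.exp(-b / a)


def molinier_multiplier(dA: float = DEFAULT_DA, dS: float = DEFAULT_DS) -> float:
    """Dimensionless A_min / k ratio for the Molinier criterion M dA/d'S.

    ``(1 + dA/100) ** (100 / dS)``; the M 20/5 default gives
    1.2**20 = 38.34.
    """
    if dA <= 0 or dS <= 0:
        raise ValidationError("Molinier increments must be positive percentages")
    return (1.0 + dA / 100.0) ** (100.0 / dS)


@dataclass
class GleasonFit:
    """Fitted Gleason model with derived k and minimal sampling area.

    ``valid`` is False when the curve is flat or falling, in which case
    k and a_min are NaN.  ``a_min_quadrats`` is the minimal area in
    whole quadrats (rounded up) when ``side_cm`` is known.
    """

    a: float
    b: float
    r2: float
    k: float
    a_min: float
    criterion: tuple[float, float] = (DEFAULT_DA, DEFAULT_DS)
    side_cm: float | None = None
    valid: bool = True

    @property
    def a_min_quadrats(self) -> int | None:
        if self.side_cm is None or not self.valid:
            return None
        return int(math.ceil(self.a_min / self.side_cm**2))

    def to_dict(self) -> dict:
        d = {
            "a": self.a,
            "b": self.b,
            "r2": self.r2,
            "k": self.k,
            "a_min": self.a_min,
            "criterion_dA": self.criterion[0],
            "criterion_dS": self.criterion[1],
            "valid": self.valid,
        }
        if self.side_cm is not None:
            d["side_cm"] = self.side_cm
            d["a_min_quadrats"] = self.a_min_quadrats
        return d


def minimal_area(fit: GleasonFit | tuple[float, float], dA: float = DEFAULT_DA, dS: float = DEFAULT_DS) -> float:
    """Molinier-point minimal sampling area ``A_min = k * multiplier(dA, dS)`` in cm^2."""
    if isinstance(fit, GleasonFit):
        a, b = fit.a, fit.b
    else:
        a, b = fit
    return k_param(a, b) * molinier_multiplier(dA, dS)


def tabulated_minimal_area(a: float, b: float, dA: float = DEFAULT_DA, dS: float = DEFAULT_DS) -> int:
    """A_min under the printed-table rounding convention.

    k is rounded to the nearest integer and multiplied by the Molinier
    multiplier rounded to 3 significant figures (38.3 for M 20/5), then
    rounded to an integer — the convention used in published minimal-
    sampling-area tables.  :func:`minimal_area` keeps full precision.
    """
    k = round(k_param(a, b))
    mult = float(f"{molinier_multiplier(dA, dS):.3g}")
    return round(k * mult)


def gleason_fit(
    curve: SpeciesAreaCurve,
    side_cm: float | None = None,
    dA: float = DEFAULT_DA,
    dS: float = DEFAULT_DS,
    min_n: int = 1,
) -> GleasonFit:
    """Fit the model to a species-area curve and derive k and A_min.

    Degenerate curves (flat, falling) yield ``valid=False`` with NaN
    k/A_min instead of raising, so multi-plot reports can keep going.
    """
    a, b, r2 = fit_gleason(curve, min_n=min_n)
    try:
        k = k_param(a, b)
        a_min = k * molinier_multiplier(dA, dS)
        valid = True
    except ValidationError:
        k = float("nan")
        a_min = float("nan")
        valid = False
    return GleasonFit(
        a=a, b=b, r2=r2, k=k, a_min=a_min, criterion=(dA, dS), side_cm=side_cm, valid=valid
    )


def round_report(fit: GleasonFit) -> dict:
    """Tabular rounding convention: integer k and A_min, r2 at 3 decimals."""
    d = fit.to_dict()
    if fit.valid:
        d["k"] = round(fit.k)
        d["a_min"] = round(fit.a_min)
    d["r2"] = round(fit.r2, 3)
    return d
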
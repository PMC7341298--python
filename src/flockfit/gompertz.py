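"""Gompertz growth equations in two parameterizations.

The Gompertz curve is the standard sigmoid for poultry body-weight growth.
Two algebraically equivalent forms are used throughout this package:

* **G1** (classic form), ``BW(t) = BWa * exp(-b * exp(-k*t))`` with the
  asymptotic (adult) weight ``BWa`` (g), a dimensionless shape parameter
  ``b`` linking the asymptote to hatch weight (``b = ln(BWa/BW0)``), and the
  instantaneous relative growth rate ``k`` (1/day).

* **G2** (lag-time form, after Zwietering's reparameterization),
  ``BW(t) = BWa * exp(-exp((e*mu/BWa)*(lam - t) + 1))`` with the absolute
  growth rate at the inflection point ``mu`` (g/day) and the lag time
  ``lam`` (days): the intercept of the inflection tangent with the time
  axis, i.e. the modelled delay before rapid growth.

Both forms inflect at ``BWa / e`` — the Gompertz constant ``1/e`` — which is
why the weight at the inflection point is a fixed fraction (~0.368) of the
adult weight for every parameter set.

Internal time unit is days; hatch is day 0.  Week inputs elsewhere in the
package are converted as ``days = 7 * week``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GOMPERTZ_CONSTANT",
    "G1Params",
    "G2Params",
    "DerivedTraits",
    "InvalidParameterError",
    "DegenerateCurveError",
    "predict_g1",
    "predict_g2",
    "convert_g1_to_g2",
    "convert_g2_to_g1",
    "derive_from_g1",
    "derive_from_g2",
    "shape_from_weights",
]

#: 1/e, the fraction of the asymptote at which every Gompertz curve inflects.
#: Kept at full precision; round only for display.
GOMPERTZ_CONSTANT = 1.0 / math.e

DEFAULT_SLAUGHTER_AGE = 180.0  # days; standard age for sale of these breeds


class InvalidParameterError(ValueError):
    """A Gompertz parameter is non-finite or outside its valid domain."""


class DegenerateCurveError(ValueError):
    """The parameter set describes no usable growth curve (e.g. mu ~ 0)."""


def _require_positive_finite(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0.0:
        raise InvalidParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class G1Params:
    """Classic Gompertz parameters.

    Attributes
    ----------
    bwa : float
        Asymptotic (adult) body weight, g.
    b : float
        Dimensionless shape parameter; equals ln(BWa / BW0) where BW0 is the
        model-implied hatch weight.
    k : float
        Instantaneous relative growth rate, 1/day.
    """

    bwa: float
    b: float
    k: float

    def __post_init__(self) -> None:
        _require_positive_finite("bwa", self.bwa)
        _require_positive_finite("b", self.b)
        _require_positive_finite("k", self.k)


@dataclass(frozen=True)
class G2Params:
    """Lag-time Gompertz parameters.

    Attributes
    ----------
    bwa : float
        Asymptotic body weight, g.
    mu : float
        Absolute growth rate at the inflection point, g/day.
    lam : float
        Lag time, days.  May be slightly negative for birds already growing
        fast from hatch (equivalently b < e in the classic form); a warning
        is emitted in that case rather than an error.
    """

    bwa: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        _require_positive_finite("bwa", self.bwa)
        _require_positive_finite("mu", self.mu)
        if not math.isfinite(self.lam):
            raise InvalidParameterError(f"lam must be finite, got {self.lam!r}")
        if self.lam < 0.0:
            warnings.warn(
                f"negative lag time lam={self.lam:.3g} d (growth already "
                "accelerating at hatch); mathematically valid",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DerivedTraits:
    """Biologically meaningful quantities derived from a Gompertz fit.

    Attributes
    ----------
    bwip : float
        Body weight at the inflection point, g (= BWa / e).
    tip : float
        Age at the inflection point, days.
    mgr : float
        Maximum (absolute) growth rate, attained at the inflection, g/day.
    bws : float
        Predicted weight at slaughter age, g.
    dm : float
        Degree of maturity, BWs / BWa (dimensionless, in (0, 1)).
    bw0_implied : float
        Model-implied hatch weight, g.
    """

    bwip: float
    tip: float
    mgr: float
    bws: float
    dm: float
    bw0_implied: float


def predict_g1(params: G1Params, t) -> np.ndarray | float:
    """Body weight (g) at age ``t`` (days) under the classic form."""
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    out = params.bwa * np.exp(-params.b * np.exp(-params.k * t_arr))
    return out if out.ndim else float(out)


def predict_g2(params: G2Params, t) -> np.ndarray | float:
    """Body weight (g) at age ``t`` (days) under the lag-time form."""
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    inner = (math.e * params.mu / params.bwa) * (params.lam - t_arr) + 1.0
    out = params.bwa * np.exp(-np.exp(inner))
    return out if out.ndim else float(out)


def convert_g1_to_g2(params: G1Params) -> G2Params:
    """Map classic parameters to the lag-time form.

    Obtained by equating the two curve forms: ``mu = BWa*k/e`` and
    ``lam = (ln b - 1)/k``.  The predicted curves are identical.
    """
    mu = params.bwa * params.k / math.e
    lam = (math.log(params.b) - 1.0) / params.k
    with warnings.catch_warnings():
        # the caller's G1 parameters were already validated; a negative lam
        # here is the documented b < e case, not a new condition to flag
        warnings.simplefilter("ignore")
        return G2Params(bwa=params.bwa, mu=mu, lam=lam)


def convert_g2_to_g1(params: G2Params) -> G1Params:
    """Inverse map: ``k = e*mu/BWa``, ``b = exp(k*lam + 1)``."""
    k = math.e * params.mu / params.bwa
    b = math.exp(k * params.lam + 1.0)
    return G1Params(bwa=params.bwa, b=b, k=k)


def shape_from_weights(bwa: float, bw0: float) -> float:
    """Shape parameter implied by adult and hatch weights, ``ln(BWa/BW0)``."""
    if not (bwa > 0 and bw0 > 0):
        raise InvalidParameterError("bwa and bw0 must be positive")
    if bw0 >= bwa:
        raise InvalidParameterError(
            f"hatch weight bw0={bw0!r} must be below the asymptote bwa={bwa!r}"
        )
    return math.log(bwa / bw0)


def derive_from_g1(params: G1Params, t_slaughter: float = DEFAULT_SLAUGHTER_AGE) -> DerivedTraits:
    """Derived traits from classic parameters.

    BWip = BWa/e, Tip = ln(b)/k, MGR = BWip*k, BWs = BW(t_slaughter),
    Dm = BWs/BWa, BW0 = BWa*exp(-b).
    """
    if t_slaughter <= 0:
        raise ValueError("t_slaughter must be positive")
    bwip = params.bwa * GOMPERTZ_CONSTANT
    tip = math.log(params.b) / params.k
    if params.b <= 1.0:
        warnings.warn(
            f"b={params.b:.3g} <= 1 places the inflection before hatch (Tip={tip:.3g} d)",
            stacklevel=2,
        )
    mgr = bwip * params.k
    bws = float(predict_g1(params, t_slaughter))
    return DerivedTraits(
        bwip=bwip,
        tip=tip,
        mgr=mgr,
        bws=bws,
        dm=bws / params.bwa,
        bw0_implied=params.bwa * math.exp(-params.b),
    )


def derive_from_g2(params: G2Params, t_slaughter: float = DEFAULT_SLAUGHTER_AGE) -> DerivedTraits:
    """Derived traits from lag-time parameters.

    Tip is defined implicitly (the age at which the curve reaches BWa/e) and
    has the closed form ``lam + BWa/(e*mu)``; a numeric root of the defining
    equation is computed as a cross-check and must agree to 1e-6 days.
    """
    if t_slaughter <= 0:
        raise ValueError("t_slaughter must be positive")
    if params.mu < 1e-12 * params.bwa:
        raise DegenerateCurveError(f"mu={params.mu!r} is degenerate for bwa={params.bwa!r}")
    bwip = params.bwa * GOMPERTZ_CONSTANT
    tip_closed = params.lam + params.bwa / (math.e * params.mu)

    half_width = max(10.0, 0.5 * abs(tip_closed))
    tip_root = brentq(
        lambda t: float(predict_g2(params, t)) - bwip,
        tip_closed - half_width,
        tip_closed + half_width,
        xtol=1e-9,
    )
    if abs(tip_root - tip_closed) > 1e-6:
        raise RuntimeError(
            f"inflection-age cross-check failed: closed form {tip_closed!r} "
            f"vs numeric root {tip_root!r}"
        )
    bws = float(predict_g2(params, t_slaughter))
    return DerivedTraits(
        bwip=bwip,
        tip=tip_closed,
        mgr=params.mu,
        bws=bws,
        dm=bws / params.bwa,
        bw0_implied=float(predict_g2(params, 0.0)),
    )
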
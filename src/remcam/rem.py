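"""The random encounter model: density, variance propagation, sensitivity.

Density follows the gas-model contact rate for a sector detection zone:

    D = (y/t) * pi / (V * r * (2 + theta))

with the encounter rate y/t in events per hour, speed V in km/h, detection
radius r in km and full detection angle theta in radians. Uncertainty is
propagated to first order as a sum of squared coefficients of variation,

    CV^2(D) = CV^2(y/t) + CV^2(V) + CV^2(r) + (theta/(2+theta))^2 * CV^2(theta),

the angle's contribution being damped by its elasticity theta/(2+theta).
"""

from __future__ import annotations

import math
from typing import Union

from .types import EncounterRate, REMParams, REMResult, ValidationError

_Z95 = 1.959963984540054

_ELASTIC = ("v", "r", "theta")


def rem_density(rate: Union[EncounterRate, float], params: REMParams) -> float:
    """REM density (animals/km^2) from an encounter rate and field parameters."""
    rho = rate.rate if isinstance(rate, EncounterRate) else float(rate)
    if rho < 0:
        raise ValidationError(f"encounter rate must be >= 0, got {rho}")
    return rho * math.pi / (params.v * params.r * (2.0 + params.theta))


def elasticity(params: REMParams, which: str) -> float:
    """Analytic elasticity of D with respect to a parameter (absolute value).

    D scales as V^-1 and r^-1 (elasticity 1) and as (2+theta)^-1, giving the
    angle an elasticity of theta/(2+theta).
    """
    which = which.lower()
    if which in ("v", "speed"):
        return 1.0
    if which in ("r", "radius"):
        return 1.0
    if which in ("theta", "angle"):
        return params.theta / (2.0 + params.theta)
    raise ValidationError(f"unknown parameter {which!r}; expected one of {_ELASTIC}")


def sensitivity(
    params: REMParams,
    which: str,
    perturbation: float = 0.01,
    rate: float = 1.0,
) -> float:
    """Percent change in D for a fractional perturbation of one parameter.

    Returns ``100 * |D(p*(1+delta)) - D(p)| / D(p)`` with the encounter rate
    held fixed. ``rate`` cancels and only anchors the finite difference.
    """
    if abs(perturbation) > 0.05:
        raise ValidationError("perturbation must be small (|delta| <= 0.05)")
    which_l = which.lower()
    if which_l in ("v", "speed"):
        perturbed = params.replace(v=params.v * (1.0 + perturbation))
    elif which_l in ("r", "radius"):
        perturbed = params.replace(r=params.r * (1.0 + perturbation))
    elif which_l in ("theta", "angle"):
        perturbed = params.replace(theta=params.theta * (1.0 + perturbation))
    else:
        raise ValidationError(f"unknown parameter {which!r}; expected one of {_ELASTIC}")
    d0 = rem_density(rate, params)
    d1 = rem_density(rate, perturbed)
    return 100.0 * abs(d1 - d0) / d0


def _interval(d: float, cv: float, method: str):
    if d == 0 or math.isnan(cv):
        return (0.0, 0.0) if d == 0 else (float("nan"), float("nan"))
    if method == "lognormal":
        # Positive by construction; matches a lognormal with matching CV.
        sdlog = math.sqrt(math.log1p(cv * cv))
        return d * math.exp(-_Z95 * sdlog), d * math.exp(_Z95 * sdlog)
    if method == "normal":
        se = d * cv
        return max(d - _Z95 * se, 0.0), d + _Z95 * se
    raise ValidationError(f"unknown CI method {method!r}; use 'lognormal' or 'normal'")


def delta_variance(
    rate: EncounterRate,
    params: REMParams,
    ci_method: str = "lognormal",
) -> REMResult:
    """REM density with first-order (delta-method) variance propagation.

    The encounter rate's CV^2 comes from its bootstrap variance; the field
    parameters contribute their own CV^2 terms, the angle damped by its
    elasticity squared. The 95% interval defaults to the lognormal form
    ``D * exp(±1.96 * sqrt(ln(1 + CV^2)))``, which keeps the bounds positive.
    """
    if not math.isnan(rate.var_boot) and rate.var_boot < 0:
        raise ValidationError("bootstrap variance must be >= 0")
    d = rem_density(rate, params)
    cv2_rate = 0.0
    if rate.rate > 0:
        if math.isnan(rate.var_boot):
            raise ValidationError(
                "encounter rate has no bootstrap variance; run bootstrap_rate_variance first"
            )
        cv2_rate = rate.var_boot / rate.rate ** 2
    damp = params.theta / (2.0 + params.theta)
    components = {
        "rate": cv2_rate,
        "v": (params.se_v / params.v) ** 2,
        "r": (params.se_r / params.r) ** 2,
        "theta": damp ** 2 * (params.se_theta / params.theta) ** 2,
    }
    cv2 = sum(components.values())
    cv = math.sqrt(cv2)
    lo, hi = _interval(d, cv, ci_method)
    return REMResult(
        d=d,
        se_d=d * cv,
        ci_low=lo,
        ci_high=hi,
        cv2_components=components,
        rate=rate,
        params=params,
        ci_method=ci_method,
    )
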
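"""Mixture cure model functions.

The conventional mixture cure model writes the net (relative) survival of
a cancer cohort as a two-component mixture

    RS(t) = pi(x) + (1 - pi(x)) * S_u(t, x),

where ``pi`` is the cure fraction (the asymptote of net survival) and
``S_u`` the Weibull net survival of uncured patients.  The corrected
model multiplies the cohort's expected (non-cancer) hazard by a factor
``alpha``, so observed survival becomes

    S_O(t) = RS(t) * S*(t | age)**alpha.

All functions take the standardized age ``x = (age - 60) / 15`` and a
:class:`~curecorrect.params.CureParams` instance.  The age effect on the
uncured component is the survival exponent (equivalently hazard
multiplier) ``exp(-delta * x)`` throughout, so positive ``delta`` means
lower uncured mortality at older ages; the same convention is used by
the simulator, so fitted ``delta`` recovers the generating value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import CureParams, standardize_age

__all__ = [
    "cure_fraction", "uncured_survival", "uncured_density", "net_survival",
    "excess_hazard", "observed_survival", "exponentiated_weibull_survival",
    "predict_summary",
]


def cure_fraction(x, params: CureParams):
    """Cure fraction pi(x) under the configured link.

    logistic: ``1 / (1 + exp(-beta0 - beta * x))``; identity:
    ``beta0 + beta * x`` (validated, not clamped — identity-link values
    outside [0, 1] raise).  The ``corrected_no_cure`` variant has no
    cured component and returns 0.
    """
    x = np.asarray(x, dtype=float)
    if params.variant == "corrected_no_cure":
        return np.zeros_like(x)
    if params.link == "logistic":
        return 1.0 / (1.0 + np.exp(-(params.beta0 + params.beta * x)))
    pi = params.beta0 + params.beta * x
    bad = (pi < 0) | (pi > 1)
    if np.any(bad):
        offending = np.atleast_1d(x)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"identity-link cure fraction outside [0, 1] at x={offending:g}")
    return pi


def _check_t(t, strict=False):
    t = np.asarray(t, dtype=float)
    if strict:
        if np.any(t <= 0):
            raise ValueError("t must be positive")
    elif np.any(t < 0):
        raise ValueError("t must be non-negative")
    return t


def uncured_survival(t, x, params: CureParams):
    """Weibull net survival of the uncured:
    ``exp(-lambda * t**gamma * exp(-delta * x))``."""
    t = _check_t(t)
    x = np.asarray(x, dtype=float)
    return np.exp(-params.lambda_ * t ** params.gamma_
                  * np.exp(-params.delta * x))


def uncured_hazard(t, x, params: CureParams):
    """Weibull hazard of the uncured:
    ``gamma * lambda * t**(gamma-1) * exp(-delta * x)``."""
    t = _check_t(t, strict=True)
    x = np.asarray(x, dtype=float)
    return (params.gamma_ * params.lambda_ * t ** (params.gamma_ - 1.0)
            * np.exp(-params.delta * x))


def uncured_density(t, x, params: CureParams):
    """Density of time to cancer death among the uncured,
    ``f_u = hazard * survival``; integrates to 1 on [0, inf)."""
    t = _check_t(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (params.gamma_ * params.lambda_ * t ** (params.gamma_ - 1.0)
             * np.exp(-params.delta * np.asarray(x, dtype=float)))
    return h * uncured_survival(t, x, params)


def net_survival(t, x, params: CureParams):
    """Mixture net survival ``RS(t) = pi + (1 - pi) * S_u(t, x)``.

    Tends to the cure fraction as t grows.
    """
    pi = cure_fraction(x, params)
    return pi + (1.0 - pi) * uncured_survival(t, x, params)


def excess_hazard(t, x, params: CureParams):
    """Cancer-attributable hazard
    ``h_c = (1 - pi) f_u / [pi + (1 - pi) S_u]``; equals
    ``-d/dt log RS`` and vanishes as t -> inf whenever pi > 0."""
    t = _check_t(t, strict=True)
    pi = cure_fraction(x, params)
    return (1.0 - pi) * uncured_density(t, x, params) / net_survival(t, x, params)


def observed_survival(t, x, age, params: CureParams, pop):
    """All-cause survival of the cohort,
    ``S_O(t) = RS(t, x) * S*(t | age)**alpha``."""
    return (net_survival(t, x, params)
            * pop.survival(age, t) ** params.alpha)


def exponentiated_weibull_survival(t, x, lambda_, gamma_, theta, delta=0.0):
    """Exponentiated-Weibull net survival of the uncured,

        S_u(t, x) = {1 - [1 - exp(-lambda * t**gamma)]**theta}**exp(-delta*x).

    The second shape ``theta`` modulates the departure from the Weibull:
    theta = 1 recovers :func:`uncured_survival` exactly; theta > 1 gives
    a bell-shaped hazard, theta < 1 a U-shaped one.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if lambda_ <= 0 or gamma_ <= 0:
        raise ValueError("lambda_ and gamma_ must be positive")
    t = _check_t(t)
    x = np.asarray(x, dtype=float)
    base = 1.0 - (-np.expm1(-lambda_ * t ** gamma_)) ** theta
    return base ** np.exp(-delta * x)


def invert_exponentiated_weibull(p, lambda_, gamma_, theta, x=0.0, delta=0.0):
    """Solve ``exponentiated_weibull_survival(t) = p`` for t."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    core = 1.0 - p ** np.exp(delta * np.asarray(x, dtype=float))
    inner = core ** (1.0 / theta)
    return (-np.log1p(-inner) / lambda_) ** (1.0 / gamma_)


def predict_summary(params: CureParams, ages=(40, 50, 60, 70),
                    horizons=(1, 5, 10, 15)):
    """Net survival at each horizon and cure fraction, by age at diagnosis.

    Returns a tidy DataFrame with one row per age: columns ``age``,
    ``pi`` and ``ns_{h}y`` for each horizon.
    """
    rows = []
    for age in ages:
        x = standardize_age(age)
        row = {"age": float(age), "pi": float(cure_fraction(x, params))}
        for h in horizons:
            row[f"ns_{h:g}y"] = float(net_survival(h, x, params))
        rows.append(row)
    return pd.DataFrame(rows)
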
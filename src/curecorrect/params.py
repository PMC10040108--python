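"""Parameter container for mixture cure models."""

from __future__ import annotations

import dataclasses
import json
import math

import yaml

__all__ = ["CureParams", "standardize_age", "REFERENCE_AGE", "AGE_SCALE"]

REFERENCE_AGE = 60.0
AGE_SCALE = 15.0

VARIANTS = ("conventional", "corrected", "corrected_no_cure")
LINKS = ("logistic", "identity")


def standardize_age(age):
    """Standardized age covariate x = (age - 60) / 15."""
    import numpy as np
    return (np.asarray(age, dtype=float) - REFERENCE_AGE) / AGE_SCALE


@dataclasses.dataclass
class CureParams:
    """Parameters of the (corrected) mixture cure model.

    Attributes
    ----------
    alpha : float
        Multiplicative excess non-cancer mortality versus the general
        population (hazard ratio; 1 in the conventional variant).
    beta0 : float
        Cure-fraction intercept on the link scale; under the logistic
        link ``pi_60 = expit(beta0)``.
    beta : float
        Cure-fraction trend per 15 years of age (link scale).
    lambda_, gamma_ : float
        Rate-scale and shape of the Weibull net survival of the uncured,
        ``S_u(t) = exp(-lambda * t**gamma)`` at the reference age.
    delta : float
        Age effect on uncured survival per 15 years of age, entering as
        the survival exponent ``exp(-delta * x)`` (equivalently a hazard
        multiplier); positive values mean lower uncured mortality at
        older ages.
    link : {"logistic", "identity"}
    variant : {"conventional", "corrected", "corrected_no_cure"}
    """

    alpha: float = 1.0
    beta0: float = 0.0
    beta: float = 0.0
    lambda_: float = 0.1
    gamma_: float = 1.0
    delta: float = 0.0
    link: str = "logistic"
    variant: str = "corrected"

    def __post_init__(self):
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.lambda_ <= 0 or self.gamma_ <= 0:
            raise ValueError("lambda_ and gamma_ must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.variant == "conventional" and self.alpha != 1.0:
            raise ValueError("conventional variant fixes alpha = 1")

    # ------------------------------------------------------------------
    @classmethod
    def from_pi60(cls, pi60, **kwargs):
        """Build parameters from the cure fraction at the reference age.

        Under the logistic link ``beta0 = logit(pi60)``; under the
        identity link ``beta0 = pi60``.
        """
        link = kwargs.get("link", "logistic")
        if link == "logistic":
            if not 0 < pi60 < 1:
                raise ValueError("pi60 must lie strictly in (0, 1)")
            beta0 = math.log(pi60 / (1.0 - pi60))
        else:
            beta0 = pi60
        return cls(beta0=beta0, **kwargs)

    @property
    def pi60(self):
        """Cure fraction at the reference age (x = 0)."""
        if self.variant == "corrected_no_cure":
            return 0.0
        if self.link == "logistic":
            return 1.0 / (1.0 + math.exp(-self.beta0))
        return self.beta0

    # ------------------------------------------------------------------
    def replace(self, **kwargs):
        return dataclasses.replace(self, **kwargs)

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(source)
        return cls.from_dict(d)

    def to_json(self):
        return json.dumps(self.to_dict())
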
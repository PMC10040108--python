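"""General-population ("expected") mortality.

In the relative-survival setting the mortality a cancer cohort would
experience in the absence of its cancer is taken from the general
population: either a parametric Weibull fitted to life-table data, or a
tabulated life table itself.  Both forms expose the conditional survival
``S*(t | age)`` from age at diagnosis, the hazard ``h*(age + t)``, and
inverse-transform sampling of non-cancer death times with the excess
mortality factor ``alpha`` applied as ``S*(t | age)**alpha``.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = ["PopulationMortality"]

_MAX_AGE = 130.0  # closing age for tabulated hazards


class PopulationMortality:
    """Expected (non-cancer) mortality of the matched general population.

    Parameters
    ----------
    kind : {"parametric_weibull", "tabulated"}
        Functional form of the mortality model.
    lambda_p, gamma_p : float
        Scale (years) and shape of the all-age Weibull survival
        ``S*(a) = exp(-(a / lambda_p)**gamma_p)`` (parametric form only).
    table : pandas.DataFrame
        Columns ``age`` and ``hazard`` (per person-year), piecewise
        constant on annual intervals (tabulated form only).
    """

    def __init__(self, kind="parametric_weibull", lambda_p=None, gamma_p=None,
                 table=None):
        if kind not in ("parametric_weibull", "tabulated"):
            raise ValueError(f"unknown population mortality kind {kind!r}")
        self.kind = kind
        if kind == "parametric_weibull":
            if lambda_p is None or gamma_p is None:
                raise ValueError("parametric form requires lambda_p and gamma_p")
            if lambda_p <= 0 or gamma_p <= 0:
                raise ValueError("lambda_p and gamma_p must be positive")
            self.lambda_p = float(lambda_p)
            self.gamma_p = float(gamma_p)
            self.table = None
        else:
            if table is None:
                raise ValueError("tabulated form requires a table")
            self.lambda_p = self.gamma_p = None
            self.table = self._prepare_table(table)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def weibull(cls, lambda_p=88.0, gamma_p=11.0):
        """Parametric Weibull population mortality (defaults: the
        both-sexes 2002 French life-table fit, scale 88 y, shape 11)."""
        return cls("parametric_weibull", lambda_p=lambda_p, gamma_p=gamma_p)

    @classmethod
    def from_table(cls, table):
        """Tabulated mortality from a DataFrame with columns ``age`` and
        either ``hazard`` (per person-year) or ``qx`` (annual death
        probability, converted as ``hazard = -log(1 - qx)``)."""
        return cls("tabulated", table=table)

    @classmethod
    def from_csv(cls, path):
        """Read a tabulated life table from CSV.

        Lines starting with ``#`` are treated as comments (a leading
        comment line conventionally declares the dialect, e.g.
        ``# columns: age,qx``).  The data must have columns ``age`` and
        ``hazard`` or ``qx``.
        """
        df = pd.read_csv(path, comment="#")
        return cls.from_table(df)

    @staticmethod
    def _prepare_table(table):
        df = pd.DataFrame(table).copy()
        if "hazard" not in df.columns:
            if "qx" not in df.columns:
                raise ValueError("table needs an 'age' and a 'hazard' or 'qx' column")
            qx = np.asarray(df["qx"], dtype=float)
            if np.any(qx < 0) or np.any(qx >= 1):
                raise ValueError("qx values must lie in [0, 1)")
            df["hazard"] = -np.log1p(-qx)
        if "age" not in df.columns:
            raise ValueError("table needs an 'age' column")
        df = df[["age", "hazard"]].astype(float).sort_values("age")
        if df["age"].duplicated().any():
            raise ValueError("duplicate ages in life table")
        if (df["hazard"] < 0).any():
            raise ValueError("hazards must be non-negative")
        return df.reset_index(drop=True)

    # ------------------------------------------------------------------
    # cumulative hazard from birth
    # ------------------------------------------------------------------
    def cumulative_hazard(self, age):
        """H*(age), the all-cause cumulative hazard from birth."""
        age = np.asarray(age, dtype=float)
        if not np.all(np.isfinite(age)) or np.any(age < 0):
            raise ValueError("age must be finite and non-negative")
        if self.kind == "parametric_weibull":
            return (age / self.lambda_p) ** self.gamma_p
        # piecewise-constant hazard => piecewise-linear cumulative hazard
        knots = self.table["age"].to_numpy()
        haz = self.table["hazard"].to_numpy()
        edges = np.append(knots, _MAX_AGE)
        cumh = np.concatenate([[0.0], np.cumsum(haz * np.diff(edges))])
        # ages below the first knot carry the first hazard; above the last
        # knot the last hazard continues
        a = np.clip(age, knots[0], None)
        idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, len(haz) - 1)
        return cumh[idx] + haz[idx] * (a - edges[idx])

    def hazard_at_age(self, age):
        """h*(age), the all-cause hazard at attained age ``age``."""
        age = np.asarray(age, dtype=float)
        if not np.all(np.isfinite(age)) or np.any(age < 0):
            raise ValueError("age must be finite and non-negative")
        if self.kind == "parametric_weibull":
            with np.errstate(divide="ignore"):
                out = (self.gamma_p / self.lambda_p) * (
                    age / self.lambda_p) ** (self.gamma_p - 1.0)
            return out
        knots = self.table["age"].to_numpy()
        haz = self.table["hazard"].to_numpy()
        idx = np.clip(np.searchsorted(knots, age, side="right") - 1, 0,
                      len(haz) - 1)
        return haz[idx]

    # ------------------------------------------------------------------
    # conditional quantities from age at diagnosis
    # ------------------------------------------------------------------
    def survival(self, age, t):
        """S*(t | age) = exp(-[H*(age + t) - H*(age)]).

        Conditional probability that a population member alive at ``age``
        is still alive ``t`` years later; equals 1 at ``t = 0``.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        return np.exp(-(self.cumulative_hazard(np.asarray(age) + t)
                        - self.cumulative_hazard(age)))

    def hazard(self, age, t):
        """h*(age + t), the expected hazard ``t`` years after diagnosis."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        return self.hazard_at_age(np.asarray(age) + t)

    def sample_death_time(self, age, u, alpha=1.0):
        """Invert ``S*(t | age)**alpha = u`` for the non-cancer death time.

        ``alpha`` is the multiplicative excess non-cancer mortality of the
        cohort relative to the general population (1 = none).
        """
        u = np.asarray(u, dtype=float)
        alpha = np.asarray(alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("alpha must be positive")
        if np.any(u <= 0) or np.any(u >= 1):
            raise ValueError("u must lie strictly in (0, 1)")
        target = -np.log(u) / alpha  # conditional cumulative hazard to reach
        age = np.asarray(age, dtype=float)
        if self.kind == "parametric_weibull":
            t = self.lambda_p * ((age / self.lambda_p) ** self.gamma_p
                                 + target) ** (1.0 / self.gamma_p) - age
            return np.maximum(t, 0.0)
        return self._invert_tabulated(age, target)

    def _invert_tabulated(self, age, target):
        knots = self.table["age"].to_numpy()
        haz = self.table["hazard"].to_numpy()
        edges = np.append(knots, _MAX_AGE)
        cumh = np.concatenate([[0.0], np.cumsum(haz * np.diff(edges))])
        h0 = self.cumulative_hazard(age)
        goal = np.atleast_1d(h0 + target)
        age1 = np.atleast_1d(age)
        # final open-ended interval keeps the last hazard so inversion
        # always succeeds
        idx = np.clip(np.searchsorted(cumh, goal, side="right") - 1, 0,
                      len(haz) - 1)
        attained = edges[idx] + (goal - cumh[idx]) / haz[idx]
        t = np.maximum(attained - age1, 0.0)
        return t if np.ndim(age) or np.ndim(target) else float(t[0])

    # ------------------------------------------------------------------
    def to_dict(self):
        if self.kind == "parametric_weibull":
            return {"kind": self.kind, "lambda_p": self.lambda_p,
                    "gamma_p": self.gamma_p}
        return {"kind": self.kind,
                "table": self.table.to_dict(orient="list")}

    @classmethod
    def from_dict(cls, d):
        if d["kind"] == "parametric_weibull":
            return cls.weibull(d["lambda_p"], d["gamma_p"])
        return cls.from_table(pd.DataFrame(d["table"]))

    def __repr__(self):
        if self.kind == "parametric_weibull":
            return (f"PopulationMortality(weibull, scale={self.lambda_p:g} y, "
                    f"shape={self.gamma_p:g})")
        return f"PopulationMortality(tabulated, {len(self.table)} ages)"


def expected_survival(age, t, pop):
    """Functional alias for :meth:`PopulationMortality.survival`."""
    return pop.survival(age, t)


def expected_hazard(age, t, pop):
    """Functional alias for :meth:`PopulationMortality.hazard`."""
    return pop.hazard(age, t)


def sample_noncancer_death_time(age, alpha, u, pop):
    """Functional alias for :meth:`PopulationMortality.sample_death_time`."""
    return pop.sample_death_time(age, u, alpha=alpha)
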
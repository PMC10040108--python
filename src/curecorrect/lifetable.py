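"""Grouped relative-survival life tables.

A life table groups a cohort into strata (age classes by default) and
annual follow-up intervals.  Each cell carries the actuarial counts
``n`` (alive at the interval start), ``d`` (deaths), ``w`` (censored),
the effective number at risk ``l = n - 0.5 w`` (censored patients
contribute half an interval), the observed conditional interval survival
``s_obs = 1 - d / l`` and the Ederer II expected conditional interval
survival ``s_exp`` — the mean, over patients at risk at the interval
start, of their individual conditional population survival over the
interval.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort
from .params import standardize_age

__all__ = ["LifeTable", "build_life_table", "ederer2_expected",
           "relative_survival_table", "DEFAULT_AGE_BREAKS"]

#: the simulation study's four age classes: 40-57, 58-64, 65-69, 70-74
DEFAULT_AGE_BREAKS = (40.0, 58.0, 65.0, 70.0, 75.0)

COLUMNS = ["stratum", "t_start", "t_end", "n", "d", "w", "l",
           "s_obs", "s_exp", "mean_age", "x"]


@dataclasses.dataclass
class LifeTable:
    """Strata x intervals life table backed by a tidy DataFrame."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in COLUMNS if c not in df.columns and c != "s_exp"]
        if missing:
            raise ValueError(f"life table is missing columns {missing}")
        if "s_exp" not in df.columns:
            df["s_exp"] = np.nan
        self.data = df[COLUMNS].reset_index(drop=True)

    # ------------------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort, pop=None, age_breaks=DEFAULT_AGE_BREAKS,
                    interval_width=1.0, max_followup=15.0):
        return build_life_table(cohort, age_breaks, interval_width,
                                max_followup, pop)

    @property
    def strata(self):
        return list(dict.fromkeys(self.data["stratum"]))

    def __len__(self):
        return len(self.data)

    def relative_survival(self):
        """Cumulative observed, expected, and relative survival."""
        return relative_survival_table(self)

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, comment="#"))


def _interval_bounds(interval_width, max_followup):
    n = int(round(max_followup / interval_width))
    if not np.isclose(n * interval_width, max_followup):
        raise ValueError("max_followup must be a multiple of interval_width")
    return np.arange(n + 1) * interval_width


def build_life_table(cohort, age_breaks=DEFAULT_AGE_BREAKS,
                     interval_width=1.0, max_followup=15.0, pop=None):
    """Group a cohort into a :class:`LifeTable`.

    Deaths and censorings are assigned to half-open intervals
    ``[t_{j-1}, t_j)``; a follow-up time exactly equal to
    ``max_followup`` falls in the last interval, where a censored
    record counts as a survivor of the whole interval (full exposure)
    rather than a mid-interval censoring.  Strata are the
    half-open age classes defined by ``age_breaks``.  When ``pop`` is
    given the Ederer II expected interval survival is filled in.
    """
    if not isinstance(cohort, Cohort):
        cohort = Cohort(cohort)
    times = cohort.time
    if np.any(times > max_followup):
        raise ValueError("follow-up times exceed max_followup")
    ages = cohort.age
    events = cohort.event
    bounds = _interval_bounds(interval_width, max_followup)
    n_int = len(bounds) - 1
    breaks = np.asarray(age_breaks, dtype=float)
    stratum_of = np.searchsorted(breaks, ages, side="right") - 1
    if np.any(stratum_of < 0) or np.any(stratum_of >= len(breaks) - 1):
        raise ValueError("ages outside the configured age classes")
    # interval of the terminal time; t == max_followup goes to the last
    interval_of = np.minimum((times // interval_width).astype(int), n_int - 1)
    # patients censored exactly at the end of follow-up are survivors of
    # the last interval (full exposure), not mid-interval censorings
    survivor = (times >= max_followup) & (events == 0)

    rows = []
    for k in range(len(breaks) - 1):
        mask = stratum_of == k
        if not mask.any():
            warnings.warn(f"empty age stratum [{breaks[k]:g}, {breaks[k+1]:g})"
                          " dropped", stacklevel=2)
            continue
        label = f"{breaks[k]:g}-{breaks[k+1]:g}"
        mean_age = float(ages[mask].mean())
        x_k = float(standardize_age(ages[mask]).mean())
        t_k, e_k, iv_k = times[mask], events[mask], interval_of[mask]
        cens_k = (e_k == 0) & ~survivor[mask]
        d = np.bincount(iv_k[e_k == 1], minlength=n_int).astype(float)
        w = np.bincount(iv_k[cens_k], minlength=n_int).astype(float)
        n = mask.sum() - np.concatenate([[0.0], np.cumsum(d + w)[:-1]])
        s_exp = (ederer2_expected(ages[mask], t_k, pop, bounds)
                 if pop is not None else np.full(n_int, np.nan))
        for j in range(n_int):
            if n[j] <= 0:
                break  # empty risk set: truncate the stratum
            l = n[j] - 0.5 * w[j]
            rows.append({
                "stratum": label, "t_start": bounds[j], "t_end": bounds[j + 1],
                "n": n[j], "d": d[j], "w": w[j], "l": l,
                "s_obs": 1.0 - d[j] / l if l > 0 else np.nan,
                "s_exp": s_exp[j], "mean_age": mean_age, "x": x_k,
            })
    return LifeTable(pd.DataFrame(rows))


def ederer2_expected(ages, times, pop, bounds):
    """Ederer II expected conditional survival per interval.

    For each interval ``[t_{j-1}, t_j)`` averages, over the patients
    still at risk at ``t_{j-1}``, the individual conditional population
    survivals ``S*(t_j | age_i) / S*(t_{j-1} | age_i)``.  Intervals with
    an empty risk set yield NaN (the table is truncated there).
    """
    ages = np.asarray(ages, dtype=float)
    times = np.asarray(times, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    # cumulative population survival of each patient at every bound
    surv = pop.survival(ages[:, None], bounds[None, :])
    cond = surv[:, 1:] / surv[:, :-1]
    at_risk = times[:, None] >= bounds[None, :-1]
    counts = at_risk.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0,
                       (cond * at_risk).sum(axis=0) / np.maximum(counts, 1),
                       np.nan)
    return out


def relative_survival_table(life_table):
    """Cumulative observed / expected / relative survival per stratum.

    Relative survival is the ratio of the cumulative products of the
    observed and Ederer II expected interval survivals; it is not
    clamped and may exceed 1.
    """
    df = life_table.data if isinstance(life_table, LifeTable) else life_table
    out = df.copy()
    out["cum_obs"] = out.groupby("stratum", sort=False)["s_obs"].cumprod()
    out["cum_exp"] = out.groupby("stratum", sort=False)["s_exp"].cumprod()
    out["rs"] = out["cum_obs"] / out["cum_exp"]
    return out[["stratum", "t_start", "t_end", "cum_obs", "cum_exp", "rs"]]
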
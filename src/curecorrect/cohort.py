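"""Individual patient records."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import standardize_age

__all__ = ["Cohort"]

REQUIRED = ("age", "time", "event")


@dataclasses.dataclass
class Cohort:
    """A cohort of individual records.

    ``data`` holds one row per patient with columns ``age`` (years at
    diagnosis), ``time`` (follow-up in years), ``event`` (1 = dead,
    0 = censored) and the derived standardized age ``x``.  Optional
    provenance columns (``true_cured``, ``cause``) may be carried by the
    simulator; they are never used by estimation.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing columns {missing}")
        df["age"] = df["age"].astype(float)
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event must be 0 or 1")
        if (df["time"] < 0).any():
            raise ValueError("follow-up times must be non-negative")
        if not np.isfinite(df["age"]).all():
            raise ValueError("ages must be finite")
        if "x" not in df.columns:
            df["x"] = standardize_age(df["age"])
        if "id" not in df.columns:
            df.insert(0, "id", np.arange(len(df)))
        self.data = df.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    @property
    def age(self):
        return self.data["age"].to_numpy()

    @property
    def x(self):
        return self.data["x"].to_numpy()

    @property
    def time(self):
        return self.data["time"].to_numpy()

    @property
    def event(self):
        return self.data["event"].to_numpy()

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, truth=False):
        """Write the cohort; provenance columns only when ``truth``."""
        df = self.data
        if not truth:
            df = df[[c for c in df.columns
                     if c in ("id", "age", "x", "time", "event")]]
        df.to_csv(path, index=False)
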
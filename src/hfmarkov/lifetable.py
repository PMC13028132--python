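"""National life tables used to cap non-CV background mortality.

The engine never lets the per-cycle probability of non-CV death exceed the
general-population value at the cohort's attained age, with life-table
annual death probabilities (qx) reduced by the fraction of deaths that are
CV-related so CV mortality is not double counted.

A synthetic Gompertz-Makeham life table is provided for self-contained
runs; real tables load from CSV (columns: age, sex, qx, cv_fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import DAYS_PER_YEAR


@dataclass
class LifeTable:
    """Age- and sex-specific annual death probabilities with CV fractions."""

    table: pd.DataFrame  # columns: age, sex, qx, cv_fraction

    def __post_init__(self):
        df = self.table
        required = {"age", "sex", "qx", "cv_fraction"}
        if missing := required - set(df.columns):
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        if ((df["qx"] < 0) | (df["qx"] > 1)).any():
            raise ValueError("qx must lie in [0, 1]")
        for sex, g in df.groupby("sex"):
            ages = np.sort(g["age"].to_numpy())
            if np.any(np.diff(ages) != 1):
                raise ValueError(f"ages not contiguous for sex {sex!r}")
            if g.loc[g["age"].idxmax(), "qx"] != 1.0:
                raise ValueError(f"terminal age must have qx = 1 for sex {sex!r}")
        self._qx = {s: g.set_index("age")["qx"] for s, g in df.groupby("sex")}
        self._cvf = {s: g.set_index("age")["cv_fraction"] for s, g in df.groupby("sex")}
        self.max_age = int(df["age"].max())

    def annual_noncv_probability(self, age: int, male_fraction: float) -> float:
        """Sex-weighted annual non-CV death probability, qx * (1 - cv_fraction)."""
        age = min(int(age), self.max_age)
        out = 0.0
        for sex, weight in (("male", male_fraction), ("female", 1.0 - male_fraction)):
            if age not in self._qx[sex].index:
                raise KeyError(f"life table does not cover age {age} for {sex}")
            out += weight * self._qx[sex].loc[age] * (1.0 - self._cvf[sex].loc[age])
        return float(out)

    def per_cycle_noncv_probability(self, age: int, male_fraction: float,
                                    cycle_days: float) -> float:
        q = self.annual_noncv_probability(age, male_fraction)
        if q >= 1.0:
            return 1.0
        return 1.0 - (1.0 - q) ** (cycle_days / DAYS_PER_YEAR)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.table.to_csv(Path(path), index=False)


def make_synthetic_life_table(min_age: int = 40, max_age: int = 110,
                              cv_fraction: float = 0.27) -> LifeTable:
    """Gompertz-Makeham life table loosely calibrated to a Western European
    population (male q70 ~ 0.02, female ~ 0.011); synthetic stand-in for a
    national table.
    """
    rows = []
    params = {"male": (5.0e-4, 2.5e-5, 0.095), "female": (4.0e-4, 1.4e-5, 0.095)}
    ages = np.arange(min_age, max_age + 1)
    for sex, (a, b, c) in params.items():
        hazard = a + b * np.exp(c * ages)
        qx = 1.0 - np.exp(-hazard)
        qx[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": qx,
                                  "cv_fraction": cv_fraction}))
    return LifeTable(pd.concat(rows, ignore_index=True))
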
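"""Other-cause mortality from a life table, and cohort generation.

The simulated men die of causes other than prostate cancer according to a
standard single-year life table (columns ``age``, ``qx``), where ``qx`` is the
conditional probability of dying within the year of age. The table must be
closed: the terminal ``qx`` equals 1, so every sampled death age is finite.
Death timing within the year of death is uniform (the usual demographic
assumption for single-year tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "LifeTable",
    "Cohort",
    "load_life_table",
    "write_life_table",
    "sample_death_age",
    "make_cohort",
]


@dataclass(frozen=True)
class LifeTable:
    """Single-year life table: integer ages from 0 and per-year death probabilities."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.ndim != 1 or len(ages) != len(qx):
            raise ConfigError("life table: ages and qx must be 1-D and equal length")
        if len(ages) == 0:
            raise ConfigError("life table: empty")
        if ages[0] != 0:
            raise ConfigError("life table: ages must start at 0")
        steps = np.diff(ages)
        if np.any(steps != 1):
            bad = int(np.argmax(steps != 1))
            raise ConfigError(
                f"life table: ages must increase by 1 (violation after row {bad}, age {ages[bad]})"
            )
        bad_q = np.where((qx < 0) | (qx > 1))[0]
        if bad_q.size:
            i = int(bad_q[0])
            raise ConfigError(f"life table: qx out of [0,1] at row {i} (age {ages[i]}, qx={qx[i]})")
        if qx[-1] != 1.0:
            raise ConfigError(
                f"life table: not closed — terminal qx at age {ages[-1]} is {qx[-1]}, expected 1"
            )

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def survival_curve(self) -> np.ndarray:
        """l(x) for x = 0..terminal_age+1: probability of surviving to exact age x."""
        lx = np.empty(len(self.ages) + 1)
        lx[0] = 1.0
        np.cumprod(1.0 - self.qx, out=lx[1:])
        return lx

    def life_expectancy(self) -> float:
        """e0 by direct summation, uniform deaths within the year: sum of (l_x+l_{x+1})/2."""
        lx = self.survival_curve()
        return float(np.sum((lx[:-1] + lx[1:]) / 2.0))

    def death_age_cdf(self) -> np.ndarray:
        """F(x+1) = P(death age < x+1) for each table row; reaches 1 at closure."""
        return 1.0 - self.survival_curve()[1:]


@dataclass
class Cohort:
    """A seeded all-male birth cohort with pre-sampled other-cause death ages."""

    n: int
    seed: int
    oc_death_ages: np.ndarray = field(repr=False)


def load_life_table(path) -> LifeTable:
    """Read a life table CSV with header columns ``age,qx`` and validate it."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ConfigError(f"life table {path}: missing columns {sorted(missing)}")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def write_life_table(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)


def sample_death_age(table: LifeTable, rng: np.random.Generator, size: int | None = None):
    """Sample continuous other-cause death ages from the table's discrete hazard.

    The year of death is drawn by inverting the death-age CDF; the sub-year
    offset is uniform. Returns a scalar when ``size`` is None.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    cdf = table.death_age_cdf()
    u = rng.uniform(size=n)
    year = np.searchsorted(cdf, u, side="right")
    ages = table.ages[year] + rng.uniform(size=n)
    return float(ages[0]) if scalar else ages


def make_cohort(table: LifeTable, n: int, seed: int) -> Cohort:
    """Generate a cohort of ``n`` men; identical seed reproduces identical ages."""
    rng = np.random.default_rng(seed)
    return Cohort(n=n, seed=seed, oc_death_ages=sample_death_age(table, rng, size=n))
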
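"""Age-specific rate tables and hazard-based event-age sampling.

The microsimulation consumes two annual rate tables: all-cause mortality
(hazard of death from natural causes, zero before age 50 because pre-screening
deaths are outside the modelled perspective) and breast-cancer carcinogenesis
incidence (annual probability that cancer cells first appear).  The national
tables the model was designed around are not bundled; this module builds
calibrated synthetic stand-ins with the same shape and level, and loads
user-supplied ``age,rate`` CSV files that override them.

Event ages are drawn from the discrete annual hazards by treating each year as
a piecewise-constant continuous hazard (lambda = -log(1 - p)), so the yearly
event probability is exactly the tabulated rate and sampling is exactly
invariant to splitting the horizon at any point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

AGE_MIN = 19
AGE_MAX = 110


@dataclass(frozen=True)
class AgeRateTable:
    """Annual event rates on the closed integer age range [19, 110].

    ``rates[i]`` is the probability of the event occurring during year of age
    ``ages[i]`` (i.e. in the interval ``[ages[i], ages[i] + 1)``) for a woman
    event-free at its start.
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.shape != rates.shape or ages.ndim != 1:
            raise ValueError("ages and rates must be 1-D and equal length")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be strictly increasing and contiguous")
        if ages[0] < AGE_MIN or ages[-1] > AGE_MAX:
            raise ValueError(f"ages must lie within [{AGE_MIN}, {AGE_MAX}]")
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValueError("rates must be probabilities in [0, 1]")

    def rate_at(self, age: float) -> float:
        """Annual rate for the year of age containing ``age`` (0 outside)."""
        idx = int(np.floor(age)) - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            return 0.0
        return float(self.rates[idx])

    def cumulative_hazard_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Knots and cumulative hazard H at the start of each year of age.

        Returns ``(knots, H)`` with ``knots = [a0, a0+1, ..., a_last+1]`` and
        ``H[0] = 0``.  A rate of 1 maps to an infinite yearly hazard.
        """
        with np.errstate(divide="ignore"):
            lam = -np.log1p(-self.rates)
        knots = np.append(self.ages, self.ages[-1] + 1).astype(float)
        h = np.concatenate([[0.0], np.cumsum(lam)])
        return knots, h

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "rate": self.rates}).to_csv(
            path, index=False, lineterminator="\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeRateTable":
        df = pd.read_csv(path)
        if not {"age", "rate"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'age,rate'")
        return cls(df["age"].to_numpy(), df["rate"].to_numpy())


def _gompertz_rates(scale: float, slope: float, makeham: float) -> np.ndarray:
    """Annual death probabilities for ages 19..110 (zero below 50)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    hazard = np.where(ages >= 50, makeham + scale * np.exp(slope * (ages - 50.0)), 0.0)
    rates = 1.0 - np.exp(-hazard)
    rates[-1] = 1.0  # terminal closure: nobody survives past 110
    return rates


def _life_expectancy_at_50(rates: np.ndarray) -> float:
    """Mean further years lived from exact age 50 under the annual rates.

    Within each year the hazard is constant, so conditional on death in the
    year [a, a+1) the expected fraction of the year lived is
    1/lam - p/(lam*(1-exp(-lam)))... computed directly from the exponential
    within-year law; the half-year approximation is avoided.
    """
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    mask = ages >= 50
    p = rates[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -np.log1p(-p)
        # E[time lived in year | death in year]
        frac = np.where(p > 0, np.where(p < 1, 1.0 / lam - (1.0 - p) / p, 1.0 / lam), 0.5)
        frac = np.where(np.isfinite(frac), frac, 0.5)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - p)])[:-1]
    death_prob = surv * p
    years_before = np.arange(len(p), dtype=float)
    return float(np.sum(death_prob * (years_before + frac)))


def build_mortality_table(
    target_le50: float = 37.0, slope: float = 0.105, makeham: float = 0.0003
) -> AgeRateTable:
    """Synthetic all-cause mortality table calibrated to a life expectancy.

    A Gompertz-Makeham hazard ``c + a*exp(b*(age-50))`` is discretised to
    annual probabilities; the level ``a`` is solved so that the implied life
    expectancy at 50 matches ``target_le50`` to well within 0.2 years.
    Mortality before 50 is zero and the rate at 110 is 1.

    Parameters
    ----------
    target_le50:
        Target further life expectancy at age 50 in years, in [25, 45].
    slope:
        Gompertz slope b (per year of age), > 0.
    makeham:
        Age-independent background hazard c (per year).
    """
    if not 25.0 <= target_le50 <= 45.0:
        raise ValueError("target_le50 must lie in [25, 45]")
    if slope <= 0:
        raise ValueError("slope must be positive")

    def gap(log_scale: float) -> float:
        return _life_expectancy_at_50(_gompertz_rates(np.exp(log_scale), slope, makeham)) - target_le50

    lo, hi = np.log(1e-8), np.log(0.5)
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValueError(f"life expectancy target {target_le50} unattainable with slope {slope}")
    log_scale = brentq(gap, lo, hi, xtol=1e-10)
    return AgeRateTable(np.arange(AGE_MIN, AGE_MAX + 1), _gompertz_rates(np.exp(log_scale), slope, makeham))


def build_incidence_table(
    lifetime_risk: float = 0.125, peak_age: float = 60.0, width: float = 14.0
) -> AgeRateTable:
    """Synthetic carcinogenesis incidence table with a given lifetime risk.

    The annual hazard is a smooth unimodal (Gaussian-in-age) curve over ages
    19-89, zero afterwards, scaled so that the cumulative incidence from 19 to
    89 (ignoring competing mortality) equals ``lifetime_risk`` within 1e-3.
    """
    if not 0.0 <= lifetime_risk < 0.3:
        raise ValueError("lifetime_risk must lie in [0, 0.3)")
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    shape = np.where(ages <= 89, np.exp(-0.5 * ((ages - peak_age) / width) ** 2), 0.0)
    if lifetime_risk == 0.0:
        return AgeRateTable(ages, np.zeros_like(shape))

    def gap(s: float) -> float:
        return 1.0 - np.prod(1.0 - s * shape) - lifetime_risk

    s = brentq(gap, 0.0, 1.0 / shape.max() - 1e-12, xtol=1e-14)
    return AgeRateTable(ages, s * shape)


def sample_event_ages(
    table: AgeRateTable,
    from_age: float,
    rng: np.random.Generator,
    n: int,
    horizon: float | None = None,
) -> np.ndarray:
    """Vectorised first-event ages for ``n`` independent women.

    Draws from the piecewise-constant-hazard process implied by the table,
    restricted to ``(from_age, from_age + horizon]``.  Entries are ``nan``
    where no event occurs in the window.
    """
    knots, H = table.cumulative_hazard_grid()
    upper = knots[-1] if horizon is None else min(from_age + horizon, knots[-1])
    h0 = np.interp(from_age, knots, H)
    e = rng.exponential(size=n) + h0
    h_upper = np.interp(upper, knots, H)
    out = np.full(n, np.nan)
    hit = e < h_upper
    if np.any(hit):
        # invert the piecewise-linear cumulative hazard; within a rate-1 year
        # H jumps to inf so interp lands at the year start (event certain).
        finite = np.isfinite(H)
        out[hit] = np.interp(e[hit], H[finite], knots[finite])
    return out


def sample_event_age(
    table: AgeRateTable,
    from_age: float,
    rng: np.random.Generator,
    horizon: float | None = None,
) -> float | None:
    """First event age after ``from_age`` (within ``horizon``), or ``None``."""
    if not table.ages[0] <= from_age <= table.ages[-1] + 1:
        raise ValueError(f"from_age {from_age} outside table range")
    age = sample_event_ages(table, from_age, rng, 1, horizon)[0]
    return None if np.isnan(age) else float(age)
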
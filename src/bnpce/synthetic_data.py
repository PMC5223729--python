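"""Synthetic external inputs: a life table and individual-patient survival data.

Two external-shaped inputs feed the pipeline. First, a general-population
life table; the bundled generator produces a Gompertz–Makeham table with
UK-scale magnitudes, clearly tagged synthetic so that headline results
against published tables are only claimed when a user supplies a genuine
national life table. Second, individual-patient right-censored survival
records with a binary age covariate, matching the statistical structure
of the routine-data survival analysis the model's baseline hazards come
from (exponential or Weibull event times, proportional hazards for the
over-75 stratum, administrative censoring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hazard_schedules import LifeTable
from .survival_fitting import SurvivalRecords

__all__ = [
    "GompertzParams",
    "DEFAULT_MALE",
    "DEFAULT_FEMALE",
    "generate_life_table",
    "simulate_ipd_survival",
]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz–Makeham annual-hazard parameters: makeham + level*e^(slope*age)."""

    makeham: float  # age-independent baseline annual hazard
    level: float  # hazard level coefficient
    slope: float  # per-year log-hazard increase

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.level <= 0 or self.slope < 0:
            raise ValueError("require makeham >= 0, level > 0, slope >= 0")

    def annual_q(self, age: np.ndarray) -> np.ndarray:
        hazard = self.makeham + self.level * np.exp(self.slope * np.asarray(age, float))
        return 1.0 - np.exp(-hazard)


# Synthetic defaults with plausible UK-scale magnitudes: male q(65) ~ 0.010,
# q(85) ~ 0.10; female mortality ~30% lower at the same ages. NOT a national
# statistics life table.
DEFAULT_MALE = GompertzParams(makeham=5e-4, level=3.97e-6, slope=0.1198)
DEFAULT_FEMALE = GompertzParams(makeham=4e-4, level=2.78e-6, slope=0.1198)


def generate_life_table(
    params_male: GompertzParams = DEFAULT_MALE,
    params_female: GompertzParams = DEFAULT_FEMALE,
    max_age: int = 110,
) -> LifeTable:
    """Synthetic life table with q(age, sex) from Gompertz–Makeham hazards.

    q is capped at 1 and the terminal age is absorbing (q = 1). With a
    positive slope, q increases strictly with age.
    """
    ages = np.arange(0, max_age + 1)
    q_m = np.clip(params_male.annual_q(ages), 0.0, 1.0)
    q_f = np.clip(params_female.annual_q(ages), 0.0, 1.0)
    q_m[-1] = 1.0
    q_f[-1] = 1.0
    return LifeTable(ages, q_m, q_f, provenance="synthetic")


def simulate_ipd_survival(
    n: int,
    model: str = "exponential",
    rate: float = 0.009,
    scale: float | None = None,
    shape: float | None = None,
    hr_over75: float = 2.801,
    prop_over75: float = 0.5,
    censor_time: float = 108.0,
    seed: int = 0,
    exclusion_window: float = 0.0,
) -> SurvivalRecords:
    """Simulate right-censored survival records with a binary age covariate.

    Event times are drawn by inverse transform from the chosen hazard —
    ``exponential`` with monthly ``rate`` or ``weibull`` with cumulative
    hazard ``scale * t^shape`` — with the over-75 stratum's hazard
    multiplied by ``hr_over75``. Records are administratively censored at
    ``censor_time`` months. A positive ``exclusion_window`` (months)
    mirrors the exclusion of very early deaths from the source cohort:
    event times are drawn conditional on survival past the window and
    reported as time since the end of the window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_time < 0:
        raise ValueError("censor_time must be >= 0")
    rng = np.random.default_rng(seed)
    over75 = rng.random(n) < prop_over75
    log_mult = np.where(over75, np.log(hr_over75), 0.0)

    # inverse transform of S(t) = exp(-H(t) * e^(beta x)): with U uniform,
    # solve H(t) = -ln(U) / e^(beta x)
    u = rng.random(n)
    target = -np.log(u) / np.exp(log_mult)
    if exclusion_window > 0:
        # condition on T > w: add the cumulative hazard already survived
        if model == "exponential":
            target = target + rate * exclusion_window
        else:
            target = target + scale * exclusion_window**shape  # type: ignore[operator]

    if model == "exponential":
        if rate <= 0:
            raise ValueError("rate must be positive")
        times = target / rate
    elif model == "weibull":
        if scale is None or shape is None or scale <= 0 or shape <= 0:
            raise ValueError("weibull model needs positive scale and shape")
        times = (target / scale) ** (1.0 / shape)
    else:
        raise ValueError(f"unknown model {model!r}")

    if exclusion_window > 0:
        times = times - exclusion_window

    event = times <= censor_time
    times = np.minimum(times, censor_time)
    # guard against zero follow-up under censor_time == 0
    times = np.maximum(times, np.finfo(float).tiny)
    return SurvivalRecords(time=times, event=event, over75=over75)
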
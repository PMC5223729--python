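"""Per-cycle death and hospitalisation probabilities for each model arm.

The cohort model runs on 3-month cycles. Mortality for the first eight
years comes from a parametric (exponential or Weibull) hazard estimated in
routinely collected data; beyond eight years it comes from general-
population life tables inflated by the heart-failure excess-mortality
relative risk. Treatment effects of BNP-guided care and the HFpEF survival
adjustment multiply the per-cycle probabilities; age effects multiply the
underlying monthly hazards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .scenarios import ScenarioConfig

__all__ = [
    "SubgroupConfig",
    "SUBGROUPS",
    "HazardSchedule",
    "LifeTable",
    "cycle_prob_from_monthly_hazard",
    "weibull_cycle_prob",
    "rr_from_interval_survival",
    "life_table_cycle_prob",
    "mortality_schedule",
    "hospitalisation_schedule",
    "build_schedule",
]

CYCLE_MONTHS = 3
CYCLES_PER_YEAR = 4
#: number of cycles covered by the parametric (registry-data) hazard phase
PARAMETRIC_PHASE_CYCLES = 32  # 8 years
#: fraction of the modelled cohort assumed male for life-table weighting
MALE_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class SubgroupConfig:
    """A modelled patient subgroup (ejection-fraction class x age band)."""

    label: str
    start_age: int  # mean age at inception of treatment, years
    horizon: int  # model horizon in 3-month cycles
    lvef_class: str  # "reduced" | "preserved"
    age_class: str  # "under75" | "over75"

    def __post_init__(self) -> None:
        if self.lvef_class not in ("reduced", "preserved"):
            raise ValueError(f"bad lvef_class {self.lvef_class!r}")
        if self.age_class not in ("under75", "over75"):
            raise ValueError(f"bad age_class {self.age_class!r}")

    @property
    def bnp_mortality_hr_name(self) -> str:
        if self.lvef_class == "preserved":
            return "bnp_mortality_hr_hfpef_u75"
        return (
            "bnp_mortality_hr_hfref_u75"
            if self.age_class == "under75"
            else "bnp_mortality_hr_hfref_o75"
        )


#: the three modelled subgroups: 30-year horizon from age 65 for the
#: under-75 groups, 15-year horizon from age 81 for the over-75 group
SUBGROUPS: dict[str, SubgroupConfig] = {
    "hfref_u75": SubgroupConfig("HFrEF <75 years", 65, 120, "reduced", "under75"),
    "hfpef_u75": SubgroupConfig("HFpEF <75 years", 65, 120, "preserved", "under75"),
    "hfref_o75": SubgroupConfig("HFrEF >=75 years", 81, 60, "reduced", "over75"),
}


@dataclass(frozen=True)
class HazardSchedule:
    """Per-cycle probabilities of death ``d`` and hospitalisation ``h``."""

    d: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if self.d.shape != self.h.shape:
            raise ValueError("death and hospitalisation vectors differ in length")
        for v in (self.d, self.h):
            if np.any(v < 0.0) or np.any(v > 1.0):
                raise ValueError("per-cycle probabilities must lie in [0, 1]")

    @property
    def horizon(self) -> int:
        return len(self.d)


class LifeTable:
    """Annual mortality probabilities q(age, sex) for ages 0..max_age.

    The terminal age is an absorbing q = 1. ``provenance`` records whether
    the table is synthetic (generated by :mod:`bnpce.synthetic_data`) or
    user-supplied (e.g. a national statistics life table).
    """

    def __init__(
        self,
        ages: np.ndarray,
        q_male: np.ndarray,
        q_female: np.ndarray,
        provenance: str = "user-supplied",
    ):
        ages = np.asarray(ages, dtype=int)
        q_male = np.asarray(q_male, dtype=float)
        q_female = np.asarray(q_female, dtype=float)
        if not (len(ages) == len(q_male) == len(q_female)):
            raise ValueError("age and q columns differ in length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        for q in (q_male, q_female):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("q must lie in [0, 1]")
        self.ages = ages
        self.q_male = q_male
        self.q_female = q_female
        self.provenance = provenance

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age: float, sex: str) -> float:
        """q for the integer year of age; 1.0 beyond the table."""
        a = int(age)
        if a > self.max_age:
            return 1.0
        if a < self.ages[0]:
            raise ValueError(f"age {age} below table range")
        i = a - int(self.ages[0])
        return float(self.q_male[i] if sex == "male" else self.q_female[i])

    def monotone_above(self, age: int = 60) -> bool:
        """True if q is non-decreasing with age above ``age`` for both sexes."""
        mask = self.ages >= age
        return bool(
            np.all(np.diff(self.q_male[mask]) >= 0)
            and np.all(np.diff(self.q_female[mask]) >= 0)
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "user-supplied") -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "q_male", "q_female"} - set(df.columns)
        if missing:
            raise ValueError(f"life-table file missing columns: {sorted(missing)}")
        return cls(
            df["age"].to_numpy(),
            df["q_male"].to_numpy(),
            df["q_female"].to_numpy(),
            provenance=provenance,
        )


def cycle_prob_from_monthly_hazard(h: float, months: float = CYCLE_MONTHS) -> float:
    """Constant monthly hazard -> per-cycle event probability 1 - exp(-h*m)."""
    if h < 0:
        raise ValueError(f"hazard must be non-negative, got {h}")
    return 1.0 - math.exp(-h * months)


def weibull_cycle_prob(scale: float, shape: float, cycle_index: int) -> float:
    """Conditional death probability in cycle ``k`` under a Weibull hazard.

    With survival ``S(t) = exp(-scale * t^shape)`` (t in months), the
    probability of dying during cycle k given alive at its start is
    ``1 - S(3(k+1)) / S(3k)``. Shape 1 reduces to the exponential case.
    """
    if scale <= 0 or shape <= 0:
        raise ValueError("scale and shape must be positive")
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t0 = CYCLE_MONTHS * cycle_index
    t1 = CYCLE_MONTHS * (cycle_index + 1)
    return 1.0 - math.exp(-scale * (t1**shape - t0**shape))


def rr_from_interval_survival(
    events_a: float,
    total_a: float,
    events_b: float,
    total_b: float,
    horizon_cycles: int,
) -> float:
    """Relative risk on the per-cycle probability scale.

    Each group's cumulative mortality ``events/total`` over a horizon of
    ``horizon_cycles`` cycles is converted to a per-cycle probability via
    ``1 - (1 - p)^(1/horizon_cycles)``; the function returns the a:b ratio
    of the two per-cycle probabilities.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    for ev, tot in ((events_a, total_a), (events_b, total_b)):
        if not 0 < ev < tot:
            raise ValueError(f"require 0 < events < total, got ({ev}, {tot})")
    pa = _per_cycle(events_a / total_a, horizon_cycles)
    pb = _per_cycle(events_b / total_b, horizon_cycles)
    if pb == 0.0:
        raise ZeroDivisionError("comparator per-cycle probability is zero")
    return pa / pb


def rr_from_cumulative_probs(p_a: float, p_b: float, horizon_cycles: int) -> float:
    """As :func:`rr_from_interval_survival` but from cumulative probabilities.

    Used in the PSA, where the cumulative mortality of each group is
    sampled from its beta distribution rather than fixed at events/total.
    """
    pa = _per_cycle(p_a, horizon_cycles)
    pb = _per_cycle(p_b, horizon_cycles)
    if pb == 0.0:
        raise ZeroDivisionError("comparator per-cycle probability is zero")
    return pa / pb


def _per_cycle(p: float, cycles: int) -> float:
    return 1.0 - (1.0 - p) ** (1.0 / cycles)


def life_table_cycle_prob(
    lt: LifeTable,
    age: float,
    male_fraction: float = MALE_FRACTION,
    rr: float = 1.0,
) -> float:
    """Excess-mortality-inflated 3-month death probability at a given age.

    The annual q is sex-weighted, converted to a 3-month probability via
    ``1 - (1-q)^(1/4)``, multiplied by the relative risk and capped at 1.
    """
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must lie in [0, 1]")
    if rr <= 0:
        raise ValueError("rr must be positive")
    q = male_fraction * lt.annual_q(age, "male") + (1.0 - male_fraction) * lt.annual_q(
        age, "female"
    )
    p_cycle = 1.0 - (1.0 - q) ** (1.0 / CYCLES_PER_YEAR)
    return min(p_cycle * rr, 1.0)


def _hf_vs_population_rr(params: ParameterSet) -> float:
    # 7-year cumulative mortality, HF cohort vs matched controls, 28 cycles
    return rr_from_cumulative_probs(
        params["mort7y_hf_deaths"], params["mort7y_gen_deaths"], 28
    )


def _hfpef_vs_hfref_rr(params: ParameterSet) -> float:
    # 1-year mortality, preserved vs reduced ejection fraction, 4 cycles
    return rr_from_cumulative_probs(
        params["mort1y_hfpef"], params["mort1y_hfref"], 4
    )


def mortality_schedule(
    sub: SubgroupConfig,
    strategy: str,
    scenario: ScenarioConfig,
    params: ParameterSet,
    life_table: LifeTable | None,
) -> np.ndarray:
    """Per-cycle death probabilities ``d_t`` for one arm of the model.

    Cycles 0-31 use the parametric hazard fitted in routine data (the
    over-75 group's monthly hazard is multiplied by the age hazard ratio);
    later cycles use the life table at the attained age inflated by the
    HF-vs-population relative risk. The HFpEF survival adjustment and the
    BNP treatment effect (within the scenario's effect window) multiply
    the per-cycle probabilities.
    """
    if strategy not in ("bnp", "clinical"):
        raise ValueError(f"unknown strategy {strategy!r}")
    horizon = sub.horizon
    n_param = min(PARAMETRIC_PHASE_CYCLES, horizon)
    if horizon > PARAMETRIC_PHASE_CYCLES and life_table is None:
        raise ValueError("life table required for horizons beyond 8 years")

    d = np.empty(horizon)

    use_weibull = scenario.survival_form == "weibull" and sub.age_class == "under75"
    if use_weibull:
        scale = params["weibull_scale_u75"]
        shape = params["weibull_shape_u75"]
        for k in range(n_param):
            d[k] = weibull_cycle_prob(scale, shape, k)
    else:
        hazard = params["mortality_hazard_u75"]
        if sub.age_class == "over75":
            hazard *= params["mortality_age_hr"]
        d[:n_param] = cycle_prob_from_monthly_hazard(hazard)

    if horizon > n_param:
        rr_hf = _hf_vs_population_rr(params)
        for k in range(n_param, horizon):
            attained_age = sub.start_age + 8 + (k - PARAMETRIC_PHASE_CYCLES) // 4
            d[k] = life_table_cycle_prob(life_table, attained_age, rr=rr_hf)

    if sub.lvef_class == "preserved":
        d *= _hfpef_vs_hfref_rr(params)

    if strategy == "bnp":
        hr = params[sub.bnp_mortality_hr_name]
        window = scenario.effect_window_cycles
        end = horizon if window is None else min(window, horizon)
        d[:end] *= hr

    return np.clip(d, 0.0, 1.0)


def hospitalisation_schedule(
    sub: SubgroupConfig,
    strategy: str,
    scenario: ScenarioConfig,
    params: ParameterSet,
) -> np.ndarray:
    """Per-cycle all-cause hospitalisation probabilities ``h_t``.

    The monthly hospitalisation hazard applies throughout the model
    lifetime (the same for reduced and preserved ejection fraction); the
    over-75 group's hazard is multiplied by the age hazard ratio, and the
    BNP arm's probability by the treatment hazard ratio during the same
    effect window as mortality.
    """
    if strategy not in ("bnp", "clinical"):
        raise ValueError(f"unknown strategy {strategy!r}")
    hazard = params["hosp_hazard_u75"]
    if sub.age_class == "over75":
        hazard *= params["hosp_age_hr"]
    h = np.full(sub.horizon, cycle_prob_from_monthly_hazard(hazard))
    if strategy == "bnp":
        window = scenario.effect_window_cycles
        end = sub.horizon if window is None else min(window, sub.horizon)
        h[:end] *= params["bnp_hosp_hr"]
    return np.clip(h, 0.0, 1.0)


def build_schedule(
    sub: SubgroupConfig,
    strategy: str,
    scenario: ScenarioConfig,
    params: ParameterSet,
    life_table: LifeTable | None,
) -> HazardSchedule:
    """Convenience: full :class:`HazardSchedule` for one model arm."""
    return HazardSchedule(
        d=mortality_schedule(sub, strategy, scenario, params, life_table),
        h=hospitalisation_schedule(sub, strategy, scenario, params),
    )
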
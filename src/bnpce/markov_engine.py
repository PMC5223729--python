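"""Two-state (Alive/Dead) Markov cohort engine with cost and QALY accrual.

The cohort starts fully alive; each 3-month cycle applies the per-cycle
death probability and splits the survivors' cycle experience into
hospitalised and not-hospitalised fractions. Transitions are assumed to
occur halfway through each cycle, so decedents accrue half a cycle of
not-hospitalised utility and cost, and discounting uses the mid-cycle
exponent. Costs and QALYs are discounted at 3.5% per year by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazard_schedules import CYCLES_PER_YEAR, HazardSchedule, SubgroupConfig
from .parameters import ParameterSet
from .scenarios import ScenarioConfig

__all__ = [
    "CYCLE_DAYS",
    "DAYS_PER_YEAR",
    "StrategyCosting",
    "Utilities",
    "CohortTrace",
    "cycle_qalys",
    "cycle_costs",
    "run_cohort",
    "median_survival",
    "lifetime_totals",
]

CYCLE_DAYS = 91.31
DAYS_PER_YEAR = 365.25
DISCOUNT_RATE = 0.035

# natural durations of the BNP-specific cost streams, in cycles
BNP_TEST_CYCLES = 6  # 3-monthly testing for 18 months
BNP_MED_CYCLES = 6  # medication uptitration for 18 months
BNP_VISIT_CYCLES = 8  # incremental unscheduled visits over 24 months


@dataclass(frozen=True)
class StrategyCosting:
    """Per-cycle cost inputs for one strategy arm.

    State costs are per person per 3-month cycle by hospitalisation
    status. The BNP-specific streams (test cost per testing cycle, total
    medication increment spread over its duration, incremental
    unscheduled-visit costs) are zero in the clinically guided arm.
    """

    cost_h: float  # hospitalised-cycle state cost, GBP
    cost_nh: float  # non-hospitalised-cycle state cost, GBP
    bnp_test_cost: float = 0.0  # per test (one per testing cycle)
    bnp_med_total: float = 0.0  # total medication increment, GBP
    incremental_visits: float = 0.0  # extra visits over the visit window
    visit_unit_cost: float = 0.0
    test_cycles: int = BNP_TEST_CYCLES
    med_cycles: int = BNP_MED_CYCLES
    visit_cycles: int = BNP_VISIT_CYCLES

    def __post_init__(self) -> None:
        for name in ("cost_h", "cost_nh", "bnp_test_cost", "bnp_med_total",
                     "incremental_visits", "visit_unit_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_params(
        cls,
        params: ParameterSet,
        sub: SubgroupConfig,
        strategy: str,
        scenario: ScenarioConfig | None = None,
    ) -> "StrategyCosting":
        suffix = "u75" if sub.age_class == "under75" else "o75"
        base = dict(
            cost_h=params[f"cost_hosp_{suffix}"],
            cost_nh=params[f"cost_nonhosp_{suffix}"],
        )
        if strategy == "clinical":
            return cls(**base)
        # incremental visit count floored at zero: the two arms' visit
        # counts are sampled independently in the PSA and may cross
        visits = max(params["visits_bnp"] - params["visits_clinical"], 0.0)
        clip = None if scenario is None else scenario.cost_clip_cycles
        test_cycles, med_cycles, visit_cycles = (
            BNP_TEST_CYCLES, BNP_MED_CYCLES, BNP_VISIT_CYCLES)
        if clip is not None:
            test_cycles = min(test_cycles, clip)
            med_cycles = min(med_cycles, clip)
            visit_cycles = min(visit_cycles, clip)
        return cls(
            **base,
            bnp_test_cost=params["bnp_test_cost"],
            bnp_med_total=params["bnp_med_cost"],
            incremental_visits=visits,
            visit_unit_cost=params["visit_unit_cost"],
            test_cycles=test_cycles,
            med_cycles=med_cycles,
            visit_cycles=visit_cycles,
        )


@dataclass(frozen=True)
class Utilities:
    """Health-state utility weights and hospital length of stay."""

    u_h: float  # utility while hospitalised
    u_nh: float  # utility while not hospitalised
    los_days: float  # length of stay within a hospitalised cycle

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_h <= 1.0 or not 0.0 <= self.u_nh <= 1.0:
            raise ValueError("utilities must lie in [0, 1]")
        if not 0.0 <= self.los_days <= CYCLE_DAYS:
            raise ValueError(f"length of stay must lie in [0, {CYCLE_DAYS}] days")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "Utilities":
        return cls(
            u_h=min(params["utility_hosp"], 1.0),
            u_nh=min(params["utility_nonhosp"], 1.0),
            los_days=min(params["los_days"], CYCLE_DAYS),
        )


@dataclass
class CohortTrace:
    """Cycle-by-cycle state occupancy and accruals of one cohort run."""

    alive_start: np.ndarray
    deaths: np.ndarray
    alive_end: np.ndarray
    p_h: np.ndarray  # proportion of survivors hospitalised in the cycle
    cost: np.ndarray  # undiscounted cycle costs
    qalys: np.ndarray  # undiscounted cycle QALYs
    cost_disc: np.ndarray
    qalys_disc: np.ndarray
    total_cost: float = field(init=False)
    total_qalys: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_cost = float(self.cost_disc.sum())
        self.total_qalys = float(self.qalys_disc.sum())

    @property
    def horizon(self) -> int:
        return len(self.alive_start)

    def survival_curve(self) -> np.ndarray:
        """Proportion alive at each cycle boundary (length horizon + 1)."""
        return np.concatenate(([1.0], self.alive_end))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.horizon),
                "alive_start": self.alive_start,
                "deaths": self.deaths,
                "alive_end": self.alive_end,
                "p_h": self.p_h,
                "cost": self.cost,
                "qalys": self.qalys,
                "cost_disc": self.cost_disc,
                "qalys_disc": self.qalys_disc,
            }
        )


def cycle_qalys(
    alive: float, p_h: float, u_h: float, u_nh: float, los: float
) -> float:
    """QALYs accrued over one 3-month cycle by an alive fraction.

    A hospitalised cycle mixes ``los`` days at the hospitalised utility
    with the remainder of the 91.31-day cycle at the not-hospitalised
    utility; a non-hospitalised cycle is entirely at the latter.
    """
    if not 0.0 <= los <= CYCLE_DAYS:
        raise ValueError(f"length of stay {los} outside [0, {CYCLE_DAYS}] days")
    q_h = (los * u_h + (CYCLE_DAYS - los) * u_nh) / DAYS_PER_YEAR
    q_nh = u_nh * CYCLE_DAYS / DAYS_PER_YEAR
    return alive * (p_h * q_h + (1.0 - p_h) * q_nh)


def cycle_costs(
    alive: float,
    p_h: float,
    costing: StrategyCosting,
    cycle_index: int,
    strategy: str,
) -> float:
    """Costs accrued over one cycle by an alive fraction.

    State costs depend on hospitalisation status; the BNP arm adds, per
    alive person, the test cost and the per-cycle share of the medication
    increment during the testing window, and the per-cycle share of the
    incremental outpatient-visit costs during the visit window.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    total = alive * (p_h * costing.cost_h + (1.0 - p_h) * costing.cost_nh)
    if strategy == "bnp":
        addon = 0.0
        if cycle_index < costing.test_cycles:
            addon += costing.bnp_test_cost
        if cycle_index < costing.med_cycles and costing.med_cycles > 0:
            addon += costing.bnp_med_total / BNP_MED_CYCLES
        if cycle_index < costing.visit_cycles and costing.visit_cycles > 0:
            addon += (
                costing.incremental_visits * costing.visit_unit_cost / BNP_VISIT_CYCLES
            )
        total += alive * addon
    return total


def run_cohort(
    schedule: HazardSchedule,
    costing: StrategyCosting,
    utilities: Utilities,
    sub: SubgroupConfig,
    strategy: str = "clinical",
    discount_rate: float = DISCOUNT_RATE,
    half_cycle: bool = True,
) -> CohortTrace:
    """Run the cohort through the horizon and accrue costs and QALYs.

    With the half-cycle convention, members dying during a cycle
    contribute half a cycle of the not-hospitalised accrual; survivors a
    full cycle split by hospitalisation status. Each cycle's accrual is
    discounted at the mid-cycle exponent ``(t + 0.5) / 4`` years.
    """
    if schedule.horizon != sub.horizon:
        raise ValueError(
            f"schedule length {schedule.horizon} != subgroup horizon {sub.horizon}"
        )
    n = sub.horizon
    alive_start = np.empty(n)
    deaths = np.empty(n)
    alive_end = np.empty(n)
    cost = np.empty(n)
    qalys = np.empty(n)

    q_nh_person = utilities.u_nh * CYCLE_DAYS / DAYS_PER_YEAR
    dead_weight = 0.5 if half_cycle else 0.0

    alive = 1.0
    for t in range(n):
        alive_start[t] = alive
        d = schedule.d[t]
        h = schedule.h[t]
        dying = alive * d
        surviving = alive * (1.0 - d)
        deaths[t] = dying
        alive_end[t] = surviving

        qalys[t] = cycle_qalys(
            surviving, h, utilities.u_h, utilities.u_nh, utilities.los_days
        ) + dead_weight * dying * q_nh_person
        cost[t] = cycle_costs(surviving, h, costing, t, strategy) + (
            dead_weight * dying * costing.cost_nh
        )
        alive = surviving

    t_idx = np.arange(n)
    df = (1.0 + discount_rate) ** (-(t_idx + 0.5) / CYCLES_PER_YEAR)
    return CohortTrace(
        alive_start=alive_start,
        deaths=deaths,
        alive_end=alive_end,
        p_h=schedule.h.copy(),
        cost=cost,
        qalys=qalys,
        cost_disc=cost * df,
        qalys_disc=qalys * df,
    )


def median_survival(trace: CohortTrace, rule: str = "interpolated") -> float:
    """Median survival time in years from the trace's alive curve.

    ``rule='interpolated'`` linearly interpolates the survival curve
    across the cycle in which it crosses 0.5; ``rule='cycle_boundary'``
    reports the end of the first cycle with survival below 0.5. Returns
    NaN (horizon-censored) if survival never falls below 0.5.
    """
    if rule not in ("interpolated", "cycle_boundary"):
        raise ValueError(f"unknown rule {rule!r}")
    s = trace.survival_curve()
    below = np.nonzero(s < 0.5)[0]
    if len(below) == 0:
        return math.nan
    k = int(below[0])  # s[k-1] >= 0.5 > s[k]; k >= 1 since s[0] = 1
    if rule == "cycle_boundary":
        return k / CYCLES_PER_YEAR
    frac = (s[k - 1] - 0.5) / (s[k - 1] - s[k])
    return (k - 1 + frac) / CYCLES_PER_YEAR


def lifetime_totals(trace: CohortTrace) -> tuple[float, float]:
    """(discounted lifetime cost, discounted lifetime QALYs)."""
    return trace.total_cost, trace.total_qalys
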
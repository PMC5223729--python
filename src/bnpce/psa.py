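"""Monte-Carlo probabilistic sensitivity analysis over the cohort model.

Each iteration draws one value of every non-fixed registry parameter from
its sampling distribution, rebuilds both strategies' hazard schedules and
cohort traces, and records discounted costs, QALYs and the incremental
net monetary benefit at the decision threshold. Uncertainty summaries are
the empirical mean and percentile interval of the iNMB draws plus the
cost-effectiveness acceptability curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .economics import LAMBDA_DEFAULT, ceac
from .hazard_schedules import LifeTable, SubgroupConfig, build_schedule
from .markov_engine import StrategyCosting, Utilities, lifetime_totals, run_cohort
from .parameters import ParameterRegistry, sample_parameter_set
from .scenarios import ScenarioConfig

__all__ = ["PSAResult", "run_psa", "summarize", "evaluate_parameter_set"]

N_ITER_DEFAULT = 10_000


def evaluate_parameter_set(
    params,
    sub: SubgroupConfig,
    scenario: ScenarioConfig,
    life_table: LifeTable | None,
) -> tuple[float, float, float, float]:
    """Both strategies' (cost, QALYs) under one concrete parameter set."""
    utilities = Utilities.from_params(params)
    out = []
    for strategy in ("clinical", "bnp"):
        schedule = build_schedule(sub, strategy, scenario, params, life_table)
        costing = StrategyCosting.from_params(params, sub, strategy, scenario)
        trace = run_cohort(schedule, costing, utilities, sub, strategy=strategy)
        out.extend(lifetime_totals(trace))
    return tuple(out)  # type: ignore[return-value]


@dataclass
class PSAResult:
    """Draw-level PSA output plus identifying metadata."""

    draws: pd.DataFrame  # one row per iteration
    subgroup: str
    scenario: str
    seed: int
    lam: float = LAMBDA_DEFAULT

    @property
    def n_iter(self) -> int:
        return len(self.draws)

    @property
    def inmb_draws(self) -> np.ndarray:
        return self.draws["inmb"].to_numpy()

    @property
    def delta_costs(self) -> np.ndarray:
        return (self.draws["cost_bnp"] - self.draws["cost_clinical"]).to_numpy()

    @property
    def delta_qalys(self) -> np.ndarray:
        return (self.draws["qalys_bnp"] - self.draws["qalys_clinical"]).to_numpy()

    def ceac(self, lambdas: np.ndarray | None = None) -> pd.DataFrame:
        if lambdas is None:
            lambdas = economics.default_lambda_grid()
        prob = ceac(self.delta_costs, self.delta_qalys, lambdas)
        return pd.DataFrame({"lambda": np.asarray(lambdas, dtype=float), "probability": prob})

    def prob_cost_effective(self, lam: float | None = None) -> float:
        """Fraction of draws with positive iNMB at the given threshold."""
        if lam is None:
            lam = self.lam
        return float(ceac(self.delta_costs, self.delta_qalys, [lam])[0])


def run_psa(
    sub: SubgroupConfig,
    scenario: ScenarioConfig,
    registry: ParameterRegistry,
    life_table: LifeTable | None,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    lam: float = LAMBDA_DEFAULT,
    subgroup_key: str = "",
) -> PSAResult:
    """Run the PSA for one subgroup/scenario.

    Reproducible under ``seed``: iteration ``i`` uses its own RNG stream
    derived from ``(seed, i)``, so results do not depend on execution
    order. Scenario overrides are applied to the registry before sampling.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    reg = registry.with_overrides(scenario.overrides) if scenario.overrides else registry
    rows = []
    for i in range(n_iter):
        params = sample_parameter_set(reg, seed, i)
        try:
            c0, e0, c1, e1 = evaluate_parameter_set(params, sub, scenario, life_table)
        except Exception as exc:  # attach the iteration for diagnosis
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        rows.append(
            {
                "iteration": i,
                "cost_clinical": c0,
                "qalys_clinical": e0,
                "cost_bnp": c1,
                "qalys_bnp": e1,
                "inmb": economics.inmb(c0, e0, c1, e1, lam),
            }
        )
    return PSAResult(
        draws=pd.DataFrame(rows),
        subgroup=subgroup_key or sub.label,
        scenario=scenario.name,
        seed=seed,
        lam=lam,
    )


def summarize(result: PSAResult, level: float = 0.95) -> tuple[float, float, float]:
    """Mean iNMB and its percentile interval across PSA draws.

    The interval is the empirical (1-level)/2 and 1-(1-level)/2
    percentiles of the draw distribution (2.5th/97.5th at the default).
    """
    if result.n_iter < 2:
        raise ValueError("summary requires at least 2 iterations")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    draws = result.inmb_draws
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return float(draws.mean()), float(lo), float(hi)
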
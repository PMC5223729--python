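"""High-level analysis drivers and tabular rendering of results.

Thin orchestration over the library: deterministic (point-estimate) runs
for one subgroup/scenario, the full analysis (all three subgroups plus
the five sensitivity analyses for the youngest HFrEF subgroup), and
rendering of headline tables shaped like the published cost-effectiveness
and sensitivity-analysis tables. Numeric outputs round only at render
time; the underlying frames carry full precision.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .economics import LAMBDA_DEFAULT, CEResult
from .hazard_schedules import SUBGROUPS, LifeTable, SubgroupConfig, build_schedule
from .markov_engine import (
    StrategyCosting,
    Utilities,
    median_survival,
    run_cohort,
)
from .parameters import ParameterRegistry, load_default_registry, point_estimate_set
from .psa import PSAResult, run_psa, summarize
from .scenarios import ScenarioConfig, build_scenario

__all__ = [
    "RunManifest",
    "DeterministicRun",
    "run_deterministic",
    "run_full_analysis",
    "render_subgroup_table",
    "render_sensitivity_table",
]


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one analysis run, written next to its outputs."""

    subgroup: str
    scenario: str
    seed: int | None
    n_iter: int | None
    life_table_provenance: str
    timestamp: str

    @classmethod
    def create(
        cls,
        subgroup: str,
        scenario: str,
        life_table: LifeTable | None,
        seed: int | None = None,
        n_iter: int | None = None,
    ) -> "RunManifest":
        return cls(
            subgroup=subgroup,
            scenario=scenario,
            seed=seed,
            n_iter=n_iter,
            life_table_provenance="none" if life_table is None else life_table.provenance,
            timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class DeterministicRun:
    """Point-estimate run of both strategies for one subgroup/scenario."""

    result: CEResult
    traces: dict  # strategy -> CohortTrace
    medians: dict  # strategy -> median survival, years
    manifest: RunManifest

    def write(self, outdir: str | Path, stem: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for strategy, trace in self.traces.items():
            trace.to_frame().to_csv(outdir / f"{stem}_{strategy}_trace.csv", index=False)
        summary = self.result.to_dict()
        summary["median_survival_years"] = self.medians
        (outdir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        self.manifest.write(outdir / f"{stem}_manifest.json")


def _resolve(subgroup: str | SubgroupConfig, scenario: str | ScenarioConfig):
    sub = SUBGROUPS[subgroup] if isinstance(subgroup, str) else subgroup
    scn = build_scenario(scenario) if isinstance(scenario, str) else scenario
    return sub, scn


def run_deterministic(
    subgroup: str | SubgroupConfig,
    scenario: str | ScenarioConfig = "primary",
    registry: ParameterRegistry | None = None,
    life_table: LifeTable | None = None,
    lam: float = LAMBDA_DEFAULT,
) -> DeterministicRun:
    """Point-estimate cohort runs for both strategies.

    Uses the bundled registry and, when no life table is given, the
    synthetic one (deterministic medians and the first eight model years
    are unaffected by the life-table choice).
    """
    sub, scn = _resolve(subgroup, scenario)
    if registry is None:
        registry = load_default_registry()
    if life_table is None:
        from .synthetic_data import generate_life_table

        life_table = generate_life_table()
    reg = registry.with_overrides(scn.overrides) if scn.overrides else registry
    params = point_estimate_set(reg)
    utilities = Utilities.from_params(params)

    traces, medians, totals = {}, {}, {}
    for strategy in ("clinical", "bnp"):
        schedule = build_schedule(sub, strategy, scn, params, life_table)
        costing = StrategyCosting.from_params(params, sub, strategy, scn)
        trace = run_cohort(schedule, costing, utilities, sub, strategy=strategy)
        traces[strategy] = trace
        medians[strategy] = median_survival(trace)
        totals[strategy] = (trace.total_cost, trace.total_qalys)

    result = CEResult(
        cost_clinical=totals["clinical"][0],
        qalys_clinical=totals["clinical"][1],
        cost_bnp=totals["bnp"][0],
        qalys_bnp=totals["bnp"][1],
        lam=lam,
    )
    manifest = RunManifest.create(sub.label, scn.name, life_table)
    return DeterministicRun(result=result, traces=traces, medians=medians, manifest=manifest)


def run_full_analysis(
    registry: ParameterRegistry | None = None,
    life_table: LifeTable | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    lam: float = LAMBDA_DEFAULT,
    sa_subgroup: str = "hfref_u75",
) -> dict:
    """All three subgroups (primary scenario) plus the five SAs.

    Returns a dict with deterministic runs, PSA results and the two
    rendered summary frames. PSA intervals accompany the deterministic
    cost/QALY columns, mirroring the published table layout.
    """
    if registry is None:
        registry = load_default_registry()
    if life_table is None:
        from .synthetic_data import generate_life_table

        life_table = generate_life_table()

    det: dict[tuple[str, str], DeterministicRun] = {}
    psa: dict[tuple[str, str], PSAResult] = {}
    for key in SUBGROUPS:
        det[(key, "primary")] = run_deterministic(key, "primary", registry, life_table, lam)
        psa[(key, "primary")] = run_psa(
            SUBGROUPS[key], build_scenario("primary"), registry, life_table,
            n_iter=n_iter, seed=seed, lam=lam, subgroup_key=key,
        )
    for name in ("SA1", "SA2", "SA3", "SA4", "SA5"):
        det[(sa_subgroup, name)] = run_deterministic(sa_subgroup, name, registry, life_table, lam)
        psa[(sa_subgroup, name)] = run_psa(
            SUBGROUPS[sa_subgroup], build_scenario(name), registry, life_table,
            n_iter=n_iter, seed=seed, lam=lam, subgroup_key=sa_subgroup,
        )

    subgroup_table = render_subgroup_table(det, psa)
    sa_table = render_sensitivity_table(det, psa, sa_subgroup)
    return {
        "deterministic": det,
        "psa": psa,
        "subgroup_table": subgroup_table,
        "sensitivity_table": sa_table,
    }


def _row(label: str, run: DeterministicRun, psa_result: PSAResult | None) -> dict:
    r = run.result
    row = {
        "label": label,
        "cost_clinical": r.cost_clinical,
        "qalys_clinical": r.qalys_clinical,
        "cost_bnp": r.cost_bnp,
        "qalys_bnp": r.qalys_bnp,
        "icer": r.icer,
    }
    if psa_result is not None:
        mean, lo, hi = summarize(psa_result)
        row.update(inmb_mean=mean, inmb_lo=lo, inmb_hi=hi,
                   prob_ce=psa_result.prob_cost_effective())
    else:
        row.update(inmb_mean=r.inmb, inmb_lo=float("nan"), inmb_hi=float("nan"),
                   prob_ce=float("nan"))
    return row


def render_subgroup_table(det: dict, psa: dict) -> pd.DataFrame:
    """One row per subgroup: costs/QALYs per arm, iNMB (95% CI), ICER."""
    rows = [
        _row(SUBGROUPS[key].label, det[(key, "primary")], psa.get((key, "primary")))
        for key in SUBGROUPS
        if (key, "primary") in det
    ]
    return pd.DataFrame(rows)


def render_sensitivity_table(det: dict, psa: dict, sa_subgroup: str = "hfref_u75") -> pd.DataFrame:
    """One row per sensitivity analysis SA1-SA5 for the SA subgroup."""
    rows = [
        _row(name, det[(sa_subgroup, name)], psa.get((sa_subgroup, name)))
        for name in ("SA1", "SA2", "SA3", "SA4", "SA5")
        if (sa_subgroup, name) in det
    ]
    return pd.DataFrame(rows)
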
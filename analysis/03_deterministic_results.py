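#!/usr/bin/env python
"""Deterministic (point-estimate) cost-effectiveness results.

Runs the cohort model at the registry point estimates for the three
patient subgroups and the five sensitivity analyses of the youngest
HFrEF subgroup, using the synthetic life table for mortality beyond the
first eight model years. Writes one table per family to results/ and
prints the headline numbers: lifetime discounted costs and QALYs per
arm, the ICER, the deterministic iNMB at £20,000/QALY, and median
survival per arm.
"""

from pathlib import Path

import pandas as pd

from bnpce.reporting import run_deterministic
from bnpce.hazard_schedules import SUBGROUPS

ROOT = Path(__file__).resolve().parents[1]


def row(label: str, run) -> dict:
    r = run.result
    return {
        "label": label,
        "cost_clinical": round(r.cost_clinical, 2),
        "qalys_clinical": round(r.qalys_clinical, 4),
        "cost_bnp": round(r.cost_bnp, 2),
        "qalys_bnp": round(r.qalys_bnp, 4),
        "icer": round(r.icer, 2),
        "inmb_at_20k": round(r.inmb, 2),
        "median_clinical_y": round(run.medians["clinical"], 3),
        "median_bnp_y": round(run.medians["bnp"], 3),
    }


def main() -> None:
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    sub_rows = [
        row(SUBGROUPS[key].label, run_deterministic(key, "primary"))
        for key in SUBGROUPS
    ]
    sub_table = pd.DataFrame(sub_rows)
    sub_table.to_csv(outdir / "deterministic_subgroups.csv", index=False)

    sa_rows = [
        row(name, run_deterministic("hfref_u75", name))
        for name in ("SA1", "SA2", "SA3", "SA4", "SA5")
    ]
    sa_table = pd.DataFrame(sa_rows)
    sa_table.to_csv(outdir / "deterministic_sensitivity.csv", index=False)

    print("Subgroups (primary scenario):")
    print(sub_table.to_string(index=False))
    print("\nSensitivity analyses (HFrEF <75):")
    print(sa_table.to_string(index=False))
    print(
        "\nMedians for the youngest HFrEF subgroup depend only on the "
        "registry hazards (the survival curve crosses 0.5 inside the "
        "8-year parametric phase); costs and QALYs beyond year 8 depend "
        "on the life table supplied, here the synthetic one."
    )


if __name__ == "__main__":
    main()
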
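#!/usr/bin/env python
"""Fit the parametric survival models to the simulated cohort.

Reads the record file written by 01_simulate_survival_data.py (or
regenerates it if absent), fits the exponential and Weibull proportional-
hazards models with the binary age covariate, and reports the recovered
baseline hazards and age hazard ratios next to the generating values
(0.009/month and HR 2.801). The exponential fit should recover both
within Monte-Carlo error; the Weibull shape should sit near 1 because the
generating hazard is constant.
"""

from pathlib import Path

import pandas as pd

from bnpce.survival_fitting import SurvivalRecords, fit_exponential, fit_weibull

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records_path = ROOT / "scratch" / "synthetic_survival_records.csv"
    if records_path.exists():
        records = SurvivalRecords.from_csv(records_path)
    else:
        from bnpce.synthetic_data import simulate_ipd_survival

        records = simulate_ipd_survival(
            n=52_122, rate=0.009, hr_over75=2.801, prop_over75=0.5,
            censor_time=108.0, seed=20_160_14,
        )

    rows = []
    for fit in (fit_exponential(records), fit_weibull(records)):
        rows.append(
            {
                "model": fit.model,
                "baseline_rate": fit.rate,
                "shape": fit.shape,
                "hr_over75": fit.hr_over75,
                "se_log_rate": fit.se_log_rate,
                "se_log_hr": fit.se_log_hr,
                "loglik": fit.loglik,
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "survival_fits.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)

    print(table.to_string(index=False))
    print(
        "\ngenerating values: rate 0.009/month, age HR 2.801; the Weibull "
        "log-likelihood exceeds the exponential's by construction (nested)."
    )


if __name__ == "__main__":
    main()
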
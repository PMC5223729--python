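# Methods

## The decision problem

Serial measurement of B-type natriuretic peptide (BNP) can guide the
intensity of heart-failure pharmacotherapy. The package implements a
decision-analytic comparison of BNP-guided against clinically guided
specialist care in recently hospitalised heart-failure patients, in three
subgroups: HFrEF patients under 75, HFpEF patients under 75, and HFrEF
patients 75 or older. The outputs are lifetime NHS costs, QALYs, the
incremental net monetary benefit iNMB(λ) = λ·ΔQALY − ΔCost at a
willingness-to-pay threshold (λ = £20,000/QALY by default), the ICER, and
cost-effectiveness acceptability curves.

## Model structure

A two-state (Alive/Dead) Markov cohort model with 3-month cycles. The
cohort starts fully alive at the subgroup's mean inception age (65 for the
under-75 subgroups, 81 for the over-75 subgroup) and is followed for 30
years (120 cycles) or 15 years (60 cycles) respectively — long enough that
more than 99% of each cohort has died, which the acceptance suite checks.
Each cycle applies a per-cycle death probability `d_t`; survivors'
experience is split between a hospitalised fraction `h_t` and a
not-hospitalised fraction. Hospitalisation does not feed back into
subsequent mortality (no published basis for that interaction), and there
are no functional-status states.

Transitions are assumed to occur halfway through each cycle: decedents
accrue half a cycle of the not-hospitalised cost and utility in their
death cycle, and discounting (3.5%/year for both costs and QALYs) uses the
mid-cycle exponent (t + 0.5)/4 years. An alternative interpretation
(trapezoidal state membership) would change totals by well under 1% at
these hazards; the half-cycle death-weight is a `half_cycle` flag on
`run_cohort`.

## Baseline mortality

* **Cycles 0–31 (first 8 years):** a constant monthly hazard of 0.009
  (exponential fit to linked routine primary-care/mortality data),
  converted per cycle as `1 − exp(−3h)`. The over-75 subgroup's *monthly
  hazard* is multiplied by the age hazard ratio 2.801 before conversion —
  age effects act on the hazard scale, matching the way the corresponding
  hospitalisation example is defined. Sensitivity analysis SA1 replaces
  the exponential with a Weibull proportional-hazards baseline
  (hazard scale 0.017, shape 0.842, time in months), whose per-cycle
  conditional probabilities `1 − S(3(k+1))/S(3k)` decrease over time
  (shape < 1). The Weibull applies to the under-75 baseline; the over-75
  subgroup keeps the exponential (the alternative baseline was estimated
  for younger patients, and the sensitivity analysis is only reported for
  them).
* **Cycles 32+ (beyond 8 years):** general-population life-table
  mortality at the attained age (start age + 8, advancing one year every
  4 cycles), sex-weighted with a fixed two-thirds male fraction,
  converted to a 3-month probability via `1 − (1−q)^(1/4)`, and inflated
  by the HF-vs-population mortality relative risk (≈3.14). That RR is
  derived, not asserted: each group's 7-year cumulative mortality
  (199/293 HF cases vs 176/586 matched controls) is converted to a
  per-cycle probability over 28 cycles and the ratio taken — in the PSA
  the two cumulative probabilities are redrawn from their beta
  distributions and the RR recomputed per iteration.
* **HFpEF adjustment:** every cycle's death probability is multiplied by
  the HFpEF-vs-HFrEF relative risk (≈0.78), likewise recomputed from two
  beta-distributed 1-year mortality probabilities (766/3631 vs 584/2205
  over 4 cycles). The adjustment is applied across the whole horizon,
  including the life-table phase, since the evidence adjusts HFpEF
  survival without restricting the window.
* **Treatment effect:** the BNP arm's per-cycle death probability is
  multiplied by the subgroup-specific mortality hazard ratio (0.68 HFrEF
  <75; 0.76 HFpEF <75; 0.87 HFrEF ≥75) during the effect window — 16
  cycles (4 years) in the primary analysis, 8 cycles in SA2, the whole
  horizon in SA3. Treatment HRs act on the *probability* scale; at these
  magnitudes the probability-scale and hazard-scale conventions differ by
  under 0.5% per cycle (0.018114 vs 0.018192 at cycle 0 for HFrEF <75),
  and the choice is deliberately the simpler one, consistent with how the
  relative risks are used. All products are capped at probability 1; no
  floor at the general-population rate is applied.

## Hospitalisation

A constant monthly all-cause hospitalisation hazard of 0.066 applies over
the whole lifetime (×1.248 on the hazard scale for the over-75 subgroup);
HFrEF and HFpEF share the same risk (cohort evidence shows a negligible
adjusted difference at 1 year). The BNP arm multiplies the per-cycle
probability by the hospitalisation HR 0.94 during the *same* effect
window as mortality — whether that HR shares the 4-year window is not
stated by the evidence; sharing it is this package's design choice and is
trivially changed via `ScenarioConfig`.

## Costs and QALYs

State costs per 3-month cycle are age-specific (hospitalised £9,104 /
£8,057; not hospitalised £682 / £569 for <75 / ≥75). The BNP arm adds,
per alive person: £25 per testing cycle for 6 cycles (3-monthly testing
for 18 months), the £58.32 total medication increment spread uniformly
over the same 6 cycles, and the incremental unscheduled outpatient visits
(1.40 − 1.10 over 24 months, £123/visit) spread over 8 cycles. In SA2 the
cost streams are clipped at 8 cycles along with the effect window (which
only affects streams longer than 8 cycles — none at the defaults). A
7-test variant (baseline test plus six) is not modelled; the testing
duration is expressed in whole cycles. In the PSA the incremental visit
count is the difference of the two independently sampled visit gammas,
floored at zero.

QALYs use utilities 0.66 (hospitalised) and 0.77 (not hospitalised) and a
mean length of stay of 13.21 days within a 91.31-day cycle: a
hospitalised cycle accrues `(los·U_h + (91.31 − los)·U_nh)/365.25` QALYs,
a non-hospitalised cycle `U_nh·91.31/365.25`. Utilities are independent
of strategy and constant in age, so all quality-of-life gain from
BNP-guided care flows through reduced admissions and longer survival.

## Parameter uncertainty

Every registry parameter carries a sampling distribution: beta for
probabilities and utilities, gamma for costs, counts and durations,
log-normal for hazard rates and ratios, or fixed. Beta and gamma
parameters are method-of-moments fits from the published mean and SE
(`beta_from_mean_se`, `gamma_from_mean_se`); hazard-ratio log-normals
invert the published 95% CI on the log scale with the quantile 1.959964.
Published beta parameter pairs are exact integers and are sampled
directly; published gamma pairs are printed rounded to 2 dp (a scale of
"0.01" that is really 0.0115), so sampling uses the full-precision
method-of-moments refit and the printed pair is retained as metadata. One
published gamma shape (94.52 for the BNP-arm visit count) disagrees with
the method of moments applied to its printed mean/SE (100); the registry
documents the discrepancy and samples from the refit. The published
utility SDs (0.26/0.23) imply a far larger spread than the published beta
parameters; the beta parameters govern sampling and the SDs are metadata.

The PSA draws every non-fixed parameter independently (no published
correlation structure) and re-runs both arms per iteration; 10,000
iterations match the source analysis (≈11 s on one CPU; the test suite
exercises the machinery at 10–200 iterations, which is ample for the
structural properties it checks). Each iteration has its own RNG stream
derived from (seed, iteration), so results are order-independent and
bit-reproducible. Summaries are the mean iNMB and the 2.5th/97.5th
percentile interval — percentile rather than normal-theory intervals, a
choice the source text does not pin down — plus the CEAC: the fraction of
draws with strictly positive iNMB across a λ grid of 0–50,000 in steps of
500. The Weibull baseline (SA1) has no published SEs and is held fixed in
the PSA.

## Survival fitting and synthetic data

`survival_fitting` re-implements the parametric stage that produced the
baseline hazards: the exponential MLE is closed-form per age stratum
(events/person-time, SE of the log rate 1/√events), and the Weibull
proportional-hazards model — `S(t) = exp(−scale·e^(βx)·t^shape)` with a
shape shared across strata — is fitted by L-BFGS-B from the exponential
solution, with SEs from the numerically differenced observed information.
Helpers convert between this metric and the accelerated-failure-time
metric, and the test suite cross-checks the fit against an independent
AFT implementation (lifelines) through that conversion.

`synthetic_data` generates the two external-shaped inputs. The life table
is Gompertz–Makeham (`q = 1 − exp(−(A + B·e^(θ·age)))`) with defaults
anchored at male q(65) ≈ 0.01 and q(85) ≈ 0.10 and female mortality ≈30%
lower — plausible UK-scale magnitudes, but synthetic: headline totals
against published tables are only claimed when a user supplies a genuine
national life table via `LifeTable.from_csv` (columns age, q_male,
q_female). Survival records are drawn by inverse transform from the
chosen hazard with proportional hazards for the over-75 stratum,
administrative censoring (default 108 months, the span of the source
extract), and an optional 7-day early-death exclusion window implemented
as conditional sampling. What the generator does *not* emulate: calendar
effects, covariates beyond dichotomised age, informative censoring, and
competing risks — so parameter-recovery tests demonstrate the fitters'
correctness under the model's own assumptions, not robustness to real
registry data.

## Numerical notes

* Cycle constants are 91.31 days/cycle and 365.25 days/year as published;
  4 cycles cover 365.24 days, so an undiscounted "year" of perfect
  health accrues 0.99997 QALYs, not 1.0.
* Median survival is read off the alive curve by linear interpolation
  across the crossing cycle (reported default) or by the cycle-boundary
  rule (end of the first cycle with survival < 0.5). For the youngest
  HFrEF subgroup the interpolated medians are 6.419/7.710 years and the
  boundary medians 6.50/7.75; the published pair (6.43/7.75) appears to
  mix conventions, which is why both rules are exposed. The discrepancy
  is bounded by one cycle (0.25 y).
* Deterministic medians for this subgroup are life-table independent:
  survival crosses 0.5 inside the 8-year parametric phase.
* Scenario overrides pin parameters to fixed values (a what-if setting is
  not new evidence), which makes the SA4/SA5 invariant exact: the
  clinical arm is bit-identical to the primary run.

## Known limitations

Costs and QALYs beyond year 8 depend on the life table; with the
synthetic default the totals land close to, but not exactly on, the
published values (e.g. £58,357/5.15 vs £58,139/5.02 for clinically guided
HFrEF <75), and exact reproduction requires the national life table the
source used. Two-state structure ignores functional decline and
readmission-count dependence; utilities do not decline with age; societal
and residential-care costs are out of scope.
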
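"""Parametric survival fitting with a binary age covariate.

Maximum-likelihood fitting of exponential and Weibull proportional-hazards
models to right-censored individual-patient records, emulating the routine-
data survival stage that produced the model's baseline monthly hazards and
age hazard ratios. The Weibull is parameterised in the proportional-hazards
metric, ``S(t) = exp(-scale * e^(beta x) * t^shape)`` with t in months and
x the over-75 indicator, so `scale` is the baseline hazard-scale the cohort
model consumes directly; helpers convert to and from the accelerated-
failure-time metric used by most survival software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SurvivalRecords",
    "FitResult",
    "fit_exponential",
    "fit_weibull",
    "ph_from_aft",
    "aft_from_ph",
]


@dataclass(frozen=True)
class SurvivalRecords:
    """Right-censored survival records: time (months), event flag, age class."""

    time: np.ndarray
    event: np.ndarray
    over75: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if np.any(t <= 0):
            raise ValueError("all follow-up times must be positive")
        if not (len(self.time) == len(self.event) == len(self.over75)):
            raise ValueError("record columns differ in length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", np.asarray(self.event, dtype=bool))
        object.__setattr__(self, "over75", np.asarray(self.over75, dtype=bool))

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_months": self.time,
                "event": self.event.astype(int),
                "age_class": np.where(self.over75, "over75", "under75"),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalRecords":
        df = pd.read_csv(path)
        missing = {"time_months", "event", "age_class"} - set(df.columns)
        if missing:
            raise ValueError(f"records file missing columns: {sorted(missing)}")
        return cls(
            time=df["time_months"].to_numpy(float),
            event=df["event"].to_numpy(bool),
            over75=(df["age_class"] == "over75").to_numpy(),
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted baseline hazard, age hazard ratio and uncertainty.

    For the exponential model ``shape`` is exactly 1. Standard errors are
    on the log scale (log baseline rate/scale, log shape, log HR).
    """

    model: str  # "exponential" | "weibull"
    rate: float  # baseline hazard scale (per month^shape)
    shape: float
    hr_over75: float
    se_log_rate: float
    se_log_shape: float
    se_log_hr: float
    loglik: float

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.shape <= 0 or self.hr_over75 <= 0:
            raise ValueError("rate, shape and HR must be positive")


def fit_exponential(records: SurvivalRecords) -> FitResult:
    """Closed-form exponential MLE per age stratum.

    The stratum rate is events / person-time; the baseline is the
    under-75 rate and the hazard ratio the over/under rate ratio. The SE
    of each log rate is 1/sqrt(events).
    """
    rates, events = {}, {}
    for label, mask in (("under75", ~records.over75), ("over75", records.over75)):
        d = int(records.event[mask].sum())
        if d == 0:
            raise ValueError(f"no events in stratum {label}; rate not estimable")
        pt = float(records.time[mask].sum())
        rates[label], events[label] = d / pt, d
    rate0, rate1 = rates["under75"], rates["over75"]
    hr = rate1 / rate0
    loglik = sum(
        events[s] * math.log(rates[s]) - rates[s] * float(records.time[m].sum())
        for s, m in (("under75", ~records.over75), ("over75", records.over75))
    )
    return FitResult(
        model="exponential",
        rate=rate0,
        shape=1.0,
        hr_over75=hr,
        se_log_rate=1.0 / math.sqrt(events["under75"]),
        se_log_shape=0.0,
        se_log_hr=math.sqrt(1.0 / events["under75"] + 1.0 / events["over75"]),
        loglik=loglik,
    )


def _weibull_negloglik(theta: np.ndarray, t, d, x) -> float:
    log_scale, log_shape, beta = theta
    scale, shape = math.exp(log_scale), math.exp(log_shape)
    log_t = np.log(t)
    # hazard: scale*shape*t^(shape-1)*e^(beta x); cumulative: scale*t^shape*e^(beta x)
    ll = np.sum(d * (log_scale + log_shape + (shape - 1.0) * log_t + beta * x))
    ll -= scale * np.sum(np.exp(shape * log_t + beta * x))
    return -float(ll)


def fit_weibull(records: SurvivalRecords, x0: tuple[float, float, float] | None = None) -> FitResult:
    """Weibull proportional-hazards MLE with the shape shared across strata.

    Optimises (log scale, log shape, log HR) by quasi-Newton descent from
    the exponential fit (shape 1), which is the nested special case.
    Standard errors come from the inverse observed information
    (numerically differenced Hessian at the optimum).
    """
    if len(np.unique(records.time[records.event])) < 2:
        raise ValueError("Weibull fit needs >= 2 distinct event times")
    t, d, x = records.time, records.event.astype(float), records.over75.astype(float)
    if x0 is None:
        expo = fit_exponential(records)
        x0 = (math.log(expo.rate), 0.0, math.log(expo.hr_over75))
    res = optimize.minimize(
        _weibull_negloglik,
        np.asarray(x0, dtype=float),
        args=(t, d, x),
        method="L-BFGS-B",
    )
    if not res.success:
        raise RuntimeError(f"Weibull MLE did not converge: {res.message}; {res}")
    log_scale, log_shape, beta = res.x
    se = _hessian_se(res.x, t, d, x)
    return FitResult(
        model="weibull",
        rate=math.exp(log_scale),
        shape=math.exp(log_shape),
        hr_over75=math.exp(beta),
        se_log_rate=se[0],
        se_log_shape=se[1],
        se_log_hr=se[2],
        loglik=-float(res.fun),
    )


def _hessian_se(theta: np.ndarray, t, d, x, eps: float = 1e-5) -> np.ndarray:
    k = len(theta)
    hess = np.empty((k, k))
    f = lambda v: _weibull_negloglik(v, t, d, x)  # noqa: E731
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            hess[i, j] = hess[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * eps * eps)
    cov = np.linalg.inv(hess)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def ph_from_aft(lambda_aft: float, rho: float, beta_aft: float = 0.0) -> tuple[float, float, float]:
    """Convert accelerated-failure-time Weibull parameters to the PH metric.

    AFT: ``S(t) = exp(-(t/lambda_aft)^rho)`` with the covariate scaling
    lambda_aft by ``e^(beta_aft x)``. Returns (scale, shape, beta_ph) with
    ``scale = lambda_aft^(-rho)``, ``shape = rho``,
    ``beta_ph = -rho * beta_aft``.
    """
    return lambda_aft ** (-rho), rho, -rho * beta_aft


def aft_from_ph(scale: float, shape: float, beta_ph: float = 0.0) -> tuple[float, float, float]:
    """Inverse of :func:`ph_from_aft`."""
    return scale ** (-1.0 / shape), shape, -beta_ph / shape
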
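"""Incremental cost-effectiveness statistics and acceptability curves.

The decision statistic is the incremental net monetary benefit
iNMB(lambda) = lambda * dE - dC, where dE and dC are the incremental
QALYs and costs of BNP-guided over clinically guided care and lambda is
the willingness-to-pay per QALY. A positive iNMB at the decision
threshold (GBP 20,000/QALY, the lower NICE bound) indicates that
BNP-guided care is cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LAMBDA_DEFAULT", "CEResult", "inmb", "icer", "ceac", "default_lambda_grid"]

LAMBDA_DEFAULT = 20_000.0  # GBP per QALY


def inmb(c0: float, e0: float, c1: float, e1: float, lam: float) -> float:
    """Incremental net monetary benefit of strategy 1 over strategy 0."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * (e1 - e0) - (c1 - c0)


def icer(c0: float, e0: float, c1: float, e1: float) -> tuple[float, str]:
    """ICER (GBP/QALY) and a dominance flag.

    Returns ``(value, flag)``: flag is ``"tradeoff"`` in the ordinary
    quadrants, ``"dominant"`` (cheaper and more effective) or
    ``"dominated"`` (dearer and less effective); the value is NaN with
    flag ``"undefined"`` when the QALY increment is zero.
    """
    dc, de = c1 - c0, e1 - e0
    if de == 0.0:
        return math.nan, "undefined"
    if dc <= 0.0 and de > 0.0:
        return dc / de, "dominant"
    if dc >= 0.0 and de < 0.0:
        return dc / de, "dominated"
    return dc / de, "tradeoff"


@dataclass(frozen=True)
class CEResult:
    """Deterministic cost-effectiveness comparison of the two strategies."""

    cost_clinical: float
    qalys_clinical: float
    cost_bnp: float
    qalys_bnp: float
    lam: float = LAMBDA_DEFAULT

    @property
    def delta_cost(self) -> float:
        return self.cost_bnp - self.cost_clinical

    @property
    def delta_qalys(self) -> float:
        return self.qalys_bnp - self.qalys_clinical

    @property
    def inmb(self) -> float:
        return inmb(
            self.cost_clinical, self.qalys_clinical, self.cost_bnp, self.qalys_bnp, self.lam
        )

    @property
    def icer(self) -> float:
        return icer(
            self.cost_clinical, self.qalys_clinical, self.cost_bnp, self.qalys_bnp
        )[0]

    @property
    def icer_flag(self) -> str:
        return icer(
            self.cost_clinical, self.qalys_clinical, self.cost_bnp, self.qalys_bnp
        )[1]

    def to_dict(self) -> dict:
        return {
            "cost_clinical": self.cost_clinical,
            "qalys_clinical": self.qalys_clinical,
            "cost_bnp": self.cost_bnp,
            "qalys_bnp": self.qalys_bnp,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "icer_flag": self.icer_flag,
            "lambda": self.lam,
            "inmb": self.inmb,
        }


def default_lambda_grid() -> np.ndarray:
    """Willingness-to-pay grid 0..50,000 in steps of 500 (includes 20,000)."""
    return np.arange(0.0, 50_000.0 + 500.0, 500.0)


def ceac(
    delta_costs: np.ndarray,
    delta_qalys: np.ndarray,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    For each lambda, the fraction of PSA draws with strictly positive
    iNMB, i.e. ``lambda * dE - dC > 0``.
    """
    dc = np.asarray(delta_costs, dtype=float)
    de = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0 or de.size == 0:
        raise ValueError("CEAC requires at least one PSA draw")
    if dc.shape != de.shape:
        raise ValueError("delta_costs and delta_qalys differ in shape")
    if lambdas is None:
        lambdas = default_lambda_grid()
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam < 0):
        raise ValueError("willingness-to-pay grid must be non-negative")
    nb = lam[:, None] * de[None, :] - dc[None, :]
    return (nb > 0).mean(axis=1)
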
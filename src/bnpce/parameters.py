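"""Model parameter registry and probabilistic-sensitivity-analysis sampling.

Every transition-probability, utility, resource-use and cost parameter of
the decision model lives in a :class:`ParameterRegistry`: a point estimate
plus a sampling distribution (beta for probabilities and utilities, gamma
for costs and counts, log-normal for hazard rates and ratios, or fixed).
Distribution parameters are obtained from published means and standard
errors by the method of moments (:func:`beta_from_mean_se`,
:func:`gamma_from_mean_se`) or by inverting a ratio's confidence interval
on the log scale (:func:`lognormal_from_ratio_ci`).

A :class:`ParameterSet` is one concrete assignment of values — either the
point estimates (deterministic analysis) or one Monte-Carlo draw
(probabilistic sensitivity analysis). Draws are independent across
parameters; there is no published basis for a joint correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterRegistry",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "lognormal_from_ratio_ci",
    "sample_parameter_set",
    "point_estimate_set",
    "load_default_registry",
]

_Z975 = 1.959964  # standard-normal 97.5% quantile


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters from a mean and standard error.

    Solves ``alpha/(alpha+beta) = mean`` and
    ``var = alpha*beta/((alpha+beta)^2 (alpha+beta+1)) = se^2``.

    Raises
    ------
    ValueError
        If ``mean`` is outside (0, 1) or ``se`` is not in
        ``(0, sqrt(mean*(1-mean)))``, the feasible spread of a beta
        distribution with that mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    bound = math.sqrt(mean * (1.0 - mean))
    if not 0.0 < se < bound:
        raise ValueError(
            f"se must lie in (0, {bound:.6g}) for mean {mean}, got {se}"
        )
    nu = mean * (1.0 - mean) / se**2 - 1.0  # alpha + beta
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) from a mean and standard error.

    ``shape = (mean/se)^2`` and ``scale = se^2/mean``, so that
    ``shape * scale = mean`` and ``shape * scale^2 = se^2``.
    """
    if mean <= 0.0 or se <= 0.0:
        raise ValueError(f"mean and se must be positive, got ({mean}, {se})")
    return (mean / se) ** 2, se**2 / mean


def lognormal_from_ratio_ci(
    ratio: float, lo: float, hi: float, level: float = 0.95
) -> tuple[float, float]:
    """Log-normal (mu, sigma) for a hazard/relative ratio from its CI.

    ``mu = ln(ratio)``; ``sigma`` is the implied standard error of the log
    ratio, ``(ln hi - ln lo) / (2 z)`` with ``z`` the normal quantile for
    the interval level. A degenerate interval with ``lo == hi == ratio``
    yields ``sigma = 0`` (the parameter is effectively fixed).
    """
    if not 0.0 < lo <= ratio <= hi:
        raise ValueError(
            f"require 0 < lo <= ratio <= hi, got ({lo}, {ratio}, {hi})"
        )
    if lo == hi and lo != ratio:  # unreachable given the check above
        raise ValueError("zero-width interval not centred on the ratio")
    z = -_norm_ppf((1.0 - level) / 2.0)
    sigma = (math.log(hi) - math.log(lo)) / (2.0 * z)
    return math.log(ratio), sigma


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


_DIST_KINDS = frozenset({"beta", "gamma", "lognormal", "fixed"})


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: point estimate plus sampling distribution.

    ``dist_params`` holds ``(alpha, beta)``, ``(shape, scale)`` or
    ``(mu, sigma)`` depending on ``dist_kind``; ``None`` for fixed
    parameters. ``meta`` carries published auxiliary values (SDs, rounded
    printed distribution parameters) for provenance checks only.
    """

    name: str
    point: float
    dist_kind: str
    dist_params: tuple[float, float] | None = None
    units: str = ""
    source_note: str = ""
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dist_kind not in _DIST_KINDS:
            raise ValueError(f"unknown dist_kind {self.dist_kind!r}")
        p = self.dist_params
        if self.dist_kind == "fixed":
            if p is not None:
                raise ValueError(f"{self.name}: fixed parameters take no dist_params")
            return
        if p is None or len(p) != 2:
            raise ValueError(f"{self.name}: {self.dist_kind} needs two dist_params")
        a, b = p
        if self.dist_kind == "beta":
            if a <= 0 or b <= 0:
                raise ValueError(f"{self.name}: beta parameters must be positive")
        elif self.dist_kind == "gamma":
            if a <= 0 or b <= 0:
                raise ValueError(f"{self.name}: gamma parameters must be positive")
        elif self.dist_kind == "lognormal":
            if b < 0:
                raise ValueError(f"{self.name}: lognormal sigma must be >= 0")

    @property
    def dist_mean(self) -> float:
        """Analytic mean of the sampling distribution."""
        if self.dist_kind == "fixed":
            return self.point
        a, b = self.dist_params  # type: ignore[misc]
        if self.dist_kind == "beta":
            return a / (a + b)
        if self.dist_kind == "gamma":
            return a * b
        return math.exp(a + b**2 / 2.0)

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist_kind == "fixed":
            return self.point
        a, b = self.dist_params  # type: ignore[misc]
        if self.dist_kind == "beta":
            return float(rng.beta(a, b))
        if self.dist_kind == "gamma":
            return float(rng.gamma(a, b))
        if b == 0.0:  # degenerate lognormal
            return math.exp(a)
        return float(rng.lognormal(a, b))


class ParameterRegistry:
    """Ordered collection of :class:`ParameterSpec`, keyed by name."""

    def __init__(self, specs: list[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for s in specs:
            if s.name in self._specs:
                raise ValueError(f"duplicate parameter {s.name!r}")
            self._specs[s.name] = s

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterRegistry":
        """New registry with the given point values replaced.

        Overridden parameters become ``fixed`` at the new value: scenario
        overrides are deterministic what-if settings, not new evidence with
        a sampling distribution.
        """
        unknown = set(overrides) - set(self._specs)
        if unknown:
            raise KeyError(f"overrides reference unknown parameters: {sorted(unknown)}")
        specs = []
        for s in self:
            if s.name in overrides:
                specs.append(
                    ParameterSpec(
                        name=s.name,
                        point=float(overrides[s.name]),
                        dist_kind="fixed",
                        dist_params=None,
                        units=s.units,
                        source_note=s.source_note + " [scenario override]",
                        meta=s.meta,
                    )
                )
            else:
                specs.append(s)
        return ParameterRegistry(specs)

    def collapsed(self) -> "ParameterRegistry":
        """All distributions replaced by fixed values at their points."""
        return ParameterRegistry(
            [
                ParameterSpec(s.name, s.point, "fixed", None, s.units, s.source_note, s.meta)
                for s in self
            ]
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterRegistry":
        doc = yaml.safe_load(text)
        specs = []
        for entry in doc["parameters"]:
            kind = entry["dist_kind"]
            raw = entry.get("dist_params")
            meta = dict(entry.get("meta") or {})
            if raw == "mom":
                # fit at load time from the full-precision mean and SE
                se = float(meta["se"])
                if kind == "gamma":
                    params = gamma_from_mean_se(float(entry["point"]), se)
                elif kind == "beta":
                    params = beta_from_mean_se(float(entry["point"]), se)
                else:
                    raise ValueError(f"'mom' dist_params invalid for {kind}")
            elif raw is None:
                params = None
            else:
                params = (float(raw[0]), float(raw[1]))
            specs.append(
                ParameterSpec(
                    name=entry["name"],
                    point=float(entry["point"]),
                    dist_kind=kind,
                    dist_params=params,
                    units=entry.get("units", ""),
                    source_note=entry.get("source_note", ""),
                    meta=meta,
                )
            )
        return cls(specs)


def load_default_registry() -> ParameterRegistry:
    """Load the bundled registry mirroring the published parameter tables."""
    text = resources.files("bnpce.data").joinpath("parameters.yaml").read_text()
    return ParameterRegistry.from_yaml(text)


@dataclass(frozen=True)
class ParameterSet:
    """One concrete assignment of every registry parameter.

    ``provenance`` is ``"point"`` for the deterministic set or ``"psa"``
    for a Monte-Carlo draw, in which case ``seed`` and ``iteration``
    identify the draw.
    """

    values: Mapping[str, float]
    provenance: str = "point"
    seed: int | None = None
    iteration: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def point_estimate_set(registry: ParameterRegistry) -> ParameterSet:
    """Deterministic parameter set: every value at its point estimate."""
    return ParameterSet({s.name: s.point for s in registry}, provenance="point")


def sample_parameter_set(
    registry: ParameterRegistry, seed: int, iteration: int = 0
) -> ParameterSet:
    """Draw one PSA parameter set, reproducible from ``(seed, iteration)``.

    Each iteration gets its own RNG stream, so draws are independent of
    execution order and of how many other iterations are run.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))
    values = {s.name: s.sample(rng) for s in registry}
    return ParameterSet(values, provenance="psa", seed=seed, iteration=iteration)
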
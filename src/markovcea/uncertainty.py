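"""Deterministic and probabilistic sensitivity analysis.

Parameter uncertainty is described by :class:`ParameterSpec` rows — base
value, plausible range and a distribution family — mirroring the familiar
model-input table of a health-economic evaluation.  Ranges are read as
central 95% intervals, so moment matching sets mean = base and
sd = (high − low) / 3.92, and family-specific shape parameters are solved
from those two moments.

Probabilistic sensitivity analysis (PSA) draws every parameter
independently per iteration, rebuilds the scenario, reruns the cohort
engine for both strategies and records the incremental result.  One-way
deterministic analysis reruns the model at a parameter's bounds for
tornado-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEACCurve, IncrementalResult, ceac

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

__all__ = [
    "FAMILIES",
    "RANGE_Z_WIDTH",
    "ParameterSpec",
    "FittedDistribution",
    "PSAResult",
    "TornadoEntry",
    "fit_distribution",
    "sample_parameters",
    "run_psa",
    "one_way_sa",
    "tornado",
]

FAMILIES = ("beta", "gamma", "normal", "point")

#: Width of a central 95% normal interval in standard deviations.
RANGE_Z_WIDTH = 3.92


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input: base value, 95% range, distribution family.

    ``targets`` are dotted scenario paths (e.g. ``"comparator.p_discharge"``
    or ``"shared.medication_cost_per_cycle"``) that receive the sampled value;
    a spec with no targets defaults to its own name as the path.
    """

    name: str
    base: float
    range_low: float
    range_high: float
    family: str
    units: str = ""
    targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.range_low <= self.base <= self.range_high:
            raise ValueError(
                f"{self.name}: need range_low <= base <= range_high, "
                f"got {self.range_low} / {self.base} / {self.range_high}"
            )
        if self.family == "beta" and not (0.0 <= self.range_low and self.range_high <= 1.0):
            raise ValueError(f"{self.name}: beta family requires values in [0, 1]")
        if self.family == "gamma" and self.range_low < 0.0:
            raise ValueError(f"{self.name}: gamma family requires non-negative values")

    @property
    def sd(self) -> float:
        """Implied standard deviation, reading the range as a 95% interval."""
        return (self.range_high - self.range_low) / RANGE_Z_WIDTH

    def resolved_targets(self) -> tuple[str, ...]:
        return self.targets if self.targets else (self.name,)


@dataclass(frozen=True)
class FittedDistribution:
    """A distribution moment-matched to a :class:`ParameterSpec`."""

    family: str
    params: Mapping[str, float]

    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        return p["loc"]  # normal

    def sample(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.family == "point":
            return p["value"] if size is None else np.full(size, p["value"])
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        return rng.normal(p["loc"], p["scale"], size)


def fit_distribution(spec: ParameterSpec) -> FittedDistribution:
    """Moment-match a distribution to ``spec`` (mean = base, sd from range).

    beta: solves (α, β) from mean m and variance v via
    ν = m(1−m)/v − 1, α = mν, β = (1−m)ν.  gamma: shape = m²/v,
    scale = v/m.  A zero-width range (or family ``point``) degenerates to a
    point mass at the base value.
    """
    m, sd = spec.base, spec.sd
    if spec.family == "point" or sd == 0.0:
        return FittedDistribution("point", {"value": m})
    v = sd * sd
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.name}: beta mean must be in (0, 1), got {m}")
        nu = m * (1.0 - m) / v - 1.0
        alpha, beta = m * nu, (1.0 - m) * nu
        if alpha <= 0.0 or beta <= 0.0:
            raise ValueError(
                f"{spec.name}: implied beta moments invalid "
                f"(mean={m}, sd={sd} -> alpha={alpha}, beta={beta}); narrow the range"
            )
        return FittedDistribution("beta", {"alpha": alpha, "beta": beta})
    if spec.family == "gamma":
        if m <= 0.0:
            raise ValueError(f"{spec.name}: gamma mean must be > 0, got {m}")
        return FittedDistribution("gamma", {"shape": m * m / v, "scale": v / m})
    return FittedDistribution("normal", {"loc": m, "scale": sd})


def sample_parameters(
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` independent samples per parameter; one column per spec name."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {spec.name: fit_distribution(spec).sample(rng, n) for spec in specs}
    )


@dataclass
class PSAResult:
    """Monte-Carlo PSA output: parameter draws plus incremental results."""

    n_samples: int
    seed: int
    params: pd.DataFrame
    results: tuple[IncrementalResult, ...]
    n_rejected: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([r.delta_cost for r in self.results])

    @property
    def delta_qalys(self) -> np.ndarray:
        return np.array([r.delta_qalys for r in self.results])

    def ceac(self, wtp_grid=None, intervention_label="intervention",
             comparator_label="comparator") -> CEACCurve:
        return ceac(self.results, wtp_grid, intervention_label, comparator_label)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.params.copy()
        df["delta_cost"] = self.delta_cost
        df["delta_qalys"] = self.delta_qalys
        df["icer"] = [r.icer if r.icer is not None else np.nan for r in self.results]
        return df


def run_psa(
    scenario: "Scenario",
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
    max_redraws_per_sample: int = 1000,
) -> PSAResult:
    """Run a seeded Monte-Carlo PSA of ``scenario`` under ``specs``.

    Per iteration, every parameter is drawn from its fitted distribution, the
    scenario is rebuilt with those values, both strategies are rerun through
    the cohort engine and the incremental result is recorded.  A draw that
    violates a model invariant (e.g. a probability out of range under a
    normal tail) is rejected and redrawn; the count is kept in
    ``n_rejected`` so heavy rejection is visible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not specs:
        raise ValueError("run_psa requires at least one ParameterSpec")
    fitted = [fit_distribution(s) for s in specs]
    # Fail fast if a spec does not bind to the scenario.
    scenario.with_overrides(
        {t: s.base for s in specs for t in s.resolved_targets()}
    )

    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    results: list[IncrementalResult] = []
    n_rejected = 0
    for _ in range(n):
        for attempt in range(max_redraws_per_sample):
            draw = {s.name: float(f.sample(rng)) for s, f in zip(specs, fitted)}
            overrides = {t: draw[s.name] for s in specs for t in s.resolved_targets()}
            try:
                candidate = scenario.with_overrides(overrides)
            except ValueError:
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError(
                f"rejected {max_redraws_per_sample} consecutive draws; "
                "check parameter ranges against model invariants"
            )
        rows.append(draw)
        results.append(candidate.run().incremental)
    return PSAResult(
        n_samples=n,
        seed=seed,
        params=pd.DataFrame(rows),
        results=tuple(results),
        n_rejected=n_rejected,
    )


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result: ICER at a parameter's low and high bound."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None

    @property
    def swing(self) -> float:
        """Absolute ICER range; NaN when either end is undefined (dominance)."""
        if self.icer_at_low is None or self.icer_at_high is None:
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)


def _resolve_parameter(scenario: "Scenario", parameter: str) -> tuple[str, ...]:
    for spec in scenario.parameter_specs:
        if spec.name == parameter:
            return spec.resolved_targets()
    return (parameter,)


def one_way_sa(
    scenario: "Scenario",
    parameter: str,
    low: float,
    high: float,
) -> TornadoEntry:
    """Deterministic one-way sensitivity analysis of one parameter.

    ``parameter`` is either the name of one of the scenario's parameter specs
    or a dotted override path.  Two full model runs are performed with the
    parameter at ``low`` and at ``high``, everything else at base.
    """
    if low > high:
        raise ValueError(f"{parameter}: low bound {low} exceeds high bound {high}")
    targets = _resolve_parameter(scenario, parameter)
    icers = []
    for bound in (low, high):
        try:
            run = scenario.with_overrides({t: bound for t in targets}).run()
        except ValueError as exc:
            raise ValueError(f"{parameter}: bound {bound} outside model validity: {exc}") from exc
        icers.append(run.incremental.icer)
    return TornadoEntry(parameter, low, high, icers[0], icers[1])


def tornado(
    scenario: "Scenario",
    entries: Sequence[tuple[str, float, float]],
) -> list[TornadoEntry]:
    """One-way analyses for several parameters, sorted by swing (largest first)."""
    if not entries:
        raise ValueError("tornado requires at least one (parameter, low, high) entry")
    results = [one_way_sa(scenario, p, lo, hi) for p, lo, hi in entries]
    return sorted(
        results,
        key=lambda e: (np.isnan(e.swing), -e.swing if not np.isnan(e.swing) else 0.0),
    )


def tornado_to_dataframe(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )
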
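"""Scenario definition, validation and reference inputs.

A :class:`Scenario` is the full parameterization of a two-strategy
comparison: per-strategy transition parameters and payoffs, the cycle plan,
and the table of uncertain parameters used by sensitivity analysis.  The
shipped reference scenario encodes the published model-input table for the
ACE-inhibitor vs ARB heart-failure comparison; its
``parameter_interpretation`` block documents how each printed row maps onto
an engine role.

Also here: the subgroup ICER table (which operates on printed incremental
results directly) and a small cost-adjustment utility for inflation and
currency conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .economics import IncrementalResult, incremental, report_icer
from .engine import (
    DEAD,
    HOSPITALIZED,
    REFERENCE_STATES,
    STABLE,
    CyclePlan,
    EconResult,
    StatePayoffs,
    TransitionMatrix,
    accumulate_payoffs,
    annual_prob_to_cycle_prob,
    build_transition_matrix,
    run_cohort,
)
from .uncertainty import ParameterSpec

__all__ = [
    "StrategyParams",
    "Scenario",
    "ScenarioResult",
    "SubgroupInput",
    "ScenarioValidationError",
    "load_scenario",
    "load_scenario_path",
    "reference_scenario",
    "reference_subgroup_inputs",
    "scenario_to_yaml",
    "subgroup_icer_table",
    "adjust_cost",
]

_STRATEGY_FIELDS: dict[str, tuple[float, float, str]] = {
    # field -> (min, max, constraint description)
    "p_hospitalization_annual": (0.0, 1.0, "annual probability in [0, 1)"),
    "p_discharge": (0.0, 1.0, "per-cycle probability in [0, 1]"),
    "p_death_annual": (0.0, 1.0, "annual probability in [0, 1)"),
    "medication_cost_per_cycle": (0.0, math.inf, "cost >= 0"),
    "hospitalization_cost_per_episode": (0.0, math.inf, "cost >= 0"),
    "utility_stable": (0.0, 1.0, "utility in [0, 1]"),
    "hospitalized_utility_multiplier": (0.0, 1.0, "multiplier in [0, 1]"),
}


@dataclass(frozen=True)
class StrategyParams:
    """One treatment strategy's transition parameters and payoffs.

    Annual probabilities (hospitalization, death) are converted to the cycle
    length by the plan; ``p_discharge`` is already a per-cycle probability of
    returning from ``Hospitalized`` to ``Stable``.  Quality of life while
    hospitalized is the stable-state utility scaled down by
    ``hospitalized_utility_multiplier``.
    """

    name: str
    p_hospitalization_annual: float
    p_discharge: float
    p_death_annual: float
    medication_cost_per_cycle: float
    hospitalization_cost_per_episode: float
    utility_stable: float
    hospitalized_utility_multiplier: float = 0.80

    def __post_init__(self) -> None:
        for fname, (lo, hi, desc) in _STRATEGY_FIELDS.items():
            value = getattr(self, fname)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"{self.name}.{fname}: {value!r} is not a number")
            if not lo <= value <= hi:
                raise ValueError(f"{self.name}.{fname}: {value!r} violates {desc}")
        for fname in ("p_hospitalization_annual", "p_death_annual"):
            if getattr(self, fname) >= 1.0:
                raise ValueError(
                    f"{self.name}.{fname}: annual probability must be < 1 to rescale to a cycle"
                )

    def transition_matrix(self, plan: CyclePlan) -> TransitionMatrix:
        p_hosp = annual_prob_to_cycle_prob(self.p_hospitalization_annual, plan.cycle_length)
        p_death = annual_prob_to_cycle_prob(self.p_death_annual, plan.cycle_length)
        return build_transition_matrix(p_hosp, self.p_discharge, p_death, p_death)

    def payoffs(self) -> StatePayoffs:
        return StatePayoffs(
            space=REFERENCE_STATES,
            cost_per_cycle={
                STABLE: self.medication_cost_per_cycle,
                HOSPITALIZED: self.medication_cost_per_cycle,
                DEAD: 0.0,
            },
            cost_per_episode=self.hospitalization_cost_per_episode,
            utility={
                STABLE: self.utility_stable,
                HOSPITALIZED: self.utility_stable * self.hospitalized_utility_multiplier,
                DEAD: 0.0,
            },
        )

    def to_dict(self) -> dict[str, Any]:
        return {"name": self.name, **{f: getattr(self, f) for f in _STRATEGY_FIELDS}}


@dataclass(frozen=True)
class ScenarioResult:
    """Both strategies' economic totals plus their incremental comparison."""

    comparator: EconResult
    intervention: EconResult
    incremental: IncrementalResult
    comparator_name: str = "comparator"
    intervention_name: str = "intervention"


@dataclass(frozen=True)
class Scenario:
    """Two-strategy comparison: parameters, plan, and uncertainty specs."""

    name: str
    comparator: StrategyParams
    intervention: StrategyParams
    plan: CyclePlan
    parameter_specs: tuple[ParameterSpec, ...] = ()
    parameter_interpretation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter_specs", tuple(self.parameter_specs))
        object.__setattr__(self, "parameter_interpretation", dict(self.parameter_interpretation))
        for spec in self.parameter_specs:
            for target in spec.resolved_targets():
                value = self.get_value(target)
                if not math.isclose(value, spec.base, rel_tol=1e-9, abs_tol=1e-12):
                    raise ValueError(
                        f"parameter {spec.name!r} base {spec.base} disagrees with the "
                        f"scenario value {value} at target {target!r}"
                    )

    # -- parameter addressing ------------------------------------------------

    def get_value(self, path: str) -> float:
        """Read a scenario value by dotted path (see :meth:`with_overrides`)."""
        prefix, _, fname = path.partition(".")
        if not fname:
            raise KeyError(f"path {path!r} must look like 'section.field'")
        if prefix == "shared":
            a = getattr(self.comparator, self._strategy_field(fname))
            b = getattr(self.intervention, self._strategy_field(fname))
            if a != b:
                raise ValueError(f"shared path {path!r} but strategies disagree ({a} vs {b})")
            return a
        if prefix in ("comparator", "intervention"):
            return getattr(getattr(self, prefix), self._strategy_field(fname))
        if prefix == "plan":
            if not hasattr(self.plan, fname):
                raise KeyError(f"unknown plan field {fname!r} in path {path!r}")
            return getattr(self.plan, fname)
        raise KeyError(
            f"unknown section {prefix!r} in path {path!r}; "
            "expected comparator/intervention/shared/plan"
        )

    @staticmethod
    def _strategy_field(fname: str) -> str:
        if fname not in _STRATEGY_FIELDS:
            raise KeyError(
                f"unknown strategy field {fname!r}; known fields: {sorted(_STRATEGY_FIELDS)}"
            )
        return fname

    def with_overrides(self, overrides: Mapping[str, float]) -> "Scenario":
        """A copy of this scenario with dotted-path values replaced.

        Paths: ``comparator.<field>``, ``intervention.<field>``,
        ``shared.<field>`` (both strategies), ``plan.<field>``.  Invalid
        values raise ``ValueError`` via the underlying dataclass validation.
        Parameter specs are dropped from the copy: their bases no longer
        describe the perturbed scenario.
        """
        strat_updates: dict[str, dict[str, float]] = {"comparator": {}, "intervention": {}}
        plan_updates: dict[str, float] = {}
        for path, value in overrides.items():
            prefix, _, fname = path.partition(".")
            if not fname:
                raise KeyError(f"path {path!r} must look like 'section.field'")
            if prefix == "shared":
                fname = self._strategy_field(fname)
                strat_updates["comparator"][fname] = value
                strat_updates["intervention"][fname] = value
            elif prefix in ("comparator", "intervention"):
                strat_updates[prefix][self._strategy_field(fname)] = value
            elif prefix == "plan":
                if not hasattr(self.plan, fname):
                    raise KeyError(f"unknown plan field {fname!r} in path {path!r}")
                plan_updates[fname] = int(value) if fname == "n_cycles" else value
            else:
                raise KeyError(
                    f"unknown section {prefix!r} in path {path!r}; "
                    "expected comparator/intervention/shared/plan"
                )
        return Scenario(
            name=self.name,
            comparator=replace(self.comparator, **strat_updates["comparator"]),
            intervention=replace(self.intervention, **strat_updates["intervention"]),
            plan=replace(self.plan, **plan_updates) if plan_updates else self.plan,
            parameter_specs=(),
            parameter_interpretation=self.parameter_interpretation,
        )

    # -- running -------------------------------------------------------------

    def initial_occupancy(self) -> np.ndarray:
        """Everyone starts in Stable."""
        init = np.zeros(REFERENCE_STATES.n_states)
        init[REFERENCE_STATES.index(STABLE)] = 1.0
        return init

    def run_strategy(self, strategy: StrategyParams) -> EconResult:
        trace = run_cohort(strategy.transition_matrix(self.plan), self.initial_occupancy(), self.plan)
        return accumulate_payoffs(trace, strategy.payoffs(), self.plan)

    def run(self) -> ScenarioResult:
        comp = self.run_strategy(self.comparator)
        intv = self.run_strategy(self.intervention)
        return ScenarioResult(
            comparator=comp,
            intervention=intv,
            incremental=incremental(comp, intv),
            comparator_name=self.comparator.name,
            intervention_name=self.intervention.name,
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "plan": {
                "cycle_length": self.plan.cycle_length,
                "n_cycles": self.plan.n_cycles,
                "annual_discount_rate_costs": self.plan.annual_discount_rate_costs,
                "annual_discount_rate_effects": self.plan.annual_discount_rate_effects,
            },
            "strategies": {
                "comparator": self.comparator.to_dict(),
                "intervention": self.intervention.to_dict(),
            },
        }
        if self.parameter_interpretation:
            d["parameter_interpretation"] = dict(self.parameter_interpretation)
        if self.parameter_specs:
            d["parameters"] = [
                {
                    "name": s.name,
                    "base": s.base,
                    "low": s.range_low,
                    "high": s.range_high,
                    "family": s.family,
                    "units": s.units,
                    "targets": list(s.targets),
                }
                for s in self.parameter_specs
            ]
        return d


def scenario_to_yaml(scenario: Scenario) -> str:
    return yaml.safe_dump(scenario.to_dict(), sort_keys=False)


class ScenarioValidationError(ValueError):
    """Raised by :func:`load_scenario`; carries one message per violation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid scenario configuration:\n  " + "\n  ".join(self.errors))


def _check_number(value: Any, path: str, errors: list[str], lo=None, hi=None, desc="") -> bool:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        errors.append(f"{path}: {value!r} is not a number")
        return False
    if lo is not None and hi is not None and not lo <= value <= hi:
        errors.append(f"{path}: {value!r} violates {desc or f'value in [{lo}, {hi}]'}")
        return False
    return True


def _parse_strategy(d: Any, path: str, errors: list[str]) -> StrategyParams | None:
    if not isinstance(d, Mapping):
        errors.append(f"{path}: expected a mapping of strategy parameters")
        return None
    known = {"name", *_STRATEGY_FIELDS}
    for key in sorted(set(d) - known):
        errors.append(f"{path}.{key}: unknown key")
    kwargs: dict[str, Any] = {"name": d.get("name", path.rsplit(".", 1)[-1])}
    ok = True
    for fname, (lo, hi, desc) in _STRATEGY_FIELDS.items():
        if fname not in d:
            if fname == "hospitalized_utility_multiplier":
                continue  # has a default
            errors.append(f"{path}.{fname}: missing required key")
            ok = False
            continue
        if _check_number(d[fname], f"{path}.{fname}", errors, lo, hi, desc):
            kwargs[fname] = float(d[fname])
        else:
            ok = False
    if not ok:
        return None
    try:
        return StrategyParams(**kwargs)
    except ValueError as exc:
        errors.append(f"{path}: {exc}")
        return None


def _parse_plan(d: Any, errors: list[str]) -> CyclePlan | None:
    if not isinstance(d, Mapping):
        errors.append("plan: expected a mapping")
        return None
    known = {
        "cycle_length",
        "cycles_per_year",
        "n_cycles",
        "annual_discount_rate_costs",
        "annual_discount_rate_effects",
    }
    for key in sorted(set(d) - known):
        errors.append(f"plan.{key}: unknown key")
    if "cycle_length" in d and "cycles_per_year" in d:
        errors.append("plan: give either cycle_length or cycles_per_year, not both")
        return None
    if "cycles_per_year" in d:
        cpy = d["cycles_per_year"]
        if not isinstance(cpy, int) or cpy < 1:
            errors.append(f"plan.cycles_per_year: {cpy!r} violates positive integer")
            return None
        cycle_length = 1.0 / cpy
    else:
        cycle_length = d.get("cycle_length", 1.0 / 12.0)
        if not _check_number(cycle_length, "plan.cycle_length", errors, desc="cycle_length > 0"):
            return None
    n_cycles = d.get("n_cycles", 120)
    if not isinstance(n_cycles, int) or n_cycles < 1:
        errors.append(f"plan.n_cycles: {n_cycles!r} violates integer >= 1")
        return None
    kwargs = {"cycle_length": float(cycle_length), "n_cycles": n_cycles}
    for key in ("annual_discount_rate_costs", "annual_discount_rate_effects"):
        if key in d:
            if not _check_number(d[key], f"plan.{key}", errors, 0.0, 0.20, "rate in [0, 0.20]"):
                return None
            kwargs[key] = float(d[key])
    try:
        return CyclePlan(**kwargs)
    except ValueError as exc:
        errors.append(f"plan: {exc}")
        return None


def _parse_parameters(items: Any, errors: list[str]) -> tuple[ParameterSpec, ...]:
    if not isinstance(items, list):
        errors.append("parameters: expected a list of parameter entries")
        return ()
    specs = []
    for i, entry in enumerate(items):
        path = f"parameters[{i}]"
        if not isinstance(entry, Mapping):
            errors.append(f"{path}: expected a mapping")
            continue
        missing = [k for k in ("name", "base", "low", "high", "family") if k not in entry]
        if missing:
            errors.append(f"{path}: missing required keys {missing}")
            continue
        try:
            specs.append(
                ParameterSpec(
                    name=str(entry["name"]),
                    base=float(entry["base"]),
                    range_low=float(entry["low"]),
                    range_high=float(entry["high"]),
                    family=str(entry["family"]),
                    units=str(entry.get("units", "")),
                    targets=tuple(entry.get("targets", ())),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"{path}: {exc}")
    return tuple(specs)


def load_scenario(config_text: str) -> Scenario:
    """Parse and validate a YAML/JSON scenario document.

    Every violation is reported with its dotted path, the offending value and
    the constraint; unknown keys are rejected so typos cannot silently fall
    back to defaults.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ScenarioValidationError([f"document does not parse: {exc}"]) from exc
    if doc is None:
        raise ScenarioValidationError(
            ["empty document: missing sections ['name', 'plan', 'strategies']"]
        )
    if not isinstance(doc, Mapping):
        raise ScenarioValidationError([f"top level must be a mapping, got {type(doc).__name__}"])

    errors: list[str] = []
    known = {"name", "description", "plan", "strategies", "parameter_interpretation", "parameters"}
    for key in sorted(set(doc) - known):
        errors.append(f"{key}: unknown top-level key")
    missing = [k for k in ("name", "plan", "strategies") if k not in doc]
    if missing:
        errors.append(f"missing sections {missing}")
        raise ScenarioValidationError(errors)

    plan = _parse_plan(doc["plan"], errors)
    strategies = doc["strategies"]
    comparator = intervention = None
    if not isinstance(strategies, Mapping):
        errors.append("strategies: expected a mapping with comparator and intervention")
    else:
        for key in sorted(set(strategies) - {"comparator", "intervention"}):
            errors.append(f"strategies.{key}: unknown key (expected comparator, intervention)")
        for role in ("comparator", "intervention"):
            if role not in strategies:
                errors.append(f"strategies.{role}: missing required section")
        if "comparator" in strategies:
            comparator = _parse_strategy(strategies["comparator"], "strategies.comparator", errors)
        if "intervention" in strategies:
            intervention = _parse_strategy(
                strategies["intervention"], "strategies.intervention", errors
            )

    interpretation = doc.get("parameter_interpretation", {})
    if not isinstance(interpretation, Mapping):
        errors.append("parameter_interpretation: expected a mapping of label -> engine role")
        interpretation = {}

    specs = _parse_parameters(doc["parameters"], errors) if "parameters" in doc else ()

    if errors or plan is None or comparator is None or intervention is None:
        raise ScenarioValidationError(errors or ["unspecified validation failure"])

    try:
        return Scenario(
            name=str(doc["name"]),
            comparator=comparator,
            intervention=intervention,
            plan=plan,
            parameter_specs=specs,
            parameter_interpretation={str(k): str(v) for k, v in interpretation.items()},
        )
    except ValueError as exc:
        raise ScenarioValidationError([str(exc)]) from exc


def load_scenario_path(path) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        return load_scenario(fh.read())


def reference_scenario() -> Scenario:
    """The shipped ACE-inhibitor vs ARB heart-failure reference scenario."""
    text = resources.files("markovcea.data").joinpath("reference_scenario.yaml").read_text()
    return load_scenario(text)


def reference_subgroup_inputs() -> pd.DataFrame:
    """The shipped subgroup incremental results (age bands and severity)."""
    with resources.files("markovcea.data").joinpath("subgroup_inputs.csv").open("r") as fh:
        return pd.read_csv(fh)


# -- subgroup analysis -------------------------------------------------------


@dataclass(frozen=True)
class SubgroupInput:
    """Printed incremental results for one subgroup (age band or severity)."""

    subgroup: str
    delta_cost: float
    delta_qalys: float


def subgroup_icer_table(
    inputs: Sequence[SubgroupInput] | pd.DataFrame,
) -> pd.DataFrame:
    """One row per subgroup: ΔCost, ΔQALY, and ICER rounded half-up to dollars.

    A subgroup with ΔQALY = 0 keeps its row with a missing ICER (flagged, not
    dropped).
    """
    if isinstance(inputs, pd.DataFrame):
        required = ["subgroup", "delta_cost", "delta_qalys"]
        missing = [c for c in required if c not in inputs.columns]
        if missing:
            raise ValueError(f"subgroup inputs missing column(s): {missing}")
        rows = [
            SubgroupInput(str(r.subgroup), float(r.delta_cost), float(r.delta_qalys))
            for r in inputs.itertuples()
        ]
    else:
        rows = list(inputs)
    if not rows:
        raise ValueError("subgroup_icer_table requires at least one subgroup")

    icers = [
        report_icer((r.delta_cost, r.delta_qalys)) if r.delta_qalys != 0 else pd.NA
        for r in rows
    ]
    return pd.DataFrame(
        {
            "subgroup": [r.subgroup for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "delta_qalys": [r.delta_qalys for r in rows],
            "icer": pd.array(icers, dtype="Int64"),
        }
    )


def adjust_cost(
    amount: float,
    index_from: float,
    index_to: float,
    fx_rate: float = 1.0,
) -> float:
    """Inflate/deflate a cost by a price-index ratio and convert currency.

    Returns ``amount * (index_to / index_from) * fx_rate``.
    """
    if index_from <= 0 or index_to <= 0:
        raise ValueError(f"price indices must be > 0, got {index_from} and {index_to}")
    if fx_rate <= 0:
        raise ValueError(f"fx_rate must be > 0, got {fx_rate}")
    return amount * (index_to / index_from) * fx_rate
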
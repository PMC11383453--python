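"""Discrete-time Markov cohort engine.

The core of the package: a cohort of patients is propagated across a small set
of health states (in the reference model ``Stable``, ``Hospitalized`` and an
absorbing ``Dead`` state) in fixed cycles under a row-stochastic transition
matrix.  Per-cycle state membership is converted to person-time with a
half-cycle (trapezoidal) correction, and costs and quality-adjusted life years
(QALYs) are accumulated with annual discounting.

The engine is deliberately time-homogeneous: one transition matrix per
strategy, applied every cycle.  Tunnel states, time-varying rates and
individual covariates are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STABLE",
    "HOSPITALIZED",
    "DEAD",
    "StateSpace",
    "REFERENCE_STATES",
    "TransitionMatrix",
    "CyclePlan",
    "CohortTrace",
    "StatePayoffs",
    "EconResult",
    "annual_prob_to_cycle_prob",
    "build_transition_matrix",
    "run_cohort",
    "half_cycle_correct",
    "discount_factor",
    "accumulate_payoffs",
]

STABLE = "Stable"
HOSPITALIZED = "Hospitalized"
DEAD = "Dead"

#: Row sums must hit 1 to this tolerance when a matrix is constructed.
ROW_SUM_TOL_BUILD = 1e-12
#: Occupancy rows must sum to 1 to this tolerance after propagation.
ROW_SUM_TOL_TRACE = 1e-10


@dataclass(frozen=True)
class StateSpace:
    """Ordered health-state labels with a designated absorbing subset."""

    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        if len(self.states) < 2:
            raise ValueError("a state space needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"duplicate state labels in {self.states}")
        unknown = self.absorbing - set(self.states)
        if unknown:
            raise ValueError(f"absorbing labels not in states: {sorted(unknown)}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def living(self) -> tuple[str, ...]:
        """Non-absorbing states, in declaration order."""
        return tuple(s for s in self.states if s not in self.absorbing)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}; states are {self.states}") from None


#: The reference three-state space: Stable / Hospitalized plus absorbing Dead.
REFERENCE_STATES = StateSpace((STABLE, HOSPITALIZED, DEAD), frozenset({DEAD}))


@dataclass(frozen=True)
class TransitionMatrix:
    """Square row-stochastic matrix of per-cycle transition probabilities."""

    space: StateSpace
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.array(self.probs, dtype=float)
        n = self.space.n_states
        if probs.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got shape {probs.shape}")
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            bad = np.argwhere((probs < 0.0) | (probs > 1.0))[0]
            raise ValueError(
                f"probability out of [0, 1] at "
                f"{self.space.states[bad[0]]}->{self.space.states[bad[1]]}: "
                f"{probs[bad[0], bad[1]]!r}"
            )
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > ROW_SUM_TOL_BUILD):
            bad_row = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"row for state {self.space.states[bad_row]!r} sums to "
                f"{row_sums[bad_row]!r}, not 1"
            )
        for label in self.space.absorbing:
            i = self.space.index(label)
            unit = np.zeros(n)
            unit[i] = 1.0
            if not np.array_equal(probs[i], unit):
                raise ValueError(f"absorbing state {label!r} row is not a unit self-loop")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class CyclePlan:
    """Cycle timing and annual discount rates.

    ``cycle_length`` is a fraction of a year (monthly cycles: 1/12).  Discount
    rates are annual fractions, applied separately to costs and effects; both
    default to the conventional 3% and are capped at 20%.
    """

    cycle_length: float = 1.0 / 12.0
    n_cycles: int = 120
    annual_discount_rate_costs: float = 0.03
    annual_discount_rate_effects: float = 0.03

    def __post_init__(self) -> None:
        if not self.cycle_length > 0:
            raise ValueError(f"cycle_length must be > 0, got {self.cycle_length}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        for name in ("annual_discount_rate_costs", "annual_discount_rate_effects"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.20:
                raise ValueError(f"{name} must be in [0, 0.20], got {rate}")

    @property
    def horizon_years(self) -> float:
        return self.cycle_length * self.n_cycles

    def cycle_end_times(self) -> np.ndarray:
        """Times (in years) of the end of cycles 1..n_cycles."""
        return np.arange(1, self.n_cycles + 1, dtype=float) * self.cycle_length


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions at every cycle boundary.

    ``occupancy`` has one row per cycle boundary (row 0 = initial
    distribution); ``episode_inflow[t]`` is the fraction of the cohort newly
    entering ``Hospitalized`` during cycle t (index 0 holds the fraction that
    starts hospitalized, i.e. an episode already under way).
    """

    space: StateSpace
    occupancy: np.ndarray
    episode_inflow: np.ndarray
    cycle_length: float

    def __post_init__(self) -> None:
        occ = np.array(self.occupancy, dtype=float)
        inflow = np.array(self.episode_inflow, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != self.space.n_states:
            raise ValueError(f"occupancy must be (cycles+1, {self.space.n_states}), got {occ.shape}")
        if occ.shape[0] < 2:
            raise ValueError("a trace needs at least 2 occupancy rows (>= 1 cycle)")
        if inflow.shape != (occ.shape[0],):
            raise ValueError("episode_inflow must have one entry per occupancy row")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > ROW_SUM_TOL_TRACE):
            bad = int(np.argmax(np.abs(occ.sum(axis=1) - 1.0)))
            raise ValueError(f"occupancy row {bad} sums to {occ[bad].sum()!r}, not 1")
        if np.any(occ < -ROW_SUM_TOL_TRACE):
            raise ValueError("negative occupancy fraction")
        if np.any(inflow < -ROW_SUM_TOL_TRACE) or np.any(inflow > 1.0 + ROW_SUM_TOL_TRACE):
            raise ValueError("episode_inflow outside [0, 1]")
        if not self.cycle_length > 0:
            raise ValueError("cycle_length must be > 0")
        occ.setflags(write=False)
        inflow.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "episode_inflow", inflow)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        """One row per cycle boundary: cycle, time_years, states, episode_inflow."""
        cycles = np.arange(self.occupancy.shape[0])
        df = pd.DataFrame(self.occupancy, columns=list(self.space.states))
        df.insert(0, "cycle", cycles)
        df.insert(1, "time_years", cycles * self.cycle_length)
        df["episode_inflow"] = self.episode_inflow
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class StatePayoffs:
    """Per-state costs and utilities.

    ``cost_per_cycle`` is money accrued per full cycle of membership in a
    state (the reference model charges the monthly medication cost in both
    living states).  ``cost_per_episode`` is charged once per entry into
    ``Hospitalized``.  ``utility`` is the QALY weight per year of membership,
    in [0, 1].  Absorbing states must carry zero cost and zero utility.
    """

    space: StateSpace
    cost_per_cycle: Mapping[str, float]
    cost_per_episode: float
    utility: Mapping[str, float]

    def __post_init__(self) -> None:
        for mapping, what in ((self.cost_per_cycle, "cost_per_cycle"), (self.utility, "utility")):
            missing = set(self.space.states) - set(mapping)
            extra = set(mapping) - set(self.space.states)
            if missing or extra:
                raise ValueError(
                    f"{what} states do not match the state space "
                    f"(missing {sorted(missing)}, unknown {sorted(extra)})"
                )
        for s, c in self.cost_per_cycle.items():
            if c < 0:
                raise ValueError(f"cost_per_cycle[{s!r}] must be >= 0, got {c}")
        if self.cost_per_episode < 0:
            raise ValueError(f"cost_per_episode must be >= 0, got {self.cost_per_episode}")
        for s, u in self.utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility[{s!r}] must be in [0, 1], got {u}")
        for s in self.space.absorbing:
            if self.utility[s] != 0.0 or self.cost_per_cycle[s] != 0.0:
                raise ValueError(f"absorbing state {s!r} must have zero utility and zero cost")

    def cost_vector(self) -> np.ndarray:
        return np.array([self.cost_per_cycle[s] for s in self.space.states], dtype=float)

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utility[s] for s in self.space.states], dtype=float)


@dataclass(frozen=True)
class EconResult:
    """Discounted and undiscounted totals for one strategy."""

    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    life_years: float

    @classmethod
    def from_totals(cls, cost: float, qalys: float) -> "EconResult":
        """Wrap externally given mean cost/QALY totals (e.g. a published table)."""
        return cls(cost, qalys, cost, qalys, float("nan"))


def annual_prob_to_cycle_prob(p_annual: float, cycle_length: float) -> float:
    """Convert an annual transition probability to a per-cycle probability.

    Assumes a constant hazard within the year: the per-cycle probability is
    ``1 - (1 - p_annual)**cycle_length``, which lies in ``[0, p_annual]`` for
    cycles no longer than a year.
    """
    if not 0.0 < cycle_length <= 1.0:
        raise ValueError(f"cycle_length must be in (0, 1], got {cycle_length}")
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be a probability, got {p_annual}")
    if p_annual == 1.0 and cycle_length < 1.0:
        raise ValueError("p_annual = 1 has an undefined rate; cannot rescale to a shorter cycle")
    return 1.0 - (1.0 - p_annual) ** cycle_length


def build_transition_matrix(
    p_stable_to_hosp: float,
    p_hosp_to_stable: float,
    p_death_stable: float,
    p_death_hosp: float,
) -> TransitionMatrix:
    """Compose per-cycle probabilities into the reference 3-state matrix.

    Competing risks within a cycle are resolved death-first: the death
    probability applies to everyone in the state, and movement between living
    states applies conditionally to survivors.  This guarantees row sums of 1
    for any in-range inputs.
    """
    inputs = {
        "p_stable_to_hosp (Stable)": p_stable_to_hosp,
        "p_hosp_to_stable (Hospitalized)": p_hosp_to_stable,
        "p_death_stable (Stable)": p_death_stable,
        "p_death_hosp (Hospitalized)": p_death_hosp,
    }
    for name, p in inputs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    psh, phs = p_stable_to_hosp, p_hosp_to_stable
    pds, pdh = p_death_stable, p_death_hosp
    probs = np.array(
        [
            [(1 - pds) * (1 - psh), (1 - pds) * psh, pds],
            [(1 - pdh) * phs, (1 - pdh) * (1 - phs), pdh],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(REFERENCE_STATES, probs)


def run_cohort(
    matrix: TransitionMatrix,
    init: Sequence[float],
    plan: CyclePlan,
) -> CohortTrace:
    """Propagate an initial occupancy vector through ``plan.n_cycles`` cycles.

    Row ``t`` of the returned occupancy equals ``init @ matrix**t``.  The
    per-cycle hospitalization inflow is the mass arriving in ``Hospitalized``
    from any other state during that cycle.
    """
    init = np.asarray(init, dtype=float)
    n = matrix.space.n_states
    if init.shape != (n,):
        raise ValueError(f"init must have {n} entries, got shape {init.shape}")
    if np.any(init < 0) or abs(init.sum() - 1.0) > ROW_SUM_TOL_TRACE:
        raise ValueError(f"init must be a distribution summing to 1, got {init!r}")

    try:
        h = matrix.space.index(HOSPITALIZED)
    except KeyError:
        h = None

    occ = np.empty((plan.n_cycles + 1, n))
    inflow = np.zeros(plan.n_cycles + 1)
    occ[0] = init
    if h is not None:
        inflow[0] = init[h]
    x = init
    col_h = matrix.probs[:, h] if h is not None else None
    for t in range(1, plan.n_cycles + 1):
        if h is not None:
            arriving = x * col_h
            inflow[t] = arriving.sum() - arriving[h]
        x = x @ matrix.probs
        occ[t] = x
    return CohortTrace(matrix.space, occ, inflow, plan.cycle_length)


def half_cycle_correct(trace: CohortTrace) -> np.ndarray:
    """Person-time (years) per state per cycle, trapezoidally corrected.

    Cycle ``t`` contributes ``cycle_length * (occupancy[t-1] + occupancy[t]) / 2``
    — i.e. transitions are credited as happening mid-cycle on average.
    Returns an ``(n_cycles, n_states)`` array.
    """
    occ = trace.occupancy
    return trace.cycle_length * 0.5 * (occ[:-1] + occ[1:])


def discount_factor(annual_rate: float, time: float | np.ndarray):
    """Present-value factor ``(1 + annual_rate) ** (-time)`` at ``time`` years."""
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    if np.any(np.asarray(time) < 0):
        raise ValueError("time must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(time, dtype=float))


def accumulate_payoffs(
    trace: CohortTrace,
    payoffs: StatePayoffs,
    plan: CyclePlan,
) -> EconResult:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Per cycle t (ending at time t * cycle_length, where the discount factor is
    evaluated):

    * cost  = state-time · cost_per_cycle / cycle_length
              + episode_inflow[t] · cost_per_episode
    * QALYs = state-time · utility

    with state-time from :func:`half_cycle_correct`.  The fraction starting in
    ``Hospitalized`` (``episode_inflow[0]``) is charged an episode cost at
    time 0, undiscounted.
    """
    if payoffs.space.states != trace.space.states:
        raise ValueError(
            f"payoff states {payoffs.space.states} do not match trace states {trace.space.states}"
        )
    if trace.n_cycles != plan.n_cycles or trace.cycle_length != plan.cycle_length:
        raise ValueError("trace and plan disagree on cycle structure")

    statetime = half_cycle_correct(trace)  # (n_cycles, n_states), years
    times = plan.cycle_end_times()
    df_cost = discount_factor(plan.annual_discount_rate_costs, times)
    df_eff = discount_factor(plan.annual_discount_rate_effects, times)

    cycle_costs = (
        statetime @ payoffs.cost_vector() / plan.cycle_length
        + trace.episode_inflow[1:] * payoffs.cost_per_episode
    )
    cycle_qalys = statetime @ payoffs.utility_vector()
    cost_at_start = trace.episode_inflow[0] * payoffs.cost_per_episode

    living_idx = [trace.space.index(s) for s in trace.space.living]
    life_years = float(statetime[:, living_idx].sum())

    return EconResult(
        discounted_cost=cost_at_start + float(df_cost @ cycle_costs),
        discounted_qalys=float(df_eff @ cycle_qalys),
        undiscounted_cost=cost_at_start + float(cycle_costs.sum()),
        undiscounted_qalys=float(cycle_qalys.sum()),
        life_years=life_years,
    )
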
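"""Seeded synthetic-data generators.

The published analysis works from a parameter table, not raw data, so this
module provides the two kinds of synthetic input the test surface needs:

* :func:`random_scenario` — valid random two-strategy scenarios inside
  plausible parameter bounds, for property testing of the engine and
  economics layers;
* :func:`simulate_individuals` — individual patient trajectories drawn from
  a known transition matrix, paired with :func:`estimate_transitions`
  (row-wise maximum-likelihood counts) for parameter-recovery testing.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import HOSPITALIZED, REFERENCE_STATES, STABLE, CyclePlan, StateSpace, TransitionMatrix
from .scenarios import Scenario, StrategyParams

__all__ = [
    "DEFAULT_SCENARIO_BOUNDS",
    "TrajectorySet",
    "TransitionEstimate",
    "random_scenario",
    "simulate_individuals",
    "estimate_transitions",
    "trajectories_from_dataframe",
]

#: Plausible ranges for random scenarios: annual hospitalization and death
#: probabilities, monthly discharge, monthly medication cost, per-episode
#: hospitalization cost, stable-state utility and the hospitalized-utility
#: multiplier, per strategy; plus discounting and horizon.  Chosen to span a
#: realistic chronic-heart-failure parameter space around the reference
#: values while keeping every draw a valid model.
DEFAULT_SCENARIO_BOUNDS: dict[str, tuple[float, float]] = {
    "comparator.p_hospitalization_annual": (0.10, 0.50),
    "comparator.p_discharge": (0.40, 0.90),
    "comparator.p_death_annual": (0.02, 0.20),
    "comparator.medication_cost_per_cycle": (20.0, 100.0),
    "comparator.hospitalization_cost_per_episode": (2000.0, 8000.0),
    "comparator.utility_stable": (0.50, 0.95),
    "comparator.hospitalized_utility_multiplier": (0.50, 1.00),
    "intervention.p_hospitalization_annual": (0.10, 0.50),
    "intervention.p_discharge": (0.40, 0.90),
    "intervention.p_death_annual": (0.02, 0.20),
    "intervention.medication_cost_per_cycle": (20.0, 100.0),
    "intervention.hospitalization_cost_per_episode": (2000.0, 8000.0),
    "intervention.utility_stable": (0.50, 0.95),
    "intervention.hospitalized_utility_multiplier": (0.50, 1.00),
    "plan.annual_discount_rate_costs": (0.0, 0.05),
    "plan.annual_discount_rate_effects": (0.0, 0.05),
    "plan.n_cycles": (24, 120),
}

_STRATEGY_FIELDS = (
    "p_hospitalization_annual",
    "p_discharge",
    "p_death_annual",
    "medication_cost_per_cycle",
    "hospitalization_cost_per_episode",
    "utility_stable",
    "hospitalized_utility_multiplier",
)


def random_scenario(
    seed: int,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> Scenario:
    """A valid random scenario with each parameter uniform within its bounds.

    ``bounds`` defaults to :data:`DEFAULT_SCENARIO_BOUNDS`; collapsing every
    bound to a single value reproduces that exact scenario.  Draw order is
    the fixed key order of the default bounds, so a seed fully determines the
    result.
    """
    merged = dict(DEFAULT_SCENARIO_BOUNDS)
    if bounds is not None:
        unknown = set(bounds) - set(merged)
        if unknown:
            raise KeyError(f"unknown bound keys: {sorted(unknown)}")
        merged.update(bounds)
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for key in DEFAULT_SCENARIO_BOUNDS:  # fixed draw order
        lo, hi = merged[key]
        if lo > hi:
            raise ValueError(f"{key}: bound low {lo} exceeds high {hi}")
        if key == "plan.n_cycles":
            values[key] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            values[key] = float(rng.uniform(lo, hi)) if lo < hi else float(lo)

    def strategy(role: str, name: str) -> StrategyParams:
        return StrategyParams(name=name, **{f: values[f"{role}.{f}"] for f in _STRATEGY_FIELDS})

    plan = CyclePlan(
        cycle_length=1.0 / 12.0,
        n_cycles=int(values["plan.n_cycles"]),
        annual_discount_rate_costs=values["plan.annual_discount_rate_costs"],
        annual_discount_rate_effects=values["plan.annual_discount_rate_effects"],
    )
    return Scenario(
        name=f"synthetic-{seed}",
        comparator=strategy("comparator", "A"),
        intervention=strategy("intervention", "B"),
        plan=plan,
    )


@dataclass(frozen=True)
class TrajectorySet:
    """Individual-level state sequences simulated from one transition matrix.

    ``trajectories`` is an ``(n_patients, n_cycles + 1)`` array of state
    indices into ``space.states``; ``episode_counts`` counts each patient's
    entries into ``Hospitalized`` (a patient starting there counts one).
    """

    space: StateSpace
    n_patients: int
    n_cycles: int
    seed: int | None
    trajectories: np.ndarray
    episode_counts: np.ndarray

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectories)
        if traj.shape != (self.n_patients, self.n_cycles + 1):
            raise ValueError(
                f"trajectories shape {traj.shape} does not match "
                f"({self.n_patients}, {self.n_cycles + 1})"
            )
        if traj.min() < 0 or traj.max() >= self.space.n_states:
            raise ValueError("trajectory contains an out-of-range state index")

    def occupancy(self) -> np.ndarray:
        """Empirical state-occupancy fractions, one row per cycle boundary."""
        counts = np.stack(
            [np.bincount(self.trajectories[:, t], minlength=self.space.n_states)
             for t in range(self.n_cycles + 1)]
        )
        return counts / self.n_patients

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: patient_id, cycle, state label."""
        n, t = self.n_patients, self.n_cycles + 1
        labels = np.array(self.space.states)
        return pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(n), t),
                "cycle": np.tile(np.arange(t), n),
                "state": labels[self.trajectories.ravel()],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_individuals(
    matrix: TransitionMatrix,
    n_patients: int,
    n_cycles: int,
    seed: int,
    init_state: str = STABLE,
) -> TrajectorySet:
    """Simulate per-patient state sequences from a known transition matrix.

    Each patient's next state is drawn from the matrix row of their current
    state; absorbing states trap by construction of the matrix.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    space = matrix.space
    rng = np.random.default_rng(seed)
    cum = np.cumsum(matrix.probs, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off at the top end

    traj = np.empty((n_patients, n_cycles + 1), dtype=np.int16)
    traj[:, 0] = space.index(init_state)
    for t in range(1, n_cycles + 1):
        u = rng.random(n_patients)
        traj[:, t] = (cum[traj[:, t - 1]] <= u[:, None]).sum(axis=1)

    try:
        h = space.index(HOSPITALIZED)
        entries = (traj[:, 1:] == h) & (traj[:, :-1] != h)
        episode_counts = entries.sum(axis=1) + (traj[:, 0] == h).astype(int)
    except KeyError:
        episode_counts = np.zeros(n_patients, dtype=int)

    return TrajectorySet(
        space=space,
        n_patients=n_patients,
        n_cycles=n_cycles,
        seed=seed,
        trajectories=traj,
        episode_counts=np.asarray(episode_counts),
    )


@dataclass(frozen=True)
class TransitionEstimate:
    """Row-wise maximum-likelihood transition estimate with per-cell counts.

    ``probs`` rows for states never observed as a transition origin are NaN
    (flagged undetermined, never fabricated); ``counts`` are pooled across
    all cycles (time-homogeneous chain).
    """

    space: StateSpace
    counts: np.ndarray
    probs: np.ndarray

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def determined(self) -> np.ndarray:
        """Boolean per state: was at least one transition out of it observed?"""
        return ~np.isnan(self.probs).any(axis=1)

    def to_matrix(self) -> TransitionMatrix:
        if not self.determined.all():
            missing = [s for s, d in zip(self.space.states, self.determined) if not d]
            raise ValueError(f"rows undetermined for states {missing}; cannot build a matrix")
        return TransitionMatrix(self.space, self.probs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, frm in enumerate(self.space.states):
            for j, to in enumerate(self.space.states):
                rows.append(
                    {
                        "from_state": frm,
                        "to_state": to,
                        "count": int(self.counts[i, j]),
                        "probability": self.probs[i, j],
                    }
                )
        return pd.DataFrame(rows)


def estimate_transitions(trajectories: TrajectorySet, laplace: float = 0.0) -> TransitionEstimate:
    """Estimate the generating matrix from trajectories by pooled counts.

    The estimate for each cell is ``count(from -> to) / count(from)``,
    optionally with a Laplace pseudo-count (default 0: no smoothing).
    """
    if laplace < 0:
        raise ValueError(f"laplace pseudo-count must be >= 0, got {laplace}")
    n_states = trajectories.space.n_states
    traj = trajectories.trajectories
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (traj[:, :-1].ravel(), traj[:, 1:].ravel()), 1)

    smoothed = counts + laplace
    row_totals = smoothed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = smoothed / row_totals[:, None]
    probs[row_totals == 0] = np.nan
    return TransitionEstimate(space=trajectories.space, counts=counts, probs=probs)


def trajectories_from_dataframe(
    df: pd.DataFrame,
    space: StateSpace = REFERENCE_STATES,
) -> TrajectorySet:
    """Rebuild a :class:`TrajectorySet` from its long-format export."""
    required = ["patient_id", "cycle", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing column(s): {missing}")
    unknown = set(df["state"]) - set(space.states)
    if unknown:
        raise ValueError(f"unknown state labels in trajectory table: {sorted(unknown)}")

    wide = (
        df.assign(_idx=[space.index(s) for s in df["state"]])
        .pivot(index="patient_id", columns="cycle", values="_idx")
        .sort_index()
    )
    if wide.isna().any().any():
        raise ValueError("trajectory table has missing (patient, cycle) entries")
    traj = wide.to_numpy(dtype=np.int16)
    n_patients, n_boundaries = traj.shape
    try:
        h = space.index(HOSPITALIZED)
        entries = (traj[:, 1:] == h) & (traj[:, :-1] != h)
        episode_counts = entries.sum(axis=1) + (traj[:, 0] == h).astype(int)
    except KeyError:
        episode_counts = np.zeros(n_patients, dtype=int)
    return TrajectorySet(
        space=space,
        n_patients=n_patients,
        n_cycles=n_boundaries - 1,
        seed=None,
        trajectories=traj,
        episode_counts=np.asarray(episode_counts),
    )
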
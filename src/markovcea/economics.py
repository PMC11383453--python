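"""Incremental cost-effectiveness analysis between two strategies.

Implements the standard decision rules: incremental cost and effect
differences, the incremental cost-effectiveness ratio (ICER = ΔCost/ΔQALY),
four-quadrant dominance classification, net monetary benefit
(NMB = λ·ΔQALY − ΔCost) and the cost-effectiveness acceptability curve
(CEAC) derived from probabilistic sensitivity-analysis samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import EconResult

__all__ = [
    "Dominance",
    "IncrementalResult",
    "CEACCurve",
    "DEFAULT_WTP_GRID",
    "incremental",
    "report_icer",
    "net_monetary_benefit",
    "ceac",
]

#: Default willingness-to-pay grid: $0–$100,000 per QALY in $1,000 steps.
DEFAULT_WTP_GRID = np.arange(0, 100_001, 1000, dtype=float)


class Dominance(str, Enum):
    """Four-quadrant classification of an incremental comparison."""

    INTERVENTION_DOMINANT = "intervention_dominant"  # cheaper-or-equal and better
    COMPARATOR_DOMINANT = "comparator_dominant"      # costlier-or-equal and worse
    TRADE_OFF = "trade_off"                          # more costly & more effective (or the mirror)
    EQUAL = "equal"


@dataclass(frozen=True)
class IncrementalResult:
    """ΔCost, ΔQALY, ICER and dominance for intervention vs comparator.

    ``icer`` is ``None`` unless the comparison is a genuine trade-off
    (both differences non-zero and of the same sign).
    """

    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: Dominance


def _totals(result) -> tuple[float, float]:
    """Accept an EconResult (discounted totals) or a plain (cost, qalys) pair."""
    if isinstance(result, EconResult):
        return result.discounted_cost, result.discounted_qalys
    cost, qalys = result
    return float(cost), float(qalys)


def incremental(comparator, intervention) -> IncrementalResult:
    """Incremental analysis of ``intervention`` against ``comparator``.

    Either argument may be an :class:`~markovcea.engine.EconResult` or a plain
    ``(cost, qalys)`` pair (useful for published summary tables).
    """
    c_cost, c_eff = _totals(comparator)
    i_cost, i_eff = _totals(intervention)
    dc = i_cost - c_cost
    de = i_eff - c_eff

    if dc == 0.0 and de == 0.0:
        dom = Dominance.EQUAL
    elif de >= 0.0 and dc <= 0.0:
        dom = Dominance.INTERVENTION_DOMINANT
    elif de <= 0.0 and dc >= 0.0:
        dom = Dominance.COMPARATOR_DOMINANT
    else:
        dom = Dominance.TRADE_OFF

    icer = dc / de if dom is Dominance.TRADE_OFF else None
    return IncrementalResult(delta_cost=dc, delta_qalys=de, icer=icer, dominance=dom)


def report_icer(result, nearest: int = 1) -> int:
    """ΔCost/ΔQALY rounded half-up to the nearest ``nearest`` dollars.

    For tabulation the ratio is reported whenever ΔQALY ≠ 0, including in
    dominance quadrants where the decision-analytic ICER is undefined;
    dominance itself is carried separately by :class:`IncrementalResult`.
    """
    if isinstance(result, IncrementalResult):
        dc, de = result.delta_cost, result.delta_qalys
    else:
        dc, de = result
    if de == 0:
        raise ValueError("ICER undefined: delta_qalys is 0")
    if nearest < 1:
        raise ValueError("nearest must be a positive number of dollars")
    ratio = Decimal(repr(float(dc))) / Decimal(repr(float(de))) / nearest
    return int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP)) * nearest


def net_monetary_benefit(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """NMB = wtp · ΔQALY − ΔCost; positive means cost-effective at ``wtp``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * delta_qalys - delta_cost


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is cost-effective over a WTP grid.

    The two probabilities sum to 1 at every threshold; ties (NMB exactly 0)
    are assigned to the comparator, the lower-cost incumbent.
    """

    wtp_grid: np.ndarray
    prob_cost_effective: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        grid.setflags(write=False)
        object.__setattr__(self, "wtp_grid", grid)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.wtp_grid})
        for label, probs in self.prob_cost_effective.items():
            df[f"prob_{label}"] = probs
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ceac(
    psa_samples: Sequence[IncrementalResult] | Iterable[IncrementalResult],
    wtp_grid: np.ndarray | None = None,
    intervention_label: str = "intervention",
    comparator_label: str = "comparator",
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA incremental samples.

    At each threshold λ the intervention's probability is the fraction of
    samples with strictly positive NMB(λ); samples with NMB exactly 0 count
    for the comparator.
    """
    samples = list(psa_samples)
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wtp_grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    if np.any(grid < 0):
        raise ValueError("wtp_grid thresholds must be >= 0")

    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_qalys for s in samples])
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    p_int = (nmb > 0).mean(axis=1)
    return CEACCurve(
        wtp_grid=grid,
        prob_cost_effective={intervention_label: p_int, comparator_label: 1.0 - p_int},
    )
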
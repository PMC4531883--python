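"""Monetary arithmetic: inflation, discounting, ICERs, dominance and NMB.

All internal arithmetic is full precision; rounding to whole euros happens
only at the reporting boundary (and in :func:`inflate_cost`, whose output
is itself a reported model input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .cohort import ArmOutcome

__all__ = [
    "Dominance",
    "IncrementalResult",
    "round_euro",
    "inflate_cost",
    "discount_factor",
    "incremental",
    "net_monetary_benefit",
]


class Dominance(str, Enum):
    """Quadrant classification of an incremental cost/effect pair."""

    TRADE_OFF = "trade-off"   # more effective & more costly (or less & less)
    DOMINANT = "dominant"     # at least as cheap and strictly more effective
    DOMINATED = "dominated"   # at least as costly and no more effective
    UNDEFINED = "undefined"   # zero incremental cost and effect


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost (IC), effect (IE), their ratio and dominance class.

    ``icer`` is None when the incremental effect is zero (division guard);
    sign conventions follow the cost-effectiveness plane with the
    intervention minus the comparator.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: Dominance

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None


def round_euro(x: float) -> int:
    """Round to the nearest whole euro, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (-1 if x < 0 else 1)


def inflate_cost(base_cost: float, annual_rate: float, n_years: int) -> int:
    """Compound a past cost to the target price year, rounded to whole euros.

    E.g. 2005 annual care costs inflated over 9 years at 2.9 %/yr give
    the 2014 values used as model defaults.
    """
    if base_cost < 0:
        raise ValueError("base_cost must be non-negative")
    if n_years < 0:
        raise ValueError("n_years must be non-negative")
    return round_euro(base_cost * (1.0 + annual_rate) ** n_years)


def discount_factor(r: float, t: int) -> float:
    """Present-value factor 1/(1+r)^t for cycle t at annual rate r."""
    if r < 0 or t < 0:
        raise ValueError("rate and cycle index must be non-negative")
    return (1.0 + r) ** -t


def _classify(ic: float, ie: float) -> Dominance:
    if ie == 0.0 and ic == 0.0:
        return Dominance.UNDEFINED
    if ie > 0.0 and ic <= 0.0:
        return Dominance.DOMINANT
    if ie <= 0.0 and ic >= 0.0:
        return Dominance.DOMINATED
    return Dominance.TRADE_OFF


def incremental(avd: ArmOutcome | float, bsc: ArmOutcome | float,
                *, avd_qaly: float | None = None,
                bsc_qaly: float | None = None) -> IncrementalResult:
    """Incremental result of intervention vs comparator.

    Accepts either two :class:`~visioncea.cohort.ArmOutcome` objects or raw
    ``(cost, qaly)`` numbers via the keyword form
    ``incremental(cost_avd, cost_bsc, avd_qaly=..., bsc_qaly=...)``.
    """
    if isinstance(avd, ArmOutcome) and isinstance(bsc, ArmOutcome):
        ic = avd.discounted_cost - bsc.discounted_cost
        ie = avd.discounted_qaly - bsc.discounted_qaly
    else:
        if avd_qaly is None or bsc_qaly is None:
            raise TypeError("raw form requires avd_qaly and bsc_qaly keywords")
        ic = float(avd) - float(bsc)
        ie = avd_qaly - bsc_qaly
    icer = ic / ie if ie != 0.0 else None
    return IncrementalResult(
        delta_cost=ic, delta_effect=ie, icer=icer, dominance=_classify(ic, ie)
    )


def net_monetary_benefit(wtp: float, inc: IncrementalResult) -> float:
    """Net monetary benefit lambda * IE - IC at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * inc.delta_effect - inc.delta_cost
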
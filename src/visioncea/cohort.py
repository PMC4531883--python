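"""Three-state Markov cohort engine with yearly cycles.

States are 'Blind', 'Visual Impaired' (VIMP) and 'Death'.  Under the
artificial-vision-device (AVD) arm a fixed fraction of the cohort — the
responder rate — moves from Blind to VIMP at model entry (the device is
implanted at cycle 0) and stays there until death; under best supportive
care (BSC) nobody leaves Blind except by dying.  Mortality comes from the
life table alone and is identical across states and arms.

Costs and quality-adjusted life-years accrue at the start of each cycle
for the occupants alive at that cycle, discounted by 1/(1+r)^t with cycle
0 undiscounted.  An optional half-cycle correction (off by default)
averages adjacent-cycle occupancies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .life_tables import LifeTable

__all__ = [
    "Arm",
    "ModelParams",
    "Trace",
    "ArmOutcome",
    "STATES",
    "initial_state",
    "step",
    "run_cohort",
]

Arm = Literal["AVD", "BSC"]
Horizon = int | Literal["lifetime"]

#: State ordering used by every occupancy vector in the package.
STATES = ("Blind", "Visual Impaired", "Death")

#: Alive-fraction floor below which a lifetime run stops early.
_ALIVE_EPS = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """One complete deterministic parameterization of the two-arm model.

    Monetary amounts are EUR at 2014 prices; utilities are dimensionless
    annual quality weights in [0, 1].  'Death' carries zero cost and zero
    utility by construction and is not configurable.
    """

    start_age: int = 51
    horizon: Horizon = "lifetime"
    discount_costs: float = 0.03
    discount_effects: float = 0.03
    cost_blind: float = 4091.0
    cost_vimp: float = 3680.0
    utility_blind: float = 0.61
    utility_vimp: float = 0.77
    avd_first_year_cost: float = 85_000.0
    avd_followup_cost: float = 1_500.0
    responder_rate: float = 0.625
    half_cycle_correction: bool = False
    #: If False, annual follow-up cost applies only to responders rather
    #: than to every surviving AVD patient. Default True: follow-up effort
    #: (training, device upkeep) is device-linked, not response-linked.
    followup_all_alive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_rate <= 1.0:
            raise ValueError(f"responder_rate must be in [0, 1], got {self.responder_rate}")
        for name in ("utility_blind", "utility_vimp"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {u}")
        for name in ("cost_blind", "cost_vimp", "avd_first_year_cost", "avd_followup_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("discount_costs", "discount_effects"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.horizon != "lifetime":
            if not isinstance(self.horizon, int) or self.horizon < 1:
                raise ValueError("horizon must be 'lifetime' or a positive integer")

    def with_(self, **overrides) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class Trace:
    """Per-cycle state occupancy of one cohort run."""

    arm: str
    cycles: np.ndarray        # cycle index, 0-based years since entry
    ages: np.ndarray          # integer age at each cycle start
    occupancy: np.ndarray     # shape (n_cycles, 3) over STATES

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, 0] + self.occupancy[:, 1]


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm under one parameter set."""

    arm: str
    discounted_cost: float
    discounted_qaly: float
    life_years: float  # undiscounted expected life-years (cycle-start accrual)


def initial_state(arm: Arm, responder_rate: float) -> np.ndarray:
    """Cycle-0 occupancy over (Blind, VIMP, Death).

    AVD responders occupy VIMP from entry; BSC cohorts start — and stay —
    entirely Blind.
    """
    if not 0.0 <= responder_rate <= 1.0:
        raise ValueError(f"responder_rate must be in [0, 1], got {responder_rate}")
    if arm == "AVD":
        return np.array([1.0 - responder_rate, responder_rate, 0.0])
    if arm == "BSC":
        return np.array([1.0, 0.0, 0.0])
    raise ValueError(f"unknown arm {arm!r}; expected 'AVD' or 'BSC'")


def step(occupancy: np.ndarray, qx_t: float) -> np.ndarray:
    """Advance one yearly cycle: each alive state loses fraction qx_t to Death.

    There is no Blind<->VIMP movement after cycle 0: vision response is
    assumed permanent and blindness incurable.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if not 0.0 <= qx_t <= 1.0:
        raise ValueError(f"death probability must be in [0, 1], got {qx_t}")
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    blind, vimp, dead = occupancy
    return np.array([
        blind * (1.0 - qx_t),
        vimp * (1.0 - qx_t),
        dead + (blind + vimp) * qx_t,
    ])


def _cycle_weights(occ: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Per-cycle accrual occupancies: start-of-cycle, or adjacent-cycle means."""
    if not half_cycle:
        return occ
    nxt = np.vstack([occ[1:], occ[-1]])
    return 0.5 * (occ + nxt)


def run_cohort(params: ModelParams, lt: LifeTable, arm: Arm) -> tuple[Trace, ArmOutcome]:
    """Run the cohort trace for one arm and accrue discounted outcomes.

    The trace is built by repeated :func:`step` with the life-table death
    probability at age ``start_age + t``.  It stops at the configured
    horizon, at the terminal table age, or when the alive fraction drops
    below 1e-9.

    Cost accrual per cycle: state costs times occupancy; the AVD arm
    additionally pays the first-year device cost at cycle 0 (undiscounted)
    and the annual follow-up cost from cycle 1 onward — by default for
    every surviving patient, optionally for responders only.
    """
    if not lt.min_age <= params.start_age <= lt.max_age:
        raise ValueError(
            f"start_age {params.start_age} outside life-table range "
            f"[{lt.min_age}, {lt.max_age}]"
        )
    max_cycles = lt.max_age - params.start_age + 1
    n_cycles = max_cycles if params.horizon == "lifetime" else min(params.horizon, max_cycles)

    occ = initial_state(arm, params.responder_rate)
    rows = [occ]
    for t in range(1, n_cycles):
        if rows[-1][0] + rows[-1][1] < _ALIVE_EPS:
            break
        occ = step(rows[-1], lt.qx_at(params.start_age + t - 1))
        rows.append(occ)
    occ_arr = np.vstack(rows)
    cycles = np.arange(len(rows))
    trace = Trace(
        arm=arm,
        cycles=cycles,
        ages=params.start_age + cycles,
        occupancy=occ_arr,
    )

    w = _cycle_weights(occ_arr, params.half_cycle_correction)
    blind, vimp = w[:, 0], w[:, 1]
    alive = blind + vimp
    disc_c = (1.0 + params.discount_costs) ** -cycles.astype(float)
    disc_e = (1.0 + params.discount_effects) ** -cycles.astype(float)

    state_costs = params.cost_blind * blind + params.cost_vimp * vimp
    cost = float(np.sum(state_costs * disc_c))
    if arm == "AVD":
        cost += params.avd_first_year_cost  # paid once at cycle 0, factor 1
        payers = alive if params.followup_all_alive else vimp
        if len(cycles) > 1:
            cost += params.avd_followup_cost * float(np.sum(payers[1:] * disc_c[1:]))

    qaly = float(np.sum(
        (params.utility_blind * blind + params.utility_vimp * vimp) * disc_e
    ))
    life_years = float(np.sum(alive))

    return trace, ArmOutcome(
        arm=arm, discounted_cost=cost, discounted_qaly=qaly, life_years=life_years
    )


def run_both_arms(params: ModelParams, lt: LifeTable) -> dict[str, ArmOutcome]:
    """Convenience: run AVD and BSC under one parameter set."""
    return {arm: run_cohort(params, lt, arm)[1] for arm in ("AVD", "BSC")}
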
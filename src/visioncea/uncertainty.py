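"""Sensitivity machinery: PSA, CEAC, one-way tornado DSA and scenario grids.

The probabilistic sensitivity analysis (PSA) draws cost and utility inputs
from independent normal distributions (standard deviation 10 % of the mean),
the starting age from Normal(51.1, 5.3) rounded to an integer year, and
holds the responder rate and discount rates fixed.  Draws are clamped to
their natural bounds (costs >= 0, utilities in [0, 1]).

"Confidence intervals" of the PSA summaries are empirical 2.5th/97.5th
percentiles of the iteration distribution, not normal approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ModelParams, run_cohort
from .economics import IncrementalResult, incremental, net_monetary_benefit
from .life_tables import LifeTable

__all__ = [
    "DistributionSpec",
    "PsaResult",
    "CeacPoint",
    "TornadoEntry",
    "ScenarioCell",
    "default_specs",
    "sample_params",
    "run_psa",
    "ceac",
    "default_dsa_ranges",
    "one_way_dsa",
    "scenario_grid",
    "count_below_threshold",
    "DEFAULT_RR_SCENARIOS",
    "DEFAULT_FIRST_YEAR_COSTS",
]

#: Responder-rate scenario values (proportions).
DEFAULT_RR_SCENARIOS = (0.25, 0.50, 0.625, 0.75, 1.00)
#: First-year device cost scenario values (EUR).
DEFAULT_FIRST_YEAR_COSTS = (55_000.0, 70_000.0, 85_000.0, 100_000.0, 115_000.0)

#: ModelParams fields a PSA draws or fixes; used for spec completeness checks.
_SAMPLED_FIELDS = (
    "start_age",
    "cost_blind",
    "cost_vimp",
    "utility_blind",
    "utility_vimp",
    "avd_first_year_cost",
    "avd_followup_cost",
    "responder_rate",
    "discount_costs",
    "discount_effects",
)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling spec for one model parameter.

    ``kind`` is ``"fixed"`` (draws equal the mean) or ``"normal"``; draws
    are clamped into ``[lower, upper]``.
    """

    name: str
    kind: str  # "fixed" | "normal"
    mean: float
    sd: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed" or self.sd == 0.0:
            # consume a variate either way so the stream layout is stable
            rng.normal()
            value = self.mean
        else:
            value = rng.normal(self.mean, self.sd)
        return float(np.clip(value, self.lower, self.upper))


def default_specs(base: ModelParams, lt: LifeTable) -> dict[str, DistributionSpec]:
    """Base-case distribution specs keyed by ModelParams field name.

    Costs and utilities get normal distributions with sd = 10 % of the
    mean; starting age gets Normal(51.1, 5.3) rounded downstream; the
    responder rate and both discount rates are fixed point estimates.
    """
    p = base
    return {
        "start_age": DistributionSpec(
            "start_age", "normal", 51.1, 5.3, lower=18, upper=lt.max_age - 1
        ),
        "cost_blind": DistributionSpec(
            "cost_blind", "normal", p.cost_blind, 0.1 * p.cost_blind, lower=0.0
        ),
        "cost_vimp": DistributionSpec(
            "cost_vimp", "normal", p.cost_vimp, 0.1 * p.cost_vimp, lower=0.0
        ),
        "utility_blind": DistributionSpec(
            "utility_blind", "normal", p.utility_blind, 0.1 * p.utility_blind,
            lower=0.0, upper=1.0,
        ),
        "utility_vimp": DistributionSpec(
            "utility_vimp", "normal", p.utility_vimp, 0.1 * p.utility_vimp,
            lower=0.0, upper=1.0,
        ),
        "avd_first_year_cost": DistributionSpec(
            "avd_first_year_cost", "normal", p.avd_first_year_cost,
            0.1 * p.avd_first_year_cost, lower=0.0,
        ),
        "avd_followup_cost": DistributionSpec(
            "avd_followup_cost", "normal", p.avd_followup_cost,
            0.1 * p.avd_followup_cost, lower=0.0,
        ),
        "responder_rate": DistributionSpec(
            "responder_rate", "fixed", p.responder_rate, lower=0.0, upper=1.0
        ),
        "discount_costs": DistributionSpec(
            "discount_costs", "fixed", p.discount_costs, lower=0.0
        ),
        "discount_effects": DistributionSpec(
            "discount_effects", "fixed", p.discount_effects, lower=0.0
        ),
    }


def sample_params(
    specs: dict[str, DistributionSpec],
    rng: np.random.Generator,
    template: ModelParams | None = None,
) -> ModelParams:
    """Draw one ModelParams realization from the given specs.

    The starting age is rounded to the nearest integer year after drawing
    (the life table is integer-indexed) and clamped to the spec bounds.
    Non-sampled fields (horizon, accrual switches) come from ``template``.
    """
    missing = [f for f in _SAMPLED_FIELDS if f not in specs]
    if missing:
        raise KeyError(f"missing distribution specs for: {', '.join(missing)}")
    template = template or ModelParams()
    values: dict[str, float | int] = {}
    for name in _SAMPLED_FIELDS:  # fixed order => reproducible stream
        spec = specs[name]
        v = spec.draw(rng)
        if name == "start_age":
            v = int(np.clip(round(v), spec.lower, spec.upper))
        values[name] = v
    return template.with_(**values)


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration PSA outcomes plus summary statistics.

    ``iterations`` has one row per Monte-Carlo draw with per-arm discounted
    costs and QALYs and their increments; ``summary`` holds mean, sample SD
    and empirical 2.5/97.5 percentiles per quantity.
    """

    iterations: pd.DataFrame
    summary: pd.DataFrame
    n_iter: int
    seed: int

    @property
    def delta_costs(self) -> np.ndarray:
        return self.iterations["inc_cost"].to_numpy()

    @property
    def delta_effects(self) -> np.ndarray:
        return self.iterations["inc_qaly"].to_numpy()

    def mean_incremental(self) -> IncrementalResult:
        """Incremental result of the mean costs and effects over iterations."""
        m = self.iterations.mean()
        return incremental(
            m["avd_cost"], m["bsc_cost"], avd_qaly=m["avd_qaly"], bsc_qaly=m["bsc_qaly"]
        )


_PSA_COLUMNS = ("avd_cost", "bsc_cost", "inc_cost", "avd_qaly", "bsc_qaly", "inc_qaly")


def _summarize(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1),
        "p2.5": df.quantile(0.025),
        "p97.5": df.quantile(0.975),
    })


def run_psa(
    specs: dict[str, DistributionSpec],
    lt: LifeTable,
    n_iter: int = 1000,
    seed: int = 0,
    template: ModelParams | None = None,
) -> PsaResult:
    """Monte-Carlo PSA: sample, run both arms, store increments, summarize."""
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iter, len(_PSA_COLUMNS)))
    for i in range(n_iter):
        params = sample_params(specs, rng, template=template)
        _, avd = run_cohort(params, lt, "AVD")
        _, bsc = run_cohort(params, lt, "BSC")
        rows[i] = (
            avd.discounted_cost,
            bsc.discounted_cost,
            avd.discounted_cost - bsc.discounted_cost,
            avd.discounted_qaly,
            bsc.discounted_qaly,
            avd.discounted_qaly - bsc.discounted_qaly,
        )
    iters = pd.DataFrame(rows, columns=list(_PSA_COLUMNS))
    iters.index.name = "iteration"
    return PsaResult(iterations=iters, summary=_summarize(iters), n_iter=n_iter, seed=seed)


@dataclass(frozen=True)
class CeacPoint:
    """One cost-effectiveness acceptability curve point."""

    wtp: float
    probability: float


def ceac(psa: PsaResult, wtps: list[float] | np.ndarray) -> list[CeacPoint]:
    """Probability of cost-effectiveness per willingness-to-pay threshold.

    The probability at lambda is the fraction of iterations with strictly
    positive net monetary benefit lambda * dE - dC; ties count as not
    cost-effective.
    """
    wtps = np.asarray(wtps, dtype=float)
    if wtps.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    de = psa.delta_effects
    dc = psa.delta_costs
    return [
        CeacPoint(wtp=float(w), probability=float(np.mean(w * de - dc > 0.0)))
        for w in wtps
    ]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low_setting: object
    high_setting: object
    icer_low: float | None
    icer_high: float | None
    spread: float

    @staticmethod
    def from_icers(parameter, low_setting, high_setting, icer_low, icer_high):
        spread = (
            abs(icer_high - icer_low)
            if icer_low is not None and icer_high is not None
            else float("nan")
        )
        return TornadoEntry(parameter, low_setting, high_setting, icer_low, icer_high, spread)


def default_dsa_ranges(base: ModelParams) -> dict[str, tuple[object, object]]:
    """Default one-way ranges bracketing the base case.

    Parameters with a sampling distribution vary by +-1 SD (the 10 %-of-mean
    spread the PSA itself assumes); the responder rate spans its scenario
    extremes {25 %, 100 %}, the first-year device cost {55k, 115k} EUR, the
    horizon {10 years, lifetime} and each discount rate {0 %, 5 %}.
    """
    p = base
    return {
        "responder_rate": (0.25, 1.00),
        "start_age": (round(51.1 - 5.3), round(51.1 + 5.3)),
        "horizon": (10, "lifetime"),
        "utility_blind": (0.9 * p.utility_blind, 1.1 * p.utility_blind),
        "utility_vimp": (0.9 * p.utility_vimp, 1.1 * p.utility_vimp),
        "avd_followup_cost": (0.9 * p.avd_followup_cost, 1.1 * p.avd_followup_cost),
        "discount_costs": (0.0, 0.05),
        "discount_effects": (0.0, 0.05),
        "avd_first_year_cost": (55_000.0, 115_000.0),
        "cost_blind": (0.9 * p.cost_blind, 1.1 * p.cost_blind),
        "cost_vimp": (0.9 * p.cost_vimp, 1.1 * p.cost_vimp),
    }


def _deterministic_icer(params: ModelParams, lt: LifeTable) -> float | None:
    _, avd = run_cohort(params, lt, "AVD")
    _, bsc = run_cohort(params, lt, "BSC")
    return incremental(avd, bsc).icer


def _brackets(low, high, base) -> bool:
    if "lifetime" in (low, high) or base == "lifetime":
        return True  # horizon switch: ordering not numeric
    return low <= base <= high


def one_way_dsa(
    base: ModelParams,
    lt: LifeTable,
    ranges: dict[str, tuple[object, object]] | None = None,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis (tornado).

    Re-runs the deterministic model at the low and high setting of each
    parameter with everything else at base, and sorts entries by the
    absolute ICER spread, descending.
    """
    ranges = ranges if ranges is not None else default_dsa_ranges(base)
    entries = []
    for name, (low, high) in ranges.items():
        if not _brackets(low, high, getattr(base, name)):
            raise ValueError(
                f"range ({low}, {high}) for {name!r} does not bracket base "
                f"value {getattr(base, name)!r}"
            )
        icer_low = _deterministic_icer(base.with_(**{name: low}), lt)
        icer_high = _deterministic_icer(base.with_(**{name: high}), lt)
        entries.append(TornadoEntry.from_icers(name, low, high, icer_low, icer_high))
    entries.sort(key=lambda e: (not np.isnan(e.spread), e.spread), reverse=True)
    return entries


@dataclass(frozen=True)
class ScenarioCell:
    """One responder-rate x first-year-cost grid cell."""

    responder_rate: float
    first_year_cost: float
    delta_cost: float
    delta_effect: float
    icer: float | None


def scenario_grid(
    rr_values=DEFAULT_RR_SCENARIOS,
    first_year_costs=DEFAULT_FIRST_YEAR_COSTS,
    params: ModelParams | None = None,
    lt: LifeTable | None = None,
    mode: str = "deterministic",
    n_iter: int = 1000,
    seed: int = 0,
) -> list[ScenarioCell]:
    """Evaluate every (responder rate, first-year cost) combination.

    Cells are deterministic runs by default; ``mode="psa"`` instead reports
    mean increments over a Monte-Carlo PSA with the two scenario parameters
    held fixed (each cell gets an independent sub-seed).
    """
    if lt is None:
        raise ValueError("a life table is required")
    if not len(rr_values) or not len(first_year_costs):
        raise ValueError("scenario value lists must be non-empty")
    if mode not in ("deterministic", "psa"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or ModelParams()
    cells = []
    for k, cost in enumerate(first_year_costs):
        for j, rr in enumerate(rr_values):
            p = params.with_(responder_rate=rr, avd_first_year_cost=cost)
            if mode == "deterministic":
                _, avd = run_cohort(p, lt, "AVD")
                _, bsc = run_cohort(p, lt, "BSC")
                inc = incremental(avd, bsc)
            else:
                specs = default_specs(p, lt)
                specs["responder_rate"] = DistributionSpec(
                    "responder_rate", "fixed", rr, lower=0.0, upper=1.0
                )
                specs["avd_first_year_cost"] = DistributionSpec(
                    "avd_first_year_cost", "fixed", cost, lower=0.0
                )
                sub_seed = (seed + 1009 * (k * len(rr_values) + j)) % (2**31)
                inc = run_psa(specs, lt, n_iter=n_iter, seed=sub_seed,
                              template=p).mean_incremental()
            cells.append(ScenarioCell(
                responder_rate=rr,
                first_year_cost=cost,
                delta_cost=inc.delta_cost,
                delta_effect=inc.delta_effect,
                icer=inc.icer,
            ))
    return cells


def count_below_threshold(cells: list[ScenarioCell], wtp: float) -> int:
    """Number of scenario cells with a defined ICER strictly below ``wtp``."""
    return sum(1 for c in cells if c.icer is not None and c.icer < wtp)
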
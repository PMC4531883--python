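# Methods

## Model structure and assumptions

The engine is a three-state Markov cohort model with yearly cycles:
*Blind*, *Visual Impaired* (VIMP), *Death*. Transitions are minimal by
design:

- **Response at entry.** The artificial-vision-device (AVD) arm places the
  responder fraction in VIMP at cycle 0 — the first-year device cost
  covers device, implantation and rehabilitation, so treatment happens at
  model entry. Response is permanent: responders stay in VIMP until death.
  The comparator (best supportive care, BSC) cohort starts and remains in
  Blind; blindness from advanced retinitis pigmentosa is incurable.
- **Mortality.** The only other transition is into the absorbing Death
  state, with the life-table probability `qx(age)` applied identically to
  both alive states and both arms (no excess mortality from blindness or
  from surgery is modelled). Death carries zero cost and zero utility,
  not configurable.

Consequences worth knowing: the model is *linear* in the responder rate,
in every utility and in every cost, so
`ΔE = RR · (u_VIMP − u_Blind) · DLE(age₀, r_e)` holds exactly, where DLE
is the discounted life expectancy under the same accrual convention. The
test suite uses this identity, plus geometric-series closed forms under a
constant-`qx` table, as independent oracles for the trace engine.

## Accrual and discounting conventions

Costs and QALYs accrue at the **start of each cycle** for the occupants
alive at that cycle; cycle 0 is undiscounted (factor 1) and cycle *t* is
discounted by `1/(1+r)^t`. No half-cycle correction is applied by default;
`ModelParams(half_cycle_correction=True)` switches to averaging
adjacent-cycle occupancies for exploration. The source analysis does not
state its convention, and its printed scenario values carry Monte-Carlo
noise, so the choice cannot be settled empirically; cycle-start accrual
was chosen because it makes the linearity identity exact and the
first-year device cost land undiscounted at cycle 0 with slope exactly 1
in the incremental cost.

The annual AVD follow-up cost applies from cycle 1 onward to **all
surviving AVD patients**, responders or not: follow-up effort (training,
device upkeep) is device-linked, not response-linked. A
`followup_all_alive=False` switch restricts it to responders.

A *lifetime* horizon runs until the terminal table age (the cohort closes
because terminal `qx` is forced to 1); an integer horizon of *n* years
accrues exactly *n* cycles. Early exit also triggers when the alive
fraction drops below 1e-9.

## Parameters

| Parameter | Default | Units | Note |
|---|---|---|---|
| start_age | 51 | years | deterministic runs; the PSA samples Normal(51.1, 5.3) rounded to whole years |
| cost_blind / cost_vimp | 4,091 / 3,680 | EUR-2014 per year | 2005 values 3,163 / 2,845 inflated 9 years at 2.9 %/yr |
| utility_blind / utility_vimp | 0.61 / 0.77 | — | annual quality weights |
| avd_first_year_cost | 85,000 | EUR-2014 | scenario values 55k–115k |
| avd_followup_cost | 1,500 | EUR-2014 per year | from cycle 1 |
| responder_rate | 0.625 | proportion | scenario values 0.25–1.00 |
| discount_costs / discount_effects | 0.03 | per year | arm-independent |
| horizon | lifetime | — | or integer years |

All monetary outputs are labelled EUR-2014; the inflation step makes the
price year load-bearing. Whole-euro rounding (half away from zero)
happens only at the reporting boundary and in `inflate_cost`, whose
output is itself a quoted model input.

## Synthetic life table

The national period life table behind the original mortality schedule is
not deposited in any machine-readable form, so the package generates a
Gompertz–Makeham stand-in: `qx(age) = 1 − exp(−(c + a·e^{b·age}))` on
integer ages 18–110, terminal `qx` forced to 1. The frozen constants

```
a = 2.384e-05, b = 0.095, c = 0.0008
```

were calibrated once so that the discounted life expectancy from age 51
at 3 %/yr is ≈ 20.15 years — the midpoint of the 20.0–20.3 range implied
by the linearity identity applied to the reported incremental QALYs
(2.03 = 0.625·0.16·DLE ⇒ 20.3; 3.20 = 1.00·0.16·DLE ⇒ 20.0). The implied
undiscounted life expectancy (≈ 32 years from 51) and the qx profile
(0.004 at 51, 0.047 at 80) are plausible for a contemporary Western
European population. What the generator does **not** emulate: sex
stratification, period-vs-cohort effects, old-age mortality plateaus, or
year-of-edition differences. A green calibration test therefore
establishes that the pipeline reproduces the *structure* and the
*arithmetic* of the analysis under a realistic mortality schedule, not
that it reproduces the exact published totals — those are checked as
ranges (e.g. base-case ΔE within 1.90–2.13) and orderings instead, while
everything that is pure arithmetic on printed inputs (inflation, ICERs,
threshold counts) is checked exactly.

## Probabilistic sensitivity analysis

Costs and utilities draw from independent normal distributions with
SD = 10 % of the mean; draws clamp to natural bounds (costs ≥ 0,
utilities in [0, 1]). Starting age draws from Normal(51.1, 5.3), rounds
to the nearest integer year (the table is integer-indexed) and clamps to
[18, max_age − 1]. The responder rate and both discount rates stay fixed
— they are decision variables and policy conventions, not estimable
quantities, and carry no dispersion in the input table. Each spec draws
one variate even when fixed so the random stream layout (and hence
seed-for-seed reproducibility) is independent of which parameters vary.

Interval summaries are **empirical 2.5/97.5 percentiles** of the
iteration distribution rather than normal approximations: the quantities
are ratios and products of normals and visibly asymmetric. The mean ICER
is reported as the ratio of mean increments; the per-iteration ICER
distribution is heavy-tailed (iterations with ΔE near zero) and its SD is
not a meaningful summary, so it is not reported.

The acceptability curve (CEAC) counts iterations with strictly positive
net monetary benefit; ties — probability-zero events under continuous
draws — count as not cost-effective.

## One-way sensitivity (tornado)

Each parameter is set to its low and high value with everything else at
base, and entries sort by absolute ICER spread. Default ranges: mean
± 1 SD (i.e. ± 10 % of the mean) for parameters with a sampling
distribution; the scenario extremes {25 %, 100 %} for the responder rate
and {€55k, €115k} for the first-year cost; {10 years, lifetime} for the
horizon; {0 %, 5 %} for each discount rate. The ± 1 SD choice (rather
than, say, a 95 % interval) keeps the one-way ranges on the same "10 % of
the mean" scale the probabilistic analysis itself declares reasonable; at
± 1.96 SD the utility-difference range collapses toward zero at one end
and the utility bars would implausibly dwarf the responder-rate bar,
contradicting the documented ranking in which the responder rate has the
strongest influence. Ranges are caller-overridable.

## Scenario grid

The 5 × 5 responder-rate × first-year-cost grid is evaluated
**deterministically** by default: each cell is one model run, giving a
clean, noise-free acceptance surface (ICERs strictly increase along the
cost axis and strictly decrease along the responder axis). A
`mode="psa"` flag instead reports mean increments over a Monte-Carlo run
with the two scenario parameters held fixed, reproducing the original
procedure — whose printed per-cell effects wobble slightly around exact
linearity, consistent with 1,000-iteration means. Threshold counting
uses strict inequality (ICER < λ).

## Numerical choices and degenerate inputs

- Occupancy vectors are validated to sum to 1 within 1e-9 on entry to
  `step`; traces conserve mass to 1e-12.
- `ICER` is `None` (flagged undefined, no exception) when ΔE = 0;
  dominance classification covers all four quadrants, since PSA
  iterations can land anywhere even though the base case is a
  north-east trade-off.
- Life tables must have contiguous integer ages and `qx ∈ [0, 1]`; a
  terminal `qx ≠ 1` is forced to 1 with a logged warning on file read
  and rejected on direct construction. An optional `sex` column is
  ignored with a warning (the model is unisex).
- Fractional starting ages round to the nearest integer year.

## Known limitations

- No tunnel states, time-varying utilities, adverse-event disutilities,
  device-failure/replacement states, or societal-perspective costs.
- Parameter draws are independent; no correlation structure and no
  beta/gamma alternatives to the normal distributions.
- The synthetic mortality schedule is an acknowledged stand-in; absolute
  cost/QALY totals shift with the table edition, though increments,
  orderings and threshold counts are robust to it (the grid counts match
  the reference values under the packaged table).
- No expected-value-of-perfect-information or efficiency-frontier
  analysis.
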
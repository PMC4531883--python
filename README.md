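# visioncea

Markov cohort cost-effectiveness modelling of next-generation **artificial
vision devices (AVD)** versus **best supportive care (BSC)** for blindness
caused by retinitis pigmentosa, from a healthcare-payer perspective.

Retinal prostheses currently in pre-clinical development may lift a blind
patient's visual acuity above the legal-blindness threshold, i.e. from the
health state *Blind* to *Visual Impaired*. Whether that is worth paying for
depends on three highly uncertain quantities: the responder rate, the device
price, and the willingness-to-pay (WTP) per quality-adjusted life-year
(QALY). This package implements the early health-economic evaluation of
that question as a tested, reusable pipeline.

## The model

A three-state Markov cohort model with yearly cycles over states
*Blind*, *Visual Impaired* (VIMP) and *Death*:

- Under AVD, a fraction *RR* (responder rate) of the cohort moves
  Blind → VIMP at model entry and stays there until death; under BSC
  nobody ever leaves Blind alive.
- Mortality is identical across states and arms and comes from a period
  life table (`qx` per integer age). The package ships a synthetic
  Gompertz–Makeham table, `h(age) = c + a·e^{b·age}`, calibrated so that
  the discounted life expectancy from age 51 at 3 %/yr is ≈ 20 years.
- Per cycle *t*, costs `c_state·occupancy` and QALYs `u_state·occupancy`
  accrue at cycle start and are discounted by `1/(1+r)^t`. The AVD arm
  additionally pays a first-year device cost at cycle 0 and an annual
  follow-up cost for every survivor from cycle 1 on.
- Incremental cost-effectiveness ratio: `ICER = ΔC/ΔE`; net monetary
  benefit at threshold λ: `NMB = λ·ΔE − ΔC`.

Because the model is linear, the incremental effect obeys
`ΔE = RR · (u_VIMP − u_Blind) · DLE(age₀, r)` exactly, which the tests
exploit as an independent oracle.

Base-case inputs (EUR at 2014 prices): annual care costs €4,091 (Blind) /
€3,680 (VIMP), utilities 0.61 / 0.77, responder rate 62.5 %, first-year
device cost €85,000, follow-up €1,500/yr, start age 51, 3 % discounting of
costs and effects, lifetime horizon.

Surrounding machinery: Monte-Carlo probabilistic sensitivity analysis
(normal input distributions, SD = 10 % of the mean, empirical percentile
intervals), cost-effectiveness acceptability curves, one-way tornado
analysis, and a 5×5 responder-rate × device-cost scenario grid with WTP
threshold counting.

## Worked example

```sh
python examples/base_case.py
```

prints (with the packaged synthetic life table):

```
AVD arm: cost   190,978 EUR,  14.31 QALYs over 32.0 life-years
BSC arm: cost    82,430 EUR,  12.29 QALYs over 32.0 life-years
incremental: 108,548 EUR for 2.015 QALYs gained -> ICER 53,872 EUR per QALY (trade-off)
```

The payer spends ≈ €108.5k more per patient and gains ≈ 2.0 QALYs; at
≈ €54k per QALY gained the device sits between the €40k and €60k WTP
thresholds — "trade-off" marks the north-east quadrant of the
cost-effectiveness plane (more effective, more costly).

Other examples, one per capability: `psa_and_ceac.py` (1,000-iteration PSA
and acceptability probabilities), `tornado_dsa.py` (the responder rate
induces the widest ICER range, ≈ €106k), `scenario_grid.py` (25 scenarios;
7, 15 and 19 of them fall below €40k, €60k and €80k per QALY),
`life_table_roundtrip.py` and `full_pipeline.py` (configured run writing
all CSV outputs plus run metadata).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch — synthetic life table,
deterministic base case, inflation arithmetic, 1,000-iteration PSA with
CEAC, tornado, scenario grid and threshold counts — printing each stage's
numbers and writing the result object to `--out`.
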
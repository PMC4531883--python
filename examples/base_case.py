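"""Deterministic base case: artificial vision device (AVD) vs best supportive care.

Builds the packaged synthetic life table, runs both arms of the Markov
cohort model at the base-case parameters (responder rate 62.5 %, first-year
device cost 85,000 EUR, 3 % discounting) and prints the incremental result.
"""

from visioncea import (
    ModelParams,
    incremental,
    make_gompertz_life_table,
    round_euro,
    run_cohort,
)

lt = make_gompertz_life_table()
params = ModelParams()

trace_avd, avd = run_cohort(params, lt, "AVD")
trace_bsc, bsc = run_cohort(params, lt, "BSC")
inc = incremental(avd, bsc)

print(f"AVD arm: cost {round_euro(avd.discounted_cost):>9,} EUR, "
      f"{avd.discounted_qaly:6.2f} QALYs over {avd.life_years:.1f} life-years")
print(f"BSC arm: cost {round_euro(bsc.discounted_cost):>9,} EUR, "
      f"{bsc.discounted_qaly:6.2f} QALYs over {bsc.life_years:.1f} life-years")
print(f"incremental: {round_euro(inc.delta_cost):,} EUR for "
      f"{inc.delta_effect:.3f} QALYs gained -> ICER "
      f"{round_euro(inc.icer):,} EUR per QALY ({inc.dominance.value})")

# The ICER is what a payer gives up per quality-adjusted life-year gained by
# funding the device; 'trade-off' means the device is more effective but
# also more costly, so a willingness-to-pay threshold decides its value.
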
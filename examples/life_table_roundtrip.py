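"""Generate, write and re-read a synthetic life table.

The packaged Gompertz-Makeham constants stand in for a national period
life table: hazard(age) = c + a*exp(b*age).  The calibration target is a
discounted life expectancy of ~20 years from age 51 at 3 %/yr.
"""

import tempfile
from pathlib import Path

from visioncea import (
    GOMPERTZ_DEFAULTS,
    discounted_life_expectancy,
    make_gompertz_life_table,
    read_life_table,
    write_life_table,
)

lt = make_gompertz_life_table()
print("constants:", GOMPERTZ_DEFAULTS)
for age in (51, 65, 80, 95):
    print(f"  qx({age}) = {lt.qx_at(age):.5f}")
print(f"discounted life expectancy from 51 at 3%: "
      f"{discounted_life_expectancy(lt, 51, 0.03):.2f} years")
print(f"undiscounted: {discounted_life_expectancy(lt, 51, 0.0):.2f} years")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic_life_table.csv"
    write_life_table(lt, path)
    back = read_life_table(path)
    print(f"round-trip through {path.name}: "
          f"{len(back.ages)} ages {back.min_age}-{back.max_age}, "
          f"terminal qx = {back.qx[-1]}")
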
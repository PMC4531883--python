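"""Previously reported scenario-grid results used as fixed numeric inputs.

These are the published incremental costs (EUR) and incremental effects
(QALYs) for the 25-cell responder-rate x first-year-device-cost grid of
the original analysis.  They are carried here as *inputs* — for
willingness-to-pay threshold counting and for cross-checking ICER
arithmetic — not as outputs of this package, whose own grid is computed
by :func:`visioncea.uncertainty.scenario_grid` from a life table.
"""

from __future__ import annotations

from .uncertainty import ScenarioCell

__all__ = ["REPORTED_SCENARIO_GRID", "reported_cells"]

# (responder rate, first-year cost EUR, incremental cost EUR, incremental QALYs)
_ROWS: list[tuple[float, float, float, float]] = [
    (0.25, 55_000, 81_640, 0.80),
    (0.50, 55_000, 78_606, 1.59),
    (0.625, 55_000, 77_674, 2.03),
    (0.75, 55_000, 76_658, 2.41),
    (1.00, 55_000, 75_237, 3.20),
    (0.25, 70_000, 96_276, 0.80),
    (0.50, 70_000, 94_752, 1.59),
    (0.625, 70_000, 92_826, 2.03),
    (0.75, 70_000, 91_983, 2.41),
    (1.00, 70_000, 90_158, 3.20),
    (0.25, 85_000, 110_984, 0.80),
    (0.50, 85_000, 109_218, 1.59),
    (0.625, 85_000, 107_925, 2.03),
    (0.75, 85_000, 106_731, 2.41),
    (1.00, 85_000, 104_685, 3.20),
    (0.25, 100_000, 126_384, 0.80),
    (0.50, 100_000, 123_346, 1.59),
    (0.625, 100_000, 122_218, 2.03),
    (0.75, 100_000, 121_913, 2.41),
    (1.00, 100_000, 119_396, 3.20),
    (0.25, 115_000, 141_566, 0.80),
    (0.50, 115_000, 139_301, 1.59),
    (0.625, 115_000, 138_746, 2.03),
    (0.75, 115_000, 137_416, 2.41),
    (1.00, 115_000, 134_948, 3.20),
]

#: The reported grid as immutable tuples (rr, first_year_cost, IC, IE).
REPORTED_SCENARIO_GRID: tuple[tuple[float, float, float, float], ...] = tuple(_ROWS)


def reported_cells() -> list[ScenarioCell]:
    """The reported grid as ScenarioCell objects, ICER recomputed as IC/IE."""
    return [
        ScenarioCell(
            responder_rate=rr,
            first_year_cost=cost,
            delta_cost=ic,
            delta_effect=ie,
            icer=ic / ie,
        )
        for rr, cost, ic, ie in _ROWS
    ]
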
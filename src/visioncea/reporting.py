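"""Result tables, run metadata and optional figures.

Every pipeline stage writes plain CSV with a header row; monetary columns
carry the explicit currency-year label (EUR-2014) in their names, because
the inflation step makes the costing year semantically load-bearing.
Whole-euro rounding happens here and only here.  Figures are conveniences
generated from the tables, never the source of truth.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .config import CURRENCY_LABEL, RunConfig
from .economics import IncrementalResult, round_euro
from .uncertainty import CeacPoint, PsaResult, ScenarioCell, TornadoEntry

__all__ = [
    "incremental_frame",
    "scenario_frame",
    "ceac_frame",
    "tornado_frame",
    "write_base_case",
    "write_psa",
    "write_ceac",
    "write_tornado",
    "write_scenario_grid",
    "write_run_metadata",
    "plot_ce_plane",
    "plot_ceac",
    "plot_tornado",
]

_COST = f"cost_{CURRENCY_LABEL}"


def _pkg_version() -> str:
    try:
        return version("visioncea")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def incremental_frame(inc: IncrementalResult) -> pd.DataFrame:
    """One-row summary: IC, IE, ICER (whole euros) and dominance class."""
    return pd.DataFrame([{
        f"inc_{_COST}": round_euro(inc.delta_cost),
        "inc_qaly": inc.delta_effect,
        f"icer_{_COST}_per_qaly": round_euro(inc.icer) if inc.icer is not None else None,
        "dominance": inc.dominance.value,
    }])


def scenario_frame(cells: list[ScenarioCell]) -> pd.DataFrame:
    """Grid table: one row per cell, mirroring RR / cost / IC / IE / ICER."""
    return pd.DataFrame([{
        "responder_rate": c.responder_rate,
        f"first_year_{_COST}": c.first_year_cost,
        f"inc_{_COST}": round_euro(c.delta_cost),
        "inc_qaly": c.delta_effect,
        f"icer_{_COST}_per_qaly": round_euro(c.icer) if c.icer is not None else None,
    } for c in cells])


def ceac_frame(points: list[CeacPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        f"wtp_{_COST}_per_qaly": p.wtp,
        "prob_cost_effective": p.probability,
    } for p in points])


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "low_setting": e.low_setting,
        "high_setting": e.high_setting,
        f"icer_low_{_COST}_per_qaly": round_euro(e.icer_low) if e.icer_low is not None else None,
        f"icer_high_{_COST}_per_qaly": round_euro(e.icer_high) if e.icer_high is not None else None,
        f"spread_{_COST}_per_qaly": round_euro(e.spread),
    } for e in entries])


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path


def write_base_case(inc: IncrementalResult, out_dir: str | Path) -> Path:
    return _write(incremental_frame(inc), Path(out_dir) / "base_case.csv")


def write_psa(psa: PsaResult, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    it = _write(psa.iterations, out / "psa_iterations.csv", index=True)
    summary = psa.summary.copy()
    summary.index.name = "quantity"
    sm = _write(summary, out / "psa_summary.csv", index=True)
    return it, sm


def write_ceac(points: list[CeacPoint], out_dir: str | Path) -> Path:
    return _write(ceac_frame(points), Path(out_dir) / "ceac.csv")


def write_tornado(entries: list[TornadoEntry], out_dir: str | Path) -> Path:
    return _write(tornado_frame(entries), Path(out_dir) / "tornado.csv")


def write_scenario_grid(cells: list[ScenarioCell], out_dir: str | Path) -> Path:
    return _write(scenario_frame(cells), Path(out_dir) / "scenario_grid.csv")


def write_run_metadata(config: RunConfig, out_dir: str | Path) -> Path:
    """Record seed, config hash and package version next to the outputs."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    meta = {
        "seed": config.analysis.seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "package_version": _pkg_version(),
        "currency": CURRENCY_LABEL,
    }
    path = Path(out_dir) / "run_metadata.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# Figures (optional conveniences)

def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_ce_plane(psa: PsaResult, wtp: float | None = None, ax=None):
    """Scatter of PSA iterations on the cost-effectiveness plane."""
    ax = _axes(ax)
    ax.scatter(psa.delta_effects, psa.delta_costs, s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if wtp is not None:
        xs = ax.get_xlim()
        ax.plot(xs, [wtp * x for x in xs], "--", color="tab:red",
                label=f"WTP {wtp:,.0f} {CURRENCY_LABEL}/QALY")
        ax.legend()
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel(f"Incremental cost ({CURRENCY_LABEL})")
    return ax


def plot_ceac(points: list[CeacPoint], ax=None, label: str | None = None):
    ax = _axes(ax)
    ax.plot([p.wtp for p in points], [p.probability for p in points], label=label)
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"Willingness to pay ({CURRENCY_LABEL} per QALY)")
    ax.set_ylabel("Probability cost-effective")
    if label:
        ax.legend()
    return ax


def plot_tornado(entries: list[TornadoEntry], base_icer: float, ax=None):
    ax = _axes(ax)
    named = [e for e in entries if e.icer_low is not None and e.icer_high is not None]
    ypos = range(len(named))[::-1]
    for y, e in zip(ypos, named):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, color="tab:blue", alpha=0.7)
    ax.axvline(base_icer, color="black", lw=1)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels([e.parameter for e in named])
    ax.set_xlabel(f"ICER ({CURRENCY_LABEL} per QALY)")
    return ax
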
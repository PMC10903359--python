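"""Cost-effectiveness scenario grids: detection-vs-cost and richness-vs-cost.

Curve tables pair the cost model with either cumulative detection
probability (single-species surveys) or expected species richness
(community surveys) over a grid of scenarios: assay-development cost
A in {0, 8, 85} hours for qPCR, program size L in {1, 10, 100} locations,
seining with or without environmental (E) and permitting (P) costs, and
single- vs double-sample metabarcoding strategies, for k = 1..25 sites.

Every curve is emitted as a tidy table (one row per grid point); plotting
is a thin optional layer on top so downstream checks never parse images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accumulation import AccumulationFit, PolceKuninModel, predict_richness
from .costs import CostParams, CostScenario, EffortDesign, apply_scenario, total_cost
from .detection import DetectionEstimate, cumulative_detection

__all__ = [
    "ScenarioGrid",
    "detection_cost_curves",
    "richness_cost_curves",
    "summarize_crossovers",
    "plot_curves",
]

CURVE_COLUMNS = [
    "method", "scenario", "L", "k", "n", "effort",
    "cost_hours_per_location", "total_hours", "response", "ci_low", "ci_high",
]


@dataclass(frozen=True)
class ScenarioGrid:
    """The enumerated scenario cross-product behind the curve tables."""

    assay_costs: Sequence[float] = (0.0, 8.0, 85.0)
    locations: Sequence[int] = (1, 10, 100)
    seine_variants: Sequence[str] = ("full", "no_E", "no_P_no_E")
    strategies: Sequence[int] = (1, 2)  # samples per site for metabarcoding
    k_values: Sequence[int] = tuple(range(1, 26))


_SEINE_OVERRIDES = {
    "full": {},
    "no_E": {"E": 0.0},
    "no_P_no_E": {"P": 0.0, "E": 0.0},
}


def _method_scenarios(method: str, params: CostParams, grid: ScenarioGrid):
    """Yield (scenario_label, CostScenario) cells for one method."""
    if "seine" in method.lower():
        for variant in grid.seine_variants:
            if variant not in _SEINE_OVERRIDES:
                raise ValueError(f"unknown seine variant {variant!r}")
            yield variant, CostScenario(label=variant, param_overrides=_SEINE_OVERRIDES[variant])
    elif "qpcr" in method.lower():
        for a in grid.assay_costs:
            yield f"A={a:g}", CostScenario(label=f"A={a:g}", param_overrides={"A": a})
    else:
        yield "base", CostScenario(label="base")


def detection_cost_curves(
    cost_params: Mapping[str, CostParams],
    detection: Mapping[str, DetectionEstimate],
    grid: ScenarioGrid | None = None,
    n: int = 1,
) -> pd.DataFrame:
    """Detection-probability-vs-cost curve table across the scenario grid.

    ``cost_params`` and ``detection`` are keyed by the same method names.
    For each method, scenario cell, program size L and site count k, one row
    gives the effort (n*k samples; n defaults to one sample per site), the
    cost per location, the program total, and cumulative detection d with
    its CI.
    """
    grid = grid or ScenarioGrid()
    missing = set(detection) - set(cost_params)
    if missing:
        raise KeyError(f"methods missing from cost parameters: {sorted(missing)}")
    rows = []
    for method, est in detection.items():
        base = cost_params[method]
        for label, scenario in _method_scenarios(method, base, grid):
            for L in grid.locations:
                for k in grid.k_values:
                    params, design = apply_scenario(
                        base, EffortDesign(L=int(L), k=int(k), n=int(n)), scenario
                    )
                    cost = total_cost(params, design)
                    cum = cumulative_detection(est, n=design.n, k=design.k)
                    rows.append((
                        method, label, L, k, design.n, design.n * design.k,
                        cost, cost * L, cum.d, cum.ci_low, cum.ci_high,
                    ))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def richness_cost_curves(
    fits: Mapping[str, AccumulationFit | PolceKuninModel],
    cost_params: Mapping[str, CostParams],
    grid: ScenarioGrid | None = None,
    strategies: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Expected-richness-vs-cost curve table across the scenario grid.

    ``fits`` maps method names to converged accumulation fits.  By default
    metabarcoding methods run both grid strategies (n = 1 single-sample and
    n = 2 double-sample) while other methods use n = 1; pass ``strategies``
    to override the per-method sample counts.  Refuses unconverged fits.
    """
    grid = grid or ScenarioGrid()
    missing = set(fits) - set(cost_params)
    if missing:
        raise KeyError(f"methods missing from cost parameters: {sorted(missing)}")
    rows = []
    for method, fit in fits.items():
        converged = fit.converged_ if isinstance(fit, PolceKuninModel) else fit.converged
        if not converged:
            message = fit.message_ if isinstance(fit, PolceKuninModel) else fit.message
            raise ValueError(
                f"accumulation fit for {method!r} did not converge: {message}"
            )
        model = fit if isinstance(fit, PolceKuninModel) else fit.model
        if strategies is not None:
            n_values = strategies.get(method, (1,))
        elif "barcode" in method.lower() or "metabarcod" in method.lower():
            n_values = grid.strategies
        else:
            n_values = (1,)
        base = cost_params[method]
        for label, scenario in _method_scenarios(method, base, grid):
            for L in grid.locations:
                for n in n_values:
                    X = np.array([[n, k] for k in grid.k_values], dtype=float)
                    pred = predict_richness(fit, X[:, 0], X[:, 1])
                    if model is not None:
                        ci = model.predict_ci(X)
                        lo, hi = ci["ci_low"].to_numpy(), ci["ci_high"].to_numpy()
                    else:
                        lo = hi = np.full(len(X), np.nan)
                    for i, k in enumerate(grid.k_values):
                        params, design = apply_scenario(
                            base, EffortDesign(L=int(L), k=int(k), n=int(n)), scenario
                        )
                        cost = total_cost(params, design)
                        rows.append((
                            method, label, L, k, n, n * k,
                            cost, cost * L, float(pred[i]), float(lo[i]), float(hi[i]),
                        ))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def summarize_crossovers(
    curves: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.9, 0.95, 0.99),
) -> pd.DataFrame:
    """Rank methods by the cost at which each detection threshold is reached.

    For every (L, threshold) and every (method, scenario) curve, finds the
    least per-location cost among grid points whose response meets the
    threshold (NaN if never reached), and ranks the curves; rank 1 is the
    most cost-effective way to reach that detection level.
    """
    if curves["method"].nunique() < 1:
        raise ValueError("no curves to summarize")
    rows = []
    for (L, threshold) in (
        (L, th) for L in sorted(curves["L"].unique()) for th in thresholds
    ):
        sub = curves[curves["L"] == L]
        for (method, scenario), grp in sub.groupby(["method", "scenario"]):
            reached = grp[grp["response"] >= threshold]
            cost = float(reached["cost_hours_per_location"].min()) if len(reached) else float("nan")
            rows.append(dict(L=L, threshold=threshold, method=method,
                             scenario=scenario, cost_at_threshold=cost))
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby(["L", "threshold"])["cost_at_threshold"]
        .rank(method="min")
    )
    return out.sort_values(["L", "threshold", "cost_at_threshold"]).reset_index(drop=True)


def plot_curves(curves: pd.DataFrame, response_label: str = "response", ax=None):
    """Optional thin plotting layer: one line per (method, scenario, L, n)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (method, scenario, L, n), grp in curves.groupby(["method", "scenario", "L", "n"]):
        grp = grp.sort_values("cost_hours_per_location")
        ax.plot(grp["cost_hours_per_location"], grp["response"],
                marker="o", markersize=3,
                label=f"{method} [{scenario}, L={L}, n={n}]")
    ax.set_xlabel("cost (hours per location)")
    ax.set_ylabel(response_label)
    ax.legend(fontsize=6)
    return ax
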
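"""Survey investment model: fixed plus variable cost in technician-hours.

A monitoring program visits ``L`` locations; at each location ``k`` sites are
visited and ``n`` samples are taken per site.  The total investment per
location, ``H``, decomposes into a fixed part that is independent of the
within-location effort,

    fixed = (P + G + A) / L + B + W*V + R,

and a variable part that scales with sites and samples,

    variable = k * (v + n * (t*W + E + D + q)).

All parameters are expressed in technician-hours (the common cost currency;
monetary costs convert at a stated hourly rate).  ``P`` permit management,
``G`` gear, ``A`` assay development/validation, ``B`` background knowledge
(e.g. compiling a plausible species list), ``W`` crew size (a dimensionless
multiplier), ``V`` travel/preparation per location visit, ``R`` reporting,
``v`` per-site visit time, ``t`` per-sample field time (multiplied by crew
size), ``E`` per-sample environmental-impact cost, ``D`` per-sample data
entry, ``q`` per-sample sequencing, and ``r`` per-technical-replicate cost
(small enough to be ignorable by default).

Fixed one-off costs (``P``, ``G``, ``A``) are divided across the ``L``
locations of the program; crew size enters both the fixed travel term
(``W*V``) and the per-sample field term (``t*W``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

from ._fixtures import packaged_data_path

__all__ = [
    "HOURLY_RATE_USD",
    "CostParams",
    "EffortDesign",
    "CostScenario",
    "ScenarioError",
    "fixed_cost",
    "variable_cost",
    "total_cost",
    "apply_scenario",
    "hours_to_dollars",
    "load_cost_params",
    "load_scenario",
    "default_cost_params",
]

#: 2023 field-technician hourly rate used by the dollar-conversion helper.
HOURLY_RATE_USD = 30.0

_METHOD_LABELS = {
    "qPCR",
    "goby_metabarcode",
    "fish_metabarcode",
    "goby_seine",
    "fish_seine",
    "custom",
}


@dataclass(frozen=True)
class CostParams:
    """Cost-model parameters for one survey method, in technician-hours.

    Field names follow the standard symbols: P, B, G, A, W, V, v, t, E, q,
    D, R, r.  ``W`` is a dimensionless crew-size multiplier (>= 1); every
    other field is an hour equivalent and must be non-negative.
    """

    P: float = 0.0  # permit management
    B: float = 0.0  # background knowledge
    G: float = 0.0  # gear
    A: float = 0.0  # assay development / validation
    W: float = 1.0  # workers (count multiplier)
    V: float = 0.0  # visit to location
    v: float = 0.0  # visit to site
    t: float = 0.0  # time per sample
    E: float = 0.0  # external (environmental) cost per sample
    q: float = 0.0  # sequencing per sample
    D: float = 0.0  # data entry per sample
    R: float = 0.0  # reporting
    r: float = 0.0  # per-technical-replicate cost, ignorable by default
    method_label: str = "custom"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "method_label":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"cost parameter {f.name} must be >= 0, got {value}")
        if self.W < 1:
            raise ValueError(f"worker multiplier W must be >= 1, got {self.W}")
        if self.method_label not in _METHOD_LABELS:
            raise ValueError(
                f"unknown method_label {self.method_label!r}; "
                f"expected one of {sorted(_METHOD_LABELS)}"
            )


@dataclass(frozen=True)
class EffortDesign:
    """Sampling effort: L locations, k sites per location, n samples per site."""

    L: int = 1
    k: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("L", "k", "n"):
            value = getattr(self, name)
            if value != int(value):
                raise ValueError(f"effort {name} must be an integer, got {value}")
            object.__setattr__(self, name, int(value))
        if self.L < 1:
            raise ValueError(f"locations L must be >= 1, got {self.L}")
        if self.k < 0 or self.n < 0:
            raise ValueError(f"site/sample counts must be >= 0, got k={self.k}, n={self.n}")


class ScenarioError(ValueError):
    """A scenario override references a field that does not exist."""


@dataclass(frozen=True)
class CostScenario:
    """Named substitutions on cost parameters and/or effort design.

    Examples: dropping the environmental cost of seining (``E -> 0``),
    pricing an already-validated assay (``A -> 0``), or spreading fixed
    costs across many locations (``L -> 100``).
    """

    label: str = "baseline"
    param_overrides: Mapping[str, float] = None
    design_overrides: Mapping[str, int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_overrides", dict(self.param_overrides or {}))
        object.__setattr__(self, "design_overrides", dict(self.design_overrides or {}))
        param_fields = {f.name for f in fields(CostParams)} - {"method_label"}
        for name in self.param_overrides:
            if name not in param_fields:
                raise ScenarioError(f"unknown cost-parameter override {name!r}")
        for name in self.design_overrides:
            if name not in {"L", "k", "n"}:
                raise ScenarioError(f"unknown effort-design override {name!r}")


def fixed_cost(params: CostParams, design: EffortDesign) -> float:
    """Fixed hours per location: (P + G + A)/L + B + W*V + R."""
    return (params.P + params.G + params.A) / design.L + params.B + params.W * params.V + params.R


def variable_cost(params: CostParams, design: EffortDesign) -> float:
    """Variable hours per location: k*(v + n*(t*W + E + D + q))."""
    per_sample = params.t * params.W + params.E + params.D + params.q
    return design.k * (params.v + design.n * per_sample)


def total_cost(params: CostParams, design: EffortDesign) -> float:
    """Total investment H per location, in technician-hours."""
    return fixed_cost(params, design) + variable_cost(params, design)


def apply_scenario(
    params: CostParams, design: EffortDesign, scenario: CostScenario
) -> tuple[CostParams, EffortDesign]:
    """Return copies of ``params`` and ``design`` with scenario overrides applied."""
    new_params = replace(params, **scenario.param_overrides) if scenario.param_overrides else params
    new_design = replace(design, **scenario.design_overrides) if scenario.design_overrides else design
    return new_params, new_design


def hours_to_dollars(hours: float, rate: float = HOURLY_RATE_USD) -> float:
    """Convert technician-hours to USD at the stated hourly rate."""
    return hours * rate


# ---------------------------------------------------------------------------
# I/O


def load_cost_params(path: str | Path) -> dict[str, CostParams]:
    """Read a cost-parameter CSV (one row per method) into CostParams objects.

    Expected columns: ``method_label`` plus the parameter symbols
    P,B,G,A,W,V,v,t,E,q,D,R and optionally r.  Lines starting with ``#``
    are comments.
    """
    out: dict[str, CostParams] = {}
    with open(path, newline="") as fh:
        rows = csv.DictReader(line for line in fh if not line.startswith("#"))
        for row in rows:
            label = row.pop("method_label")
            values = {key: float(val) for key, val in row.items() if val != ""}
            out[label] = CostParams(method_label=label, **values)
    if not out:
        raise ValueError(f"no cost-parameter rows found in {path}")
    return out


def default_cost_params() -> dict[str, CostParams]:
    """Packaged default parameters for all five survey-method columns."""
    return load_cost_params(packaged_data_path("table1.csv"))


def load_scenario(path: str | Path) -> tuple[CostScenario, EffortDesign | None]:
    """Read a scenario JSON: {label, overrides: {field: value}, design: {L,k,n}}.

    Overrides naming cost-parameter fields go to the scenario's parameter
    substitutions; L/k/n go to the design substitutions.  The optional
    ``design`` block gives a full base design and is returned alongside.
    """
    with open(path) as fh:
        payload = json.load(fh)
    overrides = dict(payload.get("overrides", {}))
    design_over = {key: overrides.pop(key) for key in ("L", "k", "n") if key in overrides}
    scenario = CostScenario(
        label=payload.get("label", "scenario"),
        param_overrides=overrides,
        design_overrides=design_over,
    )
    base = payload.get("design")
    design = EffortDesign(**base) if base else None
    return scenario, design
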
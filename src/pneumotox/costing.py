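"""Weighted unit-cost model for symptomatic pneumonitis episodes.

The model is a linear sum over resource lines: each line carries a usage
weight (a probability, an expected count, or a product such as expected
admission nights x admission probability) and a unit cost in GBP taken from
the National Schedule of NHS Costs 2019/20 or the BNF.  Per-patient cost is
the sum of weight x unit_cost over all lines; cohort cost extrapolates the
*unrounded* per-patient sum to ``n_cases`` cases over ``n_years`` years.

Display values are rounded half-up to 2 decimal places; every arithmetic
step retains the unrounded float internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CostLine",
    "CostModel",
    "line_cost",
    "per_patient_cost",
    "cohort_cost",
    "sensitivity",
    "read_cost_table",
    "write_cost_table",
    "reference_cost_model",
    "immunosuppressive_course_cost",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (``0.005 -> 0.01``), the convention
    used for all displayed monetary values and percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _parse_weight_expr(expr: str | float | int) -> float:
    """Evaluate a weight expression: a number or a ``*``-separated product
    such as ``"10.5*0.39"`` (also accepts the typographic ``×``)."""
    if isinstance(expr, (int, float)):
        return float(expr)
    factors = str(expr).replace("×", "*").split("*")
    out = 1.0
    for f in factors:
        out *= float(f.strip())
    return out


@dataclass(frozen=True)
class CostLine:
    """One resource line: name, usage weight, unit cost (GBP), service code.

    ``weight_expr`` preserves the human-readable form (e.g. ``"10.5*0.39"``
    for expected nights x admission probability); ``weight`` is its value.
    """

    resource: str
    weight_expr: str
    unit_cost: float
    code: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"negative weight on line {self.resource!r}")
        if self.unit_cost < 0:
            raise ValueError(f"negative unit cost on line {self.resource!r}")

    @property
    def weight(self) -> float:
        return _parse_weight_expr(self.weight_expr)


@dataclass(frozen=True)
class CostModel:
    """Ordered list of cost lines with cohort-extrapolation parameters."""

    lines: tuple[CostLine, ...]
    n_cases: int = 0
    n_years: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.n_years <= 0:
            raise ValueError("n_years must be > 0")

    def with_lines(self, lines: Iterable[CostLine]) -> "CostModel":
        return replace(self, lines=tuple(lines))


def line_cost(line: CostLine) -> float:
    """Unrounded cost of one line (weight x unit cost)."""
    return line.weight * line.unit_cost


def per_patient_cost(model: CostModel) -> float:
    """Unrounded average cost per symptomatic case (sum over lines)."""
    if not model.lines:
        raise ValueError("cost model has no lines")
    return sum(line_cost(l) for l in model.lines)


def cohort_cost(model: CostModel) -> tuple[float, float]:
    """(total, annual) cohort cost, both unrounded.

    The total multiplies the *unrounded* per-patient sum by ``n_cases``;
    rounding the per-patient figure first would drift the cohort total by
    several pence over a hundred-odd cases.
    """
    total = per_patient_cost(model) * model.n_cases
    return total, total / model.n_years


# A perturbation maps resource name -> (op, value) with op one of
# "scale_weight", "set_weight", "add_weight", "scale_cost", "set_cost".
Perturbation = Mapping[str, tuple[str, float]]

_OPS = {
    "scale_weight": lambda l, v: replace(l, weight_expr=repr(l.weight * v)),
    "set_weight": lambda l, v: replace(l, weight_expr=repr(v)),
    "add_weight": lambda l, v: replace(l, weight_expr=repr(l.weight + v)),
    "scale_cost": lambda l, v: replace(l, unit_cost=l.unit_cost * v),
    "set_cost": lambda l, v: replace(l, unit_cost=v),
}


def sensitivity(
    model: CostModel, perturbations: Mapping[str, Perturbation]
) -> pd.DataFrame:
    """Per-patient cost under named what-if scenarios.

    The returned table always starts with a ``baseline`` row equal to
    :func:`per_patient_cost` of the unperturbed model.
    """
    rows = [("baseline", per_patient_cost(model))]
    for name, pert in perturbations.items():
        unknown = set(pert) - {l.resource for l in model.lines}
        if unknown:
            raise KeyError(f"scenario {name!r} perturbs unknown lines {sorted(unknown)}")
        lines = []
        for l in model.lines:
            if l.resource in pert:
                op, value = pert[l.resource]
                l = _OPS[op](l, value)
            lines.append(l)
        rows.append((name, per_patient_cost(model.with_lines(lines))))
    out = pd.DataFrame(rows, columns=["scenario", "per_patient_cost"])
    out["display"] = out["per_patient_cost"].map(round_half_up)
    return out


def read_cost_table(path: str | Path, n_cases: int = 0, n_years: float = 1.0) -> CostModel:
    """Load a cost model from CSV (columns resource, weight_expr, unit_cost,
    code; ``weight_expr`` admits products like ``10.5*0.39``)."""
    df = pd.read_csv(path, dtype={"weight_expr": str, "code": str})
    lines = tuple(
        CostLine(
            resource=r.resource,
            weight_expr=str(r.weight_expr),
            unit_cost=float(r.unit_cost),
            code="" if pd.isna(r.code) else str(r.code),
        )
        for r in df.itertuples(index=False)
    )
    return CostModel(lines=lines, n_cases=n_cases, n_years=n_years)


def write_cost_table(model: CostModel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "resource": l.resource,
                "weight_expr": l.weight_expr,
                "unit_cost": l.unit_cost,
                "code": l.code,
            }
            for l in model.lines
        ]
    ).to_csv(path, index=False)


# Admission statistics observed in the study cohort: 39% of symptomatic
# cases admitted to hospital (mean stay 10.5 nights), 7% to critical care
# (mean stay 6.5 nights).  The admission line weights are formed as
# expected nights x admission probability.  NB some published renderings
# of this table transpose the two probability factors; the assignment here
# (hospital 0.39, CCU 0.07) is the one consistent with the admission
# percentages and with the line totals.
HOSPITAL_ADMISSION_PROB = 0.39
CCU_ADMISSION_PROB = 0.07
HOSPITAL_MEAN_NIGHTS = 10.5
CCU_MEAN_NIGHTS = 6.5


def reference_cost_model(n_cases: int = 139, n_years: float = 6.0) -> CostModel:
    """The NHS 2019/20 reference cost model shipped with the package.

    Defaults extrapolate to the study cohort: 139 symptomatic cases over
    the 6-year window 2015-2020.
    """
    with _ilres.as_file(
        _ilres.files("pneumotox").joinpath("data/nhs_costs_2019_20.csv")
    ) as p:
        return read_cost_table(p, n_cases=n_cases, n_years=n_years)


def immunosuppressive_course_cost(
    weight_kg: float = 70.0,
    dose_mg_per_kg: float = 5.0,
    doses_per_day: int = 2,
    days: int = 5,
    cost_per_100mg: float = 377.0,
) -> float:
    """Cost of one rescue-immunosuppression course (infliximab example).

    5 mg/kg twice daily for 5 days is 3,500 mg for a 70 kg patient; at the
    BNF price of GBP 377 per 100 mg that is GBP 13,195.  Used to validate
    the unit cost on the "other immunosuppressive agent" line.
    """
    total_mg = weight_kg * dose_mg_per_kg * doses_per_day * days
    return total_mg / 100.0 * cost_per_100mg


def cost_report(model: CostModel) -> dict:
    """Machine-readable cost summary (displayed values rounded half-up)."""
    per_patient = per_patient_cost(model)
    total, annual = cohort_cost(model)
    return {
        "lines": [
            {
                "resource": l.resource,
                "weight": l.weight,
                "unit_cost": l.unit_cost,
                "code": l.code,
                "cost": round_half_up(line_cost(l)),
            }
            for l in model.lines
        ],
        "per_patient_cost": round_half_up(per_patient),
        "n_cases": model.n_cases,
        "n_years": model.n_years,
        "cohort_total_cost": round_half_up(total),
        "annual_cost": round_half_up(annual),
    }


def write_cost_report(model: CostModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cost_report(model), indent=2) + "\n")
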
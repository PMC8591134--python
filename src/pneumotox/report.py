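"""End-to-end pipeline orchestration and summary tables.

Runs simulate -> identify -> attribute -> grade -> resources -> cost on
one directory of record streams, tracking the identification funnel
(reports flagged, descriptor-filtered, treatment-matched, validated,
episodes, attributed, symptomatic) and producing machine-readable
summaries: incidence percentages against treated denominators, severity
and aetiology breakdowns, the strata comparison and the cost model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import io as pio
from .attribution import AttributionWindows, attribute_cases
from .cohort import TermConfig, run_cascade
from .costing import CostModel, cost_report, reference_cost_model, round_half_up
from .grading import ClinicalFlags, assign_grade
from .resources import compare_strata, extract_profiles

logger = logging.getLogger(__name__)

__all__ = ["FunnelSummary", "run_pipeline", "summarize", "derive_flags"]


@dataclass(frozen=True)
class FunnelSummary:
    """Report counts at each cascade stage; non-increasing along the funnel."""

    reports: int
    stage1_flagged: int
    stage2_filtered: int
    treatment_filtered: int
    validated: int
    episodes: int
    attributed: int
    symptomatic: int


FLAG_EVENT_MAP = {
    "symptomatic": "symptomatic",
    "oxygen_required": "oxygen_or_admission",
    "intubation": "life_threatening",
    "death": "death",
    "infection": "superadded_infection",
}


def derive_flags(cases: pd.DataFrame, clinical_events: pd.DataFrame) -> pd.DataFrame:
    """Attach severity flag columns to attributed cases from the clinical
    event stream (any flag event on or after the diagnosis date)."""
    ev = clinical_events.assign(event_date=pd.to_datetime(clinical_events["event_date"]))
    out = cases.copy()
    for flag in FLAG_EVENT_MAP.values():
        out[flag] = False
    for i, row in out.iterrows():
        pt_ev = ev[
            (ev["patient_id"] == row["patient_id"])
            & (ev["event_date"] >= pd.Timestamp(row["diagnosis_date"]))
        ]
        for etype, flag in FLAG_EVENT_MAP.items():
            if (pt_ev["event_type"] == etype).any():
                out.loc[i, flag] = True
    out["grade"] = [
        assign_grade(
            ClinicalFlags(
                symptomatic=row["symptomatic"],
                oxygen_or_admission=row["oxygen_or_admission"],
                life_threatening=row["life_threatening"],
                death=row["death"],
            )
        )
        for _, row in out.iterrows()
    ]
    return out


def summarize(
    graded: pd.DataFrame, denominators: dict[str, int] | None = None
) -> dict:
    """Incidence and severity summary.

    ``denominators`` maps group name ("ICI", "RT") to the number of
    treated patients; percentages are 100 x cases/denominator shown to
    2 dp (half-up), raw fractions retained.  Zero denominators omit the
    group with a warning.
    """
    out: dict = {
        "n_cases": int(len(graded)),
        "by_aetiology": graded["aetiology"].value_counts().to_dict(),
        "by_grade": {int(k): int(v) for k, v in graded["grade"].value_counts().items()},
        "n_symptomatic": int((graded["grade"] >= 2).sum()),
    }
    if denominators:
        incidence = {}
        for group, denom in denominators.items():
            if denom <= 0:
                logger.warning("omitting group %r with zero denominator", group)
                continue
            n = int((graded["aetiology"] == group).sum())
            n_sympt = int(
                ((graded["aetiology"] == group) & (graded["grade"] >= 2)).sum()
            )
            incidence[group] = {
                "treated": denom,
                "cases": n,
                "pct": round_half_up(100.0 * n / denom),
                "symptomatic_cases": n_sympt,
                "symptomatic_pct": round_half_up(100.0 * n_sympt / denom),
            }
        out["incidence"] = incidence
    return out


def incidence_pct(cases: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage = 100 x cases/denominator, half-up to ``ndigits``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * cases / denominator, ndigits)


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    term_config: TermConfig = TermConfig(),
    windows: AttributionWindows = AttributionWindows(),
    cost_model: CostModel | None = None,
) -> dict:
    """Execute the identification/attribution/grading/resource/cost chain
    on one directory of record streams; writes all stage outputs and a
    ``summary.json`` to ``out_dir`` and returns the summary dict."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    reports = stage("load reports", pio.read_reports, data_dir / "reports.jsonl")
    ici = stage("load ici", pio.read_csv, data_dir / "ici.csv")
    rt = stage("load rt", pio.read_csv, data_dir / "rt.csv")
    clinical = stage("load clinical", pio.read_csv, data_dir / "clinical.csv")

    episodes, funnel = stage("identify", run_cascade, reports, ici, rt, term_config)
    episodes.to_csv(out_dir / "candidates.csv", index=False)

    cases, excluded = stage("attribute", attribute_cases, episodes, ici, rt, windows, term_config)
    excluded.to_csv(out_dir / "excluded.csv", index=False)

    graded = stage("grade", derive_flags, cases, clinical)
    graded.to_csv(out_dir / "cases.csv", index=False)

    profiles = stage("resources", extract_profiles, graded, clinical)
    profiles.to_csv(out_dir / "profiles.csv", index=False)

    comparison = None
    if (profiles["grade"] == 1).sum() >= 2 and profiles["grade"].isin([2, 3, 4]).sum() >= 2:
        comparison = asdict(stage("compare", compare_strata, profiles))

    model = cost_model or reference_cost_model()
    n_sympt = int((graded["grade"] >= 2).sum())
    from dataclasses import replace as _replace

    model = _replace(model, n_cases=n_sympt)
    costs = cost_report(model)

    denominators = {
        "ICI": int(ici["patient_id"].nunique()),
        "RT": int(rt["patient_id"].nunique()),
    }
    summary = {
        "funnel": asdict(
            FunnelSummary(
                **funnel, attributed=len(cases), symptomatic=n_sympt
            )
        ),
        "summary": summarize(graded, denominators),
        "strata_comparison": comparison,
        "costs": costs,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("pipeline funnel: %s", summary["funnel"])
    return summary


def render_html(summary: dict, path: str | Path) -> None:
    """Minimal single-page HTML rendering of the pipeline summary."""
    rows = "\n".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in summary["funnel"].items()
    )
    html = (
        "<html><head><title>Pneumonitis pipeline summary</title></head><body>"
        f"<h1>Identification funnel</h1><table>{rows}</table>"
        f"<h1>Summary</h1><pre>{json.dumps(summary['summary'], indent=2)}</pre>"
        f"<h1>Costs</h1><pre>{json.dumps(summary['costs'], indent=2)}</pre>"
        "</body></html>"
    )
    Path(path).write_text(html)
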
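"""Healthcare resource utilisation in the 16 weeks after diagnosis.

Countable events (consultant follow-up clinic attendances, CT thorax
scans, MDT discussions) are tallied over the half-open window
[diagnosis, diagnosis + 112 days), the diagnosis day included.  Admission
stays (hospital, critical care) are attributed wholly to the case when the
admission *starts* inside the window; the recorded nights are not clipped
to the window edge.  Work-up flags (respiratory referral, bronchoalveolar
lavage, pulmonary function tests) are taken from any event on or after
diagnosis, with days-to-event recorded — these can legitimately fall
beyond 16 weeks.

Severity strata are compared with Welch's unequal-variance t-test on the
follow-up clinic counts, asymptomatic (grade 1) versus symptomatic
non-fatal (grades 2-4) cases; fatal cases are excluded from that
comparison but not from admission statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResourceProfile",
    "StrataComparison",
    "extract_profile",
    "extract_profiles",
    "compare_strata",
]

WINDOW_DAYS = 112  # 16 weeks

COUNT_EVENTS = {
    "clinic_visit": "clinic_visits",
    "ct_thorax": "ct_scans",
    "mdt": "mdt_discussions",
}
FLAG_EVENTS = {"referral": "referral", "bal": "bal", "pft": "pft"}
STAY_EVENTS = {"hospital_admission": "hospital_nights", "ccu_admission": "ccu_nights"}


@dataclass(frozen=True)
class ResourceProfile:
    """Per-case 16-week utilisation counts, stays and work-up flags."""

    patient_id: str
    report_id: str
    clinic_visits: int = 0
    ct_scans: int = 0
    mdt_discussions: int = 0
    hospital_nights: float = 0.0
    ccu_nights: float = 0.0
    referral: bool = False
    referral_days: float | None = None
    bal: bool = False
    bal_days: float | None = None
    pft: bool = False
    pft_days: float | None = None


def extract_profile(
    case: pd.Series | dict,
    clinical_events: pd.DataFrame,
    window_days: int = WINDOW_DAYS,
) -> ResourceProfile:
    """Utilisation profile for one case from its patient's event stream.

    Events dated before diagnosis are ignored.
    """
    diagnosis = pd.Timestamp(case["diagnosis_date"])
    end = diagnosis + pd.Timedelta(days=window_days)
    ev = clinical_events[clinical_events["patient_id"] == case["patient_id"]]
    dates = pd.to_datetime(ev["event_date"])

    out: dict = {
        "patient_id": case["patient_id"],
        "report_id": case.get("report_id", ""),
    }
    in_window = (dates >= diagnosis) & (dates < end)
    for etype, col in COUNT_EVENTS.items():
        out[col] = int(((ev["event_type"] == etype) & in_window).sum())
    for etype, col in STAY_EVENTS.items():
        mask = (ev["event_type"] == etype) & in_window
        out[col] = float(pd.to_numeric(ev.loc[mask, "value"], errors="coerce").sum())
    for etype, col in FLAG_EVENTS.items():
        mask = (ev["event_type"] == etype) & (dates >= diagnosis)
        out[col] = bool(mask.any())
        out[f"{col}_days"] = (
            float((dates[mask].min() - diagnosis).days) if mask.any() else None
        )
    return ResourceProfile(**out)


def extract_profiles(
    cases: pd.DataFrame,
    clinical_events: pd.DataFrame,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Profiles for every case, joined with grade when present."""
    rows = [
        vars(extract_profile(row, clinical_events, window_days))
        for _, row in cases.iterrows()
    ]
    out = pd.DataFrame(rows)
    if "grade" in cases.columns:
        out["grade"] = cases["grade"].values
    return out


@dataclass(frozen=True)
class StrataComparison:
    """Welch two-sample comparison between severity strata."""

    mean_group1: float
    mean_group2: float
    difference: float  # group2 - group1
    ci_low: float
    ci_high: float
    statistic: float
    df: float
    p_value: float
    n1: int
    n2: int


def compare_strata(
    profiles: pd.DataFrame,
    value: str = "clinic_visits",
    group1_grades: tuple[int, ...] = (1,),
    group2_grades: tuple[int, ...] = (2, 3, 4),
    alpha: float = 0.05,
) -> StrataComparison:
    """Welch unpaired t-test on a utilisation count between grade strata.

    Defaults compare asymptomatic (grade 1) against symptomatic non-fatal
    (grades 2-4) cases; the difference reported is group2 minus group1.
    """
    g1 = profiles.loc[profiles["grade"].isin(group1_grades), value].to_numpy(float)
    g2 = profiles.loc[profiles["grade"].isin(group2_grades), value].to_numpy(float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each stratum needs at least two observations")
    if np.var(g1) == 0 and np.var(g2) == 0 and g1.mean() == g2.mean():
        # degenerate but well-defined: no difference at all
        return StrataComparison(
            g1.mean(), g2.mean(), 0.0, 0.0, 0.0, 0.0, float(len(g1) + len(g2) - 2),
            1.0, len(g1), len(g2),
        )
    res = stats.ttest_ind(g2, g1, equal_var=False)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return StrataComparison(
        mean_group1=float(g1.mean()),
        mean_group2=float(g2.mean()),
        difference=float(g2.mean() - g1.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n1=len(g1),
        n2=len(g2),
    )
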
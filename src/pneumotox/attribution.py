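"""Aetiology attribution for identified pneumonitis episodes.

An episode is attributed to immune checkpoint inhibition if a listed ICI
drug was administered in the 3 months before the diagnosis date, and to
radiotherapy if a qualifying course started in the preceding 12 months;
both criteria met -> "both", neither -> unattributed (the episode goes to
an exclusions stream, mirroring the manual narrowing of a screened cohort
to treatment-attributable cases).

Windows are half-open day intervals [diagnosis - w, diagnosis): treatment
strictly before diagnosis, diagnosis day itself excluded.  The diagnosis
date is the symptom-onset date when one is supplied, else the index scan
date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import TermConfig

logger = logging.getLogger(__name__)

__all__ = ["AttributionWindows", "attribute", "attribute_cases", "lost_treatment_time"]


@dataclass(frozen=True)
class AttributionWindows:
    """Look-back windows in days: 3 months for ICI, 12 months for RT."""

    ici_window_days: int = 91
    rt_window_days: int = 365

    def __post_init__(self) -> None:
        if self.ici_window_days <= 0 or self.rt_window_days <= 0:
            raise ValueError("attribution windows must be positive")


def _dates_in_window(dates, start, end) -> bool:
    return any(start <= d < end for d in dates)


def attribute(
    diagnosis_date,
    ici_admin_dates,
    rt_first_fraction_dates,
    windows: AttributionWindows = AttributionWindows(),
) -> str | None:
    """Aetiology of one case candidate: "ICI", "RT", "both" or None.

    ``ici_admin_dates`` / ``rt_first_fraction_dates`` are the patient's
    qualifying treatment dates (already restricted to listed drugs/sites).
    """
    d = pd.Timestamp(diagnosis_date)
    ici = _dates_in_window(
        ici_admin_dates, d - pd.Timedelta(days=windows.ici_window_days), d
    )
    rt = _dates_in_window(
        rt_first_fraction_dates, d - pd.Timedelta(days=windows.rt_window_days), d
    )
    if ici and rt:
        return "both"
    if ici:
        return "ICI"
    if rt:
        return "RT"
    return None


def attribute_cases(
    candidates: pd.DataFrame,
    ici_events: pd.DataFrame,
    rt_events: pd.DataFrame,
    windows: AttributionWindows = AttributionWindows(),
    term_config: TermConfig = TermConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute every candidate index report; returns (cases, excluded).

    ``candidates`` needs patient_id, report_id and scan_date columns; an
    optional ``symptom_onset_date`` column takes precedence over the scan
    date as the diagnosis date.
    """
    ici = ici_events.assign(
        drug=ici_events["drug"].str.lower(),
        admin_date=pd.to_datetime(ici_events["admin_date"]),
    )
    ici = ici[ici["drug"].isin(term_config.ici_drugs)]
    rt = rt_events.assign(
        site=rt_events["site"].str.lower(),
        first_fraction_date=pd.to_datetime(rt_events["first_fraction_date"]),
    )
    rt = rt[rt["site"].isin(term_config.rt_sites)]
    ici_by_pt = ici.groupby("patient_id")["admin_date"].agg(list)
    rt_by_pt = rt.groupby("patient_id")["first_fraction_date"].agg(list)

    rows = []
    for _, row in candidates.iterrows():
        diagnosis = row.get("symptom_onset_date", None)
        if diagnosis is None or pd.isna(diagnosis):
            diagnosis = row["scan_date"]
        diagnosis = pd.Timestamp(diagnosis)
        aet = attribute(
            diagnosis,
            ici_by_pt.get(row["patient_id"], []),
            rt_by_pt.get(row["patient_id"], []),
            windows,
        )
        rows.append(
            {
                "patient_id": row["patient_id"],
                "report_id": row["report_id"],
                "diagnosis_date": diagnosis,
                "aetiology": aet,
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "report_id", "diagnosis_date", "aetiology"])
    cases = out[out["aetiology"].notna()].reset_index(drop=True)
    excluded = out[out["aetiology"].isna()].reset_index(drop=True)
    logger.info(
        "attribution: %d candidates -> %d attributed, %d excluded",
        len(out), len(cases), len(excluded),
    )
    return cases, excluded


def lost_treatment_time(
    diagnosis_date, ici_admin_dates
) -> int | None:
    """Days of ICI interruption around a pneumonitis episode.

    Measured from the last administration on or before diagnosis (the hold)
    to the first administration after diagnosis (the re-challenge); None
    when the drug was never reintroduced or never given before diagnosis.
    """
    d = pd.Timestamp(diagnosis_date)
    dates = sorted(pd.Timestamp(x) for x in ici_admin_dates)
    before = [x for x in dates if x <= d]
    after = [x for x in dates if x > d]
    if not before or not after:
        return None
    hold, restart = before[-1], after[0]
    if restart < hold:
        raise ValueError("re-challenge date precedes hold date")
    return int((restart - hold).days)
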
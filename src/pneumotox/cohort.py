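"""Rule-based identification of candidate pneumonitis index reports.

The cascade mirrors a SQL ``LIKE``-style keyword screen over CT thorax
report text:

1. stage 1 — flag any report whose request or body text contains a
   screening phrase ("pneumonitis", "interstitial lung disease", ...);
2. stage 2 — keep only reports whose *body* (the radiologist's findings,
   not the clinician's request) contains a qualifying descriptor
   ("ground glass", "diffuse", ...);
3. treatment filter — keep only patients with a qualifying immune
   checkpoint inhibitor administration or a radiotherapy course to a
   qualifying site strictly before the report date;
4. optional labelled exclusions (a stand-in for manual validation of
   reports that mention but do not show pneumonitis);
5. episode deduplication — per patient, suppress reports within a
   6-month window of the last kept report, so each episode is represented
   by its earliest CT.

Matching is case-insensitive, punctuation-tolerant substring matching over
whitespace-normalised text.  There is no stemming and no word-boundary
enforcement ("pneumonia" matches inside "pneumonias", and a negated
mention "no evidence of pneumonitis" still matches): negation handling is
deliberately out of scope, which is why a manual-validation stand-in
exists downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TermConfig",
    "normalize_text",
    "flag_stage1",
    "filter_stage2",
    "filter_by_treatment",
    "apply_exclusions",
    "deduplicate_episodes",
    "run_cascade",
]

DEFAULT_STAGE1_TERMS = (
    "pneumonitis",
    "pulmonary toxicity",
    "lung toxicity",
    "lung injury",
    "interstitial lung disease",
    "pneumonia",
)
DEFAULT_STAGE2_TERMS = (
    "ground glass",
    "treatment",
    "drug",
    "diffuse",
    "infiltrates",
    "radiotherapy",
    "radiation",
)
ICI_DRUGS = (
    "atezolizumab",
    "avelumab",
    "durvalumab",
    "ipilimumab",
    "nivolumab",
    "pembrolizumab",
)
RT_SITES = ("thorax", "upper abdomen", "neck", "vertebrae", "breast", "chest wall")


@dataclass(frozen=True)
class TermConfig:
    """Keyword and treatment-filter rules; phrases are stored lower-cased."""

    stage1_terms: tuple[str, ...] = DEFAULT_STAGE1_TERMS
    stage2_terms: tuple[str, ...] = DEFAULT_STAGE2_TERMS
    ici_drugs: tuple[str, ...] = ICI_DRUGS
    rt_sites: tuple[str, ...] = RT_SITES
    dedup_window_days: int = 183  # 6 months

    def __post_init__(self) -> None:
        for name in ("stage1_terms", "stage2_terms", "ici_drugs", "rt_sites"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(v.lower() for v in vals))
        if self.dedup_window_days <= 0:
            raise ValueError("dedup_window_days must be > 0")


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(text: str) -> str:
    """Lower-case and collapse every punctuation/whitespace run to one
    space, so "ground-glass" matches the phrase "ground glass"."""
    if not isinstance(text, str):
        return ""
    return _NON_ALNUM.sub(" ", text.lower()).strip()


def _match_terms(text: str, terms: tuple[str, ...]) -> list[str]:
    norm = f" {normalize_text(text)} " if text else ""
    return [t for t in terms if normalize_text(t) in norm] if norm.strip() else []


def flag_stage1(reports: pd.DataFrame, config: TermConfig = TermConfig()) -> pd.DataFrame:
    """Stage-1 screen: flag reports containing any screening phrase in the
    request or body text.

    Records without a parseable scan date are rejected with a warning.
    Returns the flagged subset with ``stage1_request``/``stage1_body``
    match columns.
    """
    dates = pd.to_datetime(reports["scan_date"], errors="coerce")
    bad = dates.isna()
    if bad.any():
        logger.warning("rejecting %d report(s) with missing/invalid scan date", bad.sum())
    reports = reports.loc[~bad].assign(scan_date=dates[~bad])

    req = [
        _match_terms(t, config.stage1_terms) for t in reports["request_text"].fillna("")
    ]
    body = [
        _match_terms(t, config.stage1_terms) for t in reports["body_text"].fillna("")
    ]
    keep = [bool(r or b) for r, b in zip(req, body)]
    out = reports.loc[keep].copy()
    out["stage1_request"] = [r for r, k in zip(req, keep) if k]
    out["stage1_body"] = [b for b, k in zip(body, keep) if k]
    return out


def filter_stage2(flagged: pd.DataFrame, config: TermConfig = TermConfig()) -> pd.DataFrame:
    """Stage-2 filter: retain reports whose *body* text contains a
    qualifying descriptor.  Request-only mentions (a clinician querying
    "?pneumonitis") are dropped here."""
    body = [
        _match_terms(t, config.stage2_terms) for t in flagged["body_text"].fillna("")
    ]
    keep = [bool(b) for b in body]
    out = flagged.loc[keep].copy()
    out["stage2_body"] = [b for b, k in zip(body, keep) if k]
    return out


def filter_by_treatment(
    flagged: pd.DataFrame,
    ici_events: pd.DataFrame,
    rt_events: pd.DataFrame,
    config: TermConfig = TermConfig(),
) -> pd.DataFrame:
    """Retain reports whose patient received a listed ICI drug OR a
    radiotherapy course to a listed site strictly before the report date.

    Rows with unknown drug or site values are ignored (count logged).
    """
    ici = ici_events.assign(
        drug=ici_events["drug"].str.lower(),
        admin_date=pd.to_datetime(ici_events["admin_date"]),
    )
    unknown_drugs = ~ici["drug"].isin(config.ici_drugs)
    if unknown_drugs.any():
        logger.warning("ignoring %d ICI row(s) with unlisted drugs", unknown_drugs.sum())
    ici = ici.loc[~unknown_drugs]

    rt = rt_events.assign(
        site=rt_events["site"].str.lower(),
        first_fraction_date=pd.to_datetime(rt_events["first_fraction_date"]),
    )
    unknown_sites = ~rt["site"].isin(config.rt_sites)
    if unknown_sites.any():
        logger.warning("ignoring %d RT row(s) with unlisted sites", unknown_sites.sum())
    rt = rt.loc[~unknown_sites]

    ici_by_pt = ici.groupby("patient_id")["admin_date"].agg(list)
    rt_by_pt = rt.groupby("patient_id")["first_fraction_date"].agg(list)

    def qualifies(row: pd.Series) -> bool:
        d = row["scan_date"]
        if any(a < d for a in ici_by_pt.get(row["patient_id"], [])):
            return True
        return any(f < d for f in rt_by_pt.get(row["patient_id"], []))

    keep = flagged.apply(qualifies, axis=1) if len(flagged) else pd.Series(dtype=bool)
    return flagged.loc[keep.values if len(flagged) else []].copy()


def apply_exclusions(
    flagged: pd.DataFrame, excluded_report_ids: set[str] | None
) -> pd.DataFrame:
    """Manual-validation stand-in: drop labelled false-positive reports."""
    if not excluded_report_ids:
        return flagged
    keep = ~flagged["report_id"].isin(excluded_report_ids)
    logger.info(
        "manual-validation exclusions: %d -> %d reports", len(flagged), keep.sum()
    )
    return flagged.loc[keep].copy()


def deduplicate_episodes(
    flagged: pd.DataFrame, window_days: int = 183
) -> pd.DataFrame:
    """Per patient, keep the earliest report and suppress any subsequent
    report within ``window_days`` of the last KEPT report; a report beyond
    the window opens a new episode.

    Greedy earliest-first, deterministic (same-day ties broken by
    report_id, logged) and idempotent.
    """
    kept_idx: list = []
    window = pd.Timedelta(days=window_days)
    for pid, grp in flagged.groupby("patient_id", sort=True):
        if grp["scan_date"].duplicated().any():
            logger.warning(
                "patient %s has same-day reports; keeping first by report id", pid
            )
        grp = grp.sort_values(["scan_date", "report_id"], kind="mergesort")
        last_kept = None
        for idx, row in grp.iterrows():
            if last_kept is None or row["scan_date"] - last_kept >= window:
                kept_idx.append(idx)
                last_kept = row["scan_date"]
    out = flagged.loc[kept_idx].sort_values(
        ["patient_id", "scan_date"], kind="mergesort"
    )
    return out


def run_cascade(
    reports: pd.DataFrame,
    ici_events: pd.DataFrame,
    rt_events: pd.DataFrame,
    config: TermConfig = TermConfig(),
    excluded_report_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full cascade; returns (index reports, funnel stage counts)."""
    s1 = flag_stage1(reports, config)
    s2 = filter_stage2(s1, config)
    tr = filter_by_treatment(s2, ici_events, rt_events, config)
    va = apply_exclusions(tr, excluded_report_ids)
    ep = deduplicate_episodes(va, config.dedup_window_days)
    funnel = {
        "reports": len(reports),
        "stage1_flagged": len(s1),
        "stage2_filtered": len(s2),
        "treatment_filtered": len(tr),
        "validated": len(va),
        "episodes": len(ep),
    }
    logger.info("cascade funnel: %s", funnel)
    return ep, funnel
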
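"""Synthetic EHR generator for pneumonitis-pipeline testing.

Emits four record streams — CT thorax reports (request + body free text),
ICI administrations, radiotherapy courses, and dated clinical events —
plus a ground-truth table, with the statistical structure of a real-world
checkpoint-inhibitor / thoracic-radiotherapy pneumonitis cohort:

* a configurable share of patients are true pneumonitis cases, split
  between ICI-only, RT-only and combined aetiology (default mix 85:44:10
  among symptomatic cases, with 109 of 248 cases asymptomatic grade 1);
* time from treatment start to presentation follows a truncated
  log-normal parameterised to the observed means (ICI 4.5 months, range
  4 days-21 months; RT 3.6 months, range 8 days-8 months; 1 month =
  30.44 days throughout);
* true-case report bodies embed at least one screening term and one
  descriptor term; distractor reports exercise the cascade's failure
  modes (request-only mention, no qualifying treatment, or a negated
  mention "no evidence of pneumonitis" that a substring matcher cannot
  distinguish);
* 16-week resource events are drawn at the observed usage probabilities.

The generator is deterministic: one seed, one `numpy` Generator, fixed
iteration order, so identical config + seed gives byte-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfigError",
    "OnsetParams",
    "GeneratorConfig",
    "sample_onset",
    "generate_cohort",
    "simulate_dual_annotation",
]

DAYS_PER_MONTH = 30.44


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class OnsetParams:
    """Truncated log-normal time-to-onset: target mean and hard range, in
    days.  ``sigma`` sets the right-skew; the location parameter is solved
    so the truncated mean equals ``mean_days``."""

    mean_days: float
    min_days: float
    max_days: float
    sigma: float = 0.9

    def __post_init__(self) -> None:
        if not (self.min_days <= self.mean_days <= self.max_days):
            raise ConfigError("onset_params: mean must lie within [min, max]")
        if self.min_days <= 0:
            raise ConfigError("onset_params: min_days must be positive")


ICI_ONSET = OnsetParams(4.5 * DAYS_PER_MONTH, 4.0, 21 * DAYS_PER_MONTH, sigma=1.1)
RT_ONSET = OnsetParams(3.6 * DAYS_PER_MONTH, 8.0, 8 * DAYS_PER_MONTH, sigma=0.8)


def _check_pmf(name: str, pmf: dict[str, float] | tuple[float, ...]) -> None:
    vals = list(pmf.values()) if isinstance(pmf, dict) else list(pmf)
    if any(v < 0 for v in vals):
        raise ConfigError(f"{name}: probabilities must be non-negative")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {sum(vals)!r})")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_patients: int = 1000
    study_start: str = "2015-01-01"
    study_end: str = "2020-12-31"
    # P(case with given aetiology) over {ICI, RT, both, none}; the case
    # share defaults to 5% of scanned patients, split 85:44:10.
    p_pneumonitis_by_aetiology: dict[str, float] = field(
        default_factory=lambda: {
            "ICI": 0.05 * 85 / 139,
            "RT": 0.05 * 44 / 139,
            "both": 0.05 * 10 / 139,
            "none": 0.95,
        }
    )
    # grades 1..5; 109 asymptomatic of 248, symptomatic split 107/15/4/13
    severity_pmf: tuple[float, ...] = (
        109 / 248, 107 / 248, 15 / 248, 4 / 248, 13 / 248,
    )
    onset_params: dict[str, OnsetParams] = field(
        default_factory=lambda: {"ICI": ICI_ONSET, "RT": RT_ONSET, "both": ICI_ONSET}
    )
    # per-case 16-week usage probabilities ("all cases" column of the
    # management table)
    resource_probs: dict[str, float] = field(
        default_factory=lambda: {
            "antibiotics": 0.568,
            "steroids": 0.964,
            "cotrimoxazole": 0.295,
            "immunosuppression": 0.043,
            "referral": 0.417,
            "bal": 0.237,
            "pft": 0.086,
            "hospital_admission": 0.388,
            "ccu_admission": 0.072,
        }
    )
    p_superadded_infection: float = 0.18
    # follow-up clinic visit intensity by severity stratum
    clinic_mean_grade1: float = 4.4
    clinic_mean_grade234: float = 6.61
    clinic_mean_grade5: float = 2.0
    ct_mean: float = 1.0
    mdt_mean: float = 1.0
    hospital_stay: OnsetParams = OnsetParams(10.5, 1.0, 43.0, sigma=0.9)
    ccu_stay: OnsetParams = OnsetParams(6.5, 1.0, 20.0, sigma=0.7)
    referral_delay: OnsetParams = OnsetParams(34.0, 0.5, 215.0, sigma=1.0)
    bal_delay: OnsetParams = OnsetParams(35.0, 1.0, 149.0, sigma=1.0)
    pft_delay: OnsetParams = OnsetParams(30.0, 1.0, 112.0, sigma=1.0)
    death_delay: OnsetParams = OnsetParams(64.0, 6.0, 378.0, sigma=0.9)
    rechallenge_prob: float = 28 / 81
    lost_time: OnsetParams = OnsetParams(73.0, 11.0, 275.0, sigma=0.8)
    drug_pmf: dict[str, float] = field(
        default_factory=lambda: {
            "Pembrolizumab": 0.38,
            "Nivolumab": 0.24,
            "Ipilimumab": 0.13,
            "Durvalumab": 0.10,
            "Atezolizumab": 0.10,
            "Avelumab": 0.05,
        }
    )
    # combined-aetiology cases are dominated by consolidation durvalumab
    both_drug_pmf: dict[str, float] = field(
        default_factory=lambda: {
            "Durvalumab": 0.6, "Pembrolizumab": 0.3, "Atezolizumab": 0.1,
        }
    )
    site_pmf: dict[str, float] = field(
        default_factory=lambda: {
            "thorax": 0.6,
            "breast": 0.1,
            "chest wall": 0.1,
            "vertebrae": 0.1,
            "upper abdomen": 0.05,
            "neck": 0.05,
        }
    )
    distractor_rate: float = 0.15
    negated_distractors: bool = True
    p_background_ici: float = 0.5
    p_background_rt: float = 0.3
    p_clean_report: float = 0.6
    ici_cycle_days: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        _check_pmf("p_pneumonitis_by_aetiology", self.p_pneumonitis_by_aetiology)
        missing = {"ICI", "RT", "both", "none"} - set(self.p_pneumonitis_by_aetiology)
        if missing:
            raise ConfigError(
                f"p_pneumonitis_by_aetiology: missing keys {sorted(missing)}"
            )
        if len(self.severity_pmf) != 5:
            raise ConfigError("severity_pmf must have 5 entries (grades 1-5)")
        _check_pmf("severity_pmf", self.severity_pmf)
        _check_pmf("drug_pmf", self.drug_pmf)
        _check_pmf("both_drug_pmf", self.both_drug_pmf)
        _check_pmf("site_pmf", self.site_pmf)
        if not 0 <= self.distractor_rate <= 1:
            raise ConfigError("distractor_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# truncated log-normal sampling

@lru_cache(maxsize=64)
def _solve_mu(mean: float, lo: float, hi: float, sigma: float) -> float:
    """Location parameter of a log-normal truncated to [lo, hi] whose
    truncated mean equals ``mean``; solved by bisection (the truncated
    mean is monotone increasing in mu)."""
    llo, lhi = math.log(lo), math.log(hi)

    def trunc_mean(mu: float) -> float:
        a, b = (llo - mu) / sigma, (lhi - mu) / sigma
        z = norm.cdf(b) - norm.cdf(a)
        return math.exp(mu + sigma**2 / 2) * (norm.cdf(b - sigma) - norm.cdf(a - sigma)) / z

    left, right = llo - 8 * sigma, lhi + 8 * sigma
    for _ in range(200):
        mid = 0.5 * (left + right)
        if trunc_mean(mid) < mean:
            left = mid
        else:
            right = mid
    return 0.5 * (left + right)


def _trunc_lognormal(
    params: OnsetParams, rng: np.random.Generator, size: int | None = None
):
    """Inverse-CDF draw from the truncated log-normal; every value lies in
    [min_days, max_days] by construction."""
    n = 1 if size is None else size
    if params.min_days == params.max_days:
        out = np.full(n, float(params.min_days))
        return float(out[0]) if size is None else out
    mu, s = _solve_mu(params.mean_days, params.min_days, params.max_days, params.sigma), params.sigma
    a = norm.cdf((math.log(params.min_days) - mu) / s)
    b = norm.cdf((math.log(params.max_days) - mu) / s)
    u = rng.uniform(a, b, size=n)
    out = np.exp(mu + s * norm.ppf(u))
    out = np.clip(out, params.min_days, params.max_days)  # guard fp edges
    return float(out[0]) if size is None else out


def sample_onset(
    aetiology: str, params: OnsetParams, rng: np.random.Generator, size: int | None = None
):
    """Draw time-to-onset durations (days) for one aetiology.

    A degenerate range (min == max) returns that constant.
    """
    if aetiology not in {"ICI", "RT", "both"}:
        raise ValueError(f"unknown aetiology {aetiology!r}")
    return _trunc_lognormal(params, rng, size)


def _draw_days(params: OnsetParams, rng: np.random.Generator) -> float:
    """Truncated log-normal draw used for stays and delays."""
    return _trunc_lognormal(params, rng)


# ---------------------------------------------------------------------------
# report text templates

_CASE_REQUEST = (
    "Restaging CT thorax. On systemic therapy.",
    "CT thorax. New cough and breathlessness, ? pneumonitis.",
    "Urgent CT. Hypoxia on clinic review.",
)
_CASE_BODY = (
    "There is new {s2} ground glass change in both lungs. "
    "Appearances are in keeping with {s1} related to recent {cause}.",
    "New {s2} ground glass opacification and infiltrates bilaterally. "
    "Findings suggest {s1}, likely {cause} related.",
    "Interval development of {s2} ground glass change. "
    "Most likely represents {s1} secondary to {cause}.",
)
_CASE_S2 = ("diffuse", "patchy diffuse", "widespread diffuse")
_CASE_CAUSE = {"ICI": "drug treatment", "RT": "radiotherapy", "both": "drug treatment and radiotherapy"}

_CLEAN_REQUEST = ("Routine surveillance CT.", "Restaging CT thorax.")
_CLEAN_BODY = (
    "No significant abnormality. Stable appearances.",
    "Stable disease. No new lung findings.",
)
_NEGATED_BODY = (
    "No evidence of pneumonitis. Stable post-treatment appearances.",
    "Clear lungs with no pneumonitis. Expected post-radiotherapy change only.",
)
_REQUEST_ONLY = ("CT thorax. ? pneumonitis.", "CT thorax, query interstitial lung disease.")


def _pick(rng: np.random.Generator, options) -> str:
    return options[int(rng.integers(len(options)))]


def _categorical(rng: np.random.Generator, pmf: dict[str, float]) -> str:
    keys = list(pmf)
    return keys[int(rng.choice(len(keys), p=np.array([pmf[k] for k in keys])))]


# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic cohort.

    Returns a dict of DataFrames: ``reports`` (patient_id, report_id,
    scan_date, request_text, body_text), ``ici`` (patient_id, drug,
    admin_date), ``rt`` (patient_id, site, dose_gy, fractions,
    first_fraction_date), ``clinical`` (patient_id, event_type,
    event_date, value) and ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    horizon = (end - start).days

    reports, ici_rows, rt_rows, clinical, truth = [], [], [], [], []
    report_seq = 0

    def new_report(pid, date, request, body):
        nonlocal report_seq
        report_seq += 1
        reports.append(
            {
                "patient_id": pid,
                "report_id": f"R{report_seq:06d}",
                "scan_date": date.date().isoformat(),
                "request_text": request,
                "body_text": body,
            }
        )
        return reports[-1]["report_id"]

    def add_event(pid, etype, date, value=1):
        clinical.append(
            {
                "patient_id": pid,
                "event_type": etype,
                "event_date": date.date().isoformat(),
                "value": value,
            }
        )

    aet_keys = ["ICI", "RT", "both", "none"]
    aet_p = np.array([config.p_pneumonitis_by_aetiology[k] for k in aet_keys])

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        aet = aet_keys[int(rng.choice(4, p=aet_p))]

        if aet == "none":
            has_ici = rng.random() < config.p_background_ici
            has_rt = rng.random() < config.p_background_rt
            t_date = start + pd.Timedelta(days=int(rng.integers(0, horizon - 200)))
            is_distractor = rng.random() < config.distractor_rate
            dtypes = ["request_only", "no_treatment"]
            if config.negated_distractors:
                dtypes.append("negated")
            dtype = _pick(rng, dtypes) if is_distractor else ""
            if dtype == "no_treatment":
                has_ici = has_rt = False  # stage-1+2 text but nothing qualifying
            if has_ici:
                drug = _categorical(rng, config.drug_pmf)
                n_cycles = int(rng.integers(2, 12))
                for c in range(n_cycles):
                    ici_rows.append(
                        {
                            "patient_id": pid,
                            "drug": drug,
                            "admin_date": (
                                t_date + pd.Timedelta(days=c * config.ici_cycle_days)
                            ).date().isoformat(),
                        }
                    )
            if has_rt:
                rt_rows.append(
                    {
                        "patient_id": pid,
                        "site": _categorical(rng, config.site_pmf),
                        "dose_gy": 20 if rng.random() < 0.4 else 60,
                        "fractions": 5 if rng.random() < 0.4 else 30,
                        "first_fraction_date": t_date.date().isoformat(),
                    }
                )
            scan_date = t_date + pd.Timedelta(days=int(rng.integers(150, 190)))
            if dtype == "request_only":
                new_report(pid, scan_date, _pick(rng, _REQUEST_ONLY), _pick(rng, _CLEAN_BODY))
            elif dtype == "no_treatment":
                s2 = _pick(rng, _CASE_S2)
                body = _pick(rng, _CASE_BODY).format(s1="pneumonitis", s2=s2, cause="infection")
                new_report(pid, scan_date, _pick(rng, _CLEAN_REQUEST), body)
            elif dtype == "negated":
                # needs a qualifying treatment strictly before the scan to
                # survive the cascade as a false positive
                if not (has_ici or has_rt):
                    ici_rows.append(
                        {
                            "patient_id": pid,
                            "drug": "Pembrolizumab",
                            "admin_date": t_date.date().isoformat(),
                        }
                    )
                new_report(pid, scan_date, _pick(rng, _CLEAN_REQUEST), _pick(rng, _NEGATED_BODY))
            elif rng.random() < config.p_clean_report:
                new_report(pid, scan_date, _pick(rng, _CLEAN_REQUEST), _pick(rng, _CLEAN_BODY))
            truth.append(
                {
                    "patient_id": pid,
                    "is_case": False,
                    "aetiology": "",
                    "grade": 0,
                    "diagnosis_date": "",
                    "onset_days": "",
                    "distractor_type": dtype,
                    "rechallenged": False,
                    "lost_days": "",
                }
            )
            continue

        # --- true pneumonitis case -----------------------------------
        grade = 1 + int(rng.choice(5, p=np.array(config.severity_pmf)))
        onset = sample_onset(aet, config.onset_params[aet], rng)
        # keep the whole treatment->diagnosis arc inside the study window
        lead = int(math.ceil(onset))
        diag_offset = int(rng.integers(lead, max(lead + 1, horizon - 60)))
        diagnosis = start + pd.Timedelta(days=diag_offset)

        rechallenged, lost_days = False, ""
        if aet in ("ICI", "both"):
            drug = _categorical(
                rng, config.both_drug_pmf if aet == "both" else config.drug_pmf
            )
            t0 = diagnosis - pd.Timedelta(days=lead)
            admin = t0
            last_admin = t0
            while admin < diagnosis:
                ici_rows.append(
                    {
                        "patient_id": pid,
                        "drug": drug,
                        "admin_date": admin.date().isoformat(),
                    }
                )
                last_admin = admin
                admin += pd.Timedelta(days=config.ici_cycle_days)
            if aet == "ICI" and grade < 5 and rng.random() < config.rechallenge_prob:
                rechallenged = True
                lost = int(round(_draw_days(config.lost_time, rng)))
                restart = last_admin + pd.Timedelta(days=lost)
                for c in range(3):
                    ici_rows.append(
                        {
                            "patient_id": pid,
                            "drug": drug,
                            "admin_date": (
                                restart + pd.Timedelta(days=c * config.ici_cycle_days)
                            ).date().isoformat(),
                        }
                    )
                lost_days = lost
        if aet in ("RT", "both"):
            rt_onset = onset if aet == "RT" else sample_onset("RT", config.onset_params["RT"], rng)
            palliative = rng.random() < 0.18
            rt_rows.append(
                {
                    "patient_id": pid,
                    "site": "thorax",
                    "dose_gy": 20 if palliative else 60,
                    "fractions": 5 if palliative else 30,
                    "first_fraction_date": (
                        diagnosis - pd.Timedelta(days=int(math.ceil(rt_onset)))
                    ).date().isoformat(),
                }
            )

        # index report always carries stage-1 and stage-2 terms in the body
        s2 = _pick(rng, _CASE_S2)
        body = _pick(rng, _CASE_BODY).format(
            s1="pneumonitis", s2=s2, cause=_CASE_CAUSE[aet]
        )
        new_report(pid, diagnosis, _pick(rng, _CASE_REQUEST), body)
        # occasional follow-up scan inside the 6-month dedup window
        if rng.random() < 0.3:
            fu_date = diagnosis + pd.Timedelta(days=int(rng.integers(30, 150)))
            new_report(
                pid,
                fu_date,
                "Follow-up CT thorax.",
                "Improving diffuse ground glass change of the known pneumonitis.",
            )

        # severity flags consistent with the true grade
        if grade >= 2:
            add_event(pid, "symptomatic", diagnosis)
        if grade >= 3:
            add_event(pid, "oxygen_required", diagnosis)
        if grade >= 4:
            add_event(pid, "intubation", diagnosis)
        if grade == 5:
            death = diagnosis + pd.Timedelta(days=int(round(_draw_days(config.death_delay, rng))))
            add_event(pid, "death", death)
        if rng.random() < config.p_superadded_infection:
            add_event(pid, "infection", diagnosis)

        # 16-week resource events
        if grade == 1:
            clinic_mean = config.clinic_mean_grade1
        elif grade == 5:
            clinic_mean = config.clinic_mean_grade5
        else:
            clinic_mean = config.clinic_mean_grade234
        for etype, mean in (
            ("clinic_visit", clinic_mean),
            ("ct_thorax", config.ct_mean),
            ("mdt", config.mdt_mean),
        ):
            for _ in range(int(rng.poisson(mean))):
                add_event(pid, etype, diagnosis + pd.Timedelta(days=int(rng.integers(0, 112))))
        p = config.resource_probs
        if rng.random() < p["hospital_admission"]:
            nights = int(round(_draw_days(config.hospital_stay, rng)))
            add_event(pid, "hospital_admission",
                      diagnosis + pd.Timedelta(days=int(rng.integers(0, 14))), nights)
            if rng.random() < p["ccu_admission"] / p["hospital_admission"]:
                ccu_nights = int(round(_draw_days(config.ccu_stay, rng)))
                add_event(pid, "ccu_admission",
                          diagnosis + pd.Timedelta(days=int(rng.integers(0, 10))), ccu_nights)
        for etype, delay in (
            ("referral", config.referral_delay),
            ("bal", config.bal_delay),
            ("pft", config.pft_delay),
        ):
            if rng.random() < p[etype]:
                add_event(pid, etype,
                          diagnosis + pd.Timedelta(days=int(round(_draw_days(delay, rng)))))
        for etype in ("steroids", "antibiotics", "cotrimoxazole", "immunosuppression"):
            if rng.random() < p[etype]:
                add_event(pid, etype, diagnosis + pd.Timedelta(days=int(rng.integers(0, 7))))

        truth.append(
            {
                "patient_id": pid,
                "is_case": True,
                "aetiology": aet,
                "grade": grade,
                "diagnosis_date": diagnosis.date().isoformat(),
                "onset_days": round(onset, 2),
                "distractor_type": "",
                "rechallenged": rechallenged,
                "lost_days": lost_days,
            }
        )

    return {
        "reports": pd.DataFrame(
            reports,
            columns=["patient_id", "report_id", "scan_date", "request_text", "body_text"],
        ),
        "ici": pd.DataFrame(ici_rows, columns=["patient_id", "drug", "admin_date"]),
        "rt": pd.DataFrame(
            rt_rows,
            columns=["patient_id", "site", "dose_gy", "fractions", "first_fraction_date"],
        ),
        "clinical": pd.DataFrame(
            clinical, columns=["patient_id", "event_type", "event_date", "value"]
        ),
        "truth": pd.DataFrame(truth),
    }


def simulate_dual_annotation(
    grades, n_discordant: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Dual-rater grade annotations: rater 2 agrees everywhere except on
    ``n_discordant`` randomly chosen items, shifted by one grade."""
    g = np.asarray(grades, dtype=float)
    second = g.copy()
    idx = rng.choice(len(g), size=n_discordant, replace=False)
    second[idx] = np.where(second[idx] < 5, second[idx] + 1, second[idx] - 1)
    return pd.DataFrame({"rater1": g, "rater2": second})
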
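import re

import numpy as np
import pandas as pd
import pytest

from pneumotox.cohort import (
    TermConfig,
    deduplicate_episodes,
    filter_by_treatment,
    filter_stage2,
    flag_stage1,
    normalize_text,
    run_cascade,
)

# ---------------------------------------------------------------------------
# helpers: independent brute-force oracles


def _naive_contains(text, phrase):
    """Oracle matcher: lower-case, strip punctuation, substring."""
    clean = lambda s: re.sub(r"[^a-z0-9]+", " ", s.lower()).strip()
    return clean(phrase) in clean(text or "")


def _report(pid, rid, date, request="", body=""):
    return {
        "patient_id": pid,
        "report_id": rid,
        "scan_date": date,
        "request_text": request,
        "body_text": body,
    }


WORDS = (
    "lung lobe stable nodule effusion mass consolidation opacity unremarkable "
    "pneumonitis pneumonia drug treatment diffuse radiation radiotherapy "
    "ground glass infiltrates atelectasis metastasis emphysema".split()
)


def _random_corpus(rng, n=200):
    rows = []
    for i in range(n):
        req = " ".join(rng.choice(WORDS, size=rng.integers(2, 8)))
        body = " ".join(rng.choice(WORDS, size=rng.integers(4, 25)))
        rows.append(
            _report(f"P{rng.integers(1, 60):03d}", f"R{i:04d}",
                    f"20{rng.integers(15, 21):02d}-0{rng.integers(1, 10)}-1{rng.integers(0, 10)}",
                    req, body)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def test_stage1_flags_body_mention():
    reports = pd.DataFrame(
        [_report("P1", "R1", "2018-01-01", body="features in keeping with pneumonitis")]
    )
    out = flag_stage1(reports)
    assert len(out) == 1
    assert out.iloc[0]["stage1_body"] == ["pneumonitis"]


def test_stage1_empty_text_not_flagged():
    reports = pd.DataFrame([_report("P1", "R1", "2018-01-01", "", "")])
    assert len(flag_stage1(reports)) == 0


def test_stage1_missing_scan_date_rejected(caplog):
    reports = pd.DataFrame(
        [
            _report("P1", "R1", None, body="pneumonitis"),
            _report("P2", "R2", "2018-01-01", body="pneumonitis"),
        ]
    )
    out = flag_stage1(reports)
    assert list(out["report_id"]) == ["R2"]


def test_substring_semantics_no_word_boundaries():
    # "pneumonia" matches inside "pneumonias"; "pneumonitis" does not
    # match "pneumonia"
    reports = pd.DataFrame(
        [
            _report("P1", "R1", "2018-01-01", body="multifocal pneumonias"),
            _report("P2", "R2", "2018-01-01", body="basal pneumonia"),
        ]
    )
    out = flag_stage1(reports)
    assert {t for terms in out["stage1_body"] for t in terms} == {"pneumonia"}


def test_punctuation_tolerant_matching():
    reports = pd.DataFrame(
        [_report("P1", "R1", "2018-01-01", "?pneumonitis", "ground-glass change, drug related pneumonitis")]
    )
    s1 = flag_stage1(reports)
    assert "pneumonitis" in s1.iloc[0]["stage1_request"]
    s2 = filter_stage2(s1)
    assert set(s2.iloc[0]["stage2_body"]) >= {"ground glass", "drug"}


def test_stage2_drops_request_only_mentions():
    reports = pd.DataFrame(
        [_report("P1", "R1", "2018-01-01", "?pneumonitis", "unremarkable")]
    )
    assert len(filter_stage2(flag_stage1(reports))) == 0


def test_stage2_retains_body_descriptor_and_is_subset():
    reports = pd.DataFrame(
        [
            _report("P1", "R1", "2018-01-01", body="diffuse ground glass pneumonitis"),
            _report("P2", "R2", "2018-01-01", "?pneumonitis", "clear lungs"),
        ]
    )
    s1 = flag_stage1(reports)
    s2 = filter_stage2(s1)
    assert set(s2["report_id"]) <= set(s1["report_id"])
    assert list(s2["report_id"]) == ["R1"]
    assert set(s2.iloc[0]["stage2_body"]) == {"ground glass", "diffuse"}


def test_cascade_matches_bruteforce_scan_on_random_corpus(rng):
    reports = _random_corpus(rng, 200)
    cfg = TermConfig()
    s1 = flag_stage1(reports, cfg)
    expected_s1 = {
        r["report_id"]
        for _, r in reports.iterrows()
        if any(
            _naive_contains(r["request_text"], t) or _naive_contains(r["body_text"], t)
            for t in cfg.stage1_terms
        )
    }
    assert set(s1["report_id"]) == expected_s1
    s2 = filter_stage2(s1, cfg)
    expected_s2 = {
        r["report_id"]
        for _, r in s1.iterrows()
        if any(_naive_contains(r["body_text"], t) for t in cfg.stage2_terms)
    }
    assert set(s2["report_id"]) == expected_s2


def test_treatment_filter_examples():
    reports = flag_stage1(
        pd.DataFrame(
            [
                _report("P1", "R1", "2019-06-01", body="diffuse pneumonitis"),
                _report("P2", "R2", "2019-06-01", body="diffuse pneumonitis"),
            ]
        )
    )
    ici = pd.DataFrame(
        [{"patient_id": "P1", "drug": "Pembrolizumab", "admin_date": "2019-04-01"}]
    )
    rt = pd.DataFrame(columns=["patient_id", "site", "first_fraction_date"])
    out = filter_by_treatment(reports, ici, rt)
    assert list(out["report_id"]) == ["R1"]  # P2 has no treatment rows


def test_treatment_filter_strictly_before_and_unknown_values_ignored():
    reports = flag_stage1(
        pd.DataFrame([_report("P1", "R1", "2019-06-01", body="diffuse pneumonitis")])
    )
    same_day = pd.DataFrame(
        [{"patient_id": "P1", "drug": "Nivolumab", "admin_date": "2019-06-01"}]
    )
    rt_empty = pd.DataFrame(columns=["patient_id", "site", "first_fraction_date"])
    assert len(filter_by_treatment(reports, same_day, rt_empty)) == 0
    unknown = pd.DataFrame(
        [{"patient_id": "P1", "drug": "Cisplatin", "admin_date": "2019-01-01"}]
    )
    assert len(filter_by_treatment(reports, unknown, rt_empty)) == 0
    rt_site = pd.DataFrame(
        [{"patient_id": "P1", "site": "pelvis", "first_fraction_date": "2019-01-01"}]
    )
    assert len(filter_by_treatment(reports, unknown, rt_site)) == 0


def test_treatment_filter_matches_bruteforce_on_random_events(rng):
    reports = _random_corpus(rng, 150)
    flagged = flag_stage1(reports)
    cfg = TermConfig()
    pts = [f"P{i:03d}" for i in range(1, 60)]
    ici = pd.DataFrame(
        {
            "patient_id": rng.choice(pts, 120),
            "drug": rng.choice(list(cfg.ici_drugs) + ["cisplatin"], 120),
            "admin_date": [
                f"20{rng.integers(14, 22):02d}-0{rng.integers(1, 10)}-0{rng.integers(1, 10)}"
                for _ in range(120)
            ],
        }
    )
    rt = pd.DataFrame(
        {
            "patient_id": rng.choice(pts, 60),
            "site": rng.choice(list(cfg.rt_sites) + ["pelvis"], 60),
            "first_fraction_date": [
                f"20{rng.integers(14, 22):02d}-0{rng.integers(1, 10)}-0{rng.integers(1, 10)}"
                for _ in range(60)
            ],
        }
    )
    out = filter_by_treatment(flagged, ici, rt, cfg)
    expected = set()
    for _, r in flagged.iterrows():
        ok = False
        for _, e in ici.iterrows():
            if (
                e["patient_id"] == r["patient_id"]
                and e["drug"].lower() in cfg.ici_drugs
                and pd.Timestamp(e["admin_date"]) < r["scan_date"]
            ):
                ok = True
        for _, e in rt.iterrows():
            if (
                e["patient_id"] == r["patient_id"]
                and e["site"].lower() in cfg.rt_sites
                and pd.Timestamp(e["first_fraction_date"]) < r["scan_date"]
            ):
                ok = True
        if ok:
            expected.add(r["report_id"])
    assert set(out["report_id"]) == expected


# ---------------------------------------------------------------------------
# episode deduplication


def _dedup_oracle(dates, window_days):
    kept = []
    for d in sorted(dates):
        if not kept or (d - kept[-1]).days >= window_days:
            kept.append(d)
    return kept


def _flagged_frame(dates, pid="P1"):
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "report_id": f"R{i:03d}",
                "scan_date": pd.Timestamp(d),
            }
            for i, d in enumerate(dates)
        ]
    )


def test_dedup_six_month_rule_example():
    d0 = pd.Timestamp("2018-01-01")
    dates = [d0, d0 + pd.Timedelta(days=60), d0 + pd.Timedelta(days=200)]
    out = deduplicate_episodes(_flagged_frame(dates), 183)
    assert list(out["scan_date"]) == [d0, d0 + pd.Timedelta(days=200)]


def test_dedup_single_report_and_idempotence():
    f = _flagged_frame([pd.Timestamp("2019-05-05")])
    once = deduplicate_episodes(f, 183)
    assert len(once) == 1
    twice = deduplicate_episodes(once, 183)
    pd.testing.assert_frame_equal(once.reset_index(drop=True), twice.reset_index(drop=True))


def test_dedup_same_day_tie_broken_by_report_id():
    d = pd.Timestamp("2019-05-05")
    out = deduplicate_episodes(_flagged_frame([d, d]), 183)
    assert list(out["report_id"]) == ["R000"]


def test_dedup_matches_interval_suppression_oracle(rng):
    base = pd.Timestamp("2015-01-01")
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        offsets = sorted(int(x) for x in rng.choice(900, size=n, replace=False))
        dates = [base + pd.Timedelta(days=o) for o in offsets]
        window = int(rng.integers(30, 400))
        out = deduplicate_episodes(_flagged_frame(dates), window)
        assert list(out["scan_date"]) == _dedup_oracle(dates, window)
        # idempotence on the random set
        again = deduplicate_episodes(out, window)
        assert list(again["scan_date"]) == list(out["scan_date"])


# ---------------------------------------------------------------------------
# pipeline-level properties


def test_funnel_monotone_and_term_monotonicity(noisy_streams):
    s = noisy_streams
    _, funnel = run_cascade(s["reports"], s["ici"], s["rt"])
    assert (
        funnel["reports"]
        >= funnel["stage1_flagged"]
        >= funnel["stage2_filtered"]
        >= funnel["treatment_filtered"]
        >= funnel["validated"]
        >= funnel["episodes"]
    )
    # adding a stage-1 term can only grow the flagged set
    cfg = TermConfig()
    bigger = TermConfig(stage1_terms=cfg.stage1_terms + ("ground glass",))
    assert len(flag_stage1(s["reports"], bigger)) >= len(flag_stage1(s["reports"], cfg))


def test_cascade_recovers_ground_truth_exactly_when_clean(clean_streams):
    s = clean_streams
    episodes, _ = run_cascade(s["reports"], s["ici"], s["rt"])
    truth_cases = set(s["truth"].loc[s["truth"]["is_case"], "patient_id"])
    assert set(episodes["patient_id"]) == truth_cases
    assert len(episodes) == len(truth_cases)


def test_negated_distractors_hurt_precision_not_recall(noisy_streams):
    s = noisy_streams
    episodes, _ = run_cascade(s["reports"], s["ici"], s["rt"])
    found = set(episodes["patient_id"])
    truth_cases = set(s["truth"].loc[s["truth"]["is_case"], "patient_id"])
    assert truth_cases <= found  # recall 1.0
    assert found - truth_cases  # precision < 1.0: negated mentions leak through
    negated = set(
        s["truth"].loc[s["truth"]["distractor_type"] == "negated", "patient_id"]
    )
    assert (found - truth_cases) <= negated


def test_exclusions_standin_restores_precision(noisy_streams):
    s = noisy_streams
    truth = s["truth"]
    episodes, _ = run_cascade(s["reports"], s["ici"], s["rt"])
    false_pos = episodes[
        ~episodes["patient_id"].isin(truth.loc[truth["is_case"], "patient_id"])
    ]
    cleaned, funnel = run_cascade(
        s["reports"], s["ici"], s["rt"], excluded_report_ids=set(false_pos["report_id"])
    )
    assert set(cleaned["patient_id"]) == set(
        truth.loc[truth["is_case"], "patient_id"]
    )
    assert funnel["validated"] == funnel["treatment_filtered"] - len(false_pos)


def test_term_config_validation():
    with pytest.raises(ValueError):
        TermConfig(stage1_terms=())
    with pytest.raises(ValueError):
        TermConfig(dedup_window_days=0)
    cfg = TermConfig(stage1_terms=("Pneumonitis",))
    assert cfg.stage1_terms == ("pneumonitis",)
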
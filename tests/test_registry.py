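"""MELD scoring, status classification, outcomes and registry CSV I/O."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meldalloc.errors import InvalidInputError, SchemaError
from meldalloc.registry import (
    LabPanel,
    PatientRecord,
    StatusCriteria,
    SurvivalSample,
    classify_status,
    compute_meld,
    derive_outcome,
    effective_creatinine,
    labs_for_meld,
    meld_band,
    read_registry,
    summarize_cohort,
    write_registry,
)


def make_record(
    meld=15, status="3", hcc=False, reason="still_waiting", days=365.0, sex="M", **overrides
):
    criteria = {
        "2A": StatusCriteria(
            ctp_score=11, icu_admitted=True, life_expectancy_lt_7d=True, hepatorenal_syndrome=True
        ),
        "2B": StatusCriteria(ctp_score=10),
        "3": StatusCriteria(ctp_score=7),
    }[status]
    fields = dict(
        id="X1",
        age_years=50.0,
        sex=sex,
        blood_type="O",
        bmi=24.0,
        etiology="HBV",
        hcc=hcc,
        labs=labs_for_meld(meld),
        status_criteria=criteria,
        region=1,
        follow_up_days=days,
        removal_reason=reason,
        hcc_stage="T2" if hcc else None,
    )
    fields.update(overrides)
    return PatientRecord(**fields)


class TestEffectiveCreatinine:
    @pytest.mark.parametrize(
        "labs, expected",
        [
            (LabPanel(creatinine=8.0, bilirubin=1.0, inr=1.0), 4.0),  # cap
            (LabPanel(creatinine=0.5, bilirubin=1.0, inr=1.0), 1.0),  # floor
            (LabPanel(creatinine=1.2, bilirubin=1.0, inr=1.0, dialysis_sessions_last_week=2), 4.0),
            (LabPanel(creatinine=1.2, bilirubin=1.0, inr=1.0, cvvh_24h=True), 4.0),
            (LabPanel(creatinine=2.5, bilirubin=1.0, inr=1.0, dialysis_sessions_last_week=1), 2.5),
        ],
    )
    def test_override_cap_and_floor(self, labs, expected):
        assert effective_creatinine(labs) == expected

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(InvalidInputError):
            LabPanel(creatinine=-1.0, bilirubin=1.0, inr=1.0)
        with pytest.raises(InvalidInputError):
            LabPanel(creatinine=0.0, bilirubin=1.0, inr=1.0)


class TestComputeMeld:
    def test_floor_case(self):
        result = compute_meld(LabPanel(creatinine=1.0, bilirubin=1.0, inr=1.0))
        assert result.raw == pytest.approx(6.43)
        assert result.score == 6

    def test_hand_derived_example(self):
        # cr 8 (capped at 4), bili 5, INR 2: hand evaluation of the equation
        result = compute_meld(LabPanel(creatinine=8.0, bilirubin=5.0, inr=2.0))
        assert result.raw == pytest.approx(33.54, abs=0.01)
        assert result.score == 34

    def test_cap_at_40(self):
        labs = LabPanel(creatinine=4.0, bilirubin=50.0, inr=10.0, dialysis_sessions_last_week=3)
        assert compute_meld(labs).score == 40

    def test_sub_one_labs_floored_in_log(self):
        low = compute_meld(LabPanel(creatinine=0.7, bilirubin=0.4, inr=0.9))
        assert low.raw == pytest.approx(6.43)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        cr=st.floats(0.3, 10.0),
        bili=st.floats(0.3, 60.0),
        inr=st.floats(0.8, 20.0),
        bump=st.floats(0.01, 2.0),
    )
    def test_monotone_in_each_lab(self, cr, bili, inr, bump):
        base = compute_meld(LabPanel(creatinine=cr, bilirubin=bili, inr=inr))
        assert 6 <= base.score <= 40
        assert base.raw >= 6.43 - 1e-9
        for kwargs in (
            {"creatinine": cr + bump, "bilirubin": bili, "inr": inr},
            {"creatinine": cr, "bilirubin": bili + bump, "inr": inr},
            {"creatinine": cr, "bilirubin": bili, "inr": inr + bump},
        ):
            assert compute_meld(LabPanel(**kwargs)).raw >= base.raw - 1e-9

    def test_labs_for_meld_inverts_scoring(self):
        for score in range(6, 41):
            assert compute_meld(labs_for_meld(score)).score == score


class TestClassifyStatus:
    def test_status_2a_requires_icu_and_short_life_expectancy(self):
        c = StatusCriteria(
            ctp_score=11, icu_admitted=True, life_expectancy_lt_7d=True, hepatorenal_syndrome=True
        )
        assert classify_status(c) == "2A"

    def test_status_2b_from_ctp7_with_sbp(self):
        c = StatusCriteria(ctp_score=8, spontaneous_bacterial_peritonitis=True)
        assert classify_status(c) == "2B"

    def test_status_3_plain_ctp7(self):
        assert classify_status(StatusCriteria(ctp_score=7)) == "3"

    def test_t2_hcc_is_2b_even_with_low_ctp(self):
        assert classify_status(StatusCriteria(ctp_score=6, hcc_stage_t1_t2=True)) == "2B"

    def test_fulminant_trumps_everything(self):
        c = StatusCriteria(
            ctp_score=11,
            icu_admitted=True,
            life_expectancy_lt_7d=True,
            hepatorenal_syndrome=True,
            fulminant_or_early_graft_failure=True,
        )
        assert classify_status(c) == "1"

    def test_low_ctp_no_criteria_unlisted(self):
        assert classify_status(StatusCriteria(ctp_score=5)) == "unlisted"

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        ctp=st.integers(5, 15),
        flags=st.tuples(*[st.booleans()] * 9),
    )
    def test_total_function_with_urgency_precedence(self, ctp, flags):
        c = StatusCriteria(ctp, *flags)
        status = classify_status(c)
        assert status in ("1", "2A", "2B", "3", "unlisted")
        if c.fulminant_or_early_graft_failure:
            assert status == "1"
        elif status == "2A":
            assert c.ctp_score >= 10 and c.icu_admitted and c.life_expectancy_lt_7d
        elif status == "3":
            assert c.ctp_score >= 7 and c.ctp_score < 10 and not c.hcc_stage_t1_t2


class TestDeriveOutcome:
    @pytest.mark.parametrize(
        "reason, days, event",
        [
            ("deterioration", 40.0, True),
            ("death", 10.0, True),
            ("transplant", 100.0, False),
            ("improvement", 50.0, False),
            ("still_waiting", 365.0, False),
        ],
    )
    def test_composite_endpoint(self, reason, days, event):
        sample = derive_outcome(make_record(reason=reason, days=days))
        assert sample == SurvivalSample(time_days=days, event=event)

    def test_unknown_reason_rejected_at_construction(self):
        with pytest.raises(InvalidInputError):
            make_record(reason="lost")

    def test_event_plus_censored_preserves_count(self, default_cohort):
        _, records = default_cohort
        outcomes = [derive_outcome(r) for r in records]
        events = sum(o.event for o in outcomes)
        censored = sum(not o.event for o in outcomes)
        assert events + censored == len(records)


class TestRegistryIO:
    def test_round_trip_identity(self, tmp_path, default_cohort):
        _, records = default_cohort
        path = tmp_path / "registry.csv"
        write_registry(records[:25], path)
        assert read_registry(path) == records[:25]

    def test_malformed_row_reported_with_line_number(self, tmp_path, default_cohort):
        _, records = default_cohort
        path = tmp_path / "registry.csv"
        write_registry(records[:3], path)
        text = path.read_text().splitlines()
        text[2] = text[2].replace(f",{records[1].labs.creatinine}", ",-1", 1)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(InvalidInputError, match="line 3"):
            read_registry(path)

    def test_header_only_file_gives_empty_list(self, tmp_path, default_cohort):
        _, records = default_cohort
        path = tmp_path / "registry.csv"
        write_registry(records[:1], path)
        header = path.read_text().splitlines()[0]
        path.write_text(header + "\n")
        assert read_registry(path) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,age\n1,50\n")
        with pytest.raises(SchemaError, match="missing mandatory columns"):
            read_registry(path)


class TestSummarizeCohort:
    def test_single_record_single_cell(self):
        summary = summarize_cohort([make_record(meld=15, status="3")])
        counts = summary.status_band_counts
        assert counts.loc["3", "<=20"] == 1
        assert counts.values.sum() == 1

    def test_counts_sum_to_n_and_percentages_to_100(self, default_cohort):
        _, records = default_cohort
        summary = summarize_cohort(records)
        assert summary.status_band_counts.values.sum() == len(records)
        percent = summary.status_band_percent
        rows = summary.status_band_counts.sum(axis=1) > 0
        assert percent[rows.values].sum(axis=1).values == pytest.approx([100.0] * int(rows.sum()))
        for table in summary.covariates.values():
            assert table.sum() == len(records)

    def test_meld_band_bounds(self):
        assert meld_band(6) == (6, 20)
        assert meld_band(20) == (6, 20)
        assert meld_band(21) == (21, 30)
        assert meld_band(37) == (31, 37)
        assert meld_band(38) == (38, 40)
        with pytest.raises(InvalidInputError):
            meld_band(41)
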
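"""Cohort construction: arm assignment, eligibility, outcomes, covariates."""

import numpy as np
import pandas as pd
import pytest

from drclaims.cohort import (
    EXCLUSION_ORDER,
    apply_inclusion_exclusion,
    assign_treatment_group,
    build_cohort,
    compute_follow_up,
    extract_baseline_features,
)
from drclaims.exceptions import ConfigError, DataError


def rx(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "fill_date", "drug_class"])


IDENTITY_MAP = pd.DataFrame(
    {"code": ["428.1", "428.2", "428.3", "428.4", "250.1", "250.2", "xyz"],
     "phecode": ["428.1", "428.2", "428.3", "428.4", "250.1", "250.2", "xyz"]}
)


class TestAssignTreatmentGroup:
    @pytest.mark.parametrize(
        "fills, expected_class, expected_index",
        [
            # second fill at ~6.5 months: sustained
            ([(1, 0, "A"), (1, 200, "A")], "A", 0),
            # second fill at ~3 months: outside the 6-12-month window
            ([(1, 0, "A"), (1, 90, "A")], None, None),
            # earliest sustained class wins across classes
            ([(1, 0, "B"), (1, 210, "B"), (1, 30, "A"), (1, 250, "A")], "B", 0),
            # boundary days 183 and 365 are inside the window
            ([(1, 0, "A"), (1, 183, "A")], "A", 0),
            ([(1, 0, "A"), (1, 365, "A")], "A", 0),
            ([(1, 0, "A"), (1, 366, "A")], None, None),
            # a third fill in the window qualifies even if the second is early
            ([(1, 0, "A"), (1, 60, "A"), (1, 200, "A")], "A", 0),
        ],
    )
    def test_sustained_use_rule(self, fills, expected_class, expected_index):
        out = assign_treatment_group(rx(*fills), ["A", "B"])
        row = out.iloc[0]
        if expected_class is None:
            assert row["arm_class"] is None
            assert pd.isna(row["index_date"])
        else:
            assert row["arm_class"] == expected_class
            assert row["index_date"] == expected_index

    def test_same_day_tie_broken_by_priority(self):
        fills = rx((1, 0, "B"), (1, 200, "B"), (1, 0, "A"), (1, 210, "A"))
        out = assign_treatment_group(fills, ["A", "B"])
        assert out.iloc[0]["arm_class"] == "A"  # priority = listed order
        out2 = assign_treatment_group(fills, ["A", "B"], class_priority=["B", "A"])
        assert out2.iloc[0]["arm_class"] == "B"

    def test_unknown_class_warned_and_ignored(self):
        fills = rx((1, 0, "A"), (1, 200, "A"), (1, 10, "vitamin"))
        with pytest.warns(UserWarning, match="vitamin"):
            out = assign_treatment_group(fills, ["A"])
        assert out.iloc[0]["arm_class"] == "A"

    def test_empty_fills_give_no_arm(self):
        out = assign_treatment_group(rx(), ["A"])
        assert len(out) == 0


def _eligible_patient_tables(pid=1, index=400):
    assignments = pd.DataFrame(
        {"patient_id": [pid], "arm_class": ["A"],
         "index_date": pd.array([index], dtype="Int64")}
    )
    labs = pd.DataFrame(
        {"patient_id": [pid], "date": [index - 30], "lab_name": ["hba1c"],
         "value": [8.0]}
    )
    coverage = pd.DataFrame(
        {"patient_id": [pid], "start_date": [0], "end_date": [index + 600],
         "plan_type": ["MAPD"]}
    )
    dx = pd.DataFrame(
        {"patient_id": [pid, pid], "date": [100, 150], "code": ["250.2", "250.2"]}
    )
    return assignments, labs, coverage, dx


class TestInclusionExclusion:
    def test_fully_eligible_patient_retained(self):
        a, l, c, d = _eligible_patient_tables()
        eligible, attrition = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        assert len(eligible) == 1
        assert attrition.set_index("stage")["n"]["retained"] == 1

    def test_no_hba1c_excluded_with_reason(self):
        a, l, c, d = _eligible_patient_tables()
        l = l[l["lab_name"] != "hba1c"]
        _, attrition = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        tally = attrition.set_index("stage")["n"]
        assert tally["no_hba1c"] == 1 and tally["retained"] == 0

    def test_prior_hf_excluded(self):
        a, l, c, d = _eligible_patient_tables(index=400)
        d = pd.concat(
            [d, pd.DataFrame({"patient_id": [1], "date": [370], "code": ["428.2"]})]
        )
        _, attrition = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        assert attrition.set_index("stage")["n"]["prior_hf"] == 1

    def test_hf_on_index_day_is_not_prior(self):
        a, l, c, d = _eligible_patient_tables(index=400)
        d = pd.concat(
            [d, pd.DataFrame({"patient_id": [1], "date": [400], "code": ["428.2"]})]
        )
        eligible, _ = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        assert len(eligible) == 1

    def test_short_coverage_excluded(self):
        a, l, c, d = _eligible_patient_tables()
        c["end_date"] = c["start_date"] + 100
        _, attrition = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        assert attrition.set_index("stage")["n"]["coverage"] == 1

    def test_likely_t1dm_excluded(self):
        a, l, c, d = _eligible_patient_tables()
        d = pd.concat(
            [d, pd.DataFrame({"patient_id": [1] * 3, "date": [50, 60, 70],
                              "code": ["250.1"] * 3})]
        )
        _, attrition = apply_inclusion_exclusion(a, l, c, d, IDENTITY_MAP)
        assert attrition.set_index("stage")["n"]["t1dm"] == 1

    def test_map_without_hf_codes_is_config_error(self):
        a, l, c, d = _eligible_patient_tables()
        bad_map = IDENTITY_MAP[~IDENTITY_MAP["phecode"].str.startswith("428")]
        with pytest.raises(ConfigError, match="428"):
            apply_inclusion_exclusion(a, l, c, d, bad_map)

    def test_attrition_counts_sum_to_input(self, small_stream):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignments = assign_treatment_group(
                small_stream.rx_claims, ["insulin", "GLP1"]
            )
        _, attrition = apply_inclusion_exclusion(
            assignments, small_stream.labs, small_stream.coverage,
            small_stream.dx_claims, small_stream.code_map,
        )
        tally = attrition.set_index("stage")["n"]
        assert tally["input"] == tally["retained"] + sum(
            tally[r] for r in EXCLUSION_ORDER
        )


class TestComputeFollowUp:
    def _eligible(self, index=100):
        return pd.DataFrame(
            {"patient_id": [1], "arm_class": ["A"], "index_date": [index]}
        )

    @pytest.mark.parametrize(
        "hf_offsets, last_offset, expected_time, expected_event",
        [
            ([400], 2000, 400, 1),       # event before end of follow-up
            ([], 1500, 1500, 0),         # censored at last follow-up
            ([300, 500], 2000, 300, 1),  # first occurrence counts
            ([0], 2000, 0.5, 1),         # same-day event gets half a day
            ([1800], 1500, 1500, 0),     # HF after last follow-up: censored
        ],
    )
    def test_time_and_event(
        self, hf_offsets, last_offset, expected_time, expected_event
    ):
        index = 100
        dx = pd.DataFrame(
            {"patient_id": [1] * len(hf_offsets),
             "date": [index + d for d in hf_offsets],
             "code": ["428.1"] * len(hf_offsets)}
        )
        out = compute_follow_up(
            self._eligible(index), dx, IDENTITY_MAP,
            pd.Series({1: index + last_offset}),
        )
        assert out.iloc[0]["follow_up_days"] == expected_time
        assert out.iloc[0]["event"] == expected_event

    def test_event_time_is_offset_from_index(self):
        dx = pd.DataFrame(
            {"patient_id": [1], "date": [500], "code": ["428.3"]}
        )
        out = compute_follow_up(
            self._eligible(100), dx, IDENTITY_MAP, pd.Series({1: 2100})
        )
        assert out.iloc[0]["follow_up_days"] == 400
        assert out.iloc[0]["event"] == 1

    def test_censored_when_no_hf(self):
        dx = pd.DataFrame({"patient_id": [], "date": [], "code": []})
        out = compute_follow_up(
            self._eligible(100), dx, IDENTITY_MAP, pd.Series({1: 1600})
        )
        assert out.iloc[0]["follow_up_days"] == 1500
        assert out.iloc[0]["event"] == 0

    def test_first_of_multiple_hf_codes(self):
        dx = pd.DataFrame(
            {"patient_id": [1, 1], "date": [400, 600], "code": ["428.1", "428.4"]}
        )
        out = compute_follow_up(
            self._eligible(100), dx, IDENTITY_MAP, pd.Series({1: 2100})
        )
        assert out.iloc[0]["follow_up_days"] == 300

    def test_same_day_event_gets_half_day(self):
        dx = pd.DataFrame({"patient_id": [1], "date": [100], "code": ["428.1"]})
        out = compute_follow_up(
            self._eligible(100), dx, IDENTITY_MAP, pd.Series({1: 500})
        )
        assert out.iloc[0]["follow_up_days"] == 0.5
        assert out.iloc[0]["event"] == 1

    def test_last_followup_before_index_is_data_error(self):
        dx = pd.DataFrame({"patient_id": [], "date": [], "code": []})
        with pytest.raises(DataError, match="patient"):
            compute_follow_up(
                self._eligible(100), dx, IDENTITY_MAP, pd.Series({1: 50})
            )


class TestBaselineFeatures:
    def _inputs(self):
        eligible = pd.DataFrame(
            {"patient_id": [1], "arm_class": ["A"], "index_date": [400]}
        )
        patients = pd.DataFrame(
            {"patient_id": [1], "birth_year": [1950], "sex": ["M"],
             "medicaid": [0], "rural": [1], "socio_index": [52.0]}
        )
        dx = pd.DataFrame(
            {"patient_id": [1] * 4, "date": [390, 300, 405, 100],
             "code": ["xyz", "xyz", "xyz", "250.2"]}
        )
        labs = pd.DataFrame(
            {"patient_id": [1, 1], "date": [200, 370],
             "lab_name": ["hba1c", "hba1c"], "value": [8.1, 7.5]}
        )
        fills = rx((1, 350, "metformin"), (1, 380, "metformin"), (1, 420, "statins"))
        return eligible, patients, dx, labs, fills

    def test_most_recent_lab_in_window(self):
        eligible, patients, dx, labs, fills = self._inputs()
        out = extract_baseline_features(
            eligible, patients, dx, labs, fills, IDENTITY_MAP, phecodes=["xyz"]
        )
        assert out.iloc[0]["hba1c"] == 7.5

    def test_phecode_count_excludes_post_index(self):
        eligible, patients, dx, labs, fills = self._inputs()
        out = extract_baseline_features(
            eligible, patients, dx, labs, fills, IDENTITY_MAP, phecodes=["xyz"]
        )
        assert out.iloc[0]["xyz"] == 2  # claim at day 405 is post-index

    def test_med_counts_respect_window(self):
        eligible, patients, dx, labs, fills = self._inputs()
        out = extract_baseline_features(
            eligible, patients, dx, labs, fills, IDENTITY_MAP, phecodes=["xyz"]
        )
        assert out.iloc[0]["metformin"] == 2
        assert out.iloc[0]["statins"] == 0  # filled post-index

    def test_missing_lab_left_as_nan(self):
        eligible, patients, dx, labs, fills = self._inputs()
        out = extract_baseline_features(
            eligible, patients, dx, labs, fills, IDENTITY_MAP, phecodes=["xyz"]
        )
        assert np.isnan(out.iloc[0]["ldl"])

    def test_age_and_disease_duration(self):
        eligible, patients, dx, labs, fills = self._inputs()
        out = extract_baseline_features(
            eligible, patients, dx, labs, fills, IDENTITY_MAP, phecodes=["xyz"]
        )
        assert out.iloc[0]["age"] == pytest.approx(2016 + 400 / 365 - 1950)
        assert out.iloc[0]["disease_duration"] == pytest.approx(300 / 30.44)


class TestRoundTrip:
    def test_arms_and_index_dates_match_generator(self, small_stream):
        cohort, attrition = build_cohort(small_stream)
        exp = small_stream.expected
        merged = cohort.merge(exp, on="patient_id")
        assert (merged["arm_class"] == merged["expected_arm_class"]).all()
        assert (merged["index_date"] == merged["expected_index_date"]).all()
        assert set(cohort["patient_id"]) == set(
            exp.loc[exp["expected_eligible"], "patient_id"]
        )

    def test_follow_up_and_events_match_generator(self, small_stream):
        cohort, _ = build_cohort(small_stream)
        merged = cohort.merge(small_stream.expected, on="patient_id")
        assert (
            merged["follow_up_days"] == merged["expected_followup_days"]
        ).all()
        assert (merged["event"] == merged["expected_event"].astype(int)).all()

    def test_claim_row_permutation_invariance(self, small_stream):
        import dataclasses

        cohort_a, _ = build_cohort(small_stream)
        shuffled = dataclasses.replace(
            small_stream,
            rx_claims=small_stream.rx_claims.sample(frac=1, random_state=4)
            .reset_index(drop=True),
            dx_claims=small_stream.dx_claims.sample(frac=1, random_state=5)
            .reset_index(drop=True),
            labs=small_stream.labs.sample(frac=1, random_state=6)
            .reset_index(drop=True),
        )
        cohort_b, _ = build_cohort(shuffled)
        a = cohort_a.sort_values("patient_id").reset_index(drop=True)
        b = cohort_b.sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_no_pre_index_hf_in_cohort(self, small_stream):
        cohort, _ = build_cohort(small_stream)
        hf_codes = small_stream.code_map.loc[
            small_stream.code_map["phecode"].str.startswith("428"), "code"
        ]
        dx = small_stream.dx_claims
        hf_dx = dx[dx["code"].isin(set(hf_codes))]
        merged = hf_dx.merge(cohort[["patient_id", "index_date"]], on="patient_id")
        assert not (merged["date"] < merged["index_date"]).any()
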
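"""Exclusions, worse-knee selection, radiographic imputation and grouping."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oawear import (
    apply_exclusions,
    carry_forward_kl,
    classify_group,
    derive_cohort,
    impute_jsw,
    select_worse_knee,
)
from oawear.clinical import CLINICAL_COLUMNS

NAN = float("nan")


class TestClassifyGroup:
    def test_increase_beyond_mcid_is_worsening(self):
        assert classify_group(10.8, 10.8 + 19.6) == "worsening"

    def test_small_improvement_is_stable(self):
        assert classify_group(12.1, 12.1 - 1.9) == "stable"

    def test_change_of_exactly_ten_is_stable(self):
        assert classify_group(5.0, 15.0) == "stable"

    def test_large_improvement_is_stable(self):
        # the two groups exhaust the cohort: any non-worsening change is stable
        assert classify_group(40.0, 5.0) == "stable"

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="both visits"):
            classify_group(NAN, 20.0)

    @given(
        st.floats(0, 96),
        st.floats(-50, 50),
        st.floats(-20, 20),
    )
    def test_label_depends_only_on_the_difference(self, base, delta, shift):
        a = classify_group(base, base + delta)
        b = classify_group(base + shift, base + delta + shift)
        assert a == b


class TestSelectWorseKnee:
    def test_higher_kl_wins(self):
        assert select_worse_knee(3, 2, 3.5, 3.5) == "left"

    def test_kl_tie_smaller_jsw_wins(self):
        assert select_worse_knee(2, 2, 3.5, 4.0) == "left"

    def test_double_tie_defaults_to_right(self):
        assert select_worse_knee(2, 2, 4.0, 4.0) == "right"

    def test_single_missing_kl_yields_other_side(self):
        assert select_worse_knee(NAN, 1, 3.0, 3.0) == "right"
        assert select_worse_knee(1, NAN, 3.0, 3.0) == "left"

    def test_both_kl_missing_rejected(self):
        with pytest.raises(ValueError, match="worse knee undefined"):
            select_worse_knee(NAN, NAN, 3.0, 3.0)


class TestRadiographicImputation:
    def test_mean_of_two_adjacent_visits(self):
        assert impute_jsw([3.8, NAN, 3.6], 1) == pytest.approx(3.7)

    def test_single_adjacent_visit(self):
        assert impute_jsw([NAN, 3.8, 3.0], 0) == pytest.approx(3.8)

    def test_all_missing_stays_missing(self):
        assert math.isnan(impute_jsw([NAN, NAN, NAN], 1))

    def test_present_value_unchanged(self):
        assert impute_jsw([3.8, 3.5, 3.6], 1) == 3.5

    @given(
        st.floats(0.5, 8.0),
        st.floats(0.5, 8.0),
    )
    def test_imputed_value_inside_convex_hull(self, lo, hi):
        got = impute_jsw([lo, NAN, hi], 1)
        assert min(lo, hi) <= got <= max(lo, hi)

    def test_kl_carried_forward_from_previous_visit(self):
        assert carry_forward_kl([2, NAN], 1) == 2

    def test_kl_no_previous_visit_stays_missing(self):
        assert math.isnan(carry_forward_kl([NAN, 3], 0))

    def test_kl_repeated_carry_forward(self):
        assert carry_forward_kl([1, NAN, NAN], 2) == 1


def _record(pid, **overrides):
    """Two complete clinical rows (baseline + follow-up) for one participant."""
    rows = []
    for visit, womac in (("baseline", 12.0), ("followup", 14.0)):
        row = {
            "participant_id": pid,
            "visit": visit,
            "age": 65.0,
            "sex": "female",
            "race": "white",
            "bmi": 28.0,
            "womac_total": womac,
            "cesd": 6.0,
            "pase": 160.0,
            "gait_speed": 1.3,
            "sit_to_stand_s": 10.5,
            "falls": 0,
            "kl_left": 2,
            "kl_right": 1,
            "jsw_left": 3.5,
            "jsw_right": 4.0,
            "knee_replacement": False,
        }
        row.update(overrides.get(visit, {}))
        row.update(overrides.get("both", {}))
        rows.append(row)
    return rows


class TestDeriveCohort:
    def _frame(self, *records):
        return pd.DataFrame(
            [row for rec in records for row in rec], columns=CLINICAL_COLUMNS
        )

    def test_complete_record_included_and_derived(self):
        derived, log = derive_cohort(self._frame(_record("A")))
        row = derived.iloc[0]
        assert bool(row["included"]) and log.empty
        assert row["worse_side"] == "left"  # KL 2 beats KL 1
        assert row["group"] == "stable"

    def test_knee_replacement_excluded_first(self):
        derived, log = derive_cohort(
            self._frame(_record("A", both={"knee_replacement": True, "bmi": NAN}))
        )
        assert log.iloc[0]["exclusion_reason"] == "knee_replacement"

    def test_missing_radiograph_excluded(self):
        overrides = {
            "both": {"kl_left": NAN, "kl_right": NAN, "jsw_left": NAN, "jsw_right": NAN}
        }
        derived, log = derive_cohort(self._frame(_record("A", **overrides)))
        assert log.iloc[0]["exclusion_reason"] == "missing_radiograph"

    def test_missing_covariate_excluded(self):
        derived, log = derive_cohort(
            self._frame(_record("A", baseline={"bmi": NAN}))
        )
        assert log.iloc[0]["exclusion_reason"] == "missing_covariate"

    def test_invalid_accelerometry_excluded(self):
        accel = pd.DataFrame(
            {
                "participant_id": ["A", "A"],
                "visit": ["baseline", "followup"],
                "n_valid_days": [7, 2],
                "valid": [True, False],
            }
        )
        derived, log = derive_cohort(self._frame(_record("A")), accel)
        assert log.iloc[0]["exclusion_reason"] == "invalid_accelerometry"

    def test_followup_radiograph_filled_from_baseline(self):
        overrides = {
            "followup": {"kl_left": NAN, "kl_right": NAN, "jsw_left": NAN, "jsw_right": NAN}
        }
        derived, _ = derive_cohort(self._frame(_record("A", **overrides)))
        row = derived.iloc[0]
        assert row["kl_worse_followup"] == row["kl_worse_baseline"]
        assert row["jsw_worse_followup"] == pytest.approx(row["jsw_worse_baseline"])

    def test_apply_exclusions_returns_included_rows(self):
        frame = self._frame(
            _record("A"), _record("B", both={"knee_replacement": True})
        )
        kept, log = apply_exclusions(frame)
        assert set(kept["participant_id"]) == {"A"}
        assert list(log["participant_id"]) == ["B"]

    def test_empty_table_round_trips(self):
        derived, log = derive_cohort(pd.DataFrame(columns=CLINICAL_COLUMNS))
        assert derived.empty and log.empty


class TestGroupRecoveryOnSyntheticCohort:
    def test_groups_match_truth_exactly(self, small_cohort):
        _, clinical, truth = small_cohort
        derived, _ = derive_cohort(clinical)
        got = derived.set_index("participant_id")["group"].sort_index()
        assert (got == truth.groups.sort_index()).all()
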
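"""Non-wear detection and wear-validation rules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oawear import AnalysisParams, detect_nonwear, valid_days, valid_participant, wear_minutes
from oawear.wear import NonWearInterval, wear_mask_day

from conftest import brute_force_nonwear, enumerate_nonwear_windows, make_series


def seq(*parts) -> np.ndarray:
    """Concatenate (value, repeat) pairs into a count sequence."""
    out = []
    for value, n in parts:
        out.extend([value] * n)
    return np.array(out, dtype=np.int64)


class TestDetectNonwear:
    def test_all_zero_day_is_one_interval(self):
        ivs = detect_nonwear(np.zeros(1440, dtype=int))
        assert ivs == [NonWearInterval(0, 1440)]
        assert wear_minutes(np.zeros(1440, dtype=int), ivs) == 0

    def test_single_subthreshold_interruption_is_tolerated(self):
        # 45 zeros, one epoch of 50, 45 zeros, bounded by active epochs
        counts = seq((500, 1), (0, 45), (50, 1), (0, 45), (500, 1))
        ivs = detect_nonwear(counts)
        assert ivs == [NonWearInterval(1, 92)]
        assert ivs[0].length == 91
        assert [(iv.start, iv.end) for iv in ivs] == brute_force_nonwear(counts)

    def test_suprathreshold_epoch_breaks_window(self):
        counts = seq((0, 60), (150, 1), (0, 60))
        assert detect_nonwear(counts) == []
        assert brute_force_nonwear(counts) == []

    def test_three_interruptions_exceed_allowance(self):
        counts = seq((0, 45), (50, 1), (60, 1), (70, 1), (0, 45))
        assert detect_nonwear(counts) == []
        assert brute_force_nonwear(counts) == []

    def test_two_consecutive_interruption_minutes_are_tolerated(self):
        counts = seq((0, 50), (50, 1), (40, 1), (0, 50))
        assert detect_nonwear(counts) == [NonWearInterval(0, 102)]

    def test_interval_must_start_and_end_on_zero(self):
        # leading/trailing sub-threshold epochs never extend an interval
        counts = seq((50, 1), (0, 95), (50, 1))
        assert detect_nonwear(counts) == [NonWearInterval(1, 96)]

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            detect_nonwear(np.array([0, -1, 0]))

    def test_rejects_empty_day(self):
        with pytest.raises(ValueError):
            detect_nonwear(np.array([], dtype=int))

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 0, 0, 50, 99, 100, 150, 500]),
            min_size=1,
            max_size=250,
        ),
        st.sampled_from([20, 40, 90]),
    )
    def test_matches_bruteforce_enumeration(self, counts, min_window):
        got = [(iv.start, iv.end) for iv in detect_nonwear(counts, min_window)]
        assert got == brute_force_nonwear(counts, min_window)

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 50, 150]), min_size=30, max_size=200
        )
    )
    def test_zeroing_detected_intervals_is_stable(self, counts):
        """Erasing detected non-wear and re-running covers the same epochs."""
        counts = np.asarray(counts)
        ivs = detect_nonwear(counts, min_window_min=20)
        erased = counts.copy()
        for iv in ivs:
            erased[iv.start : iv.end] = 0
        again = detect_nonwear(erased, min_window_min=20)
        before = ~wear_mask_day(len(counts), ivs)
        after = ~wear_mask_day(len(counts), again)
        assert (after | ~before).all()  # original coverage is preserved

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 50, 99, 150]), min_size=1, max_size=200
        )
    )
    def test_qualifying_window_union_grows_as_window_shrinks(self, counts):
        """A shorter minimum window can only enlarge the set of epochs
        coverable by some qualifying window."""
        cov = {}
        for mw in (30, 60):
            mask = np.zeros(len(counts), dtype=bool)
            for a, b in enumerate_nonwear_windows(counts, mw):
                mask[a:b] = True
            cov[mw] = mask
        assert (cov[30] | ~cov[60]).all()

    @given(
        st.lists(
            st.sampled_from([0, 0, 0, 50, 150, 2000]), min_size=1, max_size=250
        )
    )
    def test_wear_conservation(self, counts):
        counts = np.asarray(counts)
        ivs = detect_nonwear(counts, min_window_min=30)
        covered = sum(iv.length for iv in ivs)
        assert wear_minutes(counts, ivs) + covered == len(counts)
        # intervals are disjoint, in order, >= the window length,
        # and bounded by zero-count epochs
        for prev, nxt in zip(ivs, ivs[1:]):
            assert prev.end <= nxt.start
        for iv in ivs:
            assert iv.length >= 30
            assert counts[iv.start] == 0 and counts[iv.end - 1] == 0


class TestDayAndParticipantValidity:
    def test_wear_minutes_complement(self):
        day = np.full(1440, 200)
        assert wear_minutes(day, []) == 1440
        assert wear_minutes(day, [NonWearInterval(0, 91)]) == 1349

    def test_day_with_exactly_600_wear_minutes_is_valid(self):
        # 840 leading zeros form one non-wear block; 600 active minutes remain
        day = seq((0, 840), (200, 600))
        s = make_series([day])
        df = valid_days(s)
        assert df.loc[0, "wear_min"] == 600
        assert bool(df.loc[0, "valid"])

    def test_day_with_599_wear_minutes_is_invalid(self):
        day = seq((0, 841), (200, 599))
        df = valid_days(make_series([day]))
        assert df.loc[0, "wear_min"] == 599
        assert not bool(df.loc[0, "valid"])

    def test_all_zero_day_invalid_with_zero_wear(self):
        df = valid_days(make_series([np.zeros(1440, dtype=int)]))
        assert df.loc[0, "wear_min"] == 0
        assert not bool(df.loc[0, "valid"])

    @pytest.mark.parametrize(
        "n_valid, expected", [(3, False), (4, True), (7, True)]
    )
    def test_participant_requires_4_to_7_valid_days(self, n_valid, expected):
        active = seq((200, 1440))
        idle = np.zeros(1440, dtype=int)
        days = [active] * n_valid + [idle] * (7 - n_valid)
        ok, count = valid_participant(make_series(days))
        assert ok is expected
        assert count == n_valid

    def test_more_than_seven_recorded_days_rejected(self):
        days = [seq((200, 1440))] * 8
        with pytest.raises(ValueError, match="at most"):
            valid_participant(make_series(days))

    def test_custom_thresholds_flow_through(self):
        day = seq((0, 1000), (200, 440))
        params = AnalysisParams(valid_day_min_wear=400)
        df = valid_days(make_series([day]), params)
        assert bool(df.loc[0, "valid"])
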
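"""Synthetic cohort generator: contracts, determinism, realism, round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oawear import (
    CohortSpec,
    generate_cohort,
    read_epoch_csv,
    write_epoch_csv,
)
from oawear.intensity import visit_summary_table
from oawear.synthetic import IntensityMix


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_participants=-1), "n_participants"),
            (dict(n_participants=5, worsening_fraction=1.5), "worsening_fraction"),
            (dict(n_participants=5, epoch_seconds=30), "epoch_seconds"),
            (dict(n_participants=5, n_days_per_visit=0), "n_days_per_visit"),
        ],
    )
    def test_invalid_fields_named_in_error(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            CohortSpec(**kwargs)

    def test_negative_decline_factor_rejected(self):
        effects = {
            "stable": np.ones(8),
            "worsening": np.array([1, 1, 1, 1, 1, -0.5, 1, 1]),
        }
        with pytest.raises(ValueError, match="decline_effects"):
            CohortSpec(n_participants=2, decline_effects=effects)


class TestGenerateCohort:
    def test_empty_cohort(self):
        series, clinical, truth = generate_cohort(CohortSpec(n_participants=0))
        assert series == [] and clinical.empty
        assert len(truth.groups) == 0
        assert np.isnan(truth.worsening_fraction())

    def test_identical_seed_gives_bit_identical_output(self):
        a = generate_cohort(CohortSpec(n_participants=4, seed=7))
        b = generate_cohort(CohortSpec(n_participants=4, seed=7))
        for sa, sb in zip(a[0], b[0]):
            assert sa.equals(sb)
        pd.testing.assert_frame_equal(a[1], b[1])
        for key in a[2].nonwear:
            assert np.array_equal(a[2].nonwear[key], b[2].nonwear[key])

    def test_structure_two_visits_seven_days(self, small_cohort):
        series, clinical, truth = small_cohort
        assert len(series) == 2 * 25
        for s in series:
            assert s.counts.shape == (7, 1440)
            assert s.steps.shape == (7, 1440)
        assert set(clinical["visit"]) == {"baseline", "followup"}

    def test_true_nonwear_epochs_have_zero_counts(self, small_cohort):
        series, _, truth = small_cohort
        for s in series:
            mask = truth.nonwear[(s.participant_id, s.visit)]
            assert (s.counts[mask] == 0).all()

    def test_steps_zero_when_counts_zero_and_capped(self, small_cohort):
        series, _, _ = small_cohort
        for s in series:
            assert (s.steps[s.counts == 0] == 0).all()
            assert s.steps.max() <= 130

    def test_womac_change_support_respects_groups(self, small_cohort):
        _, _, truth = small_cohort
        changes = truth.womac_change
        worsening = truth.groups == "worsening"
        assert (changes[worsening] > 10).all()
        assert changes[~worsening].between(-10, 10, inclusive="neither").all()

    def test_worsening_fraction_within_binomial_ci(self):
        """Grouping the drawn WOMAC changes recovers the specified prevalence
        within the binomial 95% CI of the draw (n=500, fraction 0.16)."""
        spec = CohortSpec(n_participants=500, worsening_fraction=0.16, seed=31)
        # only the clinical/made labels are needed: one day keeps it cheap
        spec.n_days_per_visit = 1
        _, _, truth = generate_cohort(spec)
        lo, hi = stats.binom.interval(0.95, 500, 0.16)
        assert lo <= (truth.groups == "worsening").sum() <= hi


class TestIntensityRealism:
    def test_daily_composition_near_targets(self, cohort200):
        """After the full wear/intensity pipeline, cohort-mean daily
        SED/LPA/MVPA minutes land within +/-20% of the generator's targets
        (averaged over >=100 participants at baseline)."""
        from oawear import valid_participant

        series, _, _ = cohort200
        baseline = [
            s for s in series if s.visit == "baseline" and valid_participant(s)[0]
        ]
        table = visit_summary_table(baseline)
        assert len(table) >= 100
        mix = IntensityMix()
        for col, target in (("sed_min", mix.sed), ("lpa_min", mix.lpa), ("mvpa_min", mix.mvpa)):
            got = table[col].mean()
            assert abs(got - target) / target <= 0.20, (col, got, target)


class TestEpochCsvRoundTrip:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        series, _, _ = small_cohort
        path = tmp_path / "epochs.csv"
        write_epoch_csv(series[:4], path)
        back = read_epoch_csv(path)
        assert len(back) == 4
        originals = {(s.participant_id, s.visit): s for s in series[:4]}
        for s in back:
            assert s.equals(originals[(s.participant_id, s.visit)])

    def test_empty_series_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_epoch_csv([], path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1  # header only
        assert read_epoch_csv(path) == []

    def test_one_day_writes_1440_rows(self, tmp_path, series_builder):
        day = np.arange(1440) % 300
        s = series_builder([day])
        path = tmp_path / "day.csv"
        write_epoch_csv(s, path)
        assert len(path.read_text().strip().splitlines()) == 1441
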
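"""End-to-end orchestration: epochs + clinical table -> comparison report.

``process_cohort`` runs wear validation, daily and diurnal summarisation and
the clinical derivations over a list of epoch series plus a clinical table;
``compare_cohort`` then produces the Stable-vs-Worsening report tables.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import clinical as clinical_mod
from . import compare as compare_mod
from . import diurnal, intensity, wear
from .params import DEFAULT_PARAMS, AnalysisParams
from .series import EpochSeries


@dataclasses.dataclass
class CohortResult:
    """Processed cohort: summaries, validity, derivations and exclusions."""

    params: AnalysisParams
    visit_summaries: pd.DataFrame
    intervals: pd.DataFrame
    accel_valid: pd.DataFrame
    derived: pd.DataFrame
    exclusions: pd.DataFrame
    clinical: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        inc = self.derived[self.derived["included"] & self.derived["group"].notna()]
        return inc.set_index("participant_id")["group"]


def process_cohort(
    series_list: list[EpochSeries],
    clinical: pd.DataFrame,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> CohortResult:
    """Run the full preprocessing chain over a cohort.

    Participant-visits failing the 4-7 valid-day rule are recorded in
    ``accel_valid`` and lead to exclusion; their summaries are not computed.
    """
    validity_rows = []
    ok_series: list[EpochSeries] = []
    masks: dict[tuple[str, str], object] = {}
    for s in series_list:
        if s.n_days > params.max_valid_days:
            raise ValueError(
                f"series has {s.n_days} recorded days; at most "
                f"{params.max_valid_days} are allowed per visit"
            )
        worn = wear.wear_mask(s, params)
        wear_min = worn.sum(axis=1)
        n_valid = int((wear_min >= params.valid_day_min_wear).sum())
        ok = params.min_valid_days <= n_valid <= params.max_valid_days
        validity_rows.append(
            {
                "participant_id": s.participant_id,
                "visit": s.visit,
                "n_valid_days": n_valid,
                "valid": ok,
            }
        )
        if ok:
            ok_series.append(s)
            masks[(s.participant_id, s.visit)] = worn
    accel_valid = pd.DataFrame(
        validity_rows, columns=["participant_id", "visit", "n_valid_days", "valid"]
    )

    visit_summaries = intensity.visit_summary_table(ok_series, params, masks=masks)
    intervals = diurnal.interval_summary_table(ok_series, params, masks=masks)
    derived, exclusions = clinical_mod.derive_cohort(clinical, accel_valid, params)
    return CohortResult(
        params=params,
        visit_summaries=visit_summaries,
        intervals=intervals,
        accel_valid=accel_valid,
        derived=derived,
        exclusions=exclusions,
        clinical=clinical,
    )


def compare_cohort(result: CohortResult) -> dict[str, pd.DataFrame]:
    """Build the comparison report tables for a processed cohort."""
    return compare_mod.build_tables(
        result.visit_summaries,
        result.intervals,
        result.derived,
        result.clinical,
        result.params,
    )


def interval_group_pct_change(
    result: CohortResult,
    metric: str = "counts",
    bins: tuple[int, ...] | None = None,
    pooled: bool = False,
) -> pd.DataFrame | dict[str, float]:
    """Group-level percent change per diurnal bin (or pooled over bins).

    Per-bin estimates use the ratio of group means of within-person change
    to the group mean baseline. With ``pooled=True`` the bins are summed
    within participant first (e.g. ``bins=(5, 6)`` for 15:00-21:00).
    """
    groups = result.groups
    if pooled:
        return compare_mod.pooled_pct_change(
            result.intervals, groups, bins or (5, 6), metric
        )
    iv = result.intervals[result.intervals["participant_id"].isin(groups.index)]
    if bins is not None:
        iv = iv[iv["bin"].isin(bins)]
    wide = iv.pivot_table(
        index=["participant_id", "bin"], columns="visit", values=metric
    )
    rows = []
    for b in sorted(iv["bin"].unique()):
        sub = wide.xs(b, level="bin")
        g = groups.reindex(sub.index)
        for name in ("stable", "worsening"):
            grp = sub[g == name].dropna()
            if grp.empty or grp["baseline"].mean() <= 0:
                continue
            rows.append(
                {
                    "bin": b,
                    "group": name,
                    "mean_baseline": grp["baseline"].mean(),
                    "mean_change": (grp["followup"] - grp["baseline"]).mean(),
                    "pct_change": compare_mod.percent_change(
                        grp["baseline"].mean(),
                        (grp["followup"] - grp["baseline"]).mean(),
                    ),
                }
            )
    return pd.DataFrame(rows)
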
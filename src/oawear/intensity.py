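"""Count cut-point intensity classification and daily activity summaries.

Worn epochs are classified with the Freedson counts/min cut-points for older
adults: sedentary (SED) 0-99, light (LPA) 100-1951, moderate-to-vigorous
(MVPA) >=1952. The 1952 counts/min epoch itself belongs to MVPA so the three
categories partition the non-negative integers. Non-worn epochs contribute to
no category and to no count or step total.

Daily summaries are averaged over *valid* days only (>=10 h wear), giving the
per-participant-visit means reported in cohort tables (total activity counts
per day, total steps per day, SED/LPA/MVPA minutes per day).
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, AnalysisParams
from .series import EpochSeries
from . import wear

INTENSITY_LABELS = ("SED", "LPA", "MVPA")

#: columns of a day-level summary that are averaged over valid days
DAY_METRICS = ("total_counts", "total_steps", "sed_min", "lpa_min", "mvpa_min", "wear_min")


def classify_counts(
    counts: np.ndarray, params: AnalysisParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Vectorised intensity codes (0=SED, 1=LPA, 2=MVPA) for counts/min."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return (
        (counts > params.sed_max).astype(np.int8)
        + (counts > params.lpa_max).astype(np.int8)
    )


def classify_epoch(count: int, params: AnalysisParams = DEFAULT_PARAMS) -> str:
    """Intensity category label for a single epoch's counts/min."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return INTENSITY_LABELS[int(classify_counts(np.array([count]), params)[0])]


@dataclasses.dataclass(frozen=True)
class DaySummary:
    """Activity totals for one calendar day, worn epochs only."""

    date: datetime.date | None
    wear_min: int
    total_counts: int
    total_steps: int
    sed_min: int
    lpa_min: int
    mvpa_min: int

    def __post_init__(self) -> None:
        if self.sed_min + self.lpa_min + self.mvpa_min != self.wear_min:
            raise ValueError("intensity minutes must sum to wear minutes")


def summarize_day(
    counts: np.ndarray,
    steps: np.ndarray,
    worn: np.ndarray,
    date: datetime.date | None = None,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> DaySummary:
    """Summarise one day over worn epochs.

    ``worn`` is the boolean wear mask from :mod:`oawear.wear`; all three
    arrays must have equal length.
    """
    counts = np.asarray(counts)
    steps = np.asarray(steps)
    worn = np.asarray(worn, dtype=bool)
    if not (len(counts) == len(steps) == len(worn)):
        raise ValueError("counts, steps and worn must have equal lengths")
    codes = classify_counts(counts, params)
    return DaySummary(
        date=date,
        wear_min=int(worn.sum()),
        total_counts=int(counts[worn].sum()),
        total_steps=int(steps[worn].sum()),
        sed_min=int((worn & (codes == 0)).sum()),
        lpa_min=int((worn & (codes == 1)).sum()),
        mvpa_min=int((worn & (codes == 2)).sum()),
    )


@dataclasses.dataclass
class VisitSummary:
    """Per-day summaries and valid-day means for one participant-visit."""

    participant_id: str
    visit: str
    days: pd.DataFrame  # one row per recorded day, with 'valid' flag
    means: pd.Series  # unweighted means of DAY_METRICS over valid days

    @property
    def n_valid_days(self) -> int:
        return int(self.days["valid"].sum())


def summarize_visit(
    series: EpochSeries,
    params: AnalysisParams = DEFAULT_PARAMS,
    worn: np.ndarray | None = None,
) -> VisitSummary:
    """Day summaries for every recorded day plus means over valid days.

    ``worn`` may carry a precomputed wear mask (shape ``(n_days, 1440)``)
    to avoid re-running non-wear detection.

    Raises
    ------
    ValueError
        If the series has no valid day (such participants are excluded
        upstream and have no defined visit summary).
    """
    if worn is None:
        worn = wear.wear_mask(series, params)
    wear_min = worn.sum(axis=1).astype(int)
    valid = wear_min >= params.valid_day_min_wear

    rows = []
    for d in range(series.n_days):
        s = summarize_day(series.counts[d], series.steps[d], worn[d], params=params)
        rows.append(
            {
                "date": series.start_date + datetime.timedelta(days=d),
                "valid": bool(valid[d]),
                "wear_min": s.wear_min,
                "total_counts": s.total_counts,
                "total_steps": s.total_steps,
                "sed_min": s.sed_min,
                "lpa_min": s.lpa_min,
                "mvpa_min": s.mvpa_min,
            }
        )
    days = pd.DataFrame(
        rows,
        columns=["date", "valid", "wear_min", "total_counts", "total_steps",
                 "sed_min", "lpa_min", "mvpa_min"],
    )
    if not days["valid"].any():
        raise ValueError(
            f"participant {series.participant_id!r} visit {series.visit!r} "
            "has no valid day; visit summary is undefined"
        )
    means = days.loc[days["valid"], list(DAY_METRICS)].mean()
    return VisitSummary(series.participant_id, series.visit, days, means)


def visit_summary_table(
    series_list: list[EpochSeries],
    params: AnalysisParams = DEFAULT_PARAMS,
    masks: dict | None = None,
) -> pd.DataFrame:
    """Stack valid-day means for many series; one row per participant-visit.

    ``masks`` optionally maps ``(participant_id, visit)`` to precomputed
    wear masks.
    """
    rows = []
    for s in series_list:
        worn = masks.get((s.participant_id, s.visit)) if masks else None
        vs = summarize_visit(s, params, worn=worn)
        row = {"participant_id": vs.participant_id, "visit": vs.visit,
               "n_valid_days": vs.n_valid_days}
        row.update(vs.means.to_dict())
        rows.append(row)
    cols = ["participant_id", "visit", "n_valid_days", *DAY_METRICS]
    return pd.DataFrame(rows, columns=cols)
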
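"""Non-wear detection and wear-time validation.

Non-wear is inferred from sustained runs of zero activity counts: an interval
of at least ``min_window_min`` consecutive minutes of zero counts qualifies as
non-wear, tolerating up to ``allowance_count`` interruption minutes whose
counts are strictly between zero and ``allowance_threshold`` counts/min.
Interruptions must be strictly interior - every detected interval starts and
ends on a zero-count epoch - and the tolerated minutes are counted in total
per interval (they may be consecutive). Detection scans each calendar day
left to right and keeps maximal, disjoint intervals: from the leftmost
feasible start the longest qualifying window is taken, then the scan resumes
after it. Epochs with sub-threshold counts outside any qualifying window are
ordinary wear time.

Day-level wear minutes are the complement of detected non-wear; a day with at
least 10 hours (600 min) of wear is valid, and a participant-visit is
analysable when it contributes 4-7 valid days.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, AnalysisParams
from .series import EpochSeries


@dataclasses.dataclass(frozen=True)
class NonWearInterval:
    """Half-open epoch range ``[start, end)`` within one calendar day."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _zero_runs(iszero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    if not iszero.any():
        return []
    padded = np.concatenate(([False], iszero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_nonwear(
    counts: np.ndarray,
    min_window_min: int = 90,
    allowance_count: int = 2,
    allowance_threshold: int = 100,
) -> list[NonWearInterval]:
    """Detect maximal non-wear intervals in one day of minute counts.

    Parameters
    ----------
    counts:
        One calendar day of non-negative counts/min (any length >= 1).
    min_window_min:
        Minimum interval length in minutes.
    allowance_count:
        Total interruption minutes tolerated per interval.
    allowance_threshold:
        Interruption counts must be strictly below this value.

    Returns
    -------
    Disjoint, maximal :class:`NonWearInterval` objects in epoch order.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("counts must be numeric")
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")

    runs = _zero_runs(counts == 0)
    below = counts < allowance_threshold  # gap epochs are >0 by construction
    intervals: list[NonWearInterval] = []
    k = 0
    while k < len(runs):
        # Longest extension from the start of run k: bridge gaps between
        # consecutive zero runs while every gap epoch is sub-threshold and
        # the total bridged minutes stay within the allowance.
        j = k
        budget = allowance_count
        while j + 1 < len(runs):
            gap_start, gap_end = runs[j][1], runs[j + 1][0]
            gap = gap_end - gap_start
            if gap <= budget and below[gap_start:gap_end].all():
                budget -= gap
                j += 1
            else:
                break
        start, end = runs[k][0], runs[j][1]
        if end - start >= min_window_min:
            intervals.append(NonWearInterval(start, end))
            k = j + 1
        else:
            k += 1
    return intervals


def wear_mask_day(n_epochs: int, intervals: list[NonWearInterval]) -> np.ndarray:
    """Boolean per-epoch mask, True where the device was worn."""
    worn = np.ones(n_epochs, dtype=bool)
    for iv in intervals:
        worn[iv.start : iv.end] = False
    return worn


def wear_minutes(counts: np.ndarray, intervals: list[NonWearInterval]) -> int:
    """Number of epochs of the day not covered by any non-wear interval."""
    n = len(counts)
    return int(n - sum(iv.length for iv in intervals))


def wear_mask(series: EpochSeries, params: AnalysisParams = DEFAULT_PARAMS) -> np.ndarray:
    """Per-epoch wear mask of shape ``(n_days, 1440)`` for a whole series.

    Non-wear intervals never span midnight: detection runs independently per
    calendar day, so a physical removal crossing 00:00 appears as two
    intervals.
    """
    worn = np.ones_like(series.counts, dtype=bool)
    for d in range(series.n_days):
        ivs = detect_nonwear(
            series.counts[d],
            params.nonwear_min_window,
            params.nonwear_allowance_epochs,
            params.nonwear_allowance_threshold,
        )
        worn[d] = wear_mask_day(series.counts.shape[1], ivs)
    return worn


def valid_days(
    series: EpochSeries, params: AnalysisParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Per-day wear minutes and validity (wear >= 600 min).

    Returns a frame with columns ``date``, ``wear_min``, ``valid``.
    """
    worn = wear_mask(series, params)
    wear_min = worn.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "date": series.dates(),
            "wear_min": wear_min,
            "valid": wear_min >= params.valid_day_min_wear,
        }
    )


def valid_participant(
    series: EpochSeries, params: AnalysisParams = DEFAULT_PARAMS
) -> tuple[bool, int]:
    """Whether a participant-visit qualifies (4-7 valid days) and the count."""
    if series.n_days > params.max_valid_days:
        raise ValueError(
            f"series has {series.n_days} recorded days; at most "
            f"{params.max_valid_days} are allowed per visit"
        )
    n_valid = int(valid_days(series, params)["valid"].sum())
    return params.min_valid_days <= n_valid <= params.max_valid_days, n_valid


def wear_report(
    series_list: list[EpochSeries], params: AnalysisParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Cohort wear report: one row per participant-visit-day."""
    frames = []
    for s in series_list:
        df = valid_days(s, params)
        df.insert(0, "visit", s.visit)
        df.insert(0, "participant_id", s.participant_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "visit", "date", "wear_min", "valid"]
        )
    return pd.concat(frames, ignore_index=True)
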
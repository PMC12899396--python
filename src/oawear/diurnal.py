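"""Diurnal segmentation: per-3-hour-interval activity metrics.

The 24 h day is tiled by eight half-open clock-anchored bins
[00:00-03:00), [03:00-06:00), ..., [21:00-24:00); an epoch belongs to the bin
containing its start minute. For each bin we compute activity counts, step
counts, SED/LPA/MVPA minutes and the percentage of non-wear time (share of
the full 180 bin-minutes), averaged over valid days. Because overnight
non-wear dominates the early and late bins, primary analyses focus on the
four daytime bins 09:00-12:00, 12:00-15:00, 15:00-18:00 and 18:00-21:00
(indices 3-6).
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, AnalysisParams
from .series import EPOCHS_PER_DAY, EpochSeries
from . import wear
from .intensity import classify_counts

#: bin indices of the primary daytime window 09:00-21:00
DAYTIME_BINS = (3, 4, 5, 6)

#: per-bin metrics produced by :func:`summarize_intervals`
BIN_METRICS = ("counts", "steps", "sed_min", "lpa_min", "mvpa_min", "nonwear_pct")


def assign_bin(
    when: datetime.time | datetime.datetime | pd.Timestamp | int,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> int:
    """Diurnal bin index for a timestamp (or minute-of-day integer)."""
    if isinstance(when, (int, np.integer)):
        minute = int(when)
        if not 0 <= minute < EPOCHS_PER_DAY:
            raise ValueError("minute-of-day must be in [0, 1440)")
        hour = minute // 60
    else:
        hour = when.hour
    return hour // params.bin_hours


def bin_label(bin_index: int, params: AnalysisParams = DEFAULT_PARAMS) -> str:
    h = bin_index * params.bin_hours
    return f"{h:02d}:00-{h + params.bin_hours:02d}:00"


def _day_bin_metrics(
    counts: np.ndarray, steps: np.ndarray, worn: np.ndarray, params: AnalysisParams
) -> dict[str, np.ndarray]:
    """Per-bin metric vectors (length n_bins) for one 1440-epoch day."""
    n_bins, bm = params.n_bins, params.bin_minutes
    shape = (n_bins, bm)
    worn_b = worn.reshape(shape)
    counts_b = np.where(worn_b, counts.reshape(shape), 0)
    steps_b = np.where(worn_b, steps.reshape(shape), 0)
    codes_b = classify_counts(counts.reshape(shape), params)
    return {
        "counts": counts_b.sum(axis=1),
        "steps": steps_b.sum(axis=1),
        "sed_min": (worn_b & (codes_b == 0)).sum(axis=1),
        "lpa_min": (worn_b & (codes_b == 1)).sum(axis=1),
        "mvpa_min": (worn_b & (codes_b == 2)).sum(axis=1),
        "nonwear_pct": 100.0 * (bm - worn_b.sum(axis=1)) / bm,
    }


def summarize_intervals(
    series: EpochSeries,
    params: AnalysisParams = DEFAULT_PARAMS,
    worn: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin metrics averaged over valid days for one participant-visit.

    Returns a frame indexed by bin 0..7 with columns ``counts``, ``steps``,
    ``sed_min``, ``lpa_min``, ``mvpa_min``, ``nonwear_pct`` plus the clock
    ``window`` label. Within every valid day the bin-level intensity minutes
    and non-wear minutes sum to the full 180 bin-minutes, and bin totals
    aggregate exactly to the day totals. ``worn`` may carry a precomputed
    wear mask.
    """
    if worn is None:
        worn = wear.wear_mask(series, params)
    wear_min = worn.sum(axis=1)
    valid = np.flatnonzero(wear_min >= params.valid_day_min_wear)
    if valid.size == 0:
        raise ValueError(
            f"participant {series.participant_id!r} visit {series.visit!r} "
            "has no valid day"
        )
    acc = {m: np.zeros(params.n_bins) for m in BIN_METRICS}
    for d in valid:
        day = _day_bin_metrics(series.counts[d], series.steps[d], worn[d], params)
        for m in BIN_METRICS:
            acc[m] += day[m]
    out = pd.DataFrame({m: acc[m] / valid.size for m in BIN_METRICS})
    out.index.name = "bin"
    out.insert(0, "window", [bin_label(b, params) for b in out.index])
    return out


def interval_summary_table(
    series_list: list[EpochSeries],
    params: AnalysisParams = DEFAULT_PARAMS,
    masks: dict | None = None,
) -> pd.DataFrame:
    """Long-format per-bin summaries for many series.

    ``masks`` optionally maps ``(participant_id, visit)`` to precomputed
    wear masks.
    """
    frames = []
    for s in series_list:
        worn = masks.get((s.participant_id, s.visit)) if masks else None
        df = summarize_intervals(s, params, worn=worn).reset_index()
        df.insert(0, "visit", s.visit)
        df.insert(0, "participant_id", s.participant_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "visit", "bin", "window", *BIN_METRICS]
        )
    return pd.concat(frames, ignore_index=True)


def interval_change(
    baseline: pd.DataFrame, followup: pd.DataFrame
) -> pd.DataFrame:
    """Within-person change scores per bin (follow-up minus baseline).

    Both inputs are :func:`summarize_intervals` frames for the same
    participant. For every metric the frame gains ``<metric>_change`` and,
    where the baseline value is strictly positive, ``<metric>_pct`` (percent
    change relative to baseline); a zero baseline leaves the percent column
    NaN with ``<metric>_pct_defined`` False, and the absolute change is still
    reported.
    """
    if not baseline.index.equals(followup.index):
        raise ValueError("baseline and follow-up summaries cover different bins")
    out = pd.DataFrame(index=baseline.index.copy())
    if "window" in baseline.columns:
        out["window"] = baseline["window"]
    for m in BIN_METRICS:
        b, f = baseline[m].astype(float), followup[m].astype(float)
        out[f"{m}_change"] = f - b
        defined = b > 0
        out[f"{m}_pct"] = np.where(defined, 100.0 * (f - b) / b.where(defined), np.nan)
        out[f"{m}_pct_defined"] = defined
    return out
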
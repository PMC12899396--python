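"""Plain-text I/O for epoch and clinical tables.

Epoch CSV layout: ``participant_id, visit, timestamp, axis1_counts, steps``,
one row per minute epoch, ISO-8601 minute-resolution timestamps, sorted by
participant, visit, timestamp, UTF-8. Series round-trip losslessly; an empty
series writes a header-only file.
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from .clinical import CLINICAL_COLUMNS
from .series import EPOCHS_PER_DAY, EpochSeries

EPOCH_COLUMNS = ["participant_id", "visit", "timestamp", "axis1_counts", "steps"]


def _series_frame(series: EpochSeries) -> pd.DataFrame:
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    return df


def write_epoch_csv(series: EpochSeries | list[EpochSeries], path) -> None:
    """Write one or more epoch series to a single CSV file."""
    if isinstance(series, EpochSeries):
        series = [series]
    ordered = sorted(series, key=lambda s: (s.participant_id, s.visit))
    frames = [_series_frame(s) for s in ordered]
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=EPOCH_COLUMNS)
    out.to_csv(path, index=False)


def read_epoch_csv(path) -> list[EpochSeries]:
    """Read an epoch CSV back into :class:`EpochSeries` objects.

    Every participant-visit block must consist of whole, contiguous,
    minute-spaced calendar days.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    if df.empty:
        return []
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out: list[EpochSeries] = []
    for (pid, visit), sub in df.groupby(["participant_id", "visit"], sort=True):
        sub = sub.sort_values("timestamp")
        ts = sub["timestamp"]
        n = len(sub)
        if n % EPOCHS_PER_DAY != 0:
            raise ValueError(
                f"{pid}/{visit}: {n} epochs is not a whole number of days"
            )
        start = ts.iloc[0]
        if start.hour != 0 or start.minute != 0:
            raise ValueError(f"{pid}/{visit}: series must start at midnight")
        expected = pd.date_range(start, periods=n, freq="min")
        if not ts.reset_index(drop=True).equals(pd.Series(expected)):
            raise ValueError(f"{pid}/{visit}: epochs are not contiguous minutes")
        counts = sub["axis1_counts"].to_numpy(np.int64).reshape(-1, EPOCHS_PER_DAY)
        steps = sub["steps"].to_numpy(np.int64).reshape(-1, EPOCHS_PER_DAY)
        out.append(EpochSeries(pid, visit, start.date(), counts, steps))
    return out


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns: {sorted(missing)}")
    return df


def write_series_day_csv(path, date: datetime.date, counts, steps=None) -> None:
    """Convenience writer for a single synthetic day (mainly for fixtures)."""
    counts = np.asarray(counts)
    if steps is None:
        steps = np.zeros_like(counts)
    s = EpochSeries("P0000", "baseline", date, counts.reshape(1, -1),
                    np.asarray(steps).reshape(1, -1))
    write_epoch_csv(s, path)
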
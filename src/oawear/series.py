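"""Minute-epoch activity-count series for one participant-visit.

The in-memory representation keeps counts and steps as ``(n_days, 1440)``
integer arrays anchored at a start date, which makes day-level operations
(non-wear scans, diurnal binning) cheap reshapes. Timestamps are derived,
guaranteeing strictly increasing minute-resolution instants with whole
calendar days.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

EPOCHS_PER_DAY = 1440
VISITS = ("baseline", "followup")


@dataclasses.dataclass(eq=False)
class EpochSeries:
    """One participant-visit's minute-epoch counts and steps.

    ``counts`` and ``steps`` are non-negative integer arrays of shape
    ``(n_days, 1440)``; row ``i`` is the calendar day ``start_date + i``.
    """

    participant_id: str
    visit: str
    start_date: datetime.date
    counts: np.ndarray
    steps: np.ndarray

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"visit must be one of {VISITS}, got {self.visit!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        for name, arr in (("counts", self.counts), ("steps", self.steps)):
            if arr.ndim != 2 or (arr.size and arr.shape[1] != EPOCHS_PER_DAY):
                raise ValueError(
                    f"{name} must have shape (n_days, {EPOCHS_PER_DAY}), got {arr.shape}"
                )
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.counts.shape != self.steps.shape:
            raise ValueError("counts and steps must have equal shapes")

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.counts.size

    def dates(self) -> list[datetime.date]:
        return [self.start_date + datetime.timedelta(days=i) for i in range(self.n_days)]

    def timestamps(self) -> pd.DatetimeIndex:
        """Minute-resolution timestamps for every epoch, in order."""
        return pd.date_range(
            start=pd.Timestamp(self.start_date), periods=self.n_epochs, freq="min"
        )

    def day_counts(self, day: int) -> np.ndarray:
        return self.counts[day]

    def day_steps(self, day: int) -> np.ndarray:
        return self.steps[day]

    def to_frame(self) -> pd.DataFrame:
        """Long-format epoch table (one row per minute)."""
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "visit": self.visit,
                "timestamp": self.timestamps(),
                "axis1_counts": self.counts.ravel(),
                "steps": self.steps.ravel(),
            }
        )

    def equals(self, other: "EpochSeries") -> bool:
        return (
            self.participant_id == other.participant_id
            and self.visit == other.visit
            and self.start_date == other.start_date
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.steps, other.steps)
        )
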
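"""Tunable analysis parameters.

All thresholds used by the processing pipeline live here so that a single
object (optionally loaded from YAML) configures non-wear detection, valid-day
filtering, intensity cut-points, diurnal binning and the statistical battery.
Defaults follow the OAI accelerometer protocol conventions: the 90-minute
zero-count non-wear window with a 2-minute sub-100 counts/min interruption
allowance, the 10-hour valid-day rule with 4-7 valid days per participant,
Freedson count cut-points, and 3-hour clock-anchored diurnal bins with the
primary daytime window 09:00-21:00.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml


@dataclasses.dataclass(frozen=True)
class AnalysisParams:
    """Configuration for the accelerometer analysis pipeline.

    Attributes
    ----------
    nonwear_min_window:
        Minimum length (minutes) of a zero-count interval classified as
        non-wear.
    nonwear_allowance_epochs:
        Maximum number of interruption minutes tolerated inside a non-wear
        interval.
    nonwear_allowance_threshold:
        Interruption epochs must have counts strictly below this value
        (counts/min) to be tolerated.
    valid_day_min_wear:
        Minimum wear minutes for a day to count as valid (600 = 10 h).
    min_valid_days, max_valid_days:
        Range of valid days required for a participant-visit to be analysed.
    sed_max, lpa_max:
        Upper count cut-points (counts/min) for sedentary and light activity;
        anything above ``lpa_max`` is moderate-to-vigorous. The 1952 counts/min
        boundary itself is assigned to MVPA (Freedson >=1952 convention) so
        the three categories partition the non-negative integers.
    bin_hours:
        Width of a diurnal bin in hours (3 -> eight bins per day).
    daytime_bins:
        Bin indices forming the primary daytime analysis window
        (3..6 = 09:00-21:00).
    womac_mcid:
        WOMAC total-score increase beyond which a participant is classified
        as symptomatically worsening (strict inequality).
    alpha:
        Two-sided significance level for group comparisons.
    shapiro_alpha:
        Per-group Shapiro-Wilk significance level for the normality gate.
    chi2_continuity:
        Apply Yates continuity correction to 2x2 chi-square tests.
    p_adjust:
        Optional multiple-testing correction for comparison batteries:
        ``None`` (default, mirroring the source protocol) or ``"bh"`` for
        Benjamini-Hochberg.
    """

    nonwear_min_window: int = 90
    nonwear_allowance_epochs: int = 2
    nonwear_allowance_threshold: int = 100
    valid_day_min_wear: int = 600
    min_valid_days: int = 4
    max_valid_days: int = 7
    sed_max: int = 99
    lpa_max: int = 1951
    bin_hours: int = 3
    daytime_bins: tuple[int, ...] = (3, 4, 5, 6)
    womac_mcid: float = 10.0
    alpha: float = 0.05
    shapiro_alpha: float = 0.05
    chi2_continuity: bool = False
    p_adjust: str | None = None

    def __post_init__(self) -> None:
        if self.nonwear_min_window < 1:
            raise ValueError("nonwear_min_window must be >= 1")
        if self.nonwear_allowance_epochs < 0:
            raise ValueError("nonwear_allowance_epochs must be >= 0")
        if not 0 <= self.sed_max < self.lpa_max:
            raise ValueError("cut-points must satisfy 0 <= sed_max < lpa_max")
        if 24 % self.bin_hours != 0:
            raise ValueError("bin_hours must divide 24")
        n_bins = 24 // self.bin_hours
        if any(not 0 <= b < n_bins for b in self.daytime_bins):
            raise ValueError("daytime_bins out of range")
        if self.p_adjust not in (None, "bh"):
            raise ValueError("p_adjust must be None or 'bh'")

    @property
    def n_bins(self) -> int:
        return 24 // self.bin_hours

    @property
    def bin_minutes(self) -> int:
        return self.bin_hours * 60

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisParams":
        with open(path, "r", encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if "daytime_bins" in raw:
            raw["daytime_bins"] = tuple(raw["daytime_bins"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["daytime_bins"] = list(self.daytime_bins)
        return d


DEFAULT_PARAMS = AnalysisParams()
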
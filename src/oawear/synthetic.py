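"""Seeded synthetic cohort generator for the knee-OA activity analysis.

The generator emulates the data structure of a hip-worn accelerometer
sub-study of a knee-osteoarthritis cohort: every participant contributes two
visits ("baseline", "followup") of seven 1440-minute epoch days plus a
clinical record (WOMAC, CESD, PASE, gait speed, five-times sit-to-stand,
per-knee KL grade and medial minimum JSW, knee-replacement flag,
demographics). It exists so the whole processing pipeline is testable
without access-restricted cohort data, and it returns the ground truth
(group labels, injected per-bin decline factors, true non-wear epochs) for
parameter-recovery tests.

Count model
-----------
Within the waking wear window (07:00-22:00 by default) each minute's count is
a zero-inflated right-skewed draw: with hour-dependent probability ``p0(h)``
the epoch is zero, otherwise the count is Gamma-distributed with conditional
mean ``mu(h) * a_i * f / (1 - p0(h))`` so the unconditional epoch mean is
exactly ``mu(h) * a_i * f`` - ``mu`` the diurnal profile (counts/min),
``a_i`` a mean-one lognormal person-level activity factor shared across
visits, ``f`` the group's per-bin decline factor at the follow-up visit.
The zero probability rises at hours with low profile mean and is anchored to
the *baseline* profile, which keeps the epoch mean exactly linear in the
decline factor: the injected factors are recoverable from bin-level count
means without bias. On top of the background process, 0-3 contiguous
>=10-minute elevated-mean bouts per day (placement proportional to the
profile, amplitude scaled by ``a_i * f``) make MVPA accumulate in bouts
rather than isolated minutes.

Non-wear is literal: overnight (22:00-07:00) and sporadic daytime removals
are recorded as zero-count epochs, with the true non-wear mask kept in
:class:`SyntheticTruth`. Steps are a monotone stochastic function of counts
(capped at 130 steps/min, zero whenever counts are zero).
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import CLINICAL_COLUMNS
from .series import EPOCHS_PER_DAY, EpochSeries

# --- default study conditions -------------------------------------------------

#: per-hour mean counts/min of the background process during wear
DEFAULT_DIURNAL_PROFILE = np.array(
    [0, 0, 0, 0, 0, 0, 0, 120, 200, 260, 280, 280,
     260, 240, 240, 240, 230, 220, 200, 170, 140, 100, 0, 0],
    dtype=float,
)

#: multiplicative follow-up decline factors per 3-h bin. The decline of the
#: worsening group is concentrated in the late-afternoon/evening bins
#: (15:00-21:00, indices 5 and 6); the factors are chosen so that, weighted
#: by the default profile's per-bin count shares, the cohort reproduces a
#: ~-18%/-10% daily decline and ~-21%/-6% late-day decline for the
#: worsening/stable groups respectively.
DEFAULT_DECLINE_EFFECTS = {
    "stable": np.array([0.876, 0.876, 0.876, 0.876, 0.876, 0.94, 0.94, 0.876]),
    "worsening": np.array([0.838, 0.838, 0.838, 0.838, 0.838, 0.79, 0.79, 0.838]),
}

# calibrated count-model constants (see docs/methods.md)
_ZERO_BASE = 0.30
_ZERO_AMP = 0.62
_ZERO_REF = 220.0
_POS_SHAPE = 1.0
_PERSON_SIGMA = 0.45
_BOUT_TRIALS = 3
_BOUT_P = 1.0 / 3.0
_BOUT_AMP = 2600.0
_BOUT_SHAPE = 30.0
_STEP_CAP = 130
_STEP_HALF = 800.0
_STEP_POW = 0.9

#: group-conditional clinical model: (mean, sd) pairs and proportions taken
#: from the magnitudes typical of a knee-OA cohort in its mid-sixties.
CLINICAL_MODEL = {
    "stable": dict(
        age=(64.8, 8.9), female_p=0.552, white_p=0.851, bmi=(28.6, 4.8),
        cesd=(6.1, 7.1), cesd_change=(-0.2, 5.9),
        pase=(159.2, 80.5), pase_change=(1.7, 74.0),
        gait=(1.34, 0.20), gait_change=(-0.015, 0.11),
        tst=(10.50, 3.95), tst_change=(-0.034, 1.99),
        kl_ge2_p=0.744, jsw=(3.79, 1.44), jsw_change=(-0.047, 0.43),
    ),
    "worsening": dict(
        age=(65.9, 9.8), female_p=0.569, white_p=0.894, bmi=(28.6, 4.8),
        cesd=(6.8, 7.4), cesd_change=(0.3, 6.4),
        pase=(161.9, 83.8), pase_change=(-1.4, 65.0),
        gait=(1.33, 0.21), gait_change=(-0.067, 0.14),
        tst=(11.53, 5.00), tst_change=(0.563, 2.09),
        kl_ge2_p=0.821, jsw=(3.70, 1.50), jsw_change=(-0.132, 0.46),
    ),
}

_RACES = ("white", "black", "asian", "other")
_NONWHITE_P = np.array([0.915, 0.036, 0.049])  # split of the non-white share


@dataclasses.dataclass(frozen=True)
class NonWearModel:
    """Overnight off-body window plus sporadic daytime removals.

    ``overnight_start``/``overnight_end`` are clock hours (device off from
    start to end across midnight); removals arrive at ``daytime_rate``
    events/day with normally distributed durations (minutes).
    """

    overnight_start: int = 22
    overnight_end: int = 7
    daytime_rate: float = 0.2
    daytime_duration_mean: float = 110.0
    daytime_duration_sd: float = 25.0

    def __post_init__(self) -> None:
        for f in ("overnight_start", "overnight_end"):
            if not 0 <= getattr(self, f) < 24:
                raise ValueError(f"{f} must be in [0, 24)")
        if self.daytime_rate < 0:
            raise ValueError("daytime_rate must be >= 0")


@dataclasses.dataclass(frozen=True)
class IntensityMix:
    """Target daily minutes in each intensity category (valid-day means)."""

    sed: float = 579.8
    lpa: float = 278.1
    mvpa: float = 19.7

    def __post_init__(self) -> None:
        if min(self.sed, self.lpa, self.mvpa) < 0:
            raise ValueError("intensity_mix minutes must be >= 0")


@dataclasses.dataclass(frozen=True)
class WomacModel:
    """Baseline WOMAC distribution and per-group change distributions.

    Changes are truncated normals: the worsening group's support is strictly
    above the 10-point MCID, the stable group's inside (-10, 10), so group
    labels are functionally determined by the drawn change.
    """

    baseline_mean: float = 11.9
    baseline_sd: float = 14.9
    stable_change_mean: float = -1.9
    stable_change_sd: float = 8.1
    worsening_change_mean: float = 19.6
    worsening_change_sd: float = 9.2
    mcid: float = 10.0
    score_max: float = 96.0


@dataclasses.dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_participants: int
    worsening_fraction: float = 0.157
    n_days_per_visit: int = 7
    epoch_seconds: int = 60
    seed: int = 0
    diurnal_profile: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_DIURNAL_PROFILE.copy()
    )
    nonwear_model: NonWearModel = dataclasses.field(default_factory=NonWearModel)
    intensity_mix: IntensityMix = dataclasses.field(default_factory=IntensityMix)
    decline_effects: dict[str, np.ndarray] = dataclasses.field(
        default_factory=lambda: {g: v.copy() for g, v in DEFAULT_DECLINE_EFFECTS.items()}
    )
    womac_model: WomacModel = dataclasses.field(default_factory=WomacModel)
    low_wear_fraction: float = 0.02
    baseline_start: datetime.date = datetime.date(2008, 1, 7)
    followup_start: datetime.date = datetime.date(2010, 1, 4)

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be a non-negative integer")
        if not 0.0 <= self.worsening_fraction <= 1.0:
            raise ValueError("worsening_fraction must lie in [0, 1]")
        if self.n_days_per_visit < 1:
            raise ValueError("n_days_per_visit must be >= 1")
        if self.epoch_seconds != 60:
            raise ValueError("epoch_seconds: only 60-second epochs are supported")
        self.diurnal_profile = np.asarray(self.diurnal_profile, dtype=float)
        if self.diurnal_profile.shape != (24,):
            raise ValueError("diurnal_profile must have 24 per-hour values")
        if self.diurnal_profile.min() < 0:
            raise ValueError("diurnal_profile means must be >= 0")
        for g in ("stable", "worsening"):
            eff = np.asarray(self.decline_effects[g], dtype=float)
            if eff.shape != (8,):
                raise ValueError("decline_effects must give 8 per-bin factors per group")
            if eff.min() <= 0:
                raise ValueError("decline_effects factors must be > 0")
            self.decline_effects[g] = eff
        if not 0.0 <= self.low_wear_fraction <= 1.0:
            raise ValueError("low_wear_fraction must lie in [0, 1]")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a synthetic cohort draw.

    ``nonwear`` maps ``(participant_id, visit)`` to the boolean true
    non-wear mask of shape ``(n_days, 1440)``; every true non-wear epoch is
    recorded with zero counts.
    """

    groups: pd.Series
    womac_change: pd.Series
    decline_factors: dict[str, np.ndarray]
    nonwear: dict[tuple[str, str], np.ndarray]

    def worsening_fraction(self) -> float:
        if len(self.groups) == 0:
            return float("nan")
        return float((self.groups == "worsening").mean())


def _zero_prob(profile: np.ndarray, sed_target: float) -> np.ndarray:
    """Hour-level structural-zero probability, rising at low profile means."""
    scale = sed_target / IntensityMix().sed
    p0 = scale * (_ZERO_BASE + _ZERO_AMP * np.exp(-profile / _ZERO_REF))
    p0 = np.clip(p0, 0.0, 0.97)
    return np.where(profile <= 0, 1.0, p0)


def _truncnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _simulate_visit(
    rng: np.random.Generator,
    spec: CohortSpec,
    activity_factor: float,
    bin_factors: np.ndarray,
    low_wear: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts, steps and true non-wear mask for one participant-visit."""
    days = spec.n_days_per_visit
    hour = np.arange(EPOCHS_PER_DAY) // 60
    f_epoch = bin_factors[hour // 3]
    mu_base = spec.diurnal_profile[hour]
    p0 = _zero_prob(spec.diurnal_profile, spec.intensity_mix.sed)[hour]
    mu = activity_factor * mu_base * f_epoch
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_mean = np.where(p0 < 1.0, mu / (1.0 - p0), 0.0)

    u = rng.random((days, EPOCHS_PER_DAY))
    pos = rng.gamma(
        _POS_SHAPE, np.maximum(cond_mean, 1e-12) / _POS_SHAPE,
        size=(days, EPOCHS_PER_DAY),
    )
    counts = np.where(u < p0, 0, np.rint(pos)).astype(np.int64)

    # bout structure: 0-3 contiguous >=10-min elevated periods per day,
    # placed proportionally to the diurnal profile
    nw = spec.nonwear_model
    wear_hours = np.flatnonzero(spec.diurnal_profile > 0)
    bout_p = min(1.0, _BOUT_P * spec.intensity_mix.mvpa / IntensityMix().mvpa)
    if wear_hours.size:
        weights = spec.diurnal_profile[wear_hours]
        weights = weights / weights.sum()
        day_end = nw.overnight_start * 60
        for d in range(days):
            n_bouts = rng.binomial(_BOUT_TRIALS, bout_p)
            for _ in range(n_bouts):
                dur = 10 + rng.poisson(2)
                h = rng.choice(wear_hours, p=weights)
                start = int(h) * 60 + int(rng.integers(60))
                end = min(start + dur, day_end, EPOCHS_PER_DAY)
                if end <= start:
                    continue
                amp = _BOUT_AMP * activity_factor * f_epoch[start:end]
                counts[d, start:end] = np.rint(
                    rng.gamma(_BOUT_SHAPE, amp / _BOUT_SHAPE)
                ).astype(np.int64)

    # true non-wear: overnight window plus sporadic daytime removals
    nonwear = np.zeros((days, EPOCHS_PER_DAY), dtype=bool)
    minute = np.arange(EPOCHS_PER_DAY)
    overnight = (minute < nw.overnight_end * 60) | (minute >= nw.overnight_start * 60)
    nonwear[:, overnight] = True
    rate = 5.0 if low_wear else nw.daytime_rate
    dur_mean = 300.0 if low_wear else nw.daytime_duration_mean
    dur_sd = 60.0 if low_wear else nw.daytime_duration_sd
    for d in range(days):
        for _ in range(rng.poisson(rate)):
            start = int(rng.integers(540, 1141))
            dur = int(np.clip(np.rint(rng.normal(dur_mean, dur_sd)), 95, 600))
            nonwear[d, start : min(start + dur, EPOCHS_PER_DAY)] = True
    counts[nonwear] = 0

    lam = _STEP_CAP * (counts / (counts + _STEP_HALF)) ** _STEP_POW
    steps = np.minimum(rng.poisson(lam), _STEP_CAP).astype(np.int64)
    steps[counts == 0] = 0
    return counts, steps, nonwear


def _draw_womac(rng, model: WomacModel, group: str) -> tuple[float, float]:
    if group == "worsening":
        change = _truncnorm(
            rng, model.worsening_change_mean, model.worsening_change_sd,
            model.mcid, np.inf,
        )
    else:
        change = _truncnorm(
            rng, model.stable_change_mean, model.stable_change_sd,
            -model.mcid, model.mcid,
        )
    lo = max(0.0, -change)
    hi = model.score_max - max(change, 0.0)
    baseline = _truncnorm(rng, model.baseline_mean, model.baseline_sd, lo, hi)
    return round(baseline, 1), round(change, 1)


def _draw_clinical(rng, group: str) -> dict:
    """Demographics, clinical scores and radiographs for one participant."""
    m = CLINICAL_MODEL[group]
    out: dict = {}
    out["age"] = round(_truncnorm(rng, *m["age"], 45, 85), 1)
    out["sex"] = "female" if rng.random() < m["female_p"] else "male"
    if rng.random() < m["white_p"]:
        out["race"] = "white"
    else:
        out["race"] = _RACES[1:][rng.choice(3, p=_NONWHITE_P)]
    out["bmi"] = round(_truncnorm(rng, *m["bmi"], 16, 50), 1)
    out["cesd"] = round(_truncnorm(rng, *m["cesd"], 0, 60), 1)
    out["cesd_f"] = round(
        min(60.0, max(0.0, out["cesd"] + rng.normal(*m["cesd_change"]))), 1
    )
    out["pase"] = round(_truncnorm(rng, *m["pase"], 0, 500), 1)
    out["pase_f"] = round(
        min(500.0, max(0.0, out["pase"] + rng.normal(*m["pase_change"]))), 1
    )
    out["gait"] = round(_truncnorm(rng, *m["gait"], 0.3, 3.0), 3)
    out["gait_f"] = round(max(0.3, out["gait"] + rng.normal(*m["gait_change"])), 3)
    out["tst"] = round(_truncnorm(rng, *m["tst"], 3.0, 60.0), 2)
    out["tst_f"] = round(max(3.0, out["tst"] + rng.normal(*m["tst_change"])), 2)
    out["falls"] = int(rng.poisson(0.35))
    out["falls_f"] = int(rng.poisson(0.35))

    if rng.random() < m["kl_ge2_p"]:
        kl_worse = int(rng.choice([2, 3, 4], p=[0.50, 0.33, 0.17]))
    else:
        kl_worse = int(rng.choice([0, 1], p=[0.40, 0.60]))
    kl_better = int(rng.integers(0, kl_worse + 1))
    jsw_worse = round(_truncnorm(rng, *m["jsw"], 0.5, 8.0), 2)
    jsw_better = round(min(8.5, jsw_worse + abs(rng.normal(0.4, 0.3))), 2)
    jsw_delta = rng.normal(*m["jsw_change"])
    kl_worse_f = min(4, kl_worse + (1 if rng.random() < 0.04 else 0))

    worse_side = "left" if rng.random() < 0.5 else "right"
    sides = {"worse": worse_side, "better": "right" if worse_side == "left" else "left"}
    out[f"kl_{sides['worse']}"] = kl_worse
    out[f"kl_{sides['better']}"] = kl_better
    out[f"jsw_{sides['worse']}"] = jsw_worse
    out[f"jsw_{sides['better']}"] = jsw_better
    out[f"kl_{sides['worse']}_f"] = kl_worse_f
    out[f"kl_{sides['better']}_f"] = kl_better
    out[f"jsw_{sides['worse']}_f"] = round(max(0.2, jsw_worse + jsw_delta), 2)
    out[f"jsw_{sides['better']}_f"] = round(
        max(0.2, jsw_better + jsw_delta + rng.normal(0, 0.1)), 2
    )
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EpochSeries], pd.DataFrame, SyntheticTruth]:
    """Generate epoch series (both visits), the clinical table and the truth.

    Identical specs (including seed) give bit-identical outputs. With
    ``n_participants == 0`` all outputs are empty and no error is raised.
    """
    rng = np.random.default_rng(spec.seed)
    series: list[EpochSeries] = []
    clin_rows: list[dict] = []
    groups: dict[str, str] = {}
    womac_changes: dict[str, float] = {}
    nonwear: dict[tuple[str, str], np.ndarray] = {}

    width = max(4, len(str(max(spec.n_participants, 1))))
    for i in range(spec.n_participants):
        pid = f"P{i:0{width}d}"
        group = "worsening" if rng.random() < spec.worsening_fraction else "stable"
        activity = rng.lognormal(-0.5 * _PERSON_SIGMA**2, _PERSON_SIGMA)
        low_wear = rng.random() < spec.low_wear_fraction
        womac_b, womac_delta = _draw_womac(rng, spec.womac_model, group)
        clin = _draw_clinical(rng, group)
        knee_replacement = rng.random() < 0.02
        groups[pid] = group
        womac_changes[pid] = womac_delta

        # missingness injection to exercise imputation and exclusion rules
        radiograph_missing = rng.random() < 0.01
        jsw_f_missing = rng.random() < 0.03
        kl_f_missing = rng.random() < 0.03
        bmi_missing = rng.random() < 0.01

        for visit, start in (
            ("baseline", spec.baseline_start),
            ("followup", spec.followup_start),
        ):
            factors = (
                np.ones(8) if visit == "baseline" else spec.decline_effects[group]
            )
            counts, steps, nw_mask = _simulate_visit(
                rng, spec, activity, factors, low_wear
            )
            series.append(EpochSeries(pid, visit, start, counts, steps))
            nonwear[(pid, visit)] = nw_mask

            f = visit == "followup"
            suffix = "_f" if f else ""
            row = {
                "participant_id": pid,
                "visit": visit,
                "age": clin["age"],
                "sex": clin["sex"],
                "race": clin["race"],
                "bmi": np.nan if bmi_missing else clin["bmi"],
                "womac_total": round(womac_b + womac_delta, 1) if f else womac_b,
                "cesd": clin["cesd" + suffix],
                "pase": clin["pase" + suffix],
                "gait_speed": clin["gait" + suffix],
                "sit_to_stand_s": clin["tst" + suffix],
                "falls": clin["falls" + suffix],
                "kl_left": clin["kl_left" + suffix],
                "kl_right": clin["kl_right" + suffix],
                "jsw_left": clin["jsw_left" + suffix],
                "jsw_right": clin["jsw_right" + suffix],
                "knee_replacement": knee_replacement,
            }
            if radiograph_missing:
                row.update(
                    kl_left=np.nan, kl_right=np.nan, jsw_left=np.nan, jsw_right=np.nan
                )
            elif f:
                if kl_f_missing:
                    row.update(kl_left=np.nan, kl_right=np.nan)
                if jsw_f_missing:
                    row.update(jsw_left=np.nan, jsw_right=np.nan)
            clin_rows.append(row)

    clinical = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    truth = SyntheticTruth(
        groups=pd.Series(groups, dtype="object", name="group"),
        womac_change=pd.Series(womac_changes, dtype=float, name="womac_change"),
        decline_factors={g: v.copy() for g, v in spec.decline_effects.items()},
        nonwear=nonwear,
    )
    return series, clinical, truth
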
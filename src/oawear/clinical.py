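"""Clinical derivations: exclusions, worse-knee selection, imputation, grouping.

A participant is analysable when they have no knee replacement before
baseline, at least one knee with a radiographic reading, complete baseline
covariates, and valid accelerometry (4-7 valid days) at both visits.
Radiographic gaps are filled conservatively: a missing medial minimum joint
space width (JSW) is imputed as the mean of the available adjacent-visit
values, and a missing Kellgren-Lawrence (KL) grade is carried forward from
the most recent prior visit (assuming structural stability). The symptomatic
knee driving the analysis - the "worse side" - is the knee with the higher
KL grade, ties broken by smaller JSW, double ties by the right knee.

Symptom worsening follows the minimal clinically important difference for
the WOMAC total score (0-96, higher = worse): a participant whose score
increases by strictly more than 10 points between visits is "worsening",
everyone else (including large improvements) is "stable", so the two groups
exhaust the cohort.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, AnalysisParams

GROUPS = ("stable", "worsening")

EXCLUSION_REASONS = (
    "knee_replacement",
    "missing_radiograph",
    "missing_covariate",
    "invalid_accelerometry",
)

#: baseline covariates whose absence excludes a participant
BASELINE_COVARIATES = (
    "age", "sex", "bmi", "womac_total", "gait_speed", "sit_to_stand_s",
)

CLINICAL_COLUMNS = [
    "participant_id", "visit", "age", "sex", "race", "bmi",
    "womac_total", "cesd", "pase", "gait_speed", "sit_to_stand_s", "falls",
    "kl_left", "kl_right", "jsw_left", "jsw_right", "knee_replacement",
]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


def classify_group(
    womac_baseline: float, womac_followup: float, mcid: float = 10.0
) -> str:
    """MCID responder classification from two WOMAC total scores.

    Strictly more than ``mcid`` points of increase -> ``"worsening"``;
    any other change (including improvement of any size) -> ``"stable"``.
    """
    if _is_missing(womac_baseline) or _is_missing(womac_followup):
        raise ValueError("WOMAC total must be present at both visits")
    return "worsening" if (womac_followup - womac_baseline) > mcid else "stable"


def select_worse_knee(
    kl_left: float, kl_right: float, jsw_left: float, jsw_right: float
) -> str:
    """Worse-knee rule: higher KL; tie -> smaller JSW; double tie -> right."""
    if _is_missing(kl_left) and _is_missing(kl_right):
        raise ValueError("both KL grades missing; worse knee undefined")
    if _is_missing(kl_left):
        return "right"
    if _is_missing(kl_right):
        return "left"
    if kl_left != kl_right:
        return "left" if kl_left > kl_right else "right"
    if not _is_missing(jsw_left) and not _is_missing(jsw_right) and jsw_left != jsw_right:
        return "left" if jsw_left < jsw_right else "right"
    return "right"


def impute_jsw(values: Sequence[float], target: int) -> float:
    """Mean of the available adjacent-visit JSW values, else NaN.

    ``values`` is the ordered per-visit JSW sequence (NaN = missing); the
    imputed value never leaves the convex hull of the adjacent observations.
    A present value is returned unchanged.
    """
    v = list(values)
    if not _is_missing(v[target]):
        return float(v[target])
    adjacent = []
    if target - 1 >= 0 and not _is_missing(v[target - 1]):
        adjacent.append(float(v[target - 1]))
    if target + 1 < len(v) and not _is_missing(v[target + 1]):
        adjacent.append(float(v[target + 1]))
    return float(np.mean(adjacent)) if adjacent else float("nan")


def carry_forward_kl(values: Sequence[float], target: int) -> float:
    """Most recent prior non-missing KL grade, else NaN (or the value itself)."""
    v = list(values)
    if not _is_missing(v[target]):
        return float(v[target])
    for i in range(target - 1, -1, -1):
        if not _is_missing(v[i]):
            return float(v[i])
    return float("nan")


def _fill_radiographs(wide: pd.DataFrame) -> pd.DataFrame:
    """Apply JSW adjacent-mean imputation and KL carry-forward across visits.

    Vectorised two-visit specialisation of :func:`impute_jsw` /
    :func:`carry_forward_kl`: with only two visits the mean of the available
    adjacent values degenerates to the other visit's value, and carrying a
    KL grade forward can only fill the follow-up from the baseline.
    """
    wide = wide.copy()
    for side in ("left", "right"):
        jb, jf = (f"jsw_{side}", "baseline"), (f"jsw_{side}", "followup")
        kb, kf = (f"kl_{side}", "baseline"), (f"kl_{side}", "followup")
        wide[jb] = wide[jb].fillna(wide[jf])
        wide[jf] = wide[jf].fillna(wide[jb])
        wide[kf] = wide[kf].fillna(wide[kb])
    return wide


def derive_cohort(
    clinical: pd.DataFrame,
    accel_valid: pd.DataFrame | None = None,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply exclusions and derive worse knee and group for a clinical table.

    Parameters
    ----------
    clinical:
        Long-format participant-visit table with :data:`CLINICAL_COLUMNS`.
    accel_valid:
        Optional frame (``participant_id``, ``visit``, ``valid``) from the
        wear-validation stage; participants lacking a valid accelerometry
        visit are excluded with reason ``invalid_accelerometry``.

    Returns
    -------
    derived:
        One row per participant: worse side, worse-knee KL/JSW at both
        visits, WOMAC change, group label, inclusion flag and exclusion
        reason (first failed check, in the fixed audit order
        surgery -> radiograph -> covariates -> accelerometry).
    exclusion_log:
        One row per excluded participant with the reason code.
    """
    if clinical.empty:
        empty = pd.DataFrame(columns=["participant_id", "exclusion_reason"])
        derived_cols = [
            "participant_id", "worse_side", "kl_worse_baseline", "kl_worse_followup",
            "jsw_worse_baseline", "jsw_worse_followup", "womac_baseline",
            "womac_followup", "womac_change", "group", "included", "exclusion_reason",
        ]
        return pd.DataFrame(columns=derived_cols), empty

    wide = clinical.set_index(["participant_id", "visit"]).unstack("visit")
    wide = _fill_radiographs(wide)

    accel_ok: dict[str, bool] = {}
    if accel_valid is not None:
        for pid, sub in accel_valid.groupby("participant_id"):
            ok = sub.set_index("visit")["valid"]
            accel_ok[pid] = bool(
                ok.get("baseline", False) and ok.get("followup", False)
            )

    col = {c: wide[c].to_numpy() for c in wide.columns}
    rows = []
    for i, pid in enumerate(wide.index):
        def get(name: str, visit: str):
            return col[(name, visit)][i]

        reason = None
        if bool(get("knee_replacement", "baseline")):
            reason = "knee_replacement"
        elif _is_missing(get("kl_left", "baseline")) and _is_missing(
            get("kl_right", "baseline")
        ):
            reason = "missing_radiograph"
        elif any(_is_missing(get(c, "baseline")) for c in BASELINE_COVARIATES):
            reason = "missing_covariate"
        elif accel_valid is not None and not accel_ok.get(pid, False):
            reason = "invalid_accelerometry"

        womac_b, womac_f = get("womac_total", "baseline"), get("womac_total", "followup")
        group = None
        change = float("nan")
        if not _is_missing(womac_b) and not _is_missing(womac_f):
            change = float(womac_f) - float(womac_b)
            group = classify_group(womac_b, womac_f, params.womac_mcid)

        worse = None
        if not (
            _is_missing(get("kl_left", "baseline"))
            and _is_missing(get("kl_right", "baseline"))
        ):
            worse = select_worse_knee(
                get("kl_left", "baseline"), get("kl_right", "baseline"),
                get("jsw_left", "baseline"), get("jsw_right", "baseline"),
            )
        rows.append(
            {
                "participant_id": pid,
                "worse_side": worse,
                "kl_worse_baseline": get(f"kl_{worse}", "baseline") if worse else float("nan"),
                "kl_worse_followup": get(f"kl_{worse}", "followup") if worse else float("nan"),
                "jsw_worse_baseline": get(f"jsw_{worse}", "baseline") if worse else float("nan"),
                "jsw_worse_followup": get(f"jsw_{worse}", "followup") if worse else float("nan"),
                "womac_baseline": womac_b,
                "womac_followup": womac_f,
                "womac_change": change,
                "group": group,
                "included": reason is None,
                "exclusion_reason": reason,
            }
        )
    derived = pd.DataFrame(rows)
    log = derived.loc[~derived["included"], ["participant_id", "exclusion_reason"]]
    return derived, log.reset_index(drop=True)


def apply_exclusions(
    clinical: pd.DataFrame,
    accel_valid: pd.DataFrame | None = None,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Included participant rows plus the exclusion log.

    Thin wrapper around :func:`derive_cohort` returning the included subset
    of the original clinical table.
    """
    derived, log = derive_cohort(clinical, accel_valid, params)
    included_ids = set(derived.loc[derived["included"], "participant_id"])
    kept = clinical[clinical["participant_id"].isin(included_ids)].reset_index(drop=True)
    return kept, log
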
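"""Stable-vs-Worsening comparison battery.

Continuous variables are gated through a per-group Shapiro-Wilk test (both
groups must pass at alpha = 0.05 for the variable to be treated as normal):
normal variables are compared with Welch's unequal-variance t-test,
non-normal ones with the two-sided Mann-Whitney U test. Categorical
variables use the chi-square test of independence (no continuity correction
by default). Significance is two-sided at p < 0.05 and no multiple-testing
correction is applied by default; Benjamini-Hochberg adjustment is available
as an option.

Longitudinal percent change is reported as the ratio of group means
(100 * mean change / mean baseline), which reconciles exactly with group
summary tables; per-participant ratios are deliberately not the default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .params import DEFAULT_PARAMS, AnalysisParams

TESTS = ("t_test", "mann_whitney", "chi_square")


@dataclasses.dataclass(frozen=True)
class NormalityGate:
    """Per-group Shapiro-Wilk p-values and the joint normality verdict."""

    p_stable: float
    p_worsening: float
    normal: bool


@dataclasses.dataclass
class ComparisonRow:
    """One variable's two-group comparison."""

    variable: str
    kind: str  # "continuous" | "categorical"
    n_stable: int
    n_worsening: int
    mean_stable: float
    sd_stable: float
    mean_worsening: float
    sd_worsening: float
    test: str
    p: float
    significant: bool
    degenerate: bool = False
    # categorical-only payload: {category: (count_stable, count_worsening)}
    counts: dict | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("counts")
        return d


def _clean(values) -> np.ndarray:
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    return arr


def shapiro_gate(
    values_stable, values_worsening, alpha: float = 0.05
) -> NormalityGate:
    """Normality gate: both groups must pass Shapiro-Wilk at ``alpha``.

    A zero-variance sample cannot be tested and is treated as non-normal.
    """
    ps = []
    for v in (values_stable, values_worsening):
        arr = _clean(v)
        if len(arr) < 3 or np.ptp(arr) == 0:
            ps.append(0.0)
        else:
            ps.append(float(stats.shapiro(arr).pvalue))
    return NormalityGate(ps[0], ps[1], normal=all(p >= alpha for p in ps))


def choose_test(
    values_stable,
    values_worsening,
    variable_kind: str = "continuous",
    params: AnalysisParams = DEFAULT_PARAMS,
) -> str:
    """Select the between-group test for one variable.

    Categorical variables always map to the chi-square test; continuous
    variables require at least three observations per group and use Welch's
    t-test when the normality gate passes, the Mann-Whitney U test otherwise.
    """
    if variable_kind == "categorical":
        return "chi_square"
    if variable_kind != "continuous":
        raise ValueError(f"unknown variable kind {variable_kind!r}")
    x, y = _clean(values_stable), _clean(values_worsening)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >=3 observations per group for continuous tests")
    gate = shapiro_gate(x, y, params.shapiro_alpha)
    return "t_test" if gate.normal else "mann_whitney"


def compare_variable(
    variable: str,
    values_stable,
    values_worsening,
    kind: str = "continuous",
    params: AnalysisParams = DEFAULT_PARAMS,
) -> ComparisonRow:
    """Run the full comparison for one variable and populate a row."""
    if kind == "categorical":
        return _compare_categorical(variable, values_stable, values_worsening, params)
    x, y = _clean(values_stable), _clean(values_worsening)
    base = dict(
        variable=variable,
        kind="continuous",
        n_stable=len(x),
        n_worsening=len(y),
        mean_stable=float(np.mean(x)) if len(x) else float("nan"),
        sd_stable=float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
        mean_worsening=float(np.mean(y)) if len(y) else float("nan"),
        sd_worsening=float(np.std(y, ddof=1)) if len(y) > 1 else float("nan"),
    )
    if len(x) and len(y) and np.ptp(x) == 0 and np.ptp(y) == 0:
        # No within-group variability: the chosen tests are undefined.
        return ComparisonRow(
            **base, test="t_test", p=1.0, significant=False, degenerate=True
        )
    test = choose_test(x, y, "continuous", params)
    if test == "t_test":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return ComparisonRow(**base, test=test, p=p, significant=p < params.alpha)


def _compare_categorical(
    variable: str, values_stable, values_worsening, params: AnalysisParams
) -> ComparisonRow:
    xs = pd.Series(values_stable).dropna()
    ys = pd.Series(values_worsening).dropna()
    cats = sorted(set(xs) | set(ys), key=str)
    table = np.array(
        [[int((xs == c).sum()) for c in cats], [int((ys == c).sum()) for c in cats]]
    )
    counts = {c: (int(table[0, i]), int(table[1, i])) for i, c in enumerate(cats)}
    base = dict(
        variable=variable,
        kind="categorical",
        n_stable=len(xs),
        n_worsening=len(ys),
        mean_stable=float("nan"),
        sd_stable=float("nan"),
        mean_worsening=float("nan"),
        sd_worsening=float("nan"),
    )
    # Drop empty categories; with a single category left the test is void.
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return ComparisonRow(
            **base, test="chi_square", p=1.0, significant=False,
            degenerate=True, counts=counts,
        )
    props = table / table.sum(axis=1, keepdims=True)
    if np.allclose(props[0], props[1]):
        p = 1.0  # identical proportions: chi-square statistic is zero
    else:
        p = float(
            stats.chi2_contingency(table, correction=params.chi2_continuity)[1]
        )
    return ComparisonRow(
        **base, test="chi_square", p=p, significant=p < params.alpha, counts=counts
    )


def percent_change(
    mean_baseline: float, mean_change: float, ndigits: int = 1
) -> float:
    """Group-level percent change: 100 * mean change / mean baseline.

    Reported rounded (one decimal by default). The baseline mean must be
    strictly positive.
    """
    if not mean_baseline > 0:
        raise ValueError("mean_baseline must be strictly positive")
    return round(100.0 * mean_change / mean_baseline, ndigits)


def adjust_pvalues(rows: list[ComparisonRow], params: AnalysisParams) -> None:
    """Optionally apply Benjamini-Hochberg across a battery, in place."""
    if params.p_adjust != "bh" or not rows:
        return
    adj = stats.false_discovery_control([r.p for r in rows], method="bh")
    for r, p in zip(rows, adj):
        r.p = float(p)
        r.significant = p < params.alpha


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


# --- cohort-level table builders ---------------------------------------------

#: clinical variables compared at baseline, follow-up and as change scores
CLINICAL_VARS = (
    ("womac_total", "WOMAC total"),
    ("cesd", "CESD"),
    ("pase", "PASE"),
    ("gait_speed", "Gait speed [m/s]"),
    ("sit_to_stand_s", "Five times sit to stand [s]"),
)

#: accelerometer variables (daily totals are reported in 10^4 counts/day)
PA_VARS = (
    ("total_counts_1e4", "Daily total activity [10^4 counts/day]"),
    ("sed_min", "SED [min/day]"),
    ("lpa_min", "LPA [min/day]"),
    ("mvpa_min", "MVPA [min/day]"),
)

#: diurnal metrics plotted per 3-h bin
FIGURE_METRICS = ("counts", "sed_min", "lpa_min", "mvpa_min")


def _phase_values(wide: pd.DataFrame, phase: str) -> pd.Series:
    if phase == "change":
        return wide["followup"] - wide["baseline"]
    return wide[phase]


def _group_split(values: pd.Series, groups: pd.Series):
    joined = pd.concat([values.rename("v"), groups.rename("g")], axis=1).dropna()
    return (
        joined.loc[joined["g"] == "stable", "v"],
        joined.loc[joined["g"] == "worsening", "v"],
    )


def _continuous_battery(
    name: str,
    wide: pd.DataFrame,
    groups: pd.Series,
    params: AnalysisParams,
) -> list[dict]:
    """Baseline / follow-up / change comparison rows for one variable."""
    out = []
    base_means = None
    for phase in ("baseline", "followup", "change"):
        x, y = _group_split(_phase_values(wide, phase), groups)
        row = compare_variable(name, x, y, "continuous", params).as_dict()
        row["phase"] = phase
        row["pct_change_stable"] = np.nan
        row["pct_change_worsening"] = np.nan
        if phase == "baseline":
            base_means = (row["mean_stable"], row["mean_worsening"])
        if phase == "change" and base_means is not None:
            if base_means[0] > 0:
                row["pct_change_stable"] = percent_change(base_means[0], row["mean_stable"])
            if base_means[1] > 0:
                row["pct_change_worsening"] = percent_change(
                    base_means[1], row["mean_worsening"]
                )
        out.append(row)
    return out


def build_tables(
    visit_summaries: pd.DataFrame,
    intervals: pd.DataFrame,
    derived: pd.DataFrame,
    clinical: pd.DataFrame,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort report tables.

    Parameters mirror the pipeline outputs: per-participant-visit activity
    summaries, per-bin interval summaries, the derived clinical table
    (groups, worse knee) and the raw clinical table. Only included
    participants with a group label enter the comparisons.

    Returns a dict with:

    ``table1``
        Whole-cohort baseline characteristics (mean/SD or n/%).
    ``table2``
        Stable-vs-Worsening comparisons at baseline, follow-up and for
        longitudinal change, with the chosen test, p-value and group-level
        percent change (ratio of group means) for change rows.
    ``figure2``
        Mean of each diurnal metric per 3-h bin, group and visit.
    ``interval_tests``
        Per-bin group comparisons: cross-sectional at each visit and on
        within-person change scores, labelled by the ``comparison`` column,
        with per-group percent change for the change rows.
    ``groups``
        Participant-to-group assignment used throughout.
    """
    inc = derived[(derived["included"]) & derived["group"].notna()]
    groups = inc.set_index("participant_id")["group"]
    ids = groups.index

    clin = clinical[clinical["participant_id"].isin(ids)]
    vs = visit_summaries[visit_summaries["participant_id"].isin(ids)].copy()
    vs["total_counts_1e4"] = vs["total_counts"] / 1e4
    iv = intervals[intervals["participant_id"].isin(ids)]

    rows: list[dict] = []

    # demographics (baseline only)
    base = clin[clin["visit"] == "baseline"].set_index("participant_id")
    x, y = _group_split(base["age"], groups)
    r = compare_variable("Age", x, y, "continuous", params).as_dict()
    r.update(phase="baseline", pct_change_stable=np.nan, pct_change_worsening=np.nan)
    rows.append(r)
    for col, label in (("sex", "Sex"), ("race", "Race")):
        x, y = _group_split(base[col], groups)
        r = compare_variable(label, x, y, "categorical", params).as_dict()
        r.update(phase="baseline", pct_change_stable=np.nan, pct_change_worsening=np.nan)
        rows.append(r)

    # clinical outcomes across phases
    for col, label in CLINICAL_VARS:
        wide = clin.pivot(index="participant_id", columns="visit", values=col)
        rows.extend(_continuous_battery(label, wide, groups, params))

    # radiographic outcomes of the worse knee
    d = inc.set_index("participant_id")
    jsw_wide = pd.DataFrame(
        {"baseline": d["jsw_worse_baseline"], "followup": d["jsw_worse_followup"]}
    )
    rows.extend(
        _continuous_battery("Minimum medial JSW [mm]", jsw_wide, groups, params)
    )
    for phase, col in (("baseline", "kl_worse_baseline"), ("followup", "kl_worse_followup")):
        x, y = _group_split((d[col] >= 2).astype(int), groups)
        r = compare_variable("KL grade >= 2", x, y, "categorical", params).as_dict()
        r.update(phase=phase, pct_change_stable=np.nan, pct_change_worsening=np.nan)
        rows.append(r)
    new_ge2 = ((d["kl_worse_followup"] >= 2) & (d["kl_worse_baseline"] < 2)).astype(int)
    x, y = _group_split(new_ge2, groups)
    r = compare_variable("KL grade >= 2", x, y, "categorical", params).as_dict()
    r.update(phase="change", pct_change_stable=np.nan, pct_change_worsening=np.nan)
    rows.append(r)

    # accelerometer-derived activity
    for col, label in PA_VARS:
        wide = vs.pivot(index="participant_id", columns="visit", values=col)
        rows.extend(_continuous_battery(label, wide, groups, params))

    table2 = pd.DataFrame(rows)
    front = ["variable", "phase"]
    table2 = table2[front + [c for c in table2.columns if c not in front]]

    table1 = _baseline_table(base, vs, d, params)
    figure2, interval_tests = _figure_tables(iv, groups, params)
    return {
        "table1": table1,
        "table2": table2,
        "figure2": figure2,
        "interval_tests": interval_tests,
        "groups": groups.to_frame().reset_index(),
    }


def _baseline_table(
    base: pd.DataFrame, vs: pd.DataFrame, derived_idx: pd.DataFrame,
    params: AnalysisParams,
) -> pd.DataFrame:
    """Whole-cohort baseline characteristics."""
    n = len(base)
    vsb = vs[vs["visit"] == "baseline"].set_index("participant_id")
    rows = [{"variable": "Number", "n": n, "mean": np.nan, "sd": np.nan,
             "count": np.nan, "pct": np.nan}]

    def cont(label, s):
        s = s.dropna()
        rows.append({"variable": label, "n": len(s), "mean": float(s.mean()),
                     "sd": float(s.std(ddof=1)), "count": np.nan, "pct": np.nan})

    def cat(label, mask):
        c = int(mask.sum())
        rows.append({"variable": label, "n": int(mask.notna().sum()),
                     "mean": np.nan, "sd": np.nan, "count": c,
                     "pct": 100.0 * c / max(int(mask.notna().sum()), 1)})

    cont("Age", base["age"])
    cat("Female", base["sex"] == "female")
    cat("White or Caucasian", base["race"] == "white")
    cont("BMI [kg/m^2]", base["bmi"])
    cont("WOMAC total", base["womac_total"])
    cont("CESD", base["cesd"])
    cont("PASE", base["pase"])
    cat("Fall history >= 2", base["falls"] >= 2)
    cont("Gait speed [m/s]", base["gait_speed"])
    cont("Five times sit to stand [s]", base["sit_to_stand_s"])
    cont("Daily total activity [10^4 counts/day]", vsb["total_counts_1e4"])
    cont("SED [min/day]", vsb["sed_min"])
    cont("LPA [min/day]", vsb["lpa_min"])
    cont("MVPA [min/day]", vsb["mvpa_min"])
    cont("Minimum medial JSW [mm]", derived_idx["jsw_worse_baseline"])
    cat("KL grades >= 2", derived_idx["kl_worse_baseline"] >= 2)
    return pd.DataFrame(rows)


def _figure_tables(
    intervals: pd.DataFrame, groups: pd.Series, params: AnalysisParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    iv = intervals.merge(
        groups.rename("group"), left_on="participant_id", right_index=True
    )
    figure2 = (
        iv.groupby(["group", "visit", "bin"])[list(FIGURE_METRICS)]
        .mean()
        .unstack(["group", "visit"])
    )

    test_rows = []
    for metric in FIGURE_METRICS:
        wide = iv.pivot_table(
            index=["participant_id", "bin"], columns="visit", values=metric
        )
        for b in range(params.n_bins):
            try:
                sub = wide.xs(b, level="bin")
            except KeyError:
                continue
            g = groups.reindex(sub.index)
            for comparison in ("baseline", "followup", "change"):
                vals = _phase_values(sub, comparison)
                x, y = _group_split(vals, g)
                if len(x) < 3 or len(y) < 3:
                    continue
                row = compare_variable(
                    f"{metric} bin {b}", x, y, "continuous", params
                ).as_dict()
                row.update(
                    metric=metric, bin=b, comparison=comparison,
                    daytime=b in params.daytime_bins,
                    pct_change_stable=np.nan, pct_change_worsening=np.nan,
                )
                if comparison == "change":
                    bx, by = _group_split(sub["baseline"], g)
                    if bx.mean() > 0:
                        row["pct_change_stable"] = percent_change(bx.mean(), x.mean())
                    if by.mean() > 0:
                        row["pct_change_worsening"] = percent_change(by.mean(), y.mean())
                test_rows.append(row)
    interval_tests = pd.DataFrame(test_rows)
    front = ["metric", "bin", "comparison", "daytime"]
    if not interval_tests.empty:
        interval_tests = interval_tests[
            front + [c for c in interval_tests.columns if c not in front]
        ]
    return figure2, interval_tests


def pooled_pct_change(
    intervals: pd.DataFrame,
    groups: pd.Series,
    bins: tuple[int, ...] = (5, 6),
    metric: str = "counts",
) -> dict[str, float]:
    """Percent change of a metric pooled over several diurnal bins.

    Bins are summed within participant-visit before averaging, then the
    group-level percent change is the ratio of group means. Used for pooled
    windows such as 15:00-21:00 (bins 5 and 6).
    """
    sub = intervals[intervals["bin"].isin(bins)]
    pooled = (
        sub.groupby(["participant_id", "visit"])[metric].sum().unstack("visit")
    )
    g = groups.reindex(pooled.index)
    out = {}
    for name in ("stable", "worsening"):
        grp = pooled[g == name].dropna()
        base = grp["baseline"].mean()
        out[name] = percent_change(base, (grp["followup"] - grp["baseline"]).mean())
    return out
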
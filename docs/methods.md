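# Methods

This note documents the models, rules and numerical choices implemented in
`oawear`, in the order the pipeline applies them, followed by the design of
the synthetic cohort generator and the known limitations.

## Non-wear detection

Non-wear is inferred from minute-epoch counts only. An interval qualifies
when it spans at least `nonwear_min_window` minutes (default 90) in which
every epoch has zero counts except at most `nonwear_allowance_epochs`
(default 2) interruption minutes whose counts lie strictly between 0 and
`nonwear_allowance_threshold` (default 100 counts/min).

Choices the rule itself leaves open, and how they are resolved:

* **Allowance semantics.** "Up to 2 minutes" is read as *at most two
  interruption epochs in total per interval*, consecutive or not. The
  up/down-stream flanking-window refinement of Choi-style algorithms is not
  part of the stated rule and is not implemented; the thresholds are
  exposed as configuration so a stricter variant can be layered on.
* **Interior interruptions only.** Every interval starts and ends on a
  zero-count epoch. Otherwise leading/trailing sub-threshold activity could
  inflate intervals.
* **Determinism.** Detection scans each day left to right: from the
  leftmost feasible start, the longest qualifying window is selected, the
  scan resumes after it. Output intervals are maximal and disjoint, and the
  result is unique.
* **Day boundaries.** Detection runs per calendar day; a physical removal
  crossing midnight appears as two intervals. Day-level wear and the
  clock-anchored diurnal bins make this the consistent convention.
* **Monotonicity caveat.** Lowering the minimum window length enlarges the
  *set of qualifying windows* monotonically, but the greedy disjoint
  selection is not monotone in total covered minutes: a shorter window
  threshold can admit an early short interval whose selection blocks a
  longer overlapping one. The property suite therefore asserts
  monotonicity of the qualifying-window union, not of the greedy total.
* Epochs with counts in (0, 100) outside any qualifying window are
  ordinary wear; the rule defines non-wear only.

Wear minutes per day are the complement of detected non-wear. A valid day
has ≥ 600 wear minutes (boundary inclusive); a participant-visit is
analysable with 4–7 valid days; more than 7 recorded days is an error.

## Intensity classification

Freedson counts/min cut-points for older adults: SED 0–99, LPA 100–1951,
MVPA above that. Stated literally the category edges leave 1952 counts/min
unassigned; it is assigned to MVPA (the ≥ 1952 convention) so the three
categories partition the non-negative integers. The cut-points are
configuration constants. Non-worn epochs contribute to no category and no
total. Valid-day means are unweighted arithmetic means.

## Diurnal segmentation

Eight half-open bins `[3k, 3k+3)` hours tile the day; an epoch belongs to
the bin containing its start minute. Per bin and valid day: counts, steps,
SED/LPA/MVPA minutes and the non-wear percentage, computed against the
full 180 bin-minutes (not wear-conditional), so intensity minutes plus
non-wear minutes always fill the bin. Overnight bins are dominated by
non-wear; the primary analysis window is bins 3–6 (09:00–21:00).

## Clinical derivations

* Exclusion order (each participant gets the first failing reason):
  knee replacement before baseline → no radiographic reading on either
  knee → missing baseline covariates (age, sex, BMI, WOMAC, gait speed,
  sit-to-stand) → invalid accelerometry at either visit.
* Missing medial minimum JSW is imputed as the mean of available
  adjacent-visit values (with two visits this degenerates to the other
  visit's value); the imputation never leaves the convex hull of its
  sources. Missing KL grades are carried forward from the most recent
  prior visit; nothing is carried backward.
* Worse knee: higher KL grade; KL tie → smaller JSW; double tie → right
  knee (an arbitrary but fixed, logged convention). Selection uses
  baseline values after imputation, and the worse side is held fixed
  across visits.
* Grouping: WOMAC total change > 10 points (strict) is *worsening*;
  everything else — including changes of exactly 10 and improvements of
  any magnitude — is *stable*, so the two groups exhaust the cohort. The
  threshold is configurable (`womac_mcid`).

## Comparison battery

* Normality gate: Shapiro–Wilk per group; a variable is normal only when
  both groups pass at α = 0.05. A zero-variance sample is untestable and
  gates to non-normal.
* Continuous tests: Welch's unequal-variance t-test when normal (the
  conservative choice given unequal group sizes), Mann–Whitney U
  otherwise, both two-sided. If both groups are constant the comparison is
  degenerate: flagged, p reported as 1.
* Categorical: chi-square without continuity correction by default
  (configurable); identical group proportions short-circuit to p = 1.
* No multiple-testing correction by default, matching the simple
  group-based design; Benjamini–Hochberg is available via
  `AnalysisParams(p_adjust="bh")`.
* Percent change is the ratio of group means (mean change over mean
  baseline), reported to one decimal. This reconciles exactly with group
  summary tables; per-participant ratios are intentionally not the default
  because they explode for near-zero baselines. For pooled windows
  (e.g. 15:00–21:00) bins are summed within participant before the group
  ratio — both pooled and per-bin estimates are exposed since either
  convention is defensible.

## Synthetic cohort generator

The generator emulates a two-visit, 7-day, 1-minute-epoch accelerometer
sub-study of a KOA cohort. It is the package's test bed: every default is
a study condition, not a tuning knob.

**Count model.** Within the wear window each epoch draws zero with
hour-dependent probability `p0(h) = clip(s · (0.30 + 0.62 · exp(-mu(h)/220)), 0, 0.97)`
(`s` scales with the SED target), otherwise an exponential
(Gamma, shape 1) value with conditional mean `mu(h) · a_i · f / (1 - p0(h))`.
Anchoring `p0` to the baseline profile makes the unconditional epoch mean
*exactly* `mu(h) · a_i · f`, linear in the follow-up decline factor `f` —
the property that makes injected declines recoverable without bias from
bin-level count means. `a_i` is a mean-one lognormal person effect
(σ = 0.45) shared across visits, giving realistic between-person spread and
paired structure. 0–3 bouts/day (Binomial(3, ⅓), ≥ 10 min, amplitude
Gamma with mean 2600 · a_i · f counts/min, placement proportional to the
profile) make MVPA accumulate in bouts. Steps are
`min(Poisson(130 · (c/(c+800))^0.9), 130)`, zero when counts are zero —
carried through all summaries but not an analysis endpoint.

**Diurnal profile and non-wear.** The default per-hour profile rises
through the morning (peak ≈ 280 counts/min, 10:00–12:00) and decays through
the evening; hours 22:00–07:00 are the overnight off-body window and
sporadic daytime removals arrive at 0.2/day with ~110-minute durations
(a 2% subset of participants gets heavy removal behaviour to exercise the
invalid-accelerometry exclusion). All non-wear is recorded literally as
zero counts, with the truth mask kept separately. The zero-inflation,
shape and bout constants were calibrated once against the target daily
composition (SED 579.8, LPA 278.1, MVPA 19.7 min/day and ≈ 22×10⁴
counts/day) and then frozen; a 200-participant draw lands within a few
percent of each target.

**Decline effects.** Follow-up scales each 3-h bin's mean by a per-group
factor. Defaults: worsening 0.79 in bins 5–6 (15:00–21:00) and 0.838
elsewhere; stable 0.94 in bins 5–6 and 0.876 elsewhere. These were derived
analytically from the default profile's per-bin count shares so that the
cohort-level conditions are a ≈ −18%/−10% daily decline and ≈ −21%/−6%
late-day decline (worsening/stable) — the generator's target regime. Note
the stable group's decline is front-loaded (morning factors below its
late-day factors): that is what a −10% daily and only −6% late-day change
jointly imply.

**WOMAC model.** Baseline ~ N(11.9, 14.9²) truncated to keep both visits in
[0, 96]; change ~ N(−1.9, 8.1²) truncated to (−10, 10) for stable and
N(19.6, 9.2²) truncated to (10, ∞) for worsening. Labels are therefore
functionally determined by the drawn change, and the MCID rule recovers
them exactly. Clinical covariates (CESD, PASE, gait speed, sit-to-stand,
KL, JSW, demographics) are drawn from group-conditional normal/categorical
models with magnitudes typical of a KOA cohort in its mid-sixties,
including a slightly slower baseline sit-to-stand in the worsening group
and small missingness rates (1–3%) to exercise imputation and exclusions.

**What the generator does not emulate.** Raw sub-second accelerations,
device firmware behaviour, weekday/weekend structure (pooled by design),
autocorrelated bout sequencing beyond single elevated bouts, seasonal or
weather effects, and any dependence of activity decline on radiographic
severity. Passing recovery tests therefore demonstrates correctness of the
pipeline's arithmetic and inference under the stated model, not robustness
to every property of field data.

## Problem sizes and numerical choices

* Parameter recovery runs a 500-participant cohort (worsening fraction
  0.16, fixed seed): daytime-bin percent-change estimates match injected
  factors within 3 percentage points, and grouping recovers labels exactly.
* Type-I calibration uses 200 replicates of 100-participant null cohorts
  (no injected group difference); each daytime-bin change comparison must
  reject within the exact binomial 95% band around 0.05.
* Oracle equivalence checks the non-wear scan against a brute-force
  window-enumeration oracle on 10,000 random sequences up to 2000 epochs,
  plus derandomised property tests on small sequences.
* Conservation (intensity minutes = wear minutes; bin totals = day totals;
  bin minutes + non-wear = 180) is asserted over every participant of a
  seed-fixed 200-participant cohort.
* All randomness flows through explicitly passed `numpy` generators;
  identical seeds give bit-identical cohorts. Floating-point comparisons
  in conservation checks use `np.allclose` at default tolerances since the
  quantities are sums and means of integers.

## Known limitations

* The non-wear rule is the stated 90-minute/2-minute-allowance rule, not
  the full Choi algorithm with flanking windows; on real data the two can
  differ at the margins of long sedentary spells.
* With two visits the adjacent-visit JSW imputation reduces to copying the
  other visit; the general multi-visit form is implemented and tested but
  the cohort path only ever exercises the two-visit case.
* The stable sit-to-stand percent change is reported with the sign implied
  by its group means (a small improvement, ≈ −0.3%); summaries elsewhere
  sometimes quote this magnitude with the opposite sign.
* Percent change is undefined for zero baselines and is flagged rather
  than reported; overnight bins regularly trigger this on synthetic data.
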
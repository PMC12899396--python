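# oawear

Accelerometer-based diurnal physical-activity analysis for knee
osteoarthritis (KOA) symptom worsening.

People with knee osteoarthritis often reduce physical activity as symptoms
progress, and the reduction is not uniform across the day: pain and fatigue
late in the day can erode afternoon and evening activity first. `oawear`
implements the analysis pipeline used to study this phenomenon in hip-worn
accelerometer cohorts: it takes minute-epoch activity counts recorded over
7-day wear periods at two visits plus a clinical table, and compares
activity change between participants whose symptoms stayed stable and those
whose symptoms worsened. It is aimed at researchers working with
epoch-level actigraphy in musculoskeletal or ageing cohorts.

## What the pipeline computes

1. **Non-wear detection.** An interval of ≥ 90 consecutive minutes of zero
   counts is non-wear, tolerating up to 2 interruption minutes with counts
   below 100 counts/min strictly inside the interval. Detection is a greedy
   left-to-right scan that keeps maximal, disjoint intervals per calendar
   day.
2. **Wear validation.** A day with ≥ 10 h of wear is valid; a
   participant-visit enters the analysis with 4–7 valid days.
3. **Intensity summarisation.** Worn minutes are classified by Freedson
   counts/min cut-points — sedentary (SED) 0–99, light (LPA) 100–1951,
   moderate-to-vigorous (MVPA) ≥ 1952 — and daily totals (activity counts,
   steps, category minutes) are averaged over valid days.
4. **Diurnal segmentation.** The day is tiled by eight 3-h clock bins
   (00:00–03:00 … 21:00–24:00); per-bin counts, steps, intensity minutes
   and non-wear percentage are averaged over valid days. Primary analyses
   use the four daytime bins 09:00–21:00 where non-wear is minimal.
5. **Clinical derivations.** Exclusions (knee replacement, missing
   radiographs, missing baseline covariates, invalid accelerometry), the
   worse-knee rule (higher Kellgren–Lawrence grade, tie → smaller medial
   minimum joint-space width), adjacent-visit JSW imputation and KL
   carry-forward.
6. **MCID grouping.** A participant is *worsening* when the WOMAC total
   score increases by more than 10 points (the minimal clinically important
   difference) between visits, *stable* otherwise.
7. **Comparison battery.** Per variable: Shapiro–Wilk normality gate in
   each group, then Welch's t-test (normal) or Mann–Whitney U (otherwise);
   chi-square for categorical variables; two-sided α = 0.05. Longitudinal
   percent change is the ratio of group means,
   `100 × mean(change) / mean(baseline)`.

Because source cohort data of this kind are access-restricted, the package
ships a seeded synthetic cohort generator (`oawear.synthetic`) that
reproduces the data structure — diurnal count profiles, overnight and
sporadic daytime non-wear, bout-like MVPA, a worsening subgroup with
activity decline concentrated between 15:00 and 21:00 — together with the
ground truth needed for parameter-recovery testing.

## Worked example

```python
from oawear import (CohortSpec, generate_cohort, process_cohort,
                    compare_cohort, interval_group_pct_change)

spec = CohortSpec(n_participants=120, seed=11)
series, clinical, truth = generate_cohort(spec)
result = process_cohort(series, clinical)
report = compare_cohort(result)

groups = result.groups
print(f"included {len(groups)} of 120 participants "
      f"({(groups == 'worsening').sum()} worsening, {(groups == 'stable').sum()} stable)")
print("excluded:", result.exclusions["exclusion_reason"].value_counts().to_dict())

row = report["table2"].query(
    "variable == 'Daily total activity [10^4 counts/day]' and phase == 'change'"
).iloc[0]
print(f"daily total activity change: stable {row.mean_stable:.2f} / "
      f"worsening {row.mean_worsening:.2f} x10^4 counts/day "
      f"({row.pct_change_stable:+.1f}% vs {row.pct_change_worsening:+.1f}%), "
      f"{row.test} p={row.p:.3f}")

pooled = interval_group_pct_change(result, pooled=True, bins=(5, 6))
print(f"15:00-21:00 activity counts change: "
      f"stable {pooled['stable']:+.1f}%, worsening {pooled['worsening']:+.1f}%")
```

This prints:

```
included 112 of 120 participants (22 worsening, 90 stable)
excluded: {'invalid_accelerometry': 4, 'knee_replacement': 4}
daily total activity change: stable -2.46 / worsening -5.15 x10^4 counts/day
  (-11.1% vs -20.0%), mann_whitney p=0.000
15:00-21:00 activity counts change: stable -8.5%, worsening -25.7%
```

Eight participants fall to the exclusion rules; over two years the
worsening subgroup loses roughly twice as much daily activity as the stable
subgroup, and its loss is concentrated in the late-afternoon/evening
window — the pattern the generator injects and the pipeline is built to
detect.

The same steps are available from a shell:

```bash
oawear simulate --n 120 --seed 11 --out sim/
oawear preprocess --epochs sim/epochs.csv --out wear.csv
oawear summarize  --epochs sim/epochs.csv --out summaries/
oawear compare    --epochs sim/epochs.csv --clinical sim/clinical.csv --out report/
```

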
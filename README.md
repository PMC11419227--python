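# rarkit — rest-activity rhythm analysis for wrist actigraphy

`rarkit` turns epoch-level wrist actigraphy (30 s or 60 s activity counts, as
exported by Actiwatch-class devices) into per-subject rest-activity-rhythm
(RAR) metrics and cohort-level analyses. It is written for clinical and
epidemiological studies that use actigraphy to characterize circadian
disruption — for example in epilepsy with intellectual disability, where
survey instruments are hard to apply and objective wearable metrics are
especially valuable.

## What it computes

Per subject, from an integer number of full midnight-to-midnight days
(partial-day tails are discarded):

- **Cosinor regression** — least-squares fit of
  `y(t) = M + A·cos(2π(t − φ)/24)` at native epoch resolution, giving the
  mesor *M* (rhythm-adjusted mean), amplitude *A* (half peak-to-trough) and
  acrophase *φ* (clock time of the fitted peak, hours).
- **Extended sigmoidally transformed cosine** — the 5-parameter model
  `r(t) = min + amp·logistic(β·(cos(2π(t − φ)/24) − α))`, capturing the
  square-ish shape of real RARs. Its **pseudo-F statistic**
  `F = [(SS0 − SSres)/(p−1)] / [SSres/(n−p)]` (p = 5) measures rhythm
  robustness; since longer recordings alone inflate F, the reported score is
  **F/d = F / days**.
- **Nonparametric metrics** on hourly totals — intradaily variability
  `IV = N·Σ(xᵢ−xᵢ₋₁)² / [(N−1)·Σ(xᵢ−x̄)²]` (fragmentation; ≈2 for white
  noise) and interdaily stability
  `IS = N·Σₕ(x̄ₕ−x̄)² / [24·Σ(xᵢ−x̄)²]` (day-to-day stability; ∈ [0, 1]).
- **"Sleep" bouts** — maximal runs of zero-count epochs lasting ≥ 4 minutes;
  summarized as total daily "sleep", bouts/day, a bout-duration survival
  curve `S(d) = P(duration ≥ d)` and an onset-by-clock-hour histogram.

Per cohort:

- **Smoothed average actograms** — an "average of averages" (across days,
  then across subjects with equal weight), smoothed by a 101-point circular
  moving average followed by a local second-order polynomial pass.
- **K-means phenotyping** — each subject's z-normalized (total daily
  "sleep", amplitude, acrophase, F/d) vector, clustered with k = 3 and 2000
  replicate initializations, keeping the lowest total sum of squared
  distances; labels A/B/C are ordered by ascending amplitude z-score.
- **Group comparisons** — ordinary one-way ANOVA with Tukey HSD post-hoc
  tests.

A fully seeded synthetic cohort generator (negative-binomial counts with
zero-inflated rest phases, day-to-day phase/amplitude jitter, optional naps)
provides labeled phenotype presets so the entire pipeline can be exercised
and validated without any clinical data.

## Worked example

```python
import pandas as pd
from rarkit import preset, generate_cohort, subject_metrics, trim_to_full_days

_, subjects = generate_cohort([(preset("A"), 3), (preset("C"), 3)], seed=42)
rows = [subject_metrics(trim_to_full_days(s.series), group=s.truth.name)
        for s in subjects]
print(pd.DataFrame(rows).round(2).to_string(index=False))
```

```
subject_id group  n_days  mesor  amplitude  acrophase_h  F_per_day   IV   IS  total_daily_sleep_min
     A-000     A      11  40.60      39.03        15.19      28.13 0.51 0.41                 606.64
     A-001     A      11  38.95      34.00        14.14      25.36 0.56 0.40                 607.91
     A-002     A      11  35.54      32.30        13.81      22.82 0.51 0.34                 640.00
     C-000     C      11 399.43     508.15        13.52     330.20 0.20 0.96                 175.73
     C-001     C      11 386.56     495.10        13.49     311.17 0.21 0.96                 177.45
     C-002     C      11 393.46     501.09        13.36     332.42 0.20 0.97                 165.91
```

Preset "A" emulates a hypoactive, hypersomnic, fragmented phenotype: low
amplitude and mesor, low robustness (F/d) and stability (IS), high
fragmentation (IV) and ~10 h/day of detected "sleep". Preset "C" is the
hyper-robust, high-amplitude phenotype. Eleven full days are retained per
subject, matching a typical ~11-day recording.

The same analyses are available from the shell:

```sh
rarkit simulate --preset A --preset B --preset C --n 15 --seed 7 --out cohort/
rarkit metrics  --manifest cohort/manifest.csv --out metrics.csv
rarkit cluster  --metrics metrics.csv --k 3 --replicates 2000 --seed 7
rarkit actogram --manifest cohort/manifest.csv --group A --out profileA.csv
rarkit compare  --metrics metrics.csv --metric amplitude
```

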
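# Methods

This note documents the models, conventions and numerical choices behind
`rarkit`, and what the synthetic validation does and does not establish.

## Day alignment and input assumptions

Recordings are epoch-level count series (30 s or 60 s epochs) with naive
local timestamps. Analysis keeps only full midnight-to-midnight days:
epochs before the first midnight at/after the recording start and at/after
the last midnight within the recording are discarded. Gap-free, nonnegative
integer counts are a hard requirement; missing or irregular rows are errors
rather than imputation targets, because every downstream metric assumes a
uniform grid. Daylight-saving transitions are not modeled — a 23/25-hour
civil day surfaces as irregular spacing and is rejected. Off-wrist
detection is deliberately absent: long zero runs are interpreted as rest,
which is exactly what the sleep-bout estimator quantifies. Hour bins are
clock hours of the retained days; no rolling windows anywhere.

## Cosinor

The single-component 24 h cosinor is solved in its linear form
(intercept, in-phase and quadrature cosine terms) by closed-form least
squares at native epoch resolution; amplitude and acrophase are the polar
transform of the two cosine coefficients. Fitting at epoch resolution
rather than on hourly totals leaves amplitude and acrophase essentially
unchanged but makes the residual sum of squares resolution-dependent; the
package keeps epoch resolution for consistency with the extended model.
Acrophase is reported in clock hours in [0, 24); angles that round to
exactly 24.0 wrap to 0.0. The period is fixed at 24 h.

## Extended sigmoidal cosine and pseudo-F

The anti-logistic transform of the cosine gives square-ish waveforms:
`minimum` (floor), `amp` (rise), `phi` (phase, hours), `alpha` ∈ (−1, 1)
(threshold; the high-state duty cycle is arccos(alpha)/π) and `beta` > 0
(switch steepness). The fit is nonlinear least squares (trust-region
reflective, analytic Jacobian, Jacobian-based variable scaling, bounds
amp ≥ 0, |alpha| ≤ 0.999, beta ∈ [1e−3, 500]) with a deterministic
multi-start grid: phases at the cosinor acrophase plus {0, ±2, ±4} h,
beta ∈ {1, 5, 20}, alpha initialized from the observed duty cycle
(fraction of epochs above the 5–95 % quantile midpoint), floor and rise
from those quantiles. Lowest residual sum of squares wins; near-ties
(within 1e−9 of total variance) break toward the smaller beta. Each start
is capped at 150 function evaluations with 1e−8 tolerances — well past
convergence on rhythmic data, while preventing fruitless crawling on
near-flat data where phase and threshold are weakly identified.

Pseudo-F uses p = 5 parameters (numerator df 4, denominator df n − 5) and
the sum of squares about the grand mean as SS0; SSres is clipped at SS0
since the flat model lies in the closure of the family. The numerator df is
configurable. Because recording length alone inflates F, the reported
robustness score is F/d = F divided by the integer number of retained days —
days being the natural duration unit for multi-day actigraphy. Absolute
pseudo-F values depend on the sampling convention (epoch-level here);
only comparisons within one convention are meaningful.

Under a flat truth the pseudo-F is *approximately* F(4, n−5) but
stochastically larger: with amplitude near zero, phase and threshold are
unidentified, and the multi-start global fit takes a supremum over those
directions (a Davies-type boundary problem). The validation therefore
checks that the empirical 95th percentile over null replicates falls
within [0.7, 2.0] × the F(4, n−5) critical value, an allowance set by that
boundary argument rather than by exact distribution theory.

## IV and IS

Both are computed on hourly totals of the retained days. First differences
for IV run across midnights but do not wrap around the recording end. IS
for a single retained day is reported as 1.0 with a warning (the statistic
is uninformative there) rather than as an error, since trimming only
guarantees one day. Closed-form checks used in the tests: an alternating
series gives IV = 4 exactly; an hourly-sampled 24 h cosine over full days
gives IV = 8s(N/2 − s)/(N − 1) with s = sin²(π/24); white noise gives
E[IV] → 2 and E[IS] ≈ 1/m over m days.

## Sleep bouts

A bout is a maximal run of epochs with counts exactly zero (a tolerance
knob exists but defaults to 0) lasting at least 4 minutes — 4 epochs at
60 s, 8 at 30 s. Bouts may cross midnight and are attributed wholly to
their onset day, keeping durations faithful for the survival curve
S(d) = P(duration ≥ d), which is evaluated at the observed durations. The
"90 % of bouts are ≤ d" style summary is the smallest observed duration d
with P(duration > d) ≤ 0.10; this form always exists and coincides with a
sort-based percentile. No diary or off-wrist integration is attempted.

## Cohort analyses

*Actograms.* Per-subject day-mean minute profiles (30 s epochs averaged in
pairs) are averaged across subjects with equal subject weight, then
smoothed in two stages: a centered 101-point circular moving average, then
a Savitzky-Golay local quadratic with the same window and circular
padding. The window is the odd cover of "100 nearest neighbors"; circular
padding because the profile is a clock. The smoother preserves constants
and the daily mean; its gain on the 24 h harmonic is the product of the
moving-average and Savitzky-Golay frequency responses.

*Clustering.* Features are z-scored over the clustering cohort only
(sample sd, n−1). Acrophase is z-scored **linearly**, faithful to the
stated procedure; subjects straddling midnight would be artificially far
apart, a caveat that matters only for cohorts with near-midnight
acrophases. K-means is Lloyd's algorithm with squared Euclidean distance;
each replicate seeds centroids at k distinct subjects drawn without
replacement from a seeded PCG64 stream; an emptied cluster is re-seeded at
the point farthest from its centroid; the objective is verified
non-increasing per iteration. The best of 2000 replicates is returned, and
final centroids are recomputed as exact member means. Label order (A/B/C
by ascending amplitude z) is a package convention — k-means labels are
otherwise arbitrary.

*Comparisons.* Ordinary (pooled-variance, fixed-effects) one-way ANOVA
with Tukey HSD on the studentized range; no Welch correction.

## Synthetic cohorts

The generator draws, per day, a phase `acrophase + N(0, phase_jitter_sd_h)`
and amplitude `amplitude·(1 + N(0, amplitude_jitter_cv))`, builds the
sigmoidal-cosine mean curve, and emits negative-binomial counts
(variance μ + dispersion·μ²; Poisson when dispersion = 0). Epochs in the
low phase (sigmoid factor < ½) are zeroed with probability
`zero_inflation_night` — exact zeros must occur naturally for the bout
rule to see rest, which Gaussian noise would almost never produce. Naps
are Poisson-per-day forced zero runs with Normal lengths at daytime
positions, visible to the 4-minute rule by construction. All draws come
from a single PCG64 stream per subject, spawned deterministically from a
master seed, so cohorts are byte-reproducible.

Presets A (hypoactive/hypersomnic/fragmented: low amplitude, high
dispersion and zero inflation, 6 naps/day, 3 h phase jitter), B
(intermediate) and C (hyper-robust: high amplitude, steep switch, minimal
jitter) emulate the qualitative phenotype clusters reported in
actigraphy of epilepsy with intellectual disability, plus a CONTROL preset
resembling a community cohort. Recordings default to 11 days (a typical
median duration; CONTROL uses 9). Preset values were chosen once so that
group contrasts reproduce the *direction* of the published differences
(lower amplitude, mesor, F/d, IS; higher IV and total daily "sleep" in the
impaired phenotype); published magnitudes are cohort-specific and are not
targets.

What the generator does **not** emulate: device-specific count algorithms,
off-wrist artifacts, non-stationary schedules (shift work, weekends),
seasonal photoperiod, or DST. Passing tests therefore establish the
correctness and statistical behavior of the estimators under the stated
generative model, not population-level claims about clinical cohorts.

## Problem sizes and runtime choices

Validation runs at desk scale: Monte-Carlo checks use 100–1000 replicates
for closed-form limits (IV/IS, ANOVA null), 200 replicates for cosinor
recovery and the pseudo-F null, 100 for the 7-vs-21-day duration
normalization check, and cohorts of 15 subjects per phenotype (40/group for
the direction checks) for the end-to-end clustering and contrast analyses.
The acceptance script uses the same designs at somewhat smaller replicate
counts; all sizes are package choices balancing statistical resolution
against a few minutes of runtime.

## Known limitations

- Linear acrophase in the cluster space (see above).
- Absolute pseudo-F values are convention-dependent; compare only F/d
  within a pipeline.
- IS with few days is noisy and equals 1 by definition at one day.
- "Sleep" is an actigraphic estimate from zero-count runs; no staging,
  main-sleep-period consolidation scoring, or physiological fusion.
- No period estimation: both parametric models fix the 24 h period.
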
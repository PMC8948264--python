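# Methods

This note documents the models and procedures implemented in `rhythmlab`,
the defaults that matter, the design choices made where conventions diverge,
and what the synthetic-data generators do and do not emulate.

## Time and light schedules

Time is real-valued hours from an origin at the first lights-on; all
intervals are half-open `[start, end)`, which makes bin assignment and
transition bookkeeping unambiguous.  A schedule is a contiguous sequence of
epochs, each a repeating light cycle (cycle length, photoperiod, intensity).
Jetlag paradigms are built from truncated or extended transition cycles:

* **Acute advance of *s* hours** — the dark phase of the last baseline night
  is shortened by *s* (lights-on arrives early).  An alternative convention
  that truncates the light phase instead is available via
  `truncate="light"`; which phase the transition consumes is an experimental
  design choice, not something the analysis can infer, so it is explicit.
* **Acute delay** — the transition night is extended by *s* hours (one
  (24+*s*)-h cycle).
* **Chronic jetlag (advance of *a* h every *n* days)** — each *n*-day block
  ends with a (24−*a*)-h cycle.  For the canonical 6-h/2-day paradigm the
  effective Zeitgeber period is the block duration over cycles per block,
  (48 − 6)/2 = 21 h.  Negative *a* encodes chronic delays
  ((72 + 6)/3 = 26 h for 6-h delays every 3 days).

`effective_zeitgeber_period` infers the repeating block from the cycle-length
sequence and raises for constant conditions (DD/LL) or aperiodic segments.

## Behavioral generator

Each simulated subject carries one or two **phase-only oscillator
components**.  Component onsets advance by the intrinsic period τ each cycle;
when a light cycle is present, the onset receives a clamped correction toward
a reference phase (lights-off for the nocturnal mouse, lights-on for the fly
morning bout, plus a configurable steady-state angle): per cycle at most
`max_advance` hours in the advancing and `max_delay` hours in the delaying
direction, zero under constant conditions.  This is deliberately the simplest
generator with a bounded re-entrainment speed — the quantity the jetlag
endpoints must detect — and with an entrainment range: a component whose
correction limits cannot absorb the schedule's daily displacement free-runs,
which is how internal desynchrony under chronic jetlag is produced (one
entrainable and one non-entrainable component).

Counts per bin are independent Poisson draws of
`rate_rest + Σ_k w_k · rate_active_k · W_k(t)`, multiplied by
`1 − masking · 1[light on]`.  For the mouse, `W_k` is a boxcar over the
α-hour active phase; for the fly it is a bimodal waveform: raised-cosine
morning and evening bouts (half-width 2 h) with exponential anticipation
ramps (time constant 1.5 h, amplitude 0.6) anchored at the bout centers so
the ramp merges monotonically into the rising flank.  The evening bout has
full amplitude and the morning bout half amplitude; besides being the usual
shape of fly activity, an asymmetric waveform is what keeps a circadian
fundamental in the spectrum — a perfectly symmetric bimodal pattern is
12-h-periodic and would have no 24-h FFT component at all.

Defaults (mouse): τ = 23.6 h, α = 9 h, rate_active = 30 counts/6-min bin,
rate_rest = 0.5, max_advance = max_delay = 2 h/day, masking = 0.9,
6-min bins.  Defaults (fly): τ = 24 h, rate_active = 2 counts/min,
rate_rest = 0.05, masking = 0, 1-min bins.  `amplitude_decay` (< 1) decays
the active-phase rate per day spent in DD (the delayed-arrhythmicity
phenotype; 0.5/day keeps a fly rhythmic for roughly its first 3–5 DD days),
and `tau_drift_sd` makes τ a reflected random walk (the unstable-period
phenotype).  One master seed drives per-subject child streams
(`SeedSequence(seed, spawn_key=(subject,))`), so subject *i* is reproducible
regardless of cohort size.

What the generator does **not** emulate: molecular (TTFL) dynamics, a
realistic phase-response curve shape (the clamp is a rectangular PRC),
ultradian bout structure, wheel-specific autocorrelation, or
activity-intensity after-effects.  Passing recovery tests therefore show
that the statistics measure what they claim on data with the assumed
count-noise and phase dynamics — not that they are robust to every artifact
of real records.

## Rhythm statistics

**Chi-squared periodogram.** Q_P = K·N·Σ_h(M_h−M̄)²/Σ_i(x_i−M̄)² over K
complete folds of P bins; trailing partial cycles are discarded (classical
Sokolove–Bushell).  This normalization makes Q_P ~ χ²(P−1) under white
noise, verified by Monte-Carlo null calibration; a noise-free P-periodic
signal attains the maximum Q = N.  The significance line is pointwise
χ²(P−1) at 1−α by default; a Bonferroni flag divides α by the number of
tested periods (needed when "any significant peak in a scan" is the
decision, as the pointwise line's family-wise error over a hundred candidate
periods is large).  Candidate periods are integer multiples of the bin width,
so a 6-min bin gives a 0.1-h period grid.  "Periodogram amplitude" is defined
as Q minus the significance line at the main peak — a declared convention
matching common actigraphy software, since the term has no public formal
definition.

**FFT relative power** uses mean removal, no taper, and normalizes the power
spectrum to sum to one over positive frequencies; rhythm power is the band
maximum (default 18–30 h).  On this scale the 0.01 fly rhythmicity threshold
is meaningful.  A constant trace returns 0 with a flag.

**Onset detection** smooths with a centered moving average (15 min for
mouse, 30 min for fly by default — the rule itself specifies no smoothing,
and unsmoothed Poisson bins make threshold crossings erratic), then takes
per cycle the first bin at ≥20% of the cycle maximum and the last bin at
≥5%.  Cycle windows can be anchored at the rest phase of the folded profile
(`cycle_start="rest"`), which keeps the activity bout in the window interior;
thresholds are relative, so detection is invariant to count rescaling.

**Free-running period** (`free_running_period`) chains periodogram peak →
rest-anchored onset detection at that folding period → OLS regression of
unwrapped onset phases on day; the implied period is the folding period plus
the slope.  Folding at the peak rather than at 24 h keeps drifting onsets
away from window edges, which is what makes ±0.1-h recovery possible for τ
as far from 24 h as 22.5.

**Phase shift from a pulse** extrapolates pre- and post-pulse regression
lines (skipping 3 transient days by default) to the day after the pulse and
reports pre − post: positive = advance.  **Phase angle of entrainment** is
the mean of (onset − lights-off) over 6 consecutive days; negative values
mean onset precedes lights-off.

## Entrainment endpoints

**Daily phase shifts** after an acute shift are cumulative: baseline = mean
onset phase relative to the *old* schedule over the last 6 pre-shift days;
each post-shift day's shift is baseline minus that day's old-schedule phase,
signed toward the shift direction.  A regression-projection alternative was
considered and rejected as the default because jetlag onsets are
schedule-referenced, not free-running.  **Days to re-entrain** is the first
day within 0.5 h of the full shift for 3 consecutive recorded days — the
endpoint is reported in the literature without a stability definition, so
this operationalization is explicit and configurable; subjects never meeting
it are flagged rather than given a number.

**Chronic-jetlag classification** scans 16–28 h: a significant peak in the
short band (20–22 h, around the 21-h Zeitgeber) marks the entrained
component; an additional significant peak in the long band (22.5–28 h) marks
desynchrony, subtyped at 24 h.  Band edges encode "~21 h", ">24 h", "<24 h"
and are configurable.  A peak only counts if its excess over the significance
line reaches 10% of the largest peak's excess: a strongly periodic 21-h
rhythm folded at low-order rational multiples of its period (28 = 4·21/3)
throws small but formally significant subharmonic peaks (measured at ≲7% of
the main peak's excess) that must not be read as a second oscillator, while
genuine second components at mixture weights ≥ 0.3 sit far above this line.

**Fly DD classification** calls a 6-day window rhythmic when the periodogram
peak is significant and FFT power > 0.01.  Labels: rhythmic (both windows),
delayed-arrhythmic (first only), arrhythmic (neither).  A fly rhythmic in
both windows is *unstable* when the sliding-6-day-window peak-period SD
exceeds 0.5 h **or** the SD of day-to-day period estimates exceeds 0.5 h,
where daily phases come from circular cross-correlation of each cycle's
profile with the mean folded profile.  The second statistic exists because
6-day windows average away most of a τ random walk; cycle-level phases are
the sharper witness of "fluctuating period lengths", while threshold-crossing
onsets proved too noisy on 1-min fly counts for this purpose.

**Anticipation indices** are 3-h/6-h pre-transition activity ratios pooled
over subjects and the last 3 LD days; 0.5 is the exact null for uniform
activity, and a zero 6-h denominator yields a flagged NaN rather than a
value.  **Relative activity profiles** average per-subject mean day profiles
into 1-h Zeitgeber-time bins and normalize the group mean to its maximum.

**Category comparisons** use the Pearson χ² test without continuity
correction, dof = (rows−1)(cols−1).  This choice is validated: it reproduces
the published category-table p values (0.0072 and 0.0153) to their printed
precision, which a Yates-corrected test does not.

## Proteomics pipeline

Stages mirror the standard Perseus LFQ workflow: (1) drop rows flagged
reverse / potential contaminant / only-identified-by-site; (2) log2; (3) keep
proteins with ≥ `min_valid` (default 4) observed values across retained
samples (excluded samples — e.g. an outlier replicate — are removed first);
(4) impute missing cells per sample column from
Normal(μ − 1.8σ, (0.3σ)²) with μ, σ from the column's observed values
(whole-matrix mode by flag); (5) test with
d = (m₂ − m₁)/(s_pooled·√(1/n₁+1/n₂) + S0), p from t(n₁+n₂−2), two-sided,
BH-adjusted at FDR 0.05.

Choices worth stating:

* **S0 default is 0.1**, a common volcano-plot setting; published analyses
  of the same dataset sometimes report S0 = 0 and S0 = 0.1 in different
  places, so the true setting is often ambiguous and `s0` is an explicit
  argument everywhere.  Note that with small groups and BH-adjusted t
  p values, S0 = 0.1 is very conservative; the pipeline-level FDR/power
  validations run at S0 = 0, where discoveries exist.
* p values come from the t distribution rather than permutation: the
  workflow specifies a two-sample Student's t test, and the analytic route
  is deterministic.  At S0 > 0 the t reference makes the test conservative
  for small fold-changes (that damping is S0's purpose).
* Pooled-variance (Student) rather than Welch by default; Welch by flag.
* Correlation QC (pairwise Pearson over mutually observed rows, flagging
  r ≤ 0.90) runs before imputation.
* BH adjustment delegates to `statsmodels` `multipletests(fdr_bh)` and is
  tested against an explicit step-up oracle.

**Fisher enrichment** computes the hypergeometric upper tail P(X ≥ k) per
term against the quantified background, keeps terms with ≥ 3 foreground
members, and reports (k/n)/(K/M) enrichment ratios; annotation tables are
user-supplied (term → protein-id sets) — no annotation database is bundled.

## Proteome generator

Log2 intensities: y_ps = a_p + δ_p·1[s ∈ group 2] + ε_ps with
a_p ~ N(25, 2²), ε ~ N(0, 0.3²); a fraction `dep_fraction` (default 0.1) of
proteins carries δ_p = ±|N(1, 0.5²)|.  Cells go missing with probability
σ(−(y − 21)) (logistic; lower abundance ⇒ more missing — the left-censoring
that motivates downshifted imputation), and decoy/contaminant/site-only rows
with low-shifted random intensities are appended.  Defaults give a
~4,000-protein two-group (4 vs 4) table resembling a deep cell-line LFQ
experiment with a few percent missingness.  It does not emulate peptide-level
aggregation, shared-peptide ambiguity, intensity-dependent variance, or
batch structure; FDR conclusions from it speak to left-censored missingness
plus imputation, not to those artifacts.

## Validation sizes and numerical notes

The test suite validates at sizes chosen to keep the whole suite in tens of
seconds while leaving clear statistical margins: periodogram oracle
equivalence to 1e−9 on 2,000-bin traces; null calibration with 1,000
white-noise replicates at a single tested period (binomial test at 0.01);
period recovery for τ ∈ {22.5, 23.6, 24.8} over 10 subjects × 14 DD days
each; classification recovery on 200 subjects split across the six
behavioral classes (≥95% required; class exemplars: mixture weight 0.5 for
desynchronized mice, amplitude decay 0.5/day for delayed-arrhythmic flies,
τ-drift SD 1.0 h/day for unstable-period flies, with the 0.6 h/day drift of
the borderline regime tested separately as a majority call); and realized
false-discovery proportion ≤ 0.10 averaged over 20 simulations of 2,000
proteins (slack above the nominal 0.05 because imputation induces mild
dependence between tests).

Degenerate inputs are explicit errors, not silent numbers: zero-variance
traces have no periodogram; constant traces have rhythm power 0 with a flag;
columns with fewer than 2 observed values cannot be imputed; contingency
tables with zero margins are rejected.  Ties in onset thresholds resolve to
the earliest bin (first/last crossing is part of the definition), and phase
unwrapping maps successive differences into half-open half-period intervals.

## Known limitations

* The oscillator's clamp correction is a rectangular phase-response model;
  re-entrainment-speed parameters are free knobs, not values calibrated to
  any strain.
* The chronic-jetlag subharmonic guard (10% relative prominence) is a
  heuristic; mixtures with component weights well below 0.3 will not be
  called desynchronized.
* "Periodogram amplitude" and "FFT power" follow declared conventions; other
  actigraphy software may scale these differently, so thresholds that depend
  on them are configurable rather than portable constants.
* The S0 statistic's t-distribution p values are conservative for S0 > 0;
  Perseus's permutation-based FDR can be more powerful at the same S0.
* Lomb–Scargle/wavelet period estimation, cosinor fitting, and mixed-effects
  group modeling are out of scope.
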
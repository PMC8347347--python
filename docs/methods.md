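# Methods

## Signal model and preprocessing

A recording is three binary channels per foot (heel, first and fifth
metatarsal head switches; closed = 1) on a regular grid, 2 kHz by
default.  Mechanical switch bounce appears as runs of a few
milliseconds, while genuine gait phases last on the order of 100–500 ms
at self-selected speed, so debouncing is posed as run-length filtering:
every *interior* maximal constant run strictly shorter than a threshold
(default **20 ms**, configurable as `debounce_ms`) is absorbed into the
run that precedes it, shortest-first with the earliest run winning
ties, iterated to a fixpoint.  Runs touching either recording boundary
are never removed (there is no preceding/following context to justify
it).  The filter is offline ("anti-causal"): it uses future samples and
shifts no transition by more than the threshold, with no systematic
lag.  The implementation operates on the run-length encoding with a
lazily invalidated heap (O(R log R) in the number of runs) and is
exactly equivalent to the naive re-scan formulation, which the test
suite keeps as an independent oracle.  The operator is idempotent.

The threshold value itself is a package default, not a measured
hardware constant: it sits two orders of magnitude above realistic
bounce durations (1–15 ms) and one below the shortest gait phases, so
the exact choice is uncritical within roughly 10–40 ms.

Debounced channels are mapped per sample onto the four-phase contact
alphabet — H (heel only), F (heel + ≥1 metatarsal), P (≥1 metatarsal,
no heel), S (no contact) — a total mapping over all 8 switch states.  A
second run-length pass (default on) removes sub-threshold *phase* runs,
which can survive channel-level filtering when two channels toggle
near-simultaneously at a phase boundary.

## Cycle segmentation and classification

Cycles open at contact onsets, i.e. S → {H, F, P} transitions, and
close at the next onset.  Opening at *any* contact rather than heel
strike only is deliberate: pathological cycles may begin with a
forefoot (PFPS, PS) or flat-foot (FPS) strike, and a heel-strike-only
segmenter would silently misparse exactly the cycles of interest.
Partial segments before the first and after the last onset are
discarded.  Segments longer than `max_cycle_s` (default **3 s**, about
three times a normal stride period) are set aside as pauses and counted
separately rather than entering any statistic.

A cycle's class label is its run-length phase string; `HFPS` is
typical, everything else atypical — an open vocabulary, no template
list.  Cycles are attributed to the straight-walking or U-turn region
by the annotation interval containing their *onset*; a majority-overlap
rule would make attribution depend on cycle length and is harder to
reason about at region boundaries.

## Spatio-temporal parameters

* **Phase durations (%GC)** — per typical cycle, each run's duration
  over the cycle duration × 100; side summaries average over typical
  cycles, so the four phases sum to 100 exactly.
* **Cadence** — strides/min.  Default denominator is the full recording
  duration; a `straight` mode restricts both counts and time to
  straight intervals.  Both are reported with the mode flagged.
* **Double support** — per cycle, the fraction of samples during which
  neither foot is in swing, × 100, averaged over cycles (`total` mode).
  An `initial` mode counts only the double-support period beginning at
  the cycle's own onset (loading response), roughly half the total.
  The operational definition of "double support" varies across the
  literature between these two conventions; both are exposed, `total`
  is the default.
* **Walking speed** — timed straight passages are pooled:
  (number of passages × path length) / (summed passage time).  Pooling
  matches a stopwatch protocol where total distance and total time are
  accumulated; averaging per-passage speeds would weight short passages
  more.
* **Atyp** — atypical-cycle percentage divided by speed (% per m/s).
  All atypical percentages, including the per-region ones, use the
  side's *total* cycle count as denominator, so straight + turn
  percentages add up to the side's total atypical percentage whenever
  annotations cover every onset.

## Statistical battery

* **Lilliefors test** — KS distance between the standardized sample and
  the standard normal CDF, with both moments estimated.  The p-value is
  Monte-Carlo: the statistic is ranked against 10,000 (default) null
  statistics simulated at the same n, p = (1 + #{D₀ ≥ D}) / (N + 1),
  with the null table cached per (n, N, seed).  This makes the test
  exactly calibrated by construction rather than relying on asymptotic
  tables, and it is seeded and reproducible.
* **Two-group comparison** — Student's t when both samples pass
  Lilliefors at α = 0.05, otherwise the Mann-Whitney rank-sum test (a
  paired Wilcoxon signed-rank variant exists for paired designs; the
  group comparison here is between independent samples, where a
  signed-rank test would be ill-posed).  The method used is recorded in
  the result.
* **Two-way ANOVA** (Group × Side) with Tukey-HSD post-hoc, via
  statsmodels on a balanced one-value-per-subject-side layout.  An
  all-identical input returns a flagged no-effect result (F = 0,
  p = 1) instead of NaNs.
* **Hedges g** — (M₁ − M₂)/SD*pooled with pooled SD weighted by
  (nᵢ − 1), multiplied by the small-sample correction
  J = 1 − 3/(4(n₁+n₂) − 9) by default (disable to get the literal
  uncorrected quotient).  Report tables use the sign convention
  control − PD.  Because summary tables do not determine how per-side
  values were pooled into the two samples, both `per_side` (default)
  and `subject_mean` poolings are available.
* **Subgroup selection** — threshold = mean + 1 sample SD (n − 1) of
  the control Atyp values, each control's Atyp first averaged over its
  two sides; patients strictly above the threshold form the subgroup.
* **Bootstrap correlation** — Pearson r with the two-sided t-test
  p-value; 95% CI from 1000 seeded paired resamples, BCa by default
  (percentile optional).  Exactly collinear input short-circuits to the
  degenerate CI [r, r]; if BCa is undefined because resamples are
  degenerate (possible at very small n), the percentile interval over
  the finite resamples is used.  Bounds are clipped to [−1, 1].

## Synthetic cohort model

The generator emulates the acquisition protocol end to end so the whole
chain can be validated against known truth.

**Walk structure.** Straight segments of duration path/speed (9 m
default, 3% jitter) alternate with U-turns of 3 ± 0.5 s.  Straight
segments that complete a full traversal double as timed passages.  The
turn length is a package choice (protocols rarely report it); it yields
a turn share of ~25% of cycles, and it upper-bounds the turn-region
atypical percentage any subject can express (a subject cannot have 30%
of *all* cycles atypical-in-turn if only 25% of cycles are turning).

**Cycles.** Stride periods come from a per-subject cadence draw
(group means 55.7/54.6 cycles/min, SD 5.9/3.3) with 3% per-cycle
jitter; both feet share one stride sequence, the right foot offset by
half a stride, so double support emerges from stance overlap
(2 × (stance fraction − 50%) ≈ 11–16 %GC) instead of being imposed.
Phase fractions per cycle are Dirichlet draws around a per-subject
profile, itself a Dirichlet draw (concentration 120 → 3–4 %GC
between-subject SD) around the group-side profile.  Atypical classes
redistribute the missing phases' mass onto their own stance runs (PS
puts the whole stance on the forefoot; FPS merges H into F; HFHFPS
splits H and F in two).  An open-vocabulary `other` class realizes
random legal contact sequences.  Switch channels are reconstructed
run-by-run to satisfy the truth table exactly, with the metatarsal
choice (met1/met5/both) randomized per run.

**Noise.** Switch bounce is a Poisson stream (2 events/s default) of
channel flips strictly shorter than the debounce threshold, kept clear
of true transitions and of each other by one threshold margin — so
debouncing provably removes it and end-to-end class recovery is exact.
A `hard_noise` mode drops the safeguards for robustness testing only.

**Atypicality.** A subject's atypicality is a trait with two strata:
mild (60% of patients; low, right-skewed lognormal rates) and severe
(40%; high truncated-normal rates).  Stratum means are constrained so
the mixture reproduces the configured group-level region rates
(more-affected side 12.3% straight + 11.5% turn of all cycles,
less-affected 4.8 + 10.7; controls ≈ 2–2.5 straight, 6.1–6.3 turn).
Straight-walk atypicality carries the severity signal (its group SD is
large); turn atypicality is only mildly stratified (its group SD is
small, and the turn-share bound caps it).  Controls get a shared
lognormal within-subject multiplier (CV 0.7) coupling their four
components — gait quality is a subject trait, and the coupling gives
the control Atyp distribution the spread that a control-referenced
threshold needs to sit clearly above the mild-patient range.  Severe
counts are exact per cohort (round(0.4·n)), not binomial, mirroring a
fixed case-mix.

**Motor score.** UPDRS-III-like scores follow a linear link on the
more-affected side's Atyp, `updrs = 12.4 + 0.2·Atyp + ε`, with
stratum-dependent Gaussian noise (SD 7.5 mild, 2.0 severe).  The
stratification is the substantive modelling choice here: in mildly
impaired patients the motor exam is dominated by non-gait items
(tremor, rigidity), so their scores are weakly coupled to gait quality,
while in severely impaired patients the score tracks gait closely.  A
homoscedastic link cannot produce the characteristic pattern in which
the above-threshold subgroup correlates more strongly than the whole
group — under homoscedastic noise that pattern requires the
above-threshold tail to have a larger variance than the full sample,
which is incompatible with realistic group means and SDs.  With the
stratified noise the pattern (subgroup r ≈ 0.85–0.95 vs whole-group
r ≈ 0.6–0.7, subgroup ≈ 8–10 of 20) emerges in ~90% of cohorts.
Intercept, slope and noise scales were chosen to give realistic score
moments (≈ 17 ± 8) at the default Atyp distribution.

**What the generator does not emulate.** Freezing of gait, festination
and medication-state dynamics; kinematics and ground-reaction forces;
sensor detachment or pressure-dependent switching (the 3 N activation
threshold is not modelled); correlation between atypicality and
speed/cadence; day-to-day variability.  Passing tests therefore show
that the *pipeline* recovers what it is pointed at under protocol-like
conditions — not that the biological model is complete.

## Numerical choices and degenerate inputs

* Debounce removal criterion: run length < ceil(threshold × fs − ε)
  samples; thresholds that equal a run's duration keep the run.
* Intervals are half-open [start, end); region lookup at a boundary
  belongs to the later interval.
* Integer sample partitioning of a cycle's phase runs rounds cumulative
  boundaries and then enforces ≥ 1 sample per run by stealing from the
  longest run.
* Zero-cycle sides yield a flagged summary (NaN percentages, zero
  cadence) rather than an error; missing annotations yield `unknown`
  regions and a NaN speed with a logged warning.
* Monte-Carlo p-values use the (1 + k)/(N + 1) estimator, never exactly
  zero.
* Identical ANOVA inputs, empty cells, constant samples, zero pooled
  SD and zero-variance correlations raise or flag rather than returning
  silent NaNs (see the per-function docstrings).

## Problem sizes used in the test suite

The statistical end-to-end tests run the full pipeline at reduced
recording length and sampling rate (2-minute walks at 200 Hz, full
20 + 20 cohorts, 5–20 replicates), which preserves every rate and
effect size while keeping cycle counts at ~110 per side; calibration
checks (normality-test type-I error, bootstrap coverage) use
10,000-sample / 500-replicate runs at the sizes stated in the tests.
The acceptance script runs the full default configuration (5 minutes at
2 kHz).

## Known limitations

* The within-subject correlation of the two sides' atypicality (shared
  stratum, shared control multiplier) makes per-side observations
  positively dependent; the two-way ANOVA treats them as independent,
  as is conventional for this layout, so its p-values are mildly
  anti-conservative under strong coupling.
* The turn-region rate a subject can express is bounded by their
  realized turn share; configurations requesting more are clipped at a
  95% conditional ceiling, which can bias very extreme settings
  downward.
* Hedges-g pooling behind published summary tables is generally
  ambiguous; both offered poolings are defensible and can differ
  noticeably at small n.
* The debounce fixpoint is order-dependent in pathological alternating
  inputs; the shortest-first/earliest tie-break makes it deterministic,
  but other orders are equally defensible filters.
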
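# Methods

This note records the model, the synthetic-data design, the numerical
choices, and the places where the design was genuinely open.

## Pipeline

Stages run in a fixed order inside `WorkloadStudy.fit()`:

1. **Spike cleaning.** Band-power series contain occasional
   non-biological transients (electrode contact, motion): an immediate
   rise and fall within a 1 s window. A sample is flagged when it
   exceeds both the last retained sample before it and the first sample
   after it (each within 1 s) by more than k = 5 rolling median absolute
   deviations (window 30 epochs). Detection operates on **log power**
   for strictly positive series — gain fluctuations are multiplicative,
   so the log scale makes the threshold invariant to the export's units
   — and the rolling MAD is floored at the series' global MAD so a
   locally quiet stretch cannot collapse the threshold. Flagged runs
   are replaced by linear interpolation between clean flanks (in linear
   units), so cleaning never widens the clean value range.
2. **Indices.** Eight ratios per epoch from the AF7/AF8 channel-mean
   band powers (FAA uses the two alpha channels; natural log by default,
   the base only rescales it). Per-participant z-scores are computed
   with the sample-SD (n−1) convention and exported alongside, but all
   group-level reporting uses **raw** index means: reported group
   profiles of this kind (engagement ≈ 0.45–0.65) are on the raw ratio
   scale and per-participant z-scores would average to ~0 by
   construction.
3. **Track segmentation.** Windowed curvature C = Δθ/Δd, with Δθ the
   unsigned angle between the chords (i−8 → i) and (i → i+8) and Δd
   the arc length between the chord midpoints. This operationalization
   makes C → 1/R on circles (verified to 2 % at 5 m spacing), so the
   0.002 / 0.006 rad/m class thresholds read as radius cutoffs of 500 m
   and ~167 m. Thresholds are lower-inclusive. Turn extraction drops
   non-straight runs shorter than 30 m, merges runs separated by
   straight gaps under 50 m (an S-complex is one turn), numbers turns
   from the start/finish point, and rates a turn Hard when the majority
   of its points are sharp. The 30 m / 50 m defaults are the package's
   own; they yield exactly seven turns on the reference circuit and are
   configurable.
4. **Synchronization and aggregation.** EEG epochs join the nearest
   telemetry sample within 0.5 s (unmatched epochs are dropped and
   counted); positions map to the segment of the nearest centerline
   point; indices are averaged per (participant, segment) — ratios
   within an epoch, means across epochs. All laps are pooled for
   segment means; the lap-trend analysis separately drops lap 1 (the
   out-lap, contaminated by task-loading onset).
5. **Tiers.** k-means (k = 4, 50 restarts, fixed seed) on z-standardized
   (total lap time, invalid %); standardization is needed because
   seconds and percent are incommensurate. Tier names follow ascending
   raw lap-time centroids (ties broken by lower invalid %), never
   k-means' internal ids; the two fastest tiers merge into "Potential".
6. **Statistics.** One-way fixed-effects ANOVA with η² = SSB/SST;
   Tukey–Kramer HSD with SE = sqrt(MSW/2·(1/nᵢ+1/nⱼ)) and adjusted p
   from the studentized-range distribution; observation unit for the
   tier comparison is the participant × turn mean (7 per driver),
   giving df = (2, 102) at the study's size — the unit that reproduces
   that df structure. The design knowingly applies a plain one-way
   ANOVA to repeated-measures data and no multiplicity correction
   across the eight indices; both are replicated as-published
   limitations, not recommendations.
7. **Trend.** Cubic least-squares fit of per-lap mean fatigue (laps
   2..L) with R² and an overall-regression F test (df = 3, n−4).
8. **Subjective scores.** Feel index = 0.5·driving-experience +
   0.5·car-responsiveness (weights configurable); valence = mean of the
   six positive emotions − mean of the six negative; arousal = mean of
   {excited, tense, angry, frustrated} − mean of {relaxed, calm, tired,
   bored, depressed}, a circumplex placement chosen here (delighted,
   happy, content are valence-loaded and stay out of the arousal
   contrast). Spearman correlations against per-participant index
   means.

## Synthetic cohorts

The generator is the package's substitute for non-public recordings and
defines the study conditions: 15 drivers in tiers of 2/8/2/3
(MostPotential / Potential / Normal / NoPotential), 12 laps (~20 min),
10 Hz telemetry, 1 Hz EEG epochs (≈1100–1400 epochs per driver), 5 m
centerline spacing.

**Band-power inversion.** All eight indices are ratios, so one scale
per epoch is free; the gauge α+β = 1 gives θ = fatigue-target,
α = engagement − fatigue, β = 1 − α, δ = 1/consciousness-target
(default consciousness 2.0, i.e. δ = 0.5). Feasibility requires
engagement > fatigue and engagement − fatigue < 1; infeasible targets
are rejected naming the violated inequality. Total α splits across the
frontal channels as α_AF8 = 2αg/(1+g), α_AF7 = 2α/(1+g) with
g = exp(FAA-target), keeping the channel mean exactly α. Temporal
channels carry the same spectral profile (they are written to files but
never enter the indices).

**Noise model.** Two layers: (a) a *shared* per-epoch gain applied to
every band of the epoch — AR(1) in log power, lag-1 correlation 0.9
(~10-epoch memory), stationary σ = 0.3 — which cancels exactly in every
ratio index and models slow electrode/arousal gain drift (iid gain
noise would generate single-epoch excursions indistinguishable from
artifacts by the spike detector's own definition); (b) small
independent per-band lognormal jitter (default σ = 0.02) that bounds
recovery tolerance: zero jitter makes per-epoch index values exactly
equal to the segment's targets, and the across-seed spread of cohort
means shrinks as 1/√(epochs).

**Calibration.** The two top tiers share one profile (engagement 0.519,
fatigue 0.450, FAA 0.488) so the merged tier's mean equals it; Normal
is 0.569 / 0.470 / 0.586 and NoPotential 0.647 / 0.520 / 0.506. The
top tiers additionally carry per-turn structure (engagement lowest in
Turn 4 at 0.494 and Turn 3 at 0.509, highest in Turn 6 at 0.522;
fatigue peaking in Turn 7 at 0.469 and Turn 2 at 0.468, lowest in Turn
4 at 0.442). Values for turns 1, 5 and 6 fatigue / 1, 2, 5 engagement
are not externally constrained and were fixed once between the
printed-profile extremes. Straights carry the tier base values; since
turns cover ~29 % of the lap, pooled tier means sit within ~0.002 of
the base targets.

**Circuit.** A regular heptagon (circumradius 900 m) with corners
rounded at radii 400/120/100/350/140/450/150 m — a closed rounded
polygon (each arc sweeps the heptagon's exterior angle; adjacent edges
are trimmed by R·tan(φ/2)), total length ≈ 5.36 km. The radii straddle
the curvature cutoffs so turns 1/4/6 are Normal and 2/3/5/7 Hard,
giving a Grand-Prix-like mix of severities. The start point sits
mid-straight, so extraction numbering matches ground truth.

**Telemetry.** Constant-speed driving along the centerline; the 12-lap
total time and the off-track fraction are drawn from the tier's printed
ranges, concentrated in the central 35 % of each range. The published
tier boxes overlap (the fastest tier's lap-time range encloses the
second tier's), so full-width uniform draws do not define recoverable
clusters at any sample size; central draws realize the separated-tier
structure the ranges describe. Off-track time is placed as contiguous
5–20 s excursion blocks matching the drawn fraction to sample rounding.

**Questionnaires.** Integer 0–10 ratings from a truncated discretized
normal with tier-dependent means (faster tiers more positive, more
satisfied), SD 1.5.

**What the generator does not emulate:** vehicle dynamics and racing
lines (constant speed, zero lateral deviation), realistic raw EEG
morphology (the raw-FFT path is tested with synthetic tones and noise),
volume conduction/channel correlation structure, EEG–performance
coupling beyond the tier profiles, and ECG. Passing tests therefore
demonstrate the *pipeline's* correctness and calibration-recovery under
controlled conditions, not the physiological validity of the indices on
real recordings.

## Numerical choices and degenerate inputs

- Band-power CSV reader: rows missing any band are dropped and counted;
  non-monotone timestamps and unknown columns are hard errors; optional
  `RAW_*` columns are ignored (raw ingestion goes through
  `RawEEGSeries` + the FFT path). A `log10` dialect flag de-logs
  stored powers; indices always operate on the linear scale.
- FFT path: 256-sample Hann windows, non-overlapping by default,
  per-window mean removal (DC invariance), half-open bands [1,4), [4,8),
  [8,12), [12,30) Hz, 50/60 Hz notch (Q = 30) applied only in raw mode.
- z-scores of a constant index are set to 0 with a warning (zero SD).
- ANOVA with zero within-group variance reports F = ∞ (p = 0) or F = 0
  for identical means; Tukey requires every group ≥ 2 observations.
- k-means requires at least k distinct feature rows; with k = 1 all
  drivers share one cluster.
- Turn extraction on a track with no qualifying runs warns (never
  errors) when a turn count was expected.
- Trend fit needs ≥ degree + 2 points; fewer than 2 laps disables the
  trend features with a warning.

## Known limitations

- The tier comparison inherits the as-published one-way ANOVA on
  repeated measures; a mixed model would be the statistically sound
  choice on real data.
- Whether real exports are linear or log-scaled varies by app version;
  the `log10` flag covers both, but the reported raw-scale magnitudes
  assume linear power.
- Clustering recovery is only guaranteed for cohorts whose performance
  features actually separate; the overlapping published ranges are
  handled by central draws in simulation, but real cohorts may not be
  4-clusterable.
- The difficulty rating (majority-sharp) is one of several defensible
  rules; a peak-curvature strategy is exposed as an alternative through
  the per-turn curvature data.
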
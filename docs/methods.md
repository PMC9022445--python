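# Methods

This note records the models, estimators, and numerical choices behind
`pamkit`, and what the synthetic-data generator does and does not emulate.

## Data model

The canonical on-disk format is a long ("tidy") annotation table — one row per
(recording, species) with a nonnegative integer vocalization count — plus a
sites CSV (coordinates, watershed, forest age) and a daily weather CSV. In
memory the central object is the wide **count matrix** (recordings × species)
with taxon class (bird/mammal) carried as column metadata, because richness
and some dominance summaries are conventionally reported for birds only.
Recording metadata includes ordinal audible-rain (0–4) and wind (0–2) ranks;
`apply_exclusions` drops recordings above a rain threshold (default rank > 2)
or on explicitly listed dates, since heavy rain both silences birds and masks
detections. Dates are ISO-8601 strings; no timezone arithmetic is attempted.

Inter-site distances are haversine on decimal degrees with Earth radius
6371 km. At the sub-2-km extent of a typical deployment the projection choice
is immaterial (< 0.1% error), and haversine needs no projection metadata.

## Ambient sound pressure

Field recorders are rarely amplitude-calibrated, so all levels are relative.
RMS of a 1-s window is computed as the *standard deviation* of the raw
samples (divisor n, mean removed — mean removal absorbs DC offset), and
levels are log₁₀(RMS), which is approximately normal for field backgrounds.

* `a_automated`: within each whole minute, every 1-s window advanced by 0.1 s
  that fits fully inside the minute contributes a log₁₀(RMS); the minute's
  "quiet second" is the 10th percentile (linear interpolation between order
  statistics, pinned so results are bit-stable), and the recording value is
  the mean over minutes. A trailing partial minute is ignored. At the
  defaults this gives ⌊(60 − 1)/0.1⌋ + 1 = 591 windows per minute; published
  descriptions of this estimator sometimes state 580, which is not
  reproducible from the stated window/step arithmetic — we default to all
  fully contained windows and leave window, step, and percentile
  configurable. The low percentile makes the metric robust to sparse loud
  events: with ≤ 5% song duty cycle, fewer than 10% of windows overlap a
  song, so the 10th percentile still samples the background.
* `a_manual` emulates manual review: a seeded random second within each
  minute, advanced in 0.1-s steps until a 1-s window overlaps no annotated
  selection, rolling into later minutes when a minute is fully occupied
  (such minutes contribute nothing, so the number of snips is at most the
  number of minutes). It errors only when no vocalization-free second exists
  anywhere.
* Stereo input is averaged to mono; integer PCM is normalized to [−1, 1];
  clipped samples are kept (clipped vocalizations are still identifiable and
  excluding them would bias loud mornings).
* Zero-variance (digitally silent) windows are degenerate: log₁₀(0) is
  undefined. The default is to raise; a −∞ sentinel is available.

**Variance decomposition.** Per-minute quiet metrics are decomposed by
method-of-moments ANOVA with year fixed and occasion (day) and location as
crossed random factors within year; the residual is among-minute variation.
Balanced expected mean squares give E[MS_occ] = σ²ₑ + M·L·σ²_occ and
E[MS_loc] = σ²ₑ + M·O·σ²_loc; negative component estimates are truncated at
zero before normalizing to proportions (the standard MoM convention), and
per-year estimates are pooled weighting by observation count. No installed
Python package provides MoM components for crossed random factors
(statsmodels' MixedLM covers nested REML), so this is implemented directly
and validated by simulation recovery. Whether published proportions of this
kind are computed from raw or truncated components is generally unstated;
truncation is used here because negative variance shares are
uninterpretable.

## Vocal traits

Duration is defined by the annotated selection bounds (± 0.01 s convention),
never by the audio. Dominant frequency is the argmax bin of the
time-averaged power spectrum of a Hann-windowed spectrogram (DFT 512, 50%
overlap), giving one-bin resolution rate/512 ≈ 86 Hz at 44.1 kHz; per-frame
frequency tracks are out of scope. Frequency is measured only on *clean*
snips (no temporal overlap with any other selection), because overlapping
energy from another singer corrupts the argmax; species with no clean snips
get duration statistics only. Trait summaries use sample SD (divisor n − 1);
single observations report SD as missing rather than 0.

Stratified snip sampling draws up to a per-species quota without replacement
under a seeded generator; unmet quotas are reported, not fatal, mirroring how
rarely-vocal species under-fill sampling designs.

## Activity, environment, and habitat

Counts are square-root transformed before averaging; rate series are means of
transformed counts over recorders within a unit (recorder → stand →
watershed; the nested and direct averages agree in balanced designs, and the
hierarchical path exists for unbalanced stand sizes). Environmental
correlations are plain Pearson on pairwise-complete dates with the per-pair n
reported, and no multiple-comparison correction — the |r| thresholds
(r* = t*/√(t*² + n − 2), e.g. 0.444 at n = 20 and α = .05) are reported
alongside so readers can apply their own standards.

The habitat ANOVA is ordinary least squares with forest age, watershed,
their interaction, and date, all fixed. Date is coded categorical (the
conservative reading when the coding is unspecified); sums of squares are
sequential (type I), which coincides with the classical decomposition in the
balanced case. Temporal autocorrelation of residuals is not modeled.

## Spatial synchrony

Synchrony between two units is the Pearson correlation of their daily
(transformed) rates across shared dates, with the delta-method
SE = √((1 − r²)/(n − 2)). Rain-excluded dates are dropped listwise so every
pair uses the same date set.

The correlogram smooths the 45 pair correlations from 10 sites against pair
distance with a least-squares cubic regression B-spline. The smoothing level
is the number of basis functions (`df`, default 4 — a cubic polynomial;
`df` > 4 adds interior knots at distance quantiles). With only ~45 points,
strong smoothing is essential; the regression-spline parametrization makes
the equivalent degrees of freedom explicit and the fit deterministic. The
95% envelope is a **cluster bootstrap over sites**: pair correlations sharing
a site are dependent, so sites (not pairs) are resampled with replacement,
pairs and the spline are recomputed per resample, and the 2.5/97.5
percentiles taken per grid point. Self-pairs of a duplicated site (distance
0, r = 1) are excluded; bootstrap resamples with fewer usable pairs than
`df` are skipped. The percentile band of a skewed bootstrap can fail to
bracket the point estimate, so the envelope is widened where needed to
include it — this keeps the reported band honest as an uncertainty statement
about the plotted curve. An x-intercept (the distance where estimated
synchrony first crosses zero) is reported only when the spline actually
crosses zero inside the observed distance range.

## Interspecific tests and guilds

The date-randomization null destroys shared temporal structure while
preserving each species' marginal distribution: both series' date orders are
permuted independently (permuting one would give the identical null; both
are permuted because that is the natural symmetric statement of the
procedure) and the two-sided p is (1 + #{|r_null| ≥ |r_obs|})/(n_perm + 1) —
the add-one convention counts the observed ordering and keeps p > 0. An
exact-enumeration oracle (all n! orderings) validates the Monte-Carlo p at
small n. Species enter the analysis if detected on at least half the dates
(configurable); vocal mammals are eligible alongside birds.

Guild PCA standardizes the dates × species table (so the decomposition is of
the correlation matrix), drops zero-variance species with a warning, and
fixes signs so each component's largest-magnitude loading is positive.
Components are correlated with environmental covariates to identify guild
drivers. Whether significance stars on such tests should be one- or
two-sided is a judgment call; two-sided is used because the sign of an
interspecific correlation is not predictable a priori.

## Diversity and design

Incidence is count > 0 per (location = site, occasion = date) sample;
mammals are excluded from richness by default (bird richness is the usual
reporting unit), with a flag to include them. Rarefaction uses the
log-gamma form of the binomial coefficients, exact to ~1e-12 against
brute-force subset enumeration for T ≤ 8. Chao2 uses the classic estimator
(bias-corrected form when Q₂ = 0) with the standard asymptotic variance.

The occasion-extension resamples whole observed occasion rows with
replacement within each location until the target (default 190) is reached,
keeping the observed rows. Resampling whole rows preserves within-occasion
species co-occurrence and per-species detection frequencies, and a species
never seen at a location can never appear in its extension — the key closure
property for design questions. The design surface draws, per replicate,
locations without replacement and then occasions without replacement within
each chosen location (a real design cannot revisit the same morning), counts
distinct species, and averages over replicates with a Monte-Carlo SE.

## Synthetic-data generator

Counts are generated **on the sqrt scale** and squared/rounded (floored at
zero), so the analysis-side square-root transform is exactly the right
normalization — this is the generative counterpart of the observation that
field count distributions are gamma-like and sqrt-normalize well. The
sqrt-scale mean combines: a per-site baseline drawn from a per-species gamma
rate distribution (or fixed for deterministic tests); a linear seasonal
trend; a latent guild day factor shared across sites; a site-level day
effect with exponential spatial covariance σ²·exp(−d/range); a regional
(all-site) day effect; and suppression proportional to the standardized
ambient covariate. The noise term deliberately does not distinguish
behavioral suppression from detection failure — annotation data cannot
separate them either. Default conditions mirror the emulated study design:
10 sites with pairwise separations spanning ~176–1729 m, 19 breeding-season
dates, occupancy zeroing species at unoccupied sites.

Weather is multivariate normal per date under a configurable correlation
target whose default encodes the empirically typical positively
intercorrelated wind-speed / dripping / ambient-sound block; precipitation is
zero-inflated by thresholding its latent draw (most mornings are dry) and
humidity clipped to [0, 100].

Soundscapes are Gaussian background noise of known σ plus Hann-enveloped
linear chirps ("songs", with the > 1-s inter-event pause that defines
distinct vocalization events enforced per species) and 20-ms broadband
"drips" at Poisson times. Ground truth (selection tables, latent effects) is
returned alongside every output, and everything is reproducible from a seed.

**What the generator does not emulate:** real song structure (events are
synthetic chirps), diel patterns within the 10-min window, observer error in
annotation, MP3 compression artifacts, and microphone directionality.
Passing tests therefore demonstrate that the estimators recover the
statistical structure they target — not that any particular field dataset
satisfies that structure.

## Problem sizes and validation batteries

Validation batteries are sized to make their statistical claims sharp while
staying cheap: permutation calibration uses 2000 null pairs × 500
permutations (rejection-rate SE ≈ 0.005 against a ± 0.02 band); ambient
recovery uses three σ values spanning 16-fold on 10-minute recordings;
correlogram recovery uses 50 seeded runs (a ≥ 90% ordering requirement has
binomial SE ≈ 4%); the design surface uses 200 replicates per cell with its
Monte-Carlo SE reported. The variance-components check standardizes each
simulated effect vector to exactly its target variance, so the generated
data carry exactly the nominal 0.85/0.04/0.11 shares and the check isolates
estimator error from draw-to-draw luck (with only 40 day effects, the
realized day-share of an unstandardized draw varies by ± 0.04 SD).

## Known limitations

* The MoM variance decomposition assumes a balanced (or nearly balanced)
  design; strongly unbalanced minute tables would need REML.
* The correlogram's spline is global; it cannot represent non-monotone
  synchrony structure finer than its df allow, and extrapolation beyond the
  observed distance range is not meaningful.
* Chao2's variance formula is asymptotic and unreliable at very small T.
* The pipeline runner is deliberately thin: it chains the library functions
  with seed-splitting and provenance stamping, not a workflow engine.
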
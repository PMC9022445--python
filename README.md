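# pamkit

Analysis toolkit for **passive acoustic monitoring (PAM)** annotation data.

Unattended recorders capture the dawn chorus at many sites simultaneously, and
annotation (human or automated) turns each recording into counts of
vocalizations per species. `pamkit` implements the analytical chain that turns
those counts — plus the raw audio, site metadata, and daily weather — into
community-level inference:

1. **Species lists and vocal variation** — per-species vocalization totals,
   dominance shares, snip extraction, duration and dominant-frequency
   summaries.
2. **Ambient sound pressure** — relative noise-floor estimation from
   uncalibrated audio: the RMS of a 1-s window is the standard deviation of
   its samples; a recording's ambient level is the mean over minutes of a low
   percentile (default 10th) of sliding-window log₁₀(RMS) values. A
   manual-style estimator (random vocalization-free seconds) is provided for
   cross-validation, plus a method-of-moments decomposition of ambient
   variance among days, locations, and minutes.
3. **Activity vs. environment** — counts are square-root transformed (field
   count distributions are gamma-like and sqrt-normalize well); daily rate
   series are correlated with weather covariates, with |r| significance
   thresholds from inverting the two-sided t test,
   r* = t*/√(t*² + n − 2).
4. **Habitat comparison** — fixed-effects ANOVA of stand-level daily rates on
   forest age, watershed, their interaction, and date.
5. **Spatial synchrony** — Pearson correlation of two sites' daily rates
   across dates, with SE = √((1 − r²)/(n − 2)); summarized either at two
   discrete scales (paired stands vs. watersheds) or as a **spline
   correlogram**: a cubic regression spline of all pairwise correlations
   against pair distance, with a site-level (cluster) bootstrap 95% envelope.
6. **Interspecific covariation** — date-randomization tests for correlated
   daily activity between species pairs (two-sided, add-one permutation p),
   and activity guilds from correlation-matrix PCA.
7. **Diversity and survey design** — sample-based rarefaction
   E[S_t] = S_obs − Σᵢ C(T − Qᵢ, t)/C(T, t), Chao2 richness estimation, and a
   resampling **design surface**: expected richness for every
   (locations × occasions) sampling budget, built from an occasion-extended
   incidence matrix.

A fully seeded synthetic-data generator (`pamkit.simulate`) emulates the
statistical structure these analyses assume — gamma-distributed call rates,
seasonal trends, spatially correlated day effects with exponential distance
decay, noise-suppressed detection, and soundscape audio with ground-truth
selection tables — so every estimator can be validated against known truth.

## Worked example

Ambient noise-floor recovery on a synthetic soundscape with a known
σ = 0.02 background, sparse songs, and drip transients
(`examples/02_ambient_sound.py`):

```
true noise floor  log10(sigma) = -1.699
automated quiet-percentile     = -1.701
manual vocal-free seconds      = -1.699 (3 snips)
```

Both estimators land within 0.002 log₁₀ units of the truth: the quiet
percentile is robust to sparse loud events, and the near-equality of the
manual and automated estimates is what justifies replacing manual review at
scale.

Survey-design optimization (`examples/07_diversity_design.py`) on a
10-site × 19-date synthetic community extended to 190 occasions per site:

```
Equal-budget frontier at 190 annotated recordings:
 n_locations  n_occasions  mean_richness   se
           1          190           8.21 0.08
           2           95           9.18 0.06
          10           19          10.00 0.00
```

At a fixed annotation budget, spreading effort across locations detects more
species than deep sampling of one location — the γ- vs β-diversity trade-off
that the design surface quantifies.

The other scripts in `examples/` cover species summaries, vocal traits,
environmental correlations and the habitat ANOVA, spline correlograms,
interspecific guilds, and the end-to-end pipeline. The pipeline is also
exposed as a thin CLI:

```
pamkit run --config run.yaml
```

All randomness derives from one master seed in the config, so reruns are
bit-for-bit reproducible.

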
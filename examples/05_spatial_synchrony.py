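"""Spatial synchrony: does a species' daily calling rise and fall together
at nearby recorders?

Simulates one species whose day effects decay exponentially with distance
(range 500 m) over the study-like 10-site layout, then fits a spline
correlogram with a site-level bootstrap envelope.  The estimate near 200 m
should clearly exceed that near 1500 m.  The two-scale summary (paired
stands vs. watersheds) is shown on constructed series.
"""

import numpy as np
import pandas as pd

import pamkit as pk
from pamkit.activity import daily_means, rate_matrix, transform_counts
from pamkit.simulate import SpeciesSpec

spec = pk.CommunitySpec(species=[SpeciesSpec("FOC", fixed_baseline=25.0)],
                        day_effect_sd=0.7, spatial_range_m=500.0,
                        regional_sd=0.0, guild_sd=0.0, residual_sd=0.5)
sim = pk.simulate_counts(spec, seed=11)
series = rate_matrix(
    daily_means(transform_counts(sim.count_matrix), sim.recordings), "FOC")
distances = pk.pairwise_distances(sim.sites)

cg = pk.spline_correlogram(series, distances, n_boot=300, seed=12)
for d in (200, 600, 1000, 1500):
    est = np.interp(d, cg.grid, cg.estimate)
    lo = np.interp(d, cg.grid, cg.lower)
    hi = np.interp(d, cg.grid, cg.upper)
    print(f"  r({d:4d} m) = {est:+.2f}  [{lo:+.2f}, {hi:+.2f}]")
print(f"x-intercept: {cg.x_intercept() and round(cg.x_intercept())} m "
      "(distance where synchrony first crosses zero)")
print(f"Based on {len(cg.pairs)} site pairs over {series.shape[0]} dates; "
      "the decline with distance recovers the generator's 500 m range.")

# two-scale design: paired stands (~150 m) vs watersheds (~16 km)
rng = np.random.default_rng(13)
common = rng.normal(0, 0.6, 20)
stands = pd.DataFrame({
    f"{ws}/{age}": common + rng.normal(0, 0.5, 20)
    for ws in ("HB", "JB") for age in ("mature", "mid")
})
ts = pk.two_scale_correlation(stands)
print("\nTwo-scale summary (regional day effect shared by all stands):")
for ws, (r, se) in ts.within.items():
    print(f"  within {ws} (~150 m):  r = {r:+.2f} +/- {se:.2f}")
print(f"  between watersheds (~16 km): r = {ts.between[0]:+.2f} "
      f"+/- {ts.between[1]:.2f}")
print("Similar r at both scales indicates a regional (weather-like) driver.")
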
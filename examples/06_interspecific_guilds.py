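"""Interspecific correlations and activity guilds.

The default community has a seasonal guild (vocalization declines over the
season) and a noise-sensitive guild (vocalization drops on loud mornings).
Date-randomization tests flag species pairs whose daily rates covary more
than chance; PCA of the standardized dates x species table recovers the
guilds, and correlating PC scores with covariates identifies their drivers.
"""

import pamkit as pk
from pamkit.activity import species_by_date, transform_counts
from pamkit.simulate import default_dates

dates = default_dates(19)
weather = pk.simulate_weather(dates, seed=14)
sim = pk.simulate_counts(pk.CommunitySpec(), seed=15,
                         ambient=weather["ambient_sound"])
rates = species_by_date(transform_counts(sim.count_matrix), sim.recordings)
common = pk.interspecific.select_common_species(rates)
rates = rates[common]

corr, tally = pk.species_corr_matrix(rates)
print(f"{tally['n_pairs']} species pairs: {tally['n_positive']} positive, "
      f"{tally['n_negative']} negative correlations")

tests = pk.all_pair_tests(rates, n_perm=1000, seed=16)
sig = tests[tests["stars"] != ""].sort_values("p")
print(f"\n{len(sig)} pairs significant by randomization test (top rows):")
print(sig.head(6).round(3).to_string(index=False))

guilds = pk.pca_activity(rates)
print(f"\nPC1/PC2 explain {guilds.percent_variance[0]:.0f}% / "
      f"{guilds.percent_variance[1]:.0f}% of day-to-day variation")
print(guilds.loadings[["PC1", "PC2"]].round(2).to_string())

pc_env = pk.pc_env_correlation(guilds, weather[["ambient_sound"]])
print("\nPC correlations with ambient sound (components whose species are")
print("suppressed by noise correlate negatively):")
print(pc_env[pc_env["component"].isin(["PC1", "PC2"])]
      .round(3).to_string(index=False))
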
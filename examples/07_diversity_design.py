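"""Rarefaction, richness estimation, and sampling-design optimization.

Binarizes the synthetic counts into a (location, occasion) incidence matrix,
compares the single-location and pooled species accumulation curves
(alpha/beta/gamma-diversity), estimates total richness with Chao2, and builds
the design surface: expected richness for every combination of number of
locations and number of occasions, from an occasion-extended dataset.
"""

import pamkit as pk

sim = pk.simulate_counts(pk.CommunitySpec(), seed=17)
inc = pk.incidence_from_counts(sim.count_matrix, sim.recordings)
print(f"incidence matrix: T = {inc.T} samples, S_obs = {inc.s_obs} species")

curves = pk.accumulation_curves(inc)
for t in (1, 5, 19):
    row = curves.loc[t]
    print(f"  t = {t:3d}: single-location avg = "
          f"{row['single_location_mean']:.1f}, pooled = {row['pooled']:.1f}")
print("The pooled curve exceeding the single-location curve is beta-diversity:")
print("different sites contribute different species.")

chao = pk.chao2(inc)
print(f"\nChao2 richness estimate: {chao.estimate:.1f} +/- {chao.se:.1f} "
      f"(S_obs = {chao.s_obs}, Q1 = {chao.q1}, Q2 = {chao.q2})")

ext = pk.extend_occasions(inc, target_occasions=190, seed=18)
surface = pk.design_surface(ext, n_rep=200, seed=19,
                            locations_grid=[1, 2, 5, 10],
                            occasions_grid=[1, 5, 19, 95, 190])
print("\nExpected species richness by sampling design (rows = locations):")
print(surface.surface.pivot(index="n_locations", columns="n_occasions",
                            values="mean_richness").round(1).to_string())
print("\nEqual-budget frontier at 190 annotated recordings:")
print(surface.frontier(190).round(2).to_string(index=False))
print("Reading along the frontier shows whether adding locations or adding")
print("occasions buys more species for the same annotation effort.")
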
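"""Species lists and dominance: who vocalizes, and how concentrated is the
soundscape?

Builds a synthetic annotation dataset (10 recorders x 19 mornings), then
summarizes per-species vocalization totals and computes dominance shares —
the percentage of all vocalizations contributed by the most vocal species.
The same functions applied to the published Hubbard Brook totals reproduce
the reported 98.2% (2016 top-10) and 50.2% (Red-eyed Vireo, 2018) shares.
"""

import pamkit as pk
from pamkit.published import totals_as_count_matrix

sim = pk.simulate_counts(pk.CommunitySpec(), seed=1)
summary = pk.summarize_species(sim.count_matrix, sim.recordings, group_by="year")
print("Synthetic community, species sorted by total vocalizations:")
print(summary[["total"]].to_string())

share = pk.dominance_share(sim.count_matrix, top_k=3)
print(f"\nTop-3 species contribute {share}% of all synthetic vocalizations.")

print("\nPublished Hubbard Brook totals:")
print("  2016 top-10 share:",
      pk.dominance_share(totals_as_count_matrix(2016), top_k=10), "%")
print("  2018 Red-eyed Vireo share (mammals excluded):",
      pk.dominance_share(totals_as_count_matrix(2018), species="REVI",
                         exclude_taxa=("mammal",)), "%")
print("A high share means a few species dominate the acoustic record.")
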
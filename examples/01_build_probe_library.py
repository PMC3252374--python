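"""Build the probe universe of a custom protein binding microarray.

Constructs the four probe classes — consensus-derived k-mers ranked by
genome frequency, DR1/DR2 window-permutation probes, and random negative
controls — for a toy consensus and genome, and prints the category counts.
"""

from alucensus import (DR1_CONSENSUS, DR2_CONSENSUS, LibraryParams,
                       SimulationConfig, assemble_library,
                       generate_window_permutation_probes, plant_copies,
                       random_background, simulate_consensus_set)

dr1 = generate_window_permutation_probes(DR1_CONSENSUS, window=3)
dr2 = generate_window_permutation_probes(DR2_CONSENSUS, window=3)
print(f"DR1 consensus {DR1_CONSENSUS} ({len(DR1_CONSENSUS)} nt), window 3 "
      f"-> {len(dr1)} probes  (11 windows x 64 variants)")
print(f"DR2 consensus {DR2_CONSENSUS} ({len(DR2_CONSENSUS)} nt), window 3 "
      f"-> {len(dr2)} probes  (12 windows x 64 variants)")

cfg = SimulationConfig(seed=0, genome_length=60_000, n_copies_per_consensus=15)
consensus = simulate_consensus_set(cfg)
genome, _, _ = plant_copies(random_background(cfg), consensus, cfg)
library = assemble_library(consensus, {"chrS1": genome},
                           params=LibraryParams(top_n_frequency=100))

print("\nassembled library category counts:")
for category, count in sorted(library.category_counts().items()):
    print(f"  {category:20s} {count}")
print(f"raw probes: {library.raw_count}, distinct sequences: "
      f"{library.unique_sequence_count}")
print("(permutation probes repeat the consensus once per window, so the two"
      " totals differ)")
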
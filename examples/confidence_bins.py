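"""Relate confidence scores to an independent per-link signal by binning.

Ranks the interactions of a planted-module network by increasing
confidence, splits them into five equal bins, and prints the fraction
of planted (within-module) links per bin.  If the scores track
interaction veracity, that fraction rises from the lowest- to the
highest-confidence bin — the synthetic analogue of binning external
annotation-similarity values.
"""

from cappic import (
    PlantedModuleSpec,
    bin_scores,
    cappic,
    generate_planted_network,
)

spec = PlantedModuleSpec(seed=1)
network, truth = generate_planted_network(spec)
result = cappic(network, fraction=0.03, seed=1)
print(f"tuned inflation: {result.inflation}")

values = {e: (1.0 if truth[e[0]] == truth[e[1]] else 0.0)
          for e in network.edges}
print("bin (low->high confidence)  fraction of planted links")
for idx, mean in bin_scores(result.scores, values, n_bins=5):
    print(f"bin {idx + 1}                       {mean:.3f}")
print()
print("Cross-module noise links concentrate in the lowest-confidence")
print("bin; the upper bins are almost pure within-module interactions.")
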
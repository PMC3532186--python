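"""Generate a planted-module network and characterise its topology.

The generator emulates the modular architecture of interactome maps:
dense within-module wiring (p_in) against sparse cross-module noise
(p_out), with known ground-truth module labels.  The two printed
descriptors are the ones used to characterise real interactomes: the
clustering coefficient and the fraction of links in triangles (the
subset a common-neighbour method can score at all).
"""

from cappic import (
    PlantedModuleSpec,
    clustering_coefficient,
    fraction_links_in_triangles,
    generate_planted_network,
    within_module_edges,
)

spec = PlantedModuleSpec(n_modules=6, module_size=20, p_in=0.3,
                         p_out=0.005, evidence_high_fraction=0.2, seed=1)
network, truth = generate_planted_network(spec)

wm = within_module_edges(network, truth)
print(f"proteins:             {network.n_nodes}")
print(f"interactions:         {network.n_edges}")
print(f"within-module links:  {len(wm)} "
      f"({100 * len(wm) / network.n_edges:.0f}%)")
print(f"clustering coeff.:    {clustering_coefficient(network):.3f}")
print(f"links in triangles:   "
      f"{fraction_links_in_triangles(network):.3f}")
print()
print("Real physical interactomes span clustering coefficients of")
print("roughly 0.06-0.72; the defaults land in the mid range where")
print("modularity is pronounced enough for topology-only scoring.")
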
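"""Neighbour-joining tree with bootstrap supports on a small panel subset.

Builds a p-distance NJ tree for three reference sequences from each of four
species and attaches column-resampling bootstrap supports (percent of
replicate trees containing each internal split).
"""

from scombkey import Alignment, SimConfig, bootstrap_supports, generate_reference_panel, to_newick

panel = generate_reference_panel(SimConfig(seed=1))
keep = [
    rid
    for sp in ("Thunnus thynnus", "Thunnus alalunga", "Auxis rochei", "Sarda sarda")
    for rid in panel.taxonomy.ids_of_species(sp)[:3]
]
subset = panel.alignment.subset(keep)

tree = bootstrap_supports(subset, model="p-distance", n_reps=200, seed=7)
print(to_newick(tree))
print()
for block, support in sorted(tree.supports().items(), key=lambda kv: -kv[1]):
    print(f"support {support:5.1f}%  {{{', '.join(sorted(block))}}}")
print()
print("Species clusters get near-unanimous support; the supports annotate the")
print("original tree's splits, exactly as a published phenogram is labelled.")
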
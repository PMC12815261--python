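"""Lay out collapsed cells as a periodic table and render it to SVG.

Phylogenetic (patristic) and trait dissimilarities between cells are
blended, embedded in 2-D, snapped to a near-square grid by optimal
assignment, and grouped into proximity clusters.
"""

from pathlib import Path

from ptbt import (LayoutParams, SelectionParams, ShiftSpec, collapse_tree,
                  layout_cells, patristic_matrix, plant_shift_traits,
                  render_table, select_variance_nodes, summarize_cells,
                  transform, yule_tree)
from ptbt.layout import default_style
from ptbt.synth import binarize_latent, bm_root_to_leaf_sd, eligible_shift_nodes

tree = yule_tree(300, seed=21)
delta = 10 * bm_root_to_leaf_sd(tree)
nodes = eligible_shift_nodes(tree, min_clade=8)[:4]
traits = plant_shift_traits(
    tree, [ShiftSpec(nid, j, delta) for j, nid in enumerate(nodes)],
    n_traits=6, seed=22)
traits = binarize_latent(traits, 0.8, columns=["trait5", "trait6"])

selection = select_variance_nodes(transform(tree, traits), SelectionParams(0.6))
cells = collapse_tree(tree, selection.union)
scaled = summarize_cells(cells, traits, scale_mode="zscore")
raw = summarize_cells(cells, traits, scale_mode="none")
distances = patristic_matrix(cells.tree)

params = LayoutParams(alpha=0.5, perplexity=10, iterations=1000,
                      k_clusters=5, seed=23)
layout = layout_cells(distances, scaled, params)

out = Path("scratch_table.svg")
out.write_text(render_table(raw, layout,
                            default_style(traits.trait_names, traits.kinds)))

print(f"{len(cells.cells)} cells on a "
      f"{layout.grid_shape[0]}x{layout.grid_shape[1]} grid -> {out}")
print(layout.to_frame().head(8).to_string(index=False))
# Nearby grid cells are similar phylogenetically and/or in trait space;
# the cluster column gives the k-means reading-order region label.
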
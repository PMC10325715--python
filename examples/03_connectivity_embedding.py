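"""Embed neurons by shared synaptic partners.

For adjacency matrix A, A A' counts shared outputs and A' A shared inputs
for every neuron pair; the spectral embedding of their sum places neurons
with similar connectivity close together, and the type-level spring layout
plus per-neuron offsets gives display coordinates.
"""

import numpy as np

import vlconn as vl

table = vl.generate_connectome(vl.GenerationConfig(seed=1))
w = vl.build_wiring_diagram(table)

sims = vl.compute_similarities(w)
emb = vl.embed_neurons(sims, k=100)
print(f"embedded {len(emb)} neurons into {emb.shape[1] - 1} dimensions")

# neurons of the same type share partners, so same-type pairs should sit
# closer than different-type pairs in the leading dimensions
coords = emb[["dim1", "dim2"]].to_numpy(dtype=float)
types = table.types().loc[emb["neuron_id"]].to_numpy()
same = [np.linalg.norm(coords[i] - coords[j])
        for i in range(0, 300, 7) for j in range(i + 1, 300, 11) if types[i] == types[j]]
diff = [np.linalg.norm(coords[i] - coords[j])
        for i in range(0, 300, 7) for j in range(i + 1, 300, 11) if types[i] != types[j]]
print(f"median same-type distance: {np.median(same):.1f}, "
      f"different-type: {np.median(diff):.1f}")

tg = vl.build_type_graph(w, min_synapses=10)
print(f"type-level edges (>10 synapses): {sorted(tg.edge_set())}")
pos = vl.layout_type_graph(tg, seed=0)
display = vl.combine_layouts(pos, emb, table.types(), scale=0.1)
print(display.head().to_string(index=False))
# Each neuron is anchored at its type's spring-layout position and shifted
# by its own connectivity embedding - the combined circuit map.
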
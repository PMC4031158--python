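"""Embed a small metabolic pathway on a compact 2D lattice grid.

Builds a 9-reaction chain (each reaction's product feeds the next), asks
for the optimal grid arrangement, and draws it.  The total Manhattan edge
length equals the number of edges (8), meaning every pair of adjacent
reactions sits on neighboring cells — the best any embedding can do.
"""

import pathwave as pw

edges = "\n".join(f"R{i}\tR{i + 1}" for i in range(1, 9))
net = pw.read_edge_list_network(edges, pathway_id="chain9")
print(f"network: {net.n_nodes} reactions, {net.n_edges} edges")

emb = pw.embed_exact(net)  # 3x3 grid chosen automatically
print(f"grid: {emb.grid.rows}x{emb.grid.cols}, "
      f"total Manhattan edge length: {emb.total_length} "
      f"(lower bound = |E| = {net.n_edges}), proven optimal: {emb.optimal}")

cells = {rc: v for v, rc in emb.placement.items()}
for r in range(emb.grid.rows):
    print("  " + " ".join(f"{cells.get((r, c), '..'):>3s}" for c in range(emb.grid.cols)))
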
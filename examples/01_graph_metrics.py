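"""Weighted graph measures on a small hand-built connectome.

Builds a 4-region network with streamline-count edges, applies the
count threshold, and prints the global measures and the per-node
efficiency profile with the hub rule.
"""

import numpy as np

from pediconn import (
    Connectome,
    NodeTable,
    apply_streamline_threshold,
    compute_global_metrics,
    compute_nodal_metrics,
    identify_hubs,
)

table = NodeTable(
    labels=("frontal", "parietal", "temporal", "occipital"),
    abbreviations=("L.F", "L.P", "R.T", "R.O"),
    hemispheres=("L", "L", "R", "R"),
)

# streamline counts; the 3-count edge is below the threshold of 5
w = np.array(
    [
        [0, 40, 12, 3],
        [40, 0, 25, 8],
        [12, 25, 0, 15],
        [3, 8, 15, 0],
    ]
)
conn = apply_streamline_threshold(
    Connectome(weights=w, node_table=table, subject_id="demo"), min_count=5
)
print(f"edges surviving the count threshold: {conn.n_edges} of 6")

gm = compute_global_metrics(conn)
print(f"strength        = {gm.strength:.3f}   (mean summed counts per node)")
print(f"global eff  Eg  = {gm.eg:.3f}   (mean inverse shortest path, length = 1/count)")
print(f"local eff  Eloc = {gm.eloc:.3f}   (mean efficiency of neighbour subgraphs)")
print(f"path length Lp  = {gm.lp:.4f}  (mean shortest-path length)")

nm = compute_nodal_metrics(conn)
hubs = identify_hubs(nm)
for i, abbr in enumerate(table.abbreviations):
    star = " <- hub" if i in hubs.hubs else ""
    print(f"E_nodal[{abbr}] = {nm.e_nodal[i]:.3f}{star}")
print(f"hub threshold (mean + 1 SD of E_nodal): {hubs.threshold:.3f}")
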
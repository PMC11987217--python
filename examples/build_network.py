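"""Build a five-layer heterogeneous network from TSV edge lists and query it.

Writes a tiny set of edge-list files (the same format real domain/protein/
disease exports would use), loads them with a confidence threshold on the
protein-protein layer, and prints the layer shapes and a transpose identity.
"""

import tempfile
from pathlib import Path

from hetpath import (
    DISEASE,
    DOMAIN,
    PROTEIN,
    build_network,
    load_edge_table,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "dp.tsv").write_text("d1\tp1\nd1\tp2\nd2\tp2\n")
    (tmp / "pp.tsv").write_text("# src\ttgt\tcombined_score\np1\tp2\t900\np2\tp3\t250\n")
    (tmp / "ps.tsv").write_text("p1\ts1\np2\ts2\n")
    (tmp / "ss.tsv").write_text("s1\ts2\n")
    (tmp / "ds.tsv").write_text("d1\ts1\n")

    tables = [
        load_edge_table(tmp / "dp.tsv", DOMAIN, PROTEIN),
        # keep only interactions with confidence >= 400, as in curated PPI sets
        load_edge_table(tmp / "pp.tsv", PROTEIN, PROTEIN, min_weight=400),
        load_edge_table(tmp / "ps.tsv", PROTEIN, DISEASE),
        load_edge_table(tmp / "ss.tsv", DISEASE, DISEASE),
        load_edge_table(tmp / "ds.tsv", DOMAIN, DISEASE),
    ]
    net = build_network(tables)

print("node counts:", {t: net.n_nodes(t) for t in (DOMAIN, PROTEIN, DISEASE)})
for key, mat in net.adj.items():
    print(f"  {key[0]:>7s} - {key[1]:<7s} shape {mat.shape}  edges {mat.nnz}")

# reversed orientation is the transpose of the stored layer
pd_mat = net.adjacency(PROTEIN, DOMAIN)
dp_mat = net.adjacency(DOMAIN, PROTEIN)
print("protein->domain equals transpose of domain->protein:",
      (pd_mat != dp_mat.T).nnz == 0)
print("p2-p3 was dropped by the confidence threshold:",
      "p3" not in net.indices[PROTEIN])
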
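"""Assemble and export the interactor neighbourhood of a target gene.

Loads a synthetic interaction table, expands a two-layer breadth-first
neighbourhood around the best-connected gene, and writes SIF + GraphML.
"""

import tempfile
from pathlib import Path

from cismotif.fixtures import FixtureSpec, generate_fixture
from cismotif.network import export_graphml, export_sif, load_interactions, neighborhood

fx = generate_fixture(FixtureSpec(seed=4, n_genes=30, n_planted_sites=5,
                                  n_interactions=45))
outdir = Path(tempfile.mkdtemp())
paths = fx.write(outdir)

store = load_interactions(paths["interactions"])
root = max(store.graph.nodes, key=lambda n: (store.graph.degree(n), n))
print(f"{len(store)} interactions loaded; root = {root} "
      f"(degree {store.graph.degree(root)})")

nbhd = neighborhood(store, root, depth=2)
for depth, layer in nbhd.layers:
    print(f"depth {depth}: {len(layer)} edges")
    for a, b, data in layer[:5]:
        method = f" [{data['methods']}]" if data["methods"] else ""
        print(f"  {a} -- {b}  ({data['evidence']}{method})")

bio = neighborhood(store, root, depth=2, evidence_filter="biochemical")
print(f"biochemical-only edges: {len(bio.edges)} of {len(nbhd.edges)}")

export_sif(nbhd, outdir / "network.sif")
export_graphml(nbhd, outdir / "network.graphml")
print(f"wrote {outdir / 'network.sif'} and {outdir / 'network.graphml'}")
# Depth-1 edges touch the root directly; depth-2 edges add the interactors'
# own partners — the candidate pathway context of the target gene.
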
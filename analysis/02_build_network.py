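#!/usr/bin/env python
"""Build the phenotype network from the simulated catalog.

Composes the trait→pathway map, builds the bipartite trait-pathway
graph, projects it onto the phenotype side with shared-pathway-count
weights, removes isolates, and records the unfiltered network and its
degree statistics under results/network/.
"""

import json
from pathlib import Path

from phenonet.associations import (build_trait_pathway_map, read_gene_pathways,
                                   read_trait_genes)
from phenonet.netbuild import (build_bipartite, project, remove_isolates,
                               summarize, write_net)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tg = read_trait_genes(ROOT / "catalog" / "trait_genes.tsv")
    gp = read_gene_pathways(ROOT / "catalog" / "gene_pathways.tsv")
    m = build_trait_pathway_map(tg, gp)
    bn = build_bipartite(m)
    net = remove_isolates(project(bn, "trait"))
    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)
    write_net(net, out / "unfiltered.tsv", "tsv")
    write_net(net, out / "unfiltered.graphml", "graphml")
    s = summarize(net)
    (out / "summary.json").write_text(json.dumps(s.as_dict(), indent=2) + "\n")
    print(f"bipartite: {bn.number_of_nodes()} nodes, {bn.number_of_edges()} edges")
    print(f"projection: {s.n_nodes} phenotypes, {s.n_edges} edges, "
          f"mean degree {s.mean_degree:.1f}, CC {s.avg_clustering:.3f}, "
          f"APL {s.avg_path_length:.2f}")
    print(f"{len(m.pathwayless_traits)} traits had no pathway annotation; "
          f"written to {out}")


if __name__ == "__main__":
    main()
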
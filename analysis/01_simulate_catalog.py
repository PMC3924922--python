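#!/usr/bin/env python
"""Generate the synthetic association catalog used by the later steps.

Draws the default heavy-tailed catalog (200 traits, 600 genes, 300
pathways, zeta exponent 2.0, one hub trait) and writes it under
results/catalog/ in the same TSV dialect the parsers read.
"""

from pathlib import Path

from phenonet.synthetic import SynthConfig, generate_catalog

OUT = Path(__file__).resolve().parent.parent / "results" / "catalog"


def main() -> None:
    cfg = SynthConfig()
    tg, gp = generate_catalog(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    tg.write_tsv(OUT / "trait_genes.tsv")
    gp.write_tsv(OUT / "gene_pathways.tsv")
    counts = {}
    for t, _ in tg.rows:
        counts[t] = counts.get(t, 0) + 1
    hub = max(counts, key=counts.get)
    print(f"catalog: {len(tg.rows)} trait-gene rows over {len(counts)} traits, "
          f"{len(gp.rows)} gene-pathway rows")
    print(f"hub trait {hub} carries {counts[hub]} genes "
          f"(median {sorted(counts.values())[len(counts) // 2]})")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
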
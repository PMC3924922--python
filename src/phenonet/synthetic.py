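"""Synthetic association catalogs and worked-example fixtures.

Real trait-gene catalogs and pathway databases are moving targets:
snapshots go stale and cannot be redistributed.  Two substitutes make
the pipeline testable offline:

* :func:`generate_catalog` draws a synthetic trait-gene / gene-pathway
  catalog whose statistical shape matches what phenotype-pathway data
  looks like in the wild — heavy-tailed (zeta-distributed) gene counts
  per trait and pathway counts per gene, a single dominant hub trait
  (the "height" phenomenon: one trait measured in nearly every study),
  preferentially popular pathways, and a sprinkle of genes with no
  pathway annotation so isolate handling is exercised.

* :func:`load_fixture` returns small hand-encoded catalogs reproducing
  published worked examples of phenotype pairs: ``table2`` (HDL
  cholesterol / Alzheimer's disease: 4 shared genes, 6 shared
  pathways), ``table3`` (iron status biomarkers / cognitive
  performance: no shared genes, 5 shared pathways), and ``table4``
  (von Willebrand factor / hippocampal atrophy / atrial fibrillation,
  pairwise linked by the single aggregate Metabolic pathway).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .associations import (GenePathwayTable, TraitGeneTable, read_gene_pathways,
                           read_trait_genes)


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic catalog generator.

    ``genes_per_trait_exponent`` / ``pathways_per_gene_exponent`` are
    the exponents of truncated zeta distributions (support 1..cap);
    values near 2 give the strong right skew typical of association
    catalogs.  When ``hub_trait`` is set, the first trait receives
    ``hub_multiplier`` × the median gene count, creating one dominant
    hub.  ``unannotated_gene_frac`` of genes carry no pathway
    annotation at all.  ``genes_per_trait_fixed`` /
    ``pathways_per_gene_fixed`` replace the corresponding zeta draw
    with a constant count (degenerate, handy for exact-count checks).
    """

    n_traits: int = 200
    n_genes: int = 600
    n_pathways: int = 300
    genes_per_trait_exponent: float = 2.0
    pathways_per_gene_exponent: float = 2.0
    genes_per_trait_fixed: int | None = None
    pathways_per_gene_fixed: int | None = None
    hub_trait: bool = True
    hub_multiplier: float = 25.0
    unannotated_gene_frac: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_traits, self.n_genes, self.n_pathways) < 1:
            raise SynthError("all entity counts must be >= 1")
        if (self.genes_per_trait_exponent <= 1
                or self.pathways_per_gene_exponent <= 1):
            raise SynthError("zeta exponents must be > 1")
        if not 0 <= self.unannotated_gene_frac < 1:
            raise SynthError("unannotated_gene_frac must be in [0, 1)")
        if self.hub_multiplier < 1:
            raise SynthError("hub_multiplier must be >= 1")
        if (self.genes_per_trait_fixed is not None
                and not 1 <= self.genes_per_trait_fixed <= self.n_genes):
            raise SynthError("fixed genes-per-trait count outside 1..n_genes")
        if (self.pathways_per_gene_fixed is not None
                and not 0 <= self.pathways_per_gene_fixed <= self.n_pathways):
            raise SynthError("fixed pathways-per-gene count outside 0..n_pathways")


def _truncated_zipf(rng: np.random.Generator, a: float, cap: int,
                    size: int) -> np.ndarray:
    """Zeta-distributed counts on 1..cap by rejection of out-of-range draws."""
    if cap < 1:
        raise SynthError("truncation cap below distribution support")
    out = rng.zipf(a, size=size)
    while (bad := out > cap).any():
        out[bad] = rng.zipf(a, size=int(bad.sum()))
    return out


def generate_catalog(cfg: SynthConfig = SynthConfig()
                     ) -> tuple[TraitGeneTable, GenePathwayTable]:
    """Draw a (trait-gene, gene-pathway) catalog pair from the config.

    Identical config (including seed) gives identical tables.  Pathways
    are assigned to genes by popularity-weighted sampling without
    replacement, so a few pathways accumulate many genes — the
    heterogeneity that separates a local significance filter from a
    global weight cutoff downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    traits = [f"T{i:04d}" for i in range(cfg.n_traits)]
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    pathways = [f"PW{i:04d}" for i in range(cfg.n_pathways)]

    if cfg.genes_per_trait_fixed is not None:
        gpt = np.full(cfg.n_traits, cfg.genes_per_trait_fixed)
    else:
        gpt = _truncated_zipf(rng, cfg.genes_per_trait_exponent, cfg.n_genes,
                              cfg.n_traits)
    if cfg.hub_trait:
        hub_count = int(round(cfg.hub_multiplier * float(np.median(gpt))))
        gpt[0] = min(max(hub_count, 1), cfg.n_genes)

    tg_rows: list[tuple[str, str]] = []
    for t, count in zip(traits, gpt):
        chosen = rng.choice(cfg.n_genes, size=int(count), replace=False)
        tg_rows.extend((t, genes[g]) for g in sorted(chosen))

    if cfg.pathways_per_gene_fixed is not None:
        ppg = np.full(cfg.n_genes, cfg.pathways_per_gene_fixed)
    else:
        ppg = _truncated_zipf(rng, cfg.pathways_per_gene_exponent,
                              cfg.n_pathways, cfg.n_genes)
    if cfg.unannotated_gene_frac > 0:
        n_un = int(round(cfg.unannotated_gene_frac * cfg.n_genes))
        unannotated = rng.choice(cfg.n_genes, size=n_un, replace=False)
        ppg[unannotated] = 0

    popularity = np.ones(cfg.n_pathways)
    gp_rows: list[tuple[str, str]] = []
    for g, count in zip(genes, ppg):
        chosen: list[int] = []
        weights = popularity.copy()
        for _ in range(int(count)):
            probs = weights / weights.sum()
            pick = int(rng.choice(cfg.n_pathways, p=probs))
            chosen.append(pick)
            weights[pick] = 0.0  # without replacement
        for pw in sorted(chosen):
            popularity[pw] += 1.0
            gp_rows.append((g, pathways[pw]))
    if not gp_rows:
        raise SynthError("generated catalog has no gene-pathway annotation")

    return (TraitGeneTable(rows=tuple(tg_rows)),
            GenePathwayTable(rows=tuple(gp_rows)))


FIXTURE_NAMES = ("table2", "table3", "table4")


def load_fixture(name: str) -> tuple[TraitGeneTable, GenePathwayTable]:
    """Load one of the packaged worked-example catalogs.

    The pathway identifiers carry their bracketed numeric KEGG-style ids
    (e.g. ``"[1100] Metabolic pathways"``).  For ``table3`` and
    ``table4`` the published sources list per-trait pathways but not the
    underlying gene lists, so each trait is wired through one synthetic
    proxy gene (``IB_LOCUS`` etc.); this preserves the asserted facts —
    the pathway overlaps and the absence of any shared gene — exactly.

    Note on ``table3``: the published per-trait pathway columns also
    contain "[4060] Cytokine-cytokine receptor interaction" on *both*
    sides, which contradicts the same source's stated result of five
    shared pathways; the fixture resolves the conflict in favour of the
    stated result by carrying the cognitive-performance column without
    that entry (56 pathways instead of 57).
    """
    if name not in FIXTURE_NAMES:
        raise SynthError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    pkg = resources.files(__package__) / "fixtures"
    with resources.as_file(pkg / f"{name}_trait_genes.tsv") as p:
        tg = read_trait_genes(p, dialect="simple")
    with resources.as_file(pkg / f"{name}_gene_pathways.tsv") as p:
        gp = read_gene_pathways(p, fmt="tsv")
    return tg, gp
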
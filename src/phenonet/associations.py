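"""Parsing of trait-gene and gene-pathway association tables.

A pathway-based phenotype network starts from two association tables:
phenotypic traits linked to their GWAS-mapped genes, and genes linked to
the curated biological pathways they participate in.  Composing the two
gives each trait a *pathway set* — the union of the pathway annotations
of its genes — which is the raw material for the bipartite network.

Two input dialects are supported for trait-gene data: a plain two-column
TSV, and a GWAS-catalog-style TSV in which a single mapped-gene cell may
name several genes ("APOE; APOC1", or "GENE1 - GENE2" for intergenic
hits).  Gene-pathway data may come as a two-column TSV or as a GMT
gene-set file (one pathway per line: name, description, then genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: tokens in catalog mapped-gene cells that do not name a gene
NON_GENE_TOKENS = frozenset({"NR", "intergenic"})

#: default column names for the catalog dialect
CATALOG_TRAIT_COL = "DISEASE/TRAIT"
CATALOG_GENE_COL = "MAPPED_GENE"


class AssociationError(ValueError):
    """Raised when an association file cannot yield a usable table."""


def _dedup(pairs: Iterable[tuple[str, str]]) -> tuple[tuple[str, str], ...]:
    """Deduplicate while preserving first-appearance order."""
    return tuple(dict.fromkeys(pairs))


@dataclass(frozen=True)
class TraitGeneTable:
    """Deduplicated (trait_id, gene_id) association rows.

    Identifiers are whitespace-trimmed but otherwise taken verbatim;
    matching downstream is exact-string, so distinct spellings remain
    distinct traits.
    """

    rows: tuple[tuple[str, str], ...]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise AssociationError("duplicate (trait, gene) rows")
        for t, g in self.rows:
            if not t or not g:
                raise AssociationError(f"empty identifier in row {(t, g)!r}")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t for t, _ in self.rows))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for _, g in self.rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["trait_id", "gene_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class GenePathwayTable:
    """Deduplicated (gene_id, pathway_id) annotation rows."""

    rows: tuple[tuple[str, str], ...]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise AssociationError("duplicate (gene, pathway) rows")
        for g, p in self.rows:
            if not g or not p:
                raise AssociationError(f"empty identifier in row {(g, p)!r}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for g, _ in self.rows))

    @property
    def pathways(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(p for _, p in self.rows))

    def pathways_of(self) -> dict[str, frozenset[str]]:
        """Map each gene to its set of annotated pathways."""
        out: dict[str, set[str]] = {}
        for g, p in self.rows:
            out.setdefault(g, set()).add(p)
        return {g: frozenset(s) for g, s in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["gene_id", "pathway_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class TraitPathwayMap:
    """Per-trait gene sets and derived pathway sets.

    ``pathway_sets[t]`` is the union of the pathway annotations of the
    genes in ``gene_sets[t]``.  Traits whose genes carry no pathway
    annotation at all end up with an empty pathway set; they are kept
    and listed in :attr:`pathwayless_traits` rather than dropped, so the
    caller decides their fate (the bipartite builder excludes them).
    """

    gene_sets: Mapping[str, frozenset[str]]
    pathway_sets: Mapping[str, frozenset[str]]

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.gene_sets)

    @property
    def pathwayless_traits(self) -> tuple[str, ...]:
        return tuple(t for t, pws in self.pathway_sets.items() if not pws)

    def write_tsv_pair(self, trait_gene_path: str | Path,
                       trait_pathway_path: str | Path) -> None:
        tg = [(t, g) for t, gs in self.gene_sets.items() for g in sorted(gs)]
        tp = [(t, p) for t, ps in self.pathway_sets.items() for p in sorted(ps)]
        pd.DataFrame(tg).to_csv(trait_gene_path, sep="\t", index=False, header=False)
        pd.DataFrame(tp).to_csv(trait_pathway_path, sep="\t", index=False, header=False)


def split_gene_cell(cell: str) -> list[str]:
    """Split a catalog mapped-gene cell into individual gene symbols.

    Cells may list several genes separated by ";" or, for intergenic
    hits, by " - ".  Placeholder tokens ("NR", "intergenic") and empty
    fragments are discarded.
    """
    parts: list[str] = []
    for semi in cell.split(";"):
        parts.extend(semi.split(" - "))
    genes = [p.strip() for p in parts]
    return [g for g in genes if g and g not in NON_GENE_TOKENS]


def read_trait_genes(path: str | Path, dialect: str = "simple", *,
                     header: bool | None = None,
                     trait_col: str = CATALOG_TRAIT_COL,
                     gene_col: str = CATALOG_GENE_COL) -> TraitGeneTable:
    """Read a trait-gene association file.

    Parameters
    ----------
    path
        Tab-delimited UTF-8 file.
    dialect
        ``"simple"``: two columns (trait, gene), no header unless
        ``header=True``.  ``"catalog"``: header row with named trait and
        mapped-gene columns; multi-gene cells are split per
        :func:`split_gene_cell`.
    header
        Whether the first line is a header.  Defaults to False for the
        simple dialect; the catalog dialect always has one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("simple", "catalog"):
        raise AssociationError(f"unknown dialect {dialect!r}")

    pairs: list[tuple[str, str]] = []
    skipped = 0
    if dialect == "simple":
        skiprows = 1 if header else 0
        df = pd.read_csv(path, sep="\t", header=None, skiprows=skiprows,
                         dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            vals = [str(v).strip() for v in row]
            if len(vals) < 2 or not vals[0] or not vals[1]:
                skipped += 1
                continue
            pairs.append((vals[0], vals[1]))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in (trait_col, gene_col):
            if col not in df.columns:
                raise AssociationError(f"catalog file lacks column {col!r}")
        for trait, cell in zip(df[trait_col], df[gene_col]):
            trait = str(trait).strip()
            genes = split_gene_cell(str(cell))
            if not trait or not genes:
                skipped += 1
                continue
            pairs.extend((trait, g) for g in genes)

    if skipped:
        logger.warning("read_trait_genes(%s): skipped %d unusable rows",
                       path.name, skipped)
    rows = _dedup(pairs)
    if not rows:
        raise AssociationError(f"no usable trait-gene rows in {path}")
    logger.info("read_trait_genes(%s): %d rows, %d traits, %d genes",
                path.name, len(rows), len({t for t, _ in rows}),
                len({g for _, g in rows}))
    return TraitGeneTable(rows=rows, n_skipped=skipped)


def read_gene_pathways(path: str | Path, fmt: str = "tsv", *,
                       header: bool = False) -> GenePathwayTable:
    """Read a gene-pathway annotation as two-column TSV or GMT.

    In GMT format each line is one gene set: name, description, then a
    tab-separated gene list.  The set name becomes the pathway id; lines
    with fewer than three fields are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("tsv", "gmt"):
        raise AssociationError(f"unknown format {fmt!r}")

    pairs: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    skipped = 0
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, skiprows=1 if header else 0,
                         dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            vals = [str(v).strip() for v in row]
            if len(vals) < 2 or not vals[0] or not vals[1]:
                skipped += 1
                continue
            pairs.append((vals[0], vals[1]))
    else:
        # GMT is one-record-per-line with a variable field count, which
        # tabular readers cannot represent; parsed line by line.
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\n").split("\t")]
                if len(fields) < 3 or not fields[0]:
                    if line.strip():
                        skipped += 1
                    continue
                pathway, desc, *genes = fields
                descriptions[pathway] = desc
                pairs.extend((g, pathway) for g in genes if g)

    if skipped:
        logger.warning("read_gene_pathways(%s): skipped %d malformed lines",
                       path.name, skipped)
    rows = _dedup(pairs)
    if not rows:
        raise AssociationError(f"no usable gene-pathway rows in {path}")
    return GenePathwayTable(rows=rows, descriptions=descriptions, n_skipped=skipped)


def build_trait_pathway_map(tg: TraitGeneTable,
                            gp: GenePathwayTable) -> TraitPathwayMap:
    """Compose trait->gene and gene->pathway tables into a trait->pathway map.

    Each trait's pathway set is the union of its genes' annotations.
    Genes with no pathway annotation stay in the trait's gene set (gene
    overlap between traits is reported independently of pathways) but
    contribute no pathways.
    """
    gene_pathways = gp.pathways_of()
    gene_sets: dict[str, set[str]] = {}
    for t, g in tg.rows:
        gene_sets.setdefault(t, set()).add(g)

    pathway_sets = {
        t: frozenset().union(*(gene_pathways.get(g, frozenset()) for g in gs))
        for t, gs in gene_sets.items()
    }
    m = TraitPathwayMap(
        gene_sets={t: frozenset(s) for t, s in gene_sets.items()},
        pathway_sets=pathway_sets,
    )
    n_empty = len(m.pathwayless_traits)
    if n_empty:
        logger.info("build_trait_pathway_map: %d of %d traits have no "
                    "pathway annotation", n_empty, len(m.traits))
    return m
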
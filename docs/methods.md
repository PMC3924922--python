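# Methods

## Network construction

A trait's pathway set is the union of the pathway annotations of its
mapped genes. Identifier matching is exact-string after whitespace
trimming — no case folding or synonym resolution — so distinct trait
spellings are never silently merged. Traits whose genes carry no
pathway annotation are kept in the map and flagged rather than dropped;
they are excluded only when the bipartite graph is built (they would be
isolates by construction). Genes with no pathway annotation remain in
the trait's gene set because gene overlap between traits is reported
independently of pathway overlap (`explain_edge`).

The catalog dialect splits multi-gene cells on `";"` and `" - "` and
discards the placeholder tokens `NR` and `intergenic`; these mirror the
conventions of real GWAS-catalog exports without committing to a full
schema.

The one-mode projection links two same-side nodes iff they share at
least one neighbour, weighting the edge by the shared-neighbour count
(shared pathways, for the trait side). The projection itself is
delegated to networkx's bipartite machinery; the test suite checks it
against a brute-force pairwise set-intersection oracle.

Descriptive statistics are topology-only: the clustering coefficient is
the unweighted average local (Watts–Strogatz) coefficient with
degree < 2 nodes contributing 0, and the average path length is the
mean unweighted shortest-path length over the largest connected
component — the only finite definition once filtering disconnects the
graph. Isolates are removed *after* projection, so the reported isolate
count refers to phenotypes with no pathway overlap partner.

## Disparity filter

For a node of degree *k* ≥ 2 the null hypothesis is that its unit of
normalised strength is split uniformly at random among its *k* edges;
the probability that a normalised weight is at least p_ij is
α_ij = (1 − p_ij)^(k−1), the closed form of
1 − (k−1)∫₀^p (1−x)^(k−2) dx. Numerical choices:

- **k = 1 convention.** The integral form is undefined at k = 1; we set
  α_ij = 1 (the null can never be rejected by a node whose whole
  strength sits on one edge). Degree-1 edges can therefore survive only
  through the partner's side under OR, and never under AND.
- **Strict inequality.** Edges are kept iff α_ij < α, so α = 0 always
  empties the network and α = 1 keeps every edge that is significant
  from the required side(s).
- **One-shot filter.** Degrees and strengths are always those of the
  unfiltered input; the filter is not iterated.
- **No multiplicity correction.** Per-edge significances are used raw,
  as is standard for this filter.

The α sweep evaluates a grid (default 201 evenly spaced values in
[0, 1]; the analysis scripts use 101 and the acceptance study 51, which
resolve the curves equally well at these network sizes) and records the
fractions of edges, non-isolated vertices and total weight retained
plus the filtered network's clustering coefficient. `pick_alpha`
selects the grid value whose retained-edge fraction is closest to a
target (ties to the smaller, stricter α). The comparison baseline is a
global weight cutoff; `match_edge_fraction` chooses the smallest weight
whose ≥-cutoff edge fraction does not exceed the target, i.e. the
closest achievable fraction from below, and reports the achieved value
because tied weights can undershoot.

## Module detection

Weighted Newman–Girvan modularity with resolution 1, maximised by a
Louvain implementation written in the package so the procedure is
auditable and seed-controlled (established implementations serve as
independent oracles in the tests). The node visit order is shuffled
from the explicit seed once per aggregation level; a node moves only on
a strictly positive modularity gain, ties keep it in place, and equal
gains between two *other* communities break deterministically. Module
labels are canonicalised by decreasing size. Module detection uses the
backbone's edge weights — the filter preserves original weights, and
member ranking within modules is by weighted degree — which is a
modelling choice, since topology-only clustering would also be
defensible.

Louvain is greedy: it can settle in local optima (on an even path it
merges adjacent pairs and cannot reach the optimal split of triples, a
known failure mode shared by reference implementations). The tests
assert exhaustive-search optimality only on instances where the greedy
procedure provably lands there, and planted-partition recovery where
community structure is strong.

## Synthetic catalog generator

The generator emulates the statistical shape of trait–gene and
gene–pathway association snapshots: counts of genes per trait and
pathways per gene are truncated zeta draws (default exponent 2.0 for
both, giving the heavy right skew such catalogs show), one designated
hub trait receives 25× the median gene count (the "measured in every
study" phenomenon), pathways are assigned to genes by
popularity-weighted sampling without replacement so a few pathways
accumulate many genes, and 10% of genes carry no annotation to exercise
isolate handling. Defaults are 200 traits, 600 genes, 300 pathways —
a deliberate desk-scale instance of catalogs roughly 4× larger in every
dimension. The zeta exponents are implementer-chosen: public summaries
of such catalogs describe the skew qualitatively, not distributionally.

What passing tests on this generator do show: the pipeline is correct
end to end, and the disparity filter's qualitative advantage over a
global cutoff (more vertices retained at a matched edge budget) holds
on weight-heterogeneous networks of this shape. What they do not show:
quantitative agreement with any particular database snapshot —
projection density, exact retention percentages and module counts all
depend on the snapshot and are not targets here. An extreme tail draw
can occasionally rival the designated hub's gene count; the hub
guarantees a dominant trait only in expectation.

## Worked-example fixtures

Three packaged catalogs encode published phenotype-pair examples with
pathway identifiers carried verbatim, bracketed KEGG-style ids
included. Where the source lists per-trait pathways but not gene lists
(`table3`, `table4`), each trait is wired through one synthetic proxy
gene, which preserves the asserted facts exactly: pathway overlaps of
5 (iron biomarkers / cognitive performance) and 1 (vWF / hippocampal
atrophy / atrial fibrillation, pairwise), and zero shared genes. In the
iron/cognition source table the two per-trait columns both list the
cytokine–cytokine receptor interaction pathway, which would make the
overlap 6 and contradicts the same source's stated five-pathway
overlap; the fixture follows the stated overlap and carries the
cognitive-performance column without that entry (56 pathways). The
HDL/Alzheimer fixture assigns all four genes to all six pathways; only
the pooled union is asserted by the source, and every reported quantity
is invariant to the within-fixture incidence.

## Pipeline and reproducibility

`run_pipeline` validates its configuration up front, copies it into the
output directory, and writes every stage artifact plus a manifest with
per-stage counts. The manifest contains no timestamps, so identical
configurations and seeds produce identical manifests — this is asserted
by test, and the report renderer only reads persisted artifacts. An
empty projection short-circuits the backbone and module stages with an
explicit notice instead of failing. The acceptance study uses ten
replicate catalogs at the default generator size with a 51-point α grid
and an 8% target edge fraction under the AND rule.

## Known limitations

- Pathway overlap counts are raw: no normalisation for pathway size, so
  aggregate "umbrella" pathways create weak but dense connectivity
  (the single-shared-pathway edges illustrate this).
- The disparity filter assumes weights are meaningful counts; it is not
  designed for networks whose weights are already significance scores.
- Louvain gives one local optimum per seed; module counts on weakly
  modular backbones (Q near 0) are unstable across seeds.
- APL on the largest component only summarises the connected core and
  says nothing about satellites.
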
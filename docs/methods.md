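# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the `subpathways` package, in the order the pipeline runs.

## Pathway model

Pathways are undirected graphs with two node kinds: enzyme nodes carrying a
non-empty set of gene ids, and compound nodes carrying exactly one
metabolite id. Undirectedness is a deliberate modeling choice: the
subpathway location rule is defined purely in terms of shortest-path hop
distances, and directing edges by reaction reversibility would introduce
asymmetric reachability artifacts into a distance-based rule. Self-loops in
input are dropped with a warning. Enzyme entries with identical member sets
but distinct entry ids remain distinct nodes (the map topology is preserved
as drawn).

Two serializations are supported: a KGML subset (`pathway`, `entry`,
`reaction`, `relation` elements; reactions contribute enzyme↔substrate and
enzyme↔product edges, and enzyme–enzyme `relation` links contribute edges
unless `include_relations=False` — both edge sources are parsed because map
sources differ on which one encodes adjacency) and the package's own JSON
exchange format (`format_version` 1) used as the pipeline's canonical
on-disk form. Gene ids are opaque strings, trimmed but never normalized;
compound ids are only required to match the `C#####` form under the
optional strict flag.

## Signature merging

Genes: support counting per dataset (a gene listed twice in one dataset
counts once), selection at `min_gene_support` (default 4 — the strict rule
that stabilizes gene calls across heterogeneous expression datasets).
Metabolites: union across studies at `min_metabolite_support` (default 1 —
metabolomic studies each report few compounds, so the merge is lenient).
Matching is case-sensitive after whitespace trimming; ids that differ only
by case are reported in the log as a merge hazard. Direction of change is
not tracked: the merged sets are undirected differential sets.

## Subpathway location

With distance threshold *n* (default 5), two signature nodes belong to the
same candidate region when their unweighted shortest-path distance is ≤ *n*
("shorter than *n* + 1" hops, boundary inclusive). The relation is closed
transitively via connected components of the auxiliary signature-node
graph. Each component's node set is completed with **every node on any
shortest path between any two of its signature nodes** — the union over all
tied shortest paths and over all within-component pairs. Including all tied
paths removes tie-breaking nondeterminism; including all within-component
pairs (even those whose pairwise distance exceeds *n* after transitive
merging) makes the reported region a single connected piece of the map.
Candidates with fewer than `min_nodes` nodes (default 4; no canonical value
exists, so the parameter is exposed and logged) are dropped; survivors are
numbered `<pathway>_1, _2, ...` by decreasing node count, ties broken by
smallest node id.

Implementation: one BFS per signature node supplies both the pairwise
distances and the on-a-shortest-path test `d_s(v) + d_t(v) = d_s(t)`, so no
explicit path enumeration is needed (the test suite checks against an
independent oracle that does enumerate paths explicitly).

## Enrichment and FDR

Counting is at the molecule level, not the node level: a region's molecule
set is the union of its enzyme nodes' member genes plus its compound ids,
intersected with the annotation universe. The universe is every molecule
annotated to any pathway in the collection (genes and metabolites pooled),
the only universe constructible from the stated inputs and the standard
choice for pathway-annotation tests. The p-value is the hypergeometric
tail P(X ≥ x) computed via `scipy.stats.hypergeom.sf` (a numerically stable
tail sum); m = 0 yields a degenerate result with p = 1.

Benjamini–Hochberg step-up values are computed with the family size equal
to the number of candidate subpathways actually tested across all pathways
(before significance filtering); the implementation accepts a family size
larger than the supplied list so that statistics can be recomputed over a
reported top-k slice. Significance is strict: FDR < threshold (default
0.01).

## Global network

Significant subpathways merge into one network at gene/metabolite
resolution. Enzyme nodes expand into their individual member genes because
the downstream statistics count genes, not enzyme boxes. For each pathway
edge inside a region, every member molecule of one endpoint links to every
member molecule of the other; member genes of a single enzyme node are
additionally linked as a clique since they catalyze the same reaction (the
clique rule is switchable via `isoenzyme_clique=False` — whether such
edges belong in the network is not decidable from first principles, so it
is a flag). Duplicate edges merge and accumulate subpathway provenance;
every node records the set of parent pathways contributing it, which
drives the ≥ 2-pathways multiplicity statistic.

Betweenness centrality is unweighted shortest-path betweenness
(unnormalized pair counts by default, disconnected pairs contributing
nothing), delegated to networkx. Group comparisons (prognostic vs other
genes, by degree and betweenness) use the Wilcoxon rank-sum test via
`scipy.stats.mannwhitneyu`: exact null enumeration when both groups have
≤ 12 observations and no ties, otherwise the normal approximation with tie
and continuity corrections; the method used is reported. Tests are
two-sided by default, direction being read off the observed medians.

## Module detection

The default detector is a deterministic Clauset–Newman–Moore-style greedy
modularity agglomeration: start from singletons, repeatedly merge the
connected community pair with the largest modularity gain
ΔQ = L_ij/m − 2·(D_i/2m)(D_j/2m), stop when no gain is positive
(tolerance 1e-12). Ties are broken by the lexicographically smallest
community-label pair, which makes the algorithm bit-reproducible; because
that tie-break consults labels, strict invariance under node relabeling
holds exactly on graphs whose merge sequence is tie-free (the property
test verifies this and plain determinism separately). Replicating the
overlapping, hierarchical ModuLand procedure is out of scope; instead a
TSV import path accepts externally computed (possibly overlapping)
assignments, and all module statistics work on either source. With
overlapping assignments a molecule is counted in every module containing
it.

Module ids are `Module_0`, `Module_1`, ... in decreasing size order.
Summaries report per-module node counts, differential gene/metabolite
counts, distinct parent pathways, prognostic gene counts, and mean member
betweenness (a quantitative proxy for how "central" a module sits —
"center of the network" is otherwise a layout notion, so interpretation is
left to the user). The crosstalk meta-graph links two modules with weight
equal to the number of network edges running between them.

## Survival screening

Expression input is tumor-minus-normal log2 values per gene and patient
(reducing inter-patient heterogeneity). For each gene, patients split at
the mean value: strictly above → high group, at or below → low group (ties
at the mean go low; the choice is documented and switchable in effect by
negating values). Constant-expression genes are degenerate and skipped
with a log entry.

The log-rank test is an explicit risk-set sweep: at each distinct event
time, expected high-group deaths d·n₁/n and hypergeometric variance
d(n₁/n)(1−n₁/n)(n−d)/(n−1) accumulate; χ² = (O₁−E₁)²/V with 1 df. Censored
patients leave the risk set after their time; deaths precede censorings at
ties. Zero accumulated variance yields a degenerate p = 1. The scan
declares genes with raw p < alpha (default 0.05) prognostic — deliberately
uncorrected, since the screen is a raw per-gene filter; a BH reference
column is attached for users who want it. Kaplan–Meier curve coordinates
come from lifelines.

## Synthetic data generator

The generator emulates the *shape* of the real study inputs: a handful of
metabolic maps, six differential gene lists, seven metabolite study lists,
and a paired tumor/normal cohort with follow-up.

Pathway structure: each pathway draws its node count from
`nodes_per_pathway` (default 18–30), with `enzyme_fraction` (0.5) enzyme
nodes carrying 1–3 genes from a shared pool (240 genes, 140 compounds —
pools are shared across pathways so molecules recur, exercising the
multiplicity statistics). A random spanning tree in which every edge
touches at least one compound node (reaction-like topology) is densified
with extra compound-incident edges (`extra_edge_fraction` 0.35). One
connected region (default 6 nodes, grown by randomized BFS) in the first
pathway is planted.

Signatures: each background gene is called differential per dataset with
probability 0.05, each planted-region gene with probability 0.9; under six
datasets and the ≥ 4 rule, planted-gene recall follows the
Binomial(6, 0.9) tail P(X ≥ 4) ≈ 0.984. Metabolite studies are analogous
(background 0.02, planted 0.9 over seven studies, ≥ 1 rule).

Survival: each planted prognostic gene gets an independent Bernoulli(1/2)
latent group per patient; group membership shifts that gene's
tumor-minus-normal expression by `expression_shift` (default 3.0, i.e. a
marker separated by 3 SD from the reference group — chosen by an upfront
power analysis so a "strong" planted marker is reliably recoverable at
hazard ratio 3 with 120 patients) and multiplies the patient's event
hazard by `planted_hazard_ratio` (default 3). Event times are exponential
at `baseline_hazard` (0.02 per month, i.e. median ≈ 35 months for a
baseline patient); censoring is an independent exponential with one shared
rate calibrated so a baseline-hazard patient is censored with probability
`censoring_rate` (default 0.2; 0 disables censoring). Exponential forms
were chosen for closed-form sanity checks.

One global seed fans out to three `numpy.random.SeedSequence` substreams
(pathways, signatures, survival), so changing one block's parameters never
perturbs another block's draws; identical configs give byte-identical
output files.

What the generator does **not** emulate: real KEGG topology statistics
(hub compounds such as ATP/H2O, map sizes spanning orders of magnitude),
correlated differential calls across datasets, microarray noise structure,
non-exponential hazards, or covariate-dependent censoring. Passing tests
on synthetic data therefore demonstrate correctness of the algorithms and
calibration of the statistics under the stated generative model, not
biological validity on any real cohort.

## Packaged reference table

`load_escc_subpathway_table()` returns a published reference table of 39
significant ESCC metabolic subpathways (ids, pathway names, hypergeometric
p-values, BH FDR). It serves the strict-filter regression test and the
FDR-consistency check: the top row implies a BH family size of 85
(round(4.19e-10 / 4.93e-12)), and re-running the step-up over the table's
p-values reproduces the printed rank-1 FDR exactly at printed precision.
Lower ranks are reproducible only to within one unit of the printed last
digit, because the table's p-values are printed at 3 significant figures
and the FDR column at 2–3, which is below the precision the step-up
minimum propagates (rank 5's minimum binds at the rank-8 entry).

## Problem sizes and numerical choices

The test and acceptance workloads use deliberately small problem sizes
that still exercise every code path: 8 pathways of 18–30 nodes per
synthetic study, 200 random graphs of ≤ 30 nodes for the location oracle,
exhaustive hypergeometric enumeration up to N = 12, 12-node graphs for the
betweenness oracle, 50-seed recovery/power sweeps, and a 1000-gene null
scan at 120 patients. Floating-point comparisons against exact rational
oracles use relative tolerance 1e-10; the greedy modularity stop rule uses
an absolute 1e-12 gain threshold; follow-up times are clipped to ≥ 1e-6 to
maintain strict positivity.

## Known limitations

- Community detection is a deterministic stand-in with an import path; it
  does not reproduce ModuLand's overlapping hierarchy, so module counts on
  real data will differ from analyses run with that tool.
- The annotation universe is collection-relative; results are therefore
  sensitive to which pathways are loaded.
- The prognostic screen is marginal (one gene at a time, no multivariate
  adjustment or Cox modeling) and intentionally uncorrected.
- KGML parsing covers the metabolic subset only (no signaling-pathway
  relation semantics, no KEGG REST access, no map rendering).
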
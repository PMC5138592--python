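# Methods

## The network model

The analysis operates on a directed graph over proteins. Each protein
carries a set of pathway labels, two role flags (ligand = signaling source,
transcription factor = signaling sink) and a membership flag for the curated
signaling set. Proteins pulled in only through paralogy evidence sit outside
the curated set: they carry no edges, pathways or role flags, but they do
receive group labels (a paralog of a critical group is itself counted as a
critical paralog) and annotations. Self-loops are rejected rather than
ignored, because path-based essentiality and bowtieness are undefined for a
protein signaling to itself; duplicate edge records collapse silently with a
log line, since interaction databases routinely contain redundant rows.

## Paralog groups and the merge rule

Two complementary paralogy inputs are supported. Group-per-row records
(orthologous-group id, taxon, gene) are filtered to a focal taxon (default
`9606`) and yield one candidate group per id with at least two focal genes.
Pairwise similarity records build an undirected graph over (species, gene)
nodes; within each connected component the focal-species genes — possibly
linked only through genes of other species — form one candidate group.

Candidates are merged into a disjoint partition by assigning each protein to
its best-scoring candidate under the ratio score `D = n/m` (signaling
members over all members). The score is a single replaceable function, so an
alternative form is a one-line change. Exact `D` ties are resolved by the
larger `n`, remaining ties by the lexicographically smallest group id; a
configurable tolerance widens "tie" beyond exact equality but defaults to
zero because no similarity tolerance is defined for the method. After
assignment, groups are rebuilt from the winners; rebuilt groups with fewer
than two members (or none in the signaling set) dissolve and their signaling
members join the ungrouped pool. The rebuild is what guarantees
disjointness, at the cost that a group encoded only as overlapping fragments
across the two sources cannot survive as a single group — hence the
synthetic generator encodes each group wholly in at least one source.

## Tissue networks and essentiality

A tissue qualifies for a network when strictly more than half of the
signaling proteins are assigned to it after consolidating raw tissues into
organ systems (18 by default). Each qualifying tissue yields two induced
subgraphs: one with only the proteins expressed there, one additionally
keeping proteins with no expression record anywhere. A protein expressed in
*other* tissues only is excluded from both — "unannotated" is a fixed class,
not a per-tissue condition.

A protein is essential in a tissue when deleting it disconnects a
ligand→TF pair that was connected in the intact tissue graph; pairs whose
endpoint is the deleted protein never count, otherwise every ligand and TF
would be trivially essential. Rather than deleting nodes one at a time, the
implementation computes, per ligand L, the dominator tree of the flowgraph
rooted at L: a node lies on every L→T path exactly when it dominates T, so
the strict dominators of each reachable TF are precisely the proteins whose
removal breaks that pair. This is algebraically identical to the removal
definition but costs one near-linear pass per ligand; the test suite checks
exact agreement with an exhaustive simple-path oracle on 200 random graphs.
Flow-critical proteins are the union of per-tissue essential sets, and
classification runs on the annotated-only variant by default while the other
variant is always computed and any group-label disagreement reported.

## Centralities

Degree counts distinct neighbors ignoring direction. Betweenness is the
standard directed shortest-path count with endpoints excluded
(unnormalized). Closeness uses undirected distances averaged over the nodes
reachable from the focal protein (reciprocal mean distance; isolated nodes
score 0); directed variants of both conventions exist, but the definitions
here follow the common defaults of graph toolkits for these one-line
definitions. Bowtieness is the signaling-specific variant of betweenness:
the fraction of ligand→TF shortest paths passing through a node as an
intermediate. Path counts are pooled into one global numerator and
denominator across all reachable pairs — the "percentage of shortest paths"
reading — with per-pair averaging available behind a flag. Shortest-path
counting uses exact integer arithmetic on hop counts, so results are
deterministic. Within-group dispersion is the sample standard deviation
(denominator m−1) over members present in the graph; groups with fewer than
two present members are omitted.

## Cross-talk and classification

A protein is a cross-talk protein when some neighbor (either direction)
carries a pathway label the protein itself lacks. The set-difference rule
matters for multi-pathway proteins: a protein already annotated to both
pathways is not a bridge between them. A group is a CPG when at least one
member is flow-critical *and* at least one member (not necessarily the same
one) is a cross-talk protein.

## Specificity

For one annotation family, a feature is specific within a group when not
every member carries it. The group score is the number of specific
protein–feature incidences summed over members, divided by the group size
m — "specific features per protein". Members without any annotation record
count in the denominator, because the normalization is by group size. A
variant counting distinct specific features rather than incidences is
available behind a flag. The same scorer serves regulators, miRNAs, GO terms
and diseases.

## Statistics

Rank comparisons use the two-sided Wilcoxon rank-sum test: the exact null
distribution when both samples hold at most 20 tie-free observations,
otherwise the normal approximation with tie and continuity correction. The
two-sample Kolmogorov–Smirnov test (asymptotic) mirrors every rank
comparison. Categorical proportions use Pearson's chi-square on 2×2 tables
with df = 1 and no continuity correction by default — the uncorrected form
is what reproduces the printed GO-annotation comparison (p = 0.309 for 9/267
vs 30/611); Yates correction stays available behind a flag. Enrichment uses
upper-tail hypergeometric tests against the full protein universe
(signaling proteins plus grouped paralogs) with Benjamini–Hochberg
adjustment applied within one annotation family. Note that BH is *not*
idempotent, so adjusted p-values are reported once and never re-adjusted.
Significance stars follow the usual thresholds (*** p<0.001, ** p<0.01,
* p<0.05).

## The synthetic generator

The generator emulates the study conditions: 7 pathways of ≈94 proteins
(≈700 signaling proteins), 18 organ systems consolidated from ~7 raw
tissues each, 22.5% of signaling proteins without expression records, 60
paralog groups of 2–4 members (a third planted critical), and
disease/driver/drug flag rates of 41%/17.2%/16% for CPs, 21%/8.2%/4% for
PPs and 37%/15%/10% for others.

Its constructions are chosen so that, at the zero-noise defaults, the
pipeline provably recovers the planted truth:

* pathway backbones are layered DAGs with complete bipartite wiring between
  consecutive layers and at least two proteins per layer, so no single
  backbone protein is ever essential;
* a planted essential member is a regular mediator plus a private
  ligand→member→TF attachment expressed only in designated tissues — the
  only pairs it breaks are those through the private attachment, making the
  per-tissue essential truth exact;
* cross-talk edges come in redundant bundles of two parallel edges with
  same-layer sources and same-layer targets, so cross-pathway flow always
  has two node-disjoint routes and never creates accidental essentials;
  cross-talk truth is exactly the bundle endpoints;
* unannotated proteins are drawn only from unreserved filler mediators with
  a per-layer cap of size−2, which keeps the two tissue-inclusion variants
  equivalent by construction;
* group truth alternates between the two paralogy encodings (every fifth
  group in both), so the merge step is genuinely exercised;
* planted CPG bottlenecks receive extra within-pathway edges
  (`centrality_boost`, default 8) that raise CP degree and betweenness, and
  CPG members receive extra member-specific miRNA/GO features
  (`specificity_boost`, default 2).

Before emission the generator re-verifies every planted essential member
with its own BFS reachability check and re-derives the cross-talk flags from
the edge list, failing loudly on any mismatch. Noise knobs
(`expression_dropout`, `annotation_noise`, `tissue_coverage_prob`) default
to zero effect; raising them degrades recovery by design.

What the generator does **not** emulate: sequence evolution or BLAST scores
behind the paralogy records, GO's DAG structure (features are opaque IDs),
continuous expression levels (presence/absence only), cyclic signaling
(cycles are supported by the analysis but not generated by default), and
realistic degree distributions — backbones are deliberately regular so that
redundancy guarantees hold. Passing recovery tests therefore demonstrates
correctness of the pipeline's logic, not robustness to the noise and
incompleteness of curated databases.

## Problem sizes and determinism

Defaults were chosen so a full run stays interactive: the default dataset
(≈720 signaling proteins, ≈5,000 edges, 18 tissues × 2 variants) completes
the whole pipeline in a few seconds on one CPU, and the acceptance script
(200 oracle graphs of ≤12 nodes, 1000 null simulations, one full pipeline
run) in well under a minute. Every random choice flows from a single integer
seed through one generator; repeated runs are byte-identical, which the
manifest digests make checkable.

## Known limitations

* The merge cannot reunite a group split as overlapping fragments across
  sources (see above); real databases may require a pre-clustering step.
* Betweenness and closeness come from a general-purpose graph library and
  use floating-point accumulation; agreement with enumeration is asserted to
  1e-9, not exactly.
* The statistical battery reports every comparison it can form and skips
  degenerate ones (empty classes, zero margins) rather than failing.
* Gene-level paralogy records are assumed to share one identifier namespace
  with the protein network; no cross-database ID mapping is attempted.
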
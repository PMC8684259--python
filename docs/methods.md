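# Methods

This note records the models, conventions and open design choices behind
graphlike, in the order data flows through the toolkit.

## Input model

Measurement CSVs follow a fixed dialect: comma delimiter, `.` decimal,
UTF-8; the first column holds entity identifiers regardless of its header
(Ensembl gene ids for transcripts, UniProt accessions for proteins,
KEGG/ChEBI ids for metabolites); remaining columns are samples. An optional
second row whose first cell is the exact lowercase string `group` assigns
samples to experimental groups; only this spelling is accepted, which keeps
the parser deterministic. Columns named `FC_[g1]_vs_[g2]` /
`padj_[g1]_vs_[g2]` carry externally computed differential results (e.g.
from DESeq2 or limma run elsewhere) and are routed into the table's DE
block rather than its measurements — graphlike does not reimplement count
models or moderated variance shrinkage. A separate design CSV
(`sample,group,...`) overrides any embedded group row, on the view that the
stand-alone design file is the more explicit artefact; conflicts are
reported. Empty cells are missing values and are excluded pairwise by all
statistics. A warning (not an error) is raised above 200 samples, where
interactive-scale use degrades.

Exported tables add `name` and `measured` annotation columns; the reader
recognises and skips exactly those two headers so every export re-ingests
as a valid measurement table (schema closure).

## The knowledge graph and connectivity

Nodes are typed (transcript, protein, metabolite, reaction, pathway) and
edges are one of `encodes` (transcript→protein), `participates`
(protein/metabolite→reaction) or `member` (reaction→pathway). The graph
file is assumed species-consistent; no species field is modelled, since
choosing the file plays the role of choosing the database subset.

`connected(a, b)` is defined by a fixed pattern list, not reachability:
transcript–protein via an encodes edge; entity–reaction via (the encoded
protein's) participates edge; reaction–pathway via a member edge;
transcript/protein–metabolite via **one** shared reaction; entity–pathway
via a reaction that is a member of the pathway; same-kind pairs iff equal.
Unrestricted reachability would connect almost everything through hub
pathways and make drill-down filtering useless. Cross-omics links
deliberately require a single shared reaction rather than a reaction
chain, and only direct participates edges are considered (protein
complexes or sets inside the source database are not expanded).

Mapping marks uploaded ids found in the graph as *measured*; ids absent
from the graph stay out of it and are only counted (per omics) in the
mapping summary. For reactions and pathways the summary counts those
connected to at least one measured entity.

## Linked selection

A selection state is an ordered list of groups, each a set of ids from one
table. A row `x` of any table is visible iff **for every** group there
**exists** a selected id connected to `x` — within-group OR, across-group
AND. This algebra is symmetric in the groups (order-invariant) and
monotone (adding a group can only shrink visible sets); both properties
are verified against a brute-force implementation of the definition.
Selecting again on a table that already has a group *appends* (refines);
a `replace` flag supports redoing a selection instead. The measured-only
display marker is a view option, not part of connectivity. Named groups
persist as JSON (name, kind, ids, free-text annotation); names are unique.

## Queries

A query is an AND-conjunction of rules `omics.field op threshold` with
`field ∈ {padj, fold_change, abs_fold_change}`; `abs_fold_change` encodes
"at least t both ways" as `|FC| ≥ t` on the uploaded (log-scale) fold
change, which is treated as opaque — no re-basing of logarithms is
attempted. Entities missing a referenced statistic fail the rule, with the
excluded count reported; this is conservative and explicit. Evaluation
produces one selection group per omics kind mentioned, so linked tables
show entities passing their own rules AND connected to passers of every
other mentioned kind. The `padj` column is used verbatim, as it is the
only p-value column the upload format defines. Pathway-level rules are
resolved against stored pathway-activity results and must hold in every
omics analysed (logical AND), with pathways absent from some omics'
universe unable to pass.

## Differential statistics

The per-entity test is a two-sided Welch *t*-test with
Welch–Satterthwaite degrees of freedom (a pooled-variance test is the
obvious alternative; Welch is chosen because group variances are not
assumed equal, and the choice is documented here). Fold change is the
difference of group means on the stored values, which are assumed already
log-transformed/normalised; `log2(x + c)` preprocessing is available but
off by default. Entities with fewer than two usable samples in a group are
reported untestable rather than tested. Zero variance in both groups gives
p = 1 when the means agree; with unequal means the entity is flagged
untestable (NA) instead of being handed p = 0 — a zero-spread difference
carries no quantifiable finite-variance evidence. BH adjustment runs
across all tested entities of a table; it is permutation-equivariant and
monotone but **not** idempotent, and no such claim is made.

PCA treats samples as observations; variables are centred and by default
scaled to unit variance so scree fractions are comparable across omics
with different units (`scale=False` disables). Entities with missing
values (and, under scaling, zero variance) are dropped with a warning; an
all-constant table is an error.

## Pathway activity

Set membership comes either from a GMT file or from the graph (entities
connected to each pathway). Graph-derived sets are restricted to measured
entities before testing so that the ORA background equals the measured
universe — an unmeasured background would make ORA anti-conservative.
Default set-size window 3–500 (configurable); PLAGE accepts singletons,
where it provably reduces to the entity's own *t*-test.

* **ORA** uses the inclusive upper tail `P(X ≥ k)`, the standard
  over-representation convention; sets with no mapped members are
  excluded with a recorded reason, not given p = 1. The DE entity list
  defaults to `padj ≤ 0.05`, boundary inclusive.
* **GSEA** ranks entities by signal-to-noise `(m1−m2)/(s1+s2)` (sd floored
  at 1e-12 to avoid division by zero), uses weight exponent 1, and defines
  ES as the running sum's maximum signed deviation. Significance uses
  sample-label (phenotype) permutation when both groups have ≥ 7 samples
  and entity-label permutation otherwise; the scheme is recorded in the
  result. The nominal p compares the observed ES with the same-signed part
  of the permutation null, with a +1 smoothing so p is never zero.
  Permutation count defaults to 1000 and a seed is mandatory.
* **PLAGE** standardises member rows (mean 0, sd 1, ddof 1), takes the
  first right singular vector of the standardised submatrix as the
  per-sample activity, fixes its sign to correlate non-negatively with the
  mean standardised member profile, and tests the activity between groups
  with a Welch *t*-test. The Welch-on-activity significance is this
  package's own definition of PLAGE significance. Constant member rows are
  dropped; all-constant sets excluded with a reason.

GO enrichment propagates annotations to ancestor terms through the parent
relation (true-path rule) before running the same hypergeometric machinery
against the measured background. Multi-omics integration is the AND
combination of per-omics pathway results at a shared threshold.

## Clustering

Distances (cosine, correlation, euclidean) are computed pairwise-complete
over shared non-missing observations; rows that leave some pairwise
distance undefined (< 2 shared observations) are dropped, worst offender
first, with warnings. A zero-variance row under correlation distance is an
error naming the row. Agglomeration uses Lance–Williams updates for
single, complete and unweighted-average linkage; ties on merge distance
are broken by the lexicographically smallest leaf labels of the candidate
clusters, so results are independent of input row order. Defaults (cosine
distance, average linkage) are this implementation's choice. Cropping a
dendrogram node returns its leaf set, which plugs directly into linked
selection. Snapshot exports z-score rows for display by default; distance
computation itself never z-scores.

## Synthetic data

The fixtures module emulates, at toy scale, the structure the mapper
expects: each pathway owns disjoint pools of proteins (one transcript per
protein) and metabolites; each of its reactions draws 4 proteins and 2
metabolites from those pools. Defaults: 20 pathways × 3 reactions, pools
of 10 proteins and 5 metabolites per pathway, two groups ("distal",
"proximal") of 6 samples, i.i.d. Gaussian noise with sd 1 on a log-like
scale (no count model — the toolkit assumes processed, roughly symmetric
measurements). By default the first pathway carries a planted 2-SD shift
in the second group across all omics, giving demo projects a real signal;
`planted=()` yields a pure null. Everything is deterministic under the
seed, to the byte, including written files.

What the generator does **not** emulate: real pathway topology (overlap
between pathways, hub metabolites, complexes), heteroscedastic or heavy-
tailed measurement noise, correlated entities outside planted sets, and
unmapped-id noise. Passing tests therefore demonstrate correctness of the
algorithms under clean Gaussian conditions, not performance on real data.

## Problem sizes and numerics

Validation runs use sizes chosen to make brute-force oracles exhaustive:
random graphs of ≤ 60 nodes (100 of them) for connectivity and selection,
every hypergeometric setup up to N = 30 against rational arithmetic,
1000 random vectors for BH, a 2000-entity 5+5 null for *t*-test
calibration, 100 seeded runs for PLAGE recovery, 1000 permutations for the
GSEA null, and 4–8-row matrices for clustering. Agreement tolerances are
1e-12 for exact quantities and 1e-8 where SVD/eigendecomposition round-off
enters. Hypergeometric tails are computed by scipy's survival function;
ES computations are plain cumulative sums; all randomness flows through
`numpy.random.default_rng` seeds.

## Known limitations

No OR/parenthesised boolean query algebra (AND-conjunction only, matching
the query builder it models). No topology-aware pathway methods. No live
graph-database adapter, web UI, or external annotation services; the graph
arrives as a file export. DE methods beyond the Welch test are consumed,
not computed. GSEA's ranking metric and permutation split (≥ 7 samples per
group) are defaults of this implementation, documented rather than tuned.
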
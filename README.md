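# graphlike

Horizontal multi-omics integration as a headless library and CLI.

Many studies measure transcripts, proteins and metabolites on samples that
cannot be aligned vertically (sample-by-sample). **graphlike** integrates
such data *horizontally*: every uploaded entity is mapped onto a typed
knowledge graph in which transcripts are linked to the proteins they encode,
proteins and metabolites to the reactions they participate in, and reactions
to the pathways that contain them. All downstream exploration — linked
drill-down filtering, rule-based cross-omics queries, cluster "cropping" —
reduces to one fixed connectivity predicate on that graph, while global
analyses (differential expression, PCA, pathway activity, GO enrichment)
rank what the filters should focus on.

## What it computes

* **Connectivity / linked selection.** `connected(a, b)` holds iff the pair
  matches one of a fixed list of path patterns (e.g. transcript–metabolite
  only through a single shared reaction of the encoded protein) — not
  general reachability, which hub pathways would trivialise. An ordered
  list of selection groups filters every table: within a group selected ids
  act as an OR, across groups as an AND.
* **Differential expression.** Per-entity two-sided Welch *t*-tests between
  two sample groups, log-scale fold change `mean(g1) − mean(g2)`, and
  Benjamini–Hochberg FDR control `adj p_(i) = min_{j≥i} m·p_(j)/j` across
  the table. Externally computed results enter through
  `FC_[g1]_vs_[g2]` / `padj_[g1]_vs_[g2]` CSV columns.
* **Pathway activity.**
  * *ORA*: hypergeometric upper tail `P(X ≥ k)` for `k` significant
    entities among `K` set members in a measured background of `N` with
    `n` significant overall;
  * *GSEA*: running-sum enrichment score over a signal-to-noise ranking
    (hits weighted by `|r|`, misses by `1/(N−K)`), permutation *p*-values;
  * *PLAGE*: per-pathway activity = first right singular vector of the
    standardised member submatrix, tested by a Welch *t*-test between
    groups.
  Per-omics results combine across omics with a logical AND.
* **Clustering.** Deterministic agglomerative clustering (cosine /
  correlation / euclidean × average / complete / single) whose dendrogram
  nodes can be "cropped" into selections.

## Worked example

Generate a synthetic project (20 pathways; the first carries a planted
2-SD shift between the two groups), load and analyse it:

```
graphlike fixtures make --seed 7 --out demo
graphlike load --transcripts demo/transcripts.csv --proteins demo/proteins.csv \
    --metabolites demo/metabolites.csv --design demo/design.csv \
    --graph demo/graph.json --project proj
graphlike map --project proj
graphlike de --project proj --omics protein --group1 distal --group2 proximal
graphlike de --project proj --omics metabolite --group1 distal --group2 proximal
graphlike pathway --project proj --method plage --omics metabolite \
    --group1 distal --group2 proximal
graphlike query --project proj --rule "protein.padj<0.3" --rule "pathway.padj<0.05"
```

which prints:

```
mapped transcripts: 200 (unmapped: 0)
mapped proteins: 200 (unmapped: 0)
mapped metabolites: 100 (unmapped: 0)
mapped reactions: 60
mapped pathways: 20
...
plage on metabolite: 20 sets tested, 1 with padj <= 0.05 -> proj/results/pathway_plage_metabolite.csv
protein: 4 entities pass
pathway: 1 entities pass
visible transcripts: 4
visible proteins: 4
visible metabolites: 5
visible reactions: 3
visible pathways: 1
```

Read: all uploaded ids mapped; at 6 samples per group the per-entity tests
are underpowered (only 4 proteins reach padj < 0.3 after BH), but PLAGE —
which pools a pathway's members — flags exactly one pathway
(`PWY0000`, the planted one, padj ≈ 0.023). The query then intersects both
criteria through the graph: the 4 passing proteins, the 5 metabolites and
3 reactions connected to them inside the one significant pathway. The
visible rows of any table can be exported
(`graphlike export --table protein --out ...`) and saved as named groups
for GO enrichment (`graphlike groups save`, `graphlike go`).

The same operations are available as a library
(`graphlike.knowledge_graph`, `graphlike.linked_selection`,
`graphlike.query_engine`, `graphlike.diff_stats`,
`graphlike.pathway_activity`, `graphlike.clustering`,
`graphlike.fixtures`); see `docs/methods.md` for the modelling choices.

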
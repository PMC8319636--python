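# keynet

Key-protein prioritization for neuroinflammation interaction networks.

Neuroinflammation — sustained activation of microglia — is implicated in
Alzheimer's disease, but dozens of cytokines, chemokines, receptors and
downstream kinases appear in the literature and only a few of them can
plausibly *control* the process. `keynet` implements, as a tested and
fully offline pipeline, the network-pharmacology strategy for finding
those controllers:

1. **Identifier mapping** — a literature-derived query list (Ensembl gene
   IDs, gene symbols or UniProtKB accessions in any mix) is resolved
   against a three-column association table into a deduplicated query set.
2. **Pathway over-representation (ORA)** — each pathway gene set *S* with
   *K* members in a background of *N* annotated genes is scored with the
   hypergeometric upper tail
   `P(X ≥ k) = Σ_{i≥k} C(K,i)·C(N−K, n−i) / C(N,n)`
   for a query of *n* genes overlapping *S* in *k*; pathways are ranked by
   raw p (Benjamini–Hochberg q-values reported alongside), and the query
   proteins belonging to the top-ranked pathways are retained.
3. **Interaction network** — a STRING-style edge table is thresholded at
   combined score ≥ 0.7 ("high confidence"); the retained proteins form an
   undirected simple graph on which degree and unnormalized betweenness
   centrality `C_B(v) = Σ_{s<t, v∉{s,t}} σ_st(v)/σ_st`
   are computed natively (Brandes' algorithm, unordered pairs).
4. **Key-node selection** — proteins whose degree **and** betweenness both
   meet or exceed the arithmetic means over the *full* protein universe
   (isolated proteins included) are the key proteins.
5. **Overlays** — experimentally supported miRNA→target edges (filtered to
   miRNAs dysregulated in patient blood, split up/down by the sign of the
   log2 fold change), lncRNA→target edges and drug–gene interactions with
   modality and FDA-approval flags are projected onto the key set and
   summarized.

A seeded synthetic-data generator produces complete input bundles with
ground truth (planted hubs, planted enriched pathways, regulator and drug
maps), so every stage is testable without any database access.

## Worked example

The dual above-mean rule applied to the packaged worked-example table —
the eleven key proteins of the Alzheimer's-disease neuroinflammation
network with their published centralities — using the published thresholds
(mean degree 9.38, mean betweenness 47.69 over the 52-protein universe):

```sh
keynet keynodes $(python -c \
  "from keynet.datasets import key_protein_centrality_path as p; print(p())") \
  --mean-degree 9.38 --mean-betweenness 47.69 --out sel
```

prints

```
11 key proteins (mean degree 9.38, mean betweenness 47.69)
```

i.e. every published row (IL10 first at betweenness 300.55, NOS3 last at
62.26) passes both thresholds. A full end-to-end run on a synthetic bundle:

```sh
keynet simulate --out bundle
keynet run --gene-list bundle/gene_list.txt \
  --mapping-table bundle/mapping_table.tsv --gmt bundle/pathways.gmt \
  --background bundle/background.txt --edge-table bundle/edges.tsv \
  --mirna-targets bundle/mirna_targets.tsv \
  --dysregulation bundle/mirna_dysregulation.tsv \
  --lncrna-targets bundle/lncrna_targets.tsv \
  --drug-table bundle/drug_table.tsv --out out
```

reports (default config, packaged seed 20210715):

```
n_query 94      n_mapped 94        n_pathways_tested 40   n_top_pathways 10
n_union_proteins 72   n_edges 218  mean_degree 6.06       n_key_proteins 6
n_mirna 36 (16 up / 20 down)       n_lncrna 12
n_drugs 63      n_drug_edges 87    n_targeted_proteins 3
```

The 94 mapped query proteins funnel to 72 proteins in the ten top-ranked
pathways; thresholding the edge table at 0.7 leaves 218 interactions whose
centrality means select 6 key proteins — including all 3 planted hubs
(`ground_truth.json` in the bundle lists them). The overlay counts show
which dysregulated miRNAs, lncRNAs and drugs act on the key set; the
per-protein drug counts rank the most targetable proteins first.

The library mirrors the CLI one-to-one (`keynet.run_pipeline`,
`keynet.selection_only`, `keynet.generate_bundle`, ...), and every
intermediate artifact (query set, enrichment table, SIF/GraphML networks,
centrality table, key-node JSON, multilayer overlay) is written to the
output directory.

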
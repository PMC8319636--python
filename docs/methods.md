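# Methods

## Pipeline model

The pipeline prioritizes "key" proteins in an inflammation-related
interaction network through five stages. Each stage is a pure function of
its declared inputs, every intermediate table is materialized, and the
whole cascade is deterministic given its inputs.

### Identifier mapping

Raw identifiers are matched case-insensitively against any of the three
columns of an association table (Ensembl gene ID, gene symbol, UniProtKB
accession); symbols are stored uppercase. The query is deduplicated **by
gene symbol**, first occurrence wins, so the query is counted at gene
level even when one gene carries several isoform accessions; when a gene
maps to several accessions the first in table order is kept and the
alternatives logged. Every unique raw identifier ends up exactly once as
either a mapped record's key or an entry of the unmapped list (a partition
— property-tested). How multi-isoform accessions should be collapsed is
genuinely underdetermined in this kind of analysis; first-in-table order
is the simplest deterministic rule and is declared rather than guessed at.

### Over-representation analysis

For a pathway with `K` members in a background of `N` annotated genes and
a query of `n` genes (after dropping query genes absent from the
background — the standard ORA contract, which keeps `k ≤ n ≤ N` valid),
the p-value is the hypergeometric upper tail `P(X ≥ k)`, evaluated via
`scipy.stats.hypergeom.sf` and cross-checked in the tests against exact
rational enumeration. Benjamini–Hochberg q-values (statsmodels `fdr_bh`,
cross-checked against a literal hand step-up) are reported, but **raw p
drives the ranking**, matching the "most significant pathways sorted by
p-value" convention of the upstream services this stage emulates.
Zero-overlap pathways are retained at p = 1 so the output always covers
the collection. Ties are ordered by larger overlap, then lexicographic
pathway name, then id — a total order needed because realistic collections
produce exactly tied p-values (the worked example's ranks 9–10 tie at
1.085 × 10⁻⁶).

### Interaction network

Scores gate edge inclusion (inclusive `≥ min_score`, default 0.7, the
conventional high-confidence STRING cutoff) and are otherwise discarded:
shortest paths are unweighted, mirroring the practice of applying a score
cutoff and then purely topological centralities. Duplicate and reversed
edge records collapse to one undirected edge keeping the maximum score
(deterministic and conservative); self-loops are dropped; the universe is
never shrunk, so proteins without high-confidence partners stay as
isolated nodes.

Betweenness uses Brandes' dependency accumulation: one BFS per source,
`δ(v) ← Σ_w σ(v)/σ(w)·(1+δ(w))` over the shortest-path DAG, summed over
sources and halved to count **unordered** pairs, endpoints excluded, with
**no normalization**. The published worked-example magnitudes (maximum
300.55 on a 47-connected-node graph, below the unordered ceiling
C(46,2) = 1035) are consistent with unnormalized unordered-pair counting;
whether the original tooling counted ordered pairs (doubling every value)
cannot be determined, which is one reason the absolute published
betweenness values are treated as fixtures rather than recomputation
targets. The implementation is verified against explicit geodesic
enumeration (and networkx) to 10⁻⁹ on hundreds of random graphs.

### Key-node selection

Thresholds are the arithmetic means of degree and betweenness over the
**full universe including isolated proteins**: with 244 edges over 52
proteins the mean degree is 2·244/52 = 9.3846 ≈ 9.38, matching the
published value, whereas averaging over only the 47 connected nodes would
give 10.38 — this arithmetic pins the universe convention. Selection keeps
records meeting both thresholds with inclusive `≥`, sorted by betweenness
descending (symbol as tie-break for determinism). Whether the published
betweenness mean 47.69 was itself averaged over 52 or 47 proteins is not
derivable; the module's contract (full universe) is declared, and nothing
downstream depends on recomputing that constant.

### Overlays

Regulator and drug layers are projections: edges whose target is a key
protein are kept, everything else discarded, so applying a layer twice
changes nothing. miRNA edges join their blood-profile log2 fold change by
exact mature-ID match (family-level matching would conflate distinct
strands). Under `require_dysregulation` (default on) a miRNA edge needs a
present, nonzero log2fc; an exact zero is excluded with a warning because
the up/down partition by sign must be total. Drugs are counted by distinct
name (one drug may hit several targets, so edge count ≥ drug count), with
modality × approval cross-counts and per-protein edge counts sorted
descending. Evidence tags are carried through but not filtered on, since
no principled default filter exists for mixed-assay evidence.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical *shape* of the study inputs: a
~94-protein query fully covered by the mapping table; 40 pathways of which
10 are stuffed with ~15 query genes each (all planted hubs forced in, so
they survive the union step) against 30 decoys drawn purely from 900
background-only genes; an edge table in STRING-export dialect where pairs
involving a hub receive supra-threshold scores (range [0.70, 0.999]) with
probability 0.5 and other pairs with probability 0.05, plus sub-threshold
noise in [0.15, 0.69]; 80 miRNAs of which 80% carry a zero-excluded
normal(0, 1) log2 fold change (≈63 dysregulated, the magnitude the study
design anticipates); 13 lncRNAs; and 63 drugs (8/63 biologics, 16/63
FDA-approved — the study's modality and approval proportions) targeting
subsets of the hubs.

The planted-hub-and-sparse-background edge model was chosen over
preferential attachment because it gives direct, seedable control over
which nodes must exceed both centrality means. One integer seed drives a
single `numpy` Generator consumed in a fixed order (genes → pathways →
edges → regulators → drugs), and all files are written with fixed number
formats, so identical config + seed reproduces a bundle byte-for-byte.
The packaged default seed is 20210715.

What passing on synthetic bundles does **not** show: recovery of the
study's absolute numbers. Real pathway databases have overlapping,
hierarchically nested gene sets with heavy-tailed sizes; real interaction
scores integrate correlated evidence channels; real miRNA/drug maps have
hub-biased degree distributions and curation artifacts. Quantities that
depend on specific database versions — the 94-protein text-mining yield,
the published enrichment p-values, the 47-node/244-edge network and its
absolute betweenness values, the 63-miRNA/63-drug overlay counts — are
therefore packaged as worked-example fixtures and verified as consistency
checks (e.g. all published key rows pass the published thresholds), never
recomputed.

## Numerical choices and degenerate inputs

- Hypergeometric tails are evaluated through the survival function and
  clipped to [0, 1]; validity bounds (`k ≤ min(K, n)`, `K, n ≤ N`) raise a
  domain error rather than returning nonsense.
- BH adjustment enforces monotonicity via the cumulative-minimum step-up;
  `q ≥ p` always holds.
- Betweenness accumulates per connected component implicitly (BFS never
  leaves a component); isolated nodes score 0/0 but stay in the universe.
- Empty query, empty pathway collection, empty edge set and empty key set
  are handled: the first three produce empty-but-valid outputs or a named
  domain error where the operation is meaningless (empty background,
  empty universe, empty centrality table); an empty key set downgrades the
  overlay stages to a warning and a skip rather than a run failure.
- Problem sizes in the test suite and acceptance script (default-config
  bundles, 10–20 seeds for recovery fractions, random graphs ≤ 20 nodes
  for the centrality oracle) were chosen as the smallest sizes at which
  the statistical claims are meaningful; all complete in seconds.

## Known limitations

- Only degree and betweenness are implemented; other hub definitions
  (closeness, stress, top-k percentile rules) are out of scope.
- The enrichment stage models one flat gene-set collection; it does not
  traverse ontology hierarchies or group terms by semantic similarity.
- Edge confidence is a single combined score; channel decomposition and
  weighted shortest paths are not modeled.
- The drug layer is a lookup join: no dosing, directionality of effect, or
  chemistry.
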
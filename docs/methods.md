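# Methods

## The problem

Functionally related genes cluster physically in prokaryotic genomes —
operons are the classic case, but looser context conservation is far more
common. `genecontext` turns this into a statistical screen: given a query
protein domain (or an explicit gene list) and a database of Pfam-annotated
genomes, it asks which other domains are encoded in the query genes'
genomic neighborhoods significantly more often than random gene placement
would produce. Over-represented neighbors are candidate functional
partners of the query domain.

## Model

Each query gene defines a neighborhood: all genes on its contig whose
`[start, end]` interval overlaps the window `[start − r, end + r]`,
with the radius `r = 5,000` bp per direction by default (roughly 10 genes
at typical prokaryotic gene density). Membership is by interval overlap —
a long gene straddling the window edge counts — and the query gene itself
is always a member, so the query domain trivially appears in 100% of
neighborhoods and is flagged `is_query` in the output rather than removed.

For a target domain *D*, let

- `Nn` — number of query neighborhoods,
- `Nl` — mean neighborhood size in genes (empirical mean over this
  query's neighborhoods),
- `Nod` — number of genes in the database carrying *D*,
- `Sd` — total number of genes in the database,
- `k` — observed number of member genes carrying *D*, summed over all
  neighborhoods.

The `Nn · Nl` gene slots of the neighborhoods are modeled as independent
draws from the database, where each draw carries *D* with probability
`Nod / Sd`. The expected count is therefore

    λ = Nn · Nl · Nod / Sd,

and the significance of the observation is the Poisson upper tail

    P score = P(X ≥ k),  X ~ Poisson(λ).

Because the true count is a sum of bounded Bernoulli variables with
variance below λ, the Poisson tail is slightly conservative — the null
calibration and anti-conservatism checks in the test suite quantify this.
Counting is per-gene presence throughout: a domain hit twice in one
protein counts once, which makes `Nod ≤ Sd` provable and `E[k] = λ`
exact under the null by construction. Domains with `k < λ` (observed
*less* often than a random window) are excluded before anything else;
multiple-testing correction (Bonferroni or Benjamini–Hochberg, via
statsmodels) is applied over the retained set only, so `m` = number of
retained domains. The reported table keeps rows with raw P score below
the cutoff (default 1e−5) present in at least the minimum fraction of
neighborhoods (default 5%), sorted by ascending P score with ties broken
by descending `k` then accession.

### Choices the formulation leaves open

- **`Nl` is the empirical mean** of this query's neighborhood sizes, not
  a constant derived from the radius. This makes λ self-calibrating in
  gene-dense vs. gene-sparse taxa and at contig edges.
- **`k` counts per-gene presence summed over neighborhoods** (three
  carrier genes in one neighborhood contribute 3). The alternative —
  per-neighborhood presence — would break the equality `E[k] = λ`.
- **P scores use the survival function** (regularized incomplete gamma
  via `scipy.stats.poisson.sf`), never naive `1 − Σ` summation, which
  cancels catastrophically for large λ. The test suite pins the
  implementation to an arbitrary-precision summation oracle at
  |Δ| < 1e−12 over `k ≤ 50, λ ≤ 20`.

## Subtaxon averaging

Public genome collections oversample some taxa by orders of magnitude.
A co-localization private to one heavily sequenced genus would dominate a
database-wide screen. The averaging option groups the query neighborhoods
by the query genome's lineage at a chosen rank, drops subtaxa with fewer
than 25 database genomes (the threshold applies to the subtaxon's genome
count in the database, not its neighborhood count), finds the subtaxon
with the most neighborhoods (`n_sub_max`) and tops every other subtaxon up
to `n_sub_max` by drawing its own neighborhoods at random **with
replacement** (without replacement is impossible when the deficit exceeds
the group size). Every retained subtaxon then contributes exactly
`n_sub_max` entries. The random draws are governed by a required, logged
seed; a sidecar report records each subtaxon's genome count, neighborhood
count and contribution.

Only the neighborhood set is balanced. The background counts (`Nod`,
`Sd`) are recomputed over the genomes of the retained subtaxa, unweighted.
Balancing the background per subtaxon as well would be a defensible
alternative; it is deliberately not done, and this asymmetry is the main
interpretive caveat of the averaging mode.

## Neighborhood similarity clustering

Each neighborhood is reduced to its domain *set* (presence, not counts)
and compared pairwise by the Jaccard index `J = |A∩B| / |A∪B|`. Two empty
sets get `J = 0` by convention, with a warning — an unannotated
neighborhood is no evidence of similarity, and a silent 0/0 → 1 would glue
all unannotated neighborhoods into one cluster. The matrix is clustered on
the distance `d = 1 − J` with genuine single (minimum) linkage — the
variant whose flat clusters at threshold *t* equal the connected
components of the graph with edges `d ≤ t`; the tests exploit exactly this
minimum-spanning-tree property as an independent oracle. Flat clusters
come from a distance cut or a target cluster count; cluster IDs are
renumbered by first appearance in input order, so results are
deterministic and permutation-invariant up to relabeling. Clusters are
annotated with genus/family composition percentages and "featured
domains" present in ≥ 90% (configurable) of the cluster's members.

## GO decoration

Significant domains are optionally linked to Gene Ontology terms through
the `pfam2go` (external2go) mapping file. Decoration is pure: it fills the
`go_terms` field and changes nothing else, and it is idempotent. The GO
aspect is not derivable from pfam2go alone and stays blank unless a GO
metadata table (`go_id aspect name`) is supplied — shipping or requiring
the full ontology is out of scope.

## Synthetic databases

The generator (`genecontext.fixtures`) emulates what the method consumes
— coordinates and domain annotations — and nothing it does not (no
sequence content, no phylogenetic correlation between genomes). Per
genome, genes are laid on a single contig with lengths
`60 + Geometric(mean 900 − 60)` bp and intergenic gaps `Geometric(mean
100)` bp, i.e. about one gene per kilobase; strands follow a two-state
Markov chain with configurable persistence (default 0.5, i.e. independent
strands). Each of the pool's domains is assigned to a binomial number of
genes uniformly at random (default 300 domains at per-gene frequency
0.005, ~1.5 domains per gene). A query domain is planted on one gene in a
chosen fraction of genomes, and each partner domain is placed within a
bounded gene offset of the query with a chosen co-localization
probability, else on a uniformly random gene. A JSON truth record lists
every placement so expected counts are computable analytically.

Canonical conditions used by the tests and the acceptance script:

- **standard** (`standard_spec`): 200 genomes × 1,000 genes, 300-domain
  pool, query in 150 genomes, one partner within ±3 genes with
  probability 0.8 — the planted-recovery condition.
- **null** (`null_spec`): 200 genomes × 500 genes, 50-domain pool at
  frequency 0.04, no partners. The pool is small and frequent on purpose:
  it puts every domain's λ near 60, so the 20-seed mean of `k` has
  Monte-Carlo noise (≈ `1/√(20λ)` relative) far inside the 10%
  calibration band, and the calibration check probes the λ formula rather
  than sampling noise.
- **skewed** (`skewed_spec`): genus A with 50 genomes carrying the
  planted association, genus B with 30 genomes without it — the condition
  under which genus-level averaging must dilute the partner's presence
  fraction.

Because generated genomes are i.i.d. and domains are assigned
independently, passing these tests shows the statistic and its
implementation behave as designed under the model's own assumptions; it
does not certify behavior on real data, where neighboring genes are
correlated (operons), domain frequencies are heavy-tailed and taxon
structure is hierarchical rather than flat.

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive; the loader rejects `start > end`,
  `start < 1`, unknown strands and duplicate gene IDs outright.
- An absent query domain is a status ("not found"), not an exception, so
  batch runs can continue; an all-unknown gene list is an error.
- `P(X ≥ 0) = 1` exactly; `poisson_pscore` is finite for `k ≤ 10⁴`,
  `λ ≤ 10³` (far tails may underflow to 0.0, which is the correct
  double-precision answer).
- Neighborhoods of clustered query genes are *not* merged; the model
  treats windows as independent draws, accepting double-counting, and the
  tests inherit that convention.
- Problem sizes in the test suite (20 replicates of the standard
  condition, 50 random clustering instances of n ≤ 50) were chosen as the
  smallest sets at which the stochastic checks have comfortable margins.

## Known limitations

- Only protein-coding genes with Pfam annotations participate; RNA genes
  and unannotated ORFs are invisible to the statistic.
- Taxonomy matching is exact-string per rank; no name normalization or
  taxid resolution.
- The Poisson model ignores within-neighborhood correlation of domain
  occurrences, making it conservative for presence-style signals.
- Averaging balances neighborhoods only (see above).
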
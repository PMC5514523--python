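# Methods

## The prediction problem

A clinical sign is linked to a gene indirectly: some disease causes the
sign, and the gene causes the disease. Pooling these links over all
diseases gives each sign a gene set; the question the package answers is
how well the remaining genes of a sign predict a held-out one through the
interactome, and which clinical/biological factors modulate that
performance. Two prioritizers are implemented: a global-distance method
(random walk with restart) and a connectivity-significance method
(DIAMOnD-style greedy expansion).

## Network model and normalization

The interactome is an undirected simple graph over opaque gene identifiers.
Self-loops are dropped on load; parallel edges collapse to the maximum
weight; weights default to 1 and must be positive. Degree `d` is the
weighted degree. Propagation uses the symmetric normalization
`W′ᵢⱼ = wᵢⱼ/√(dᵢdⱼ)` (the PRINCE form), whose spectral radius is at most 1;
isolated nodes have all-zero rows by contract. Disconnected networks are
allowed: nodes in components containing no seed score exactly zero and are
ranked pessimistically below every scored candidate.

The interactome is treated as unweighted in all synthetic studies, but the
loader and normalization accept weights because the PRINCE normalization is
defined for weighted graphs.

## Random walk with restart

`p⁽ᵗ⁺¹⁾ = (1−γ)·W′·p⁽ᵗ⁾ + γ·p₀`, iterated from `p⁽⁰⁾ = p₀` until the L1
change drops below `tol` (default 1e-10; the contraction rate is `1−γ`, so
convergence is geometric for any γ in (0,1]). Defaults: γ = 0.4,
`max_iter` = 1000; non-convergence raises, carrying the last residual.

γ is interpreted as the **restart probability** (the weight on the seed
distribution); γ = 0.4 therefore propagates 60% of the mass per step. The
complementary convention exists in the literature; since γ is a plain
configuration field, callers preferring the other reading can pass `1−γ`.
With symmetric normalization the converged vector is not a probability
distribution; scores are used only ordinally and are not renormalized.

Seed vectors are normalized to sum to one. Sign-based leave-one-out uses
equal weights over the remaining genes. Disease-based leave-one-out weights
each seed gene by `max over contributing terms i of 1/(nᵢ−1)`, where `nᵢ`
is the term's gene count **after** ancestor expansion and interactome
restriction (the pipeline's candidate universe); weights are then
normalized. Terms with a single gene contribute nothing (the only gene is
the held-out one), and pairs whose seed comes out empty are skipped with a
warning rather than scored.

Ranks are pessimistic on ties: the held-out gene is placed after every
candidate sharing its score, so unreachable (zero-score) test genes rank
last among the unreachable pool instead of benefiting from arbitrary
ordering. The candidate pool excludes seed genes, so `M = N − |seed|`.

The leave-one-out driver batches one sign's seed vectors as columns of a
single dense block and iterates them together against the shared sparse
matrix; this is an exact, order-of-magnitude-faster equivalent of the
per-gene loop (asserted in tests).

## Connectivity significance (DIAMOnD)

At each iteration every node with at least one link into the current
cluster is scored with the hypergeometric tail
`p(N, s₀, k, ks) = Σᵢ₌ₖₛ^min(k,s₀) C(s₀,i)·C(N−s₀,k−i)/C(N,k)` and the
minimum-p node is absorbed. Ties break toward larger `ks`, then smaller
degree `k`, then lexicographically smaller gene id — the method text
leaves ties unspecified, and a fixed rule makes traces reproducible. The
seed-weighting parameter of the original algorithm is fixed at 1 (seeds
count once). The tail is evaluated with scipy's hypergeometric survival
function (stable log-space internally); the test suite re-derives entire
traces with exact rational arithmetic and requires identity. A gene not
absorbed within `max_iter` (default 1000) has a **censored** rank: it is
excluded from AUC (with its count reported) and counts as a miss at every
top-k threshold, since extrapolating beyond the trace is unfounded.

## Annotation propagation and panel selection

Disease sign annotations are closed upward over the ontology (a disease
annotated with a term is annotated with every ancestor). A propagated
ancestor's frequency class is the most prevalent class among contributing
descendants (hallmark > typical > occasional > unknown) — the conservative
reading of "frequency of the sign in the disease" when several descendant
annotations disagree.

Panel selection keeps, among terms under the phenotypic-abnormality
subroot with at least `min_genes` genes (default 25), only those with no
passing proper descendant. This "most specific wins" rule removes
ancestor/descendant redundancy; the suite checks it against literal
enumeration on random DAGs, including multi-parent ones. The size
threshold is applied **before** interactome restriction: a sign qualifies
by its annotated gene count and is then evaluated on the genes present in
the network; sets left with fewer than two network genes cannot support
leave-one-out and are dropped with a warning.

Compactness of a gene set is the fraction of members adjacent to at least
one other member. Diseases are monogenic/oligogenic by the count of their
interactome-mappable genes (1 vs >1; 0 excluded), each disease id
independently.

## Evaluation

Rank AUC is the mean of `(M−r)/(M−1)` over uncensored records — exact,
threshold-free, and equal to the Mann–Whitney probability that the
held-out gene outranks a uniformly drawn negative. An independent oracle
in the tests rebuilds the pooled ROC polyline from the per-record
false-positive rates `(r−1)/(M−1)` and integrates it with the trapezoid
rule; the two agree to 1e-12. Pooled AUC (over records) is the default;
stratified summaries are pooled within each group.

Stratification assigns each record to **every** group it matches: a sign
below two top-level classes counts in both, a disease annotated with two
onsets counts in both, and a gene-sign pair tracing to both a monogenic
and an oligogenic disease counts in both ploidy strata. Records lacking
metadata fall into an `unknown` group. The `mono_only` filter keeps
records tracing to at least one monogenic disease, mirroring analyses that
exclude purely oligogenic contributions.

The random baseline draws seed sets uniformly (sizes uniform on 25–75 by
default) and runs the same leave-one-out machinery; because the held-out
gene is exchangeable with every candidate, its pooled AUC sits at 0.5 up
to sampling noise, which the acceptance suite bounds at ±0.03 over 500
sets on a 5000-node network.

The best-sign upper bound keeps, for each (disease, gene) pair, the
minimum rank over all of that pair's sign records; min-rank dominance
makes it an upper bound on any single-sign restriction (asserted).

## Synthetic data

The generator emulates the statistical structure of real sign-gene data at
desk scale: a preferential-attachment (Barabási–Albert) network (default
5000 nodes, attachment 3 — connected, heavy-tailed); diseases with one
gene (probability `mono_weight`, default 0.9, matching the strong
monogenic majority in curated disease databases) or 2–5 genes; signs
attached to blocks of diseases so sign gene sets are multi-disease unions;
a two-level ontology (subroot → 18 classes → signs, mirroring the ~18
top-level phenotype classes); per-(disease, sign) frequency classes drawn
from a hallmark/typical/occasional mix of 0.2/0.5/0.3.

Two planted signals correspond to the factors the evaluation dissects:

- `module_density` adds each absent within-sign edge with the given
  probability (edges are only added, never removed, so the knob is
  monotone in compactness and the scale-free backbone is preserved).
- `hub_bias` places dominant (AD) disease genes in the top degree decile
  and recessive (AR) genes in the bottom degree half with the given
  per-gene probability, reproducing the reported hub/periphery asymmetry
  of AD vs AR disease genes.

Module planting draws from an RNG stream separate from the
disease/sign-structure stream, so sweeping `module_density` at a fixed
seed is a paired comparison on identical annotations. All outputs are pure
functions of the configuration; fixture directories are byte-identical
across runs.

What the generator does **not** model: literature-curation bias in edge
coverage, correlated sign co-occurrence, phenotypic series, cross-ontology
vocabularies, and realistic degree–annotation confounding beyond the
hub-bias knob. Passing the planted-signal tests therefore shows the
machinery is correct and sensitive to compactness and hub placement, not
that real-data AUCs would take any particular value.

## Study sizes used in the acceptance checks

The property experiments use 5000-node networks: 500 random seed sets for
the null; 40 signs of 25–40 genes (unions of 25–40 monogenic diseases)
for the density sweep over {0, 0.1, 0.2, 0.3}; 400 diseases at
`hub_bias` 0.9 and `module_density` 0.05 for the inheritance
stratification — a mild module signal keeps the strata off the AUC ceiling
so the hub/periphery contrast is visible. The RWR/DIAMOnD comparison runs
on a 2000-node fixture with the DIAMOnD cap at 500 iterations. Exact
oracles run on graphs of up to 50 (dense linear solve), 200 (rational
arithmetic traces) and 20,000-candidate rank vectors (ROC geometry).

## Known limitations

- The γ convention ambiguity is resolved by configuration, not detection.
- OBO parsing covers the id/name/is_a subset; other relationship types are
  ignored with a warning.
- No statistical tests on AUC differences between strata are provided.
- Gene identifiers are opaque; symbol/ID mapping is a curation concern
  outside the package's scope.
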
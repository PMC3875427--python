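# Methods

## Bicluster model

The package targets *coherent-column* biclusters: a pair (G, C) of a gene
set and a condition set such that, within every condition c ∈ C, the
expression values of the genes in G span at most a per-condition width
MAX_DIFF(c).  This captures groups of genes regulated in the same direction
with similar magnitude under a subset of conditions; it does not capture
additive/multiplicative row-shift patterns or order-preserving patterns,
which are different bicluster families.

## Preprocessing

Each column is processed independently.

* **Outlier clipping.**  The column mean and standard deviation are
  computed on the raw values; values outside Mean ± 3SD are moved to the
  nearest bound.  SD is the *population* standard deviation (divide by n):
  with small condition counts this keeps 6SD/bins stable and is a fixed
  convention, not an inference.
* **MAX_DIFF.**  The column extremes are *defined* as Mean ± 3SD after
  clipping, so the window width is MAX_DIFF = (MAX − MIN)/bins = 6·SD/bins
  unconditionally.  `bins` (default 7) is the only user input here.
* **Low-signal filter.**  Values with |v − Mean| < sd_coeff·SD (default
  0.7) are undifferentiated; the gene takes part in *no* window of that
  column, neither as anchor nor as member.  The opposite convention
  (filtered genes may still join windows anchored by retained genes) is
  conceivable; it was rejected because a value indistinguishable from the
  column mean cannot evidence coexpression.
* **Items.**  Retained genes are sorted by clipped value; each gene anchors
  the closed window [v, v + MAX_DIFF].  The closed interval matters: a gene
  set whose range equals MAX_DIFF exactly is coherent by definition and
  must lie inside some single window, which a half-open window would
  violate.  Identical windows are de-duplicated (anchor multiplicity is
  recorded).  A column with SD = 0 yields no items rather than aborting.
  Ties in the value sort are broken by gene order; under the closed-window
  rule tie order cannot change any item's content.

## Mining

Every item is coherent and a bicluster's gene set must sit inside one item
per selected column, so candidate gene sets are exactly the intersections
of items.  The miner enumerates gene sets G that are **maximal with respect
to their column coverage** C(G) = {columns owning an item ⊇ G}: no gene can
be added without losing a column.  Since C(·) is antitone, a single-gene
extension test is a complete maximality test, and maximality in this sense
is equivalent to non-domination among coherent submatrix pairs (no output
is contained in another on both axes).

An earlier formulation — maximality over *item sets* with gene-intersection
support — was implemented and rejected: overlapping same-column windows
join such an itemset and shrink its support below the gene-maximal set, so
that enumeration provably misses gene-maximal biclusters (verified against
exhaustive search on random matrices).  The shipped miner is a depth-first
set-enumeration over genes with integer-bitmask intersections, pruning by
|C| ≥ min_col (antitone, hence lossless) and by a cardinality lookahead
against min_row, with absorption of genes contained in every item of the
current closure.  Search depth is bounded by the gene count.  Correctness
is guarded by an exhaustive-enumeration oracle in the test suite (50
random matrices per run) rather than asymptotic argument.

## Significance

A bicluster's coherence statistic is the average pairwise Pearson
correlation of its R gene row vectors restricted to its C conditions,
T ∈ [−1, 1].  The average (not the sum) keeps biclusters of different
shapes on one scale.  A zero-variance row vector contributes r = 0 to each
of its pairs — a neutral convention avoiding undefined divisions.

The null distribution is Monte Carlo: n_perm submatrices of the same R × C
shape, rows and columns drawn independently, uniformly, without
replacement and not necessarily contiguous, from the full input matrix.
The p-value is the upper-tail fraction #(null T ≥ observed)/n_perm,
without add-one smoothing, so a bicluster more coherent than every null
draw reports p = 0.  The upper tail is the only direction compatible with
keeping *low* p-values for coherent biclusters.  Null ensembles are cached
per shape; a shorter ensemble is always a prefix of a longer one from the
same seed, so screening p-values (used inside the merge search at
`search_n_perm`, default 10 000) are consistent with final scores.

p-values are *not* multiplicity-corrected; α (default 0.05) is a per-
bicluster filter, matching the pipeline's screening character.

## Merging

Biclusters with exactly the same condition set that are connected through
gene overlap form a merge group; each group merges to one bicluster.  The
seed is the member with the smallest p-value; candidate genes (the group
union minus the seed) are ranked by Pearson correlation to the seed's
per-condition mean vector, restricted to the group's conditions (coherence
is only claimed there).  A binary search over ranked-prefix length finds
the largest prefix whose union with the seed keeps p ≤ α.  The feasibility
predicate need not be monotone in the prefix length; binary search is kept
as the intended fast approximation, and the tests verify agreement with an
exhaustive prefix scan whenever the predicate is in fact monotone.  The
final merged bicluster is re-scored at the full n_perm and shrunk if the
re-score lands above α, making the output contract (every merged p ≤ α)
unconditional.  Merging within a condition-set partition preserves the
disjointness of its components, so merging is idempotent.  Column
coherence (MAX_DIFF) is *not* re-imposed after merging: the significance
ceiling is the merge criterion; per-column ranges remain available from
the output tables.

## Gene set networks

Each gene occurring in a bicluster carries a membership signature (the
exact set of biclusters containing it); genes with identical signatures
form one node, so nodes partition the biclustered genes and genes in no
bicluster are omitted from all outputs.  Edge weight = |signature(u) ∩
signature(v)|, edges require weight ≥ 1; each bicluster therefore induces
a clique.  A node's condition annotation is the union of its signature
biclusters' condition sets (union chosen over intersection: the node's
genes are coexpressed in each constituent bicluster's conditions).
Connected components are reported separately, largest first; singleton
components are retained but flagged.  Node ids follow sorted signatures,
making outputs stable across runs.  Supporting operations mirror common
evaluation practice: a >50 %-cell-overlap filter against larger biclusters
(exactly 50 % is kept — "more than" is strict), top-k by cell count, an
edge-weight ≥ w sub-network filter, and hub extraction (maximum-degree
node plus its heavy-edge neighbours, with the merged gene list exported
for external enrichment tools).

Bicluster *size* is cell count |G|·|C| throughout; all orderings use the
deterministic key (size desc, p asc, lexicographic gene list).

## Synthetic data

The generator implants rectangular blocks into an i.i.d. Gaussian
background (default N(0, 1)).  Within each implanted condition the block's
genes sit at a common level plus uniform jitter; the generator re-derives
each column's clipped SD and *asserts* that the block passes max − min ≤
6·SD/bins, so an infeasible spec fails loudly instead of producing an
unlearnable fixture.  Default levels lie 2.5–3 background SDs from zero —
far enough to survive the sd_coeff = 0.7 filter — and alternate in sign
across the block's conditions so the block rows are strongly correlated
(a constant-level block would have T ≈ 0 and would rightly not be deemed
coexpressed).  Not simulated: probe effects, batch structure, heavy tails,
correlated background genes.  Recovery on these fixtures is therefore a
best case: passing tests demonstrate algorithmic correctness, not expected
performance on real expression data.

A second, fully deterministic fixture arranges three mutually overlapping
12-gene biclusters over disjoint condition pairs so that mining yields
exactly those three and the resulting network has the canonical 5-node,
7-edge shape with one weight-2 edge pair.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's
standard benchmarks: 200 × 20 matrices with one 15 × 4 block, n_perm = 500
or 1000 for fixtures (the production default stays 100 000), 50 random
8 × 6 matrices for the exhaustive-oracle comparison, and 200 sampled
submatrices for null calibration.  The null-calibration check compares 200
empirical p-values against Uniform(0, 1) by KS distance; at this sample
size the KS statistic itself fluctuates around 0.06 with a 5 % quantile
near 0.096, so occasional excursions above 0.1 are expected statistical
noise, not miscalibration.  Pearson computations clip to [−1, 1] to absorb
rounding; coherence assertions allow a 1e−9 relative tolerance; the
matrix reader uses exact (repr round-trip) float parsing so that write →
read is lossless.  One base seed drives every stage through per-purpose
spawned substreams, making whole runs bit-for-bit reproducible.

## Known limitations

* Exhaustive enumeration is exponential in the worst case; dense coherent
  structure (many tied values, tiny `bins`) can make mining expensive.
  min_row/min_col and the sd_coeff filter are the practical controls.
* The merge binary search can under-fill a group when feasibility is
  non-monotone; the exhaustive scan is the reference behaviour and is only
  feasible for small candidate lists.
* Empirical p-values are bounded below by 1/n_perm (reported as 0 when no
  null draw reaches the observation); ranking among "p = 0" biclusters
  falls back to size and gene order.
* The null preserves the matrix's global value distribution but not
  column-specific structure; matrices with strong per-column scale
  differences make the null conservative for the tightest columns.
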
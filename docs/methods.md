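# Methods

This note documents the models and procedures implemented in `evoregion`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic test bed can show.

## Input preparation

Trees are read from Newick (quoted labels and bracket comments accepted;
missing branch lengths kept as absent, never coerced to zero). Three
preprocessing steps mirror the standard treatment of taxonomy-derived
supertrees without branch-length information:

* `set_unit_branch_lengths` — every edge set to 1 (used when no molecular
  lengths exist);
* `ultrametrize_extend` — each terminal edge lengthened by
  (max tip depth − tip depth) so all tips reach the same depth; internal
  edges untouched. This is the "extend" flavour of forcing ultrametricity
  and is exactly idempotent on ultrametric trees;
* `resolve_polytomies` — every multifurcation replaced by a randomly
  ordered ladder of binary nodes. Inserted edges get ε = 1e-6 tree units:
  negligible against unit branches but strictly positive, so downstream
  Markov-model machinery never sees zero-length internal edges. The ladder
  only refines clades, so every clade of the input is a clade of the
  output; the randomization takes an explicit seed (default 0) so
  downstream matrices are reproducible.

The two steps are exposed separately rather than in a fixed order because
different data sets need them in different orders (e.g. grafted tips get
unit lengths before the whole tree is ultrametrized).

Occurrence grids are equal-angle lon/lat tilings (2° cells by default),
cells half-open so shared borders belong to exactly one cell, ids row-major
from the north-west corner. Range polygons are rasterized with the
minimum-coverage rule: present iff the range covers ≥ 12.5% of the cell
(inclusive at the threshold). Coverage ratios use the cosine-latitude area
approximation; within a single cell the latitude factor cancels, so the
ratio reduces to the planar ratio and the approximation error is
negligible at 2°. A ready cells × species 0/1 table can be supplied
instead. Empty cells are dropped before analysis (ids are retained for
traceability), and species are aligned to the tree-tip order with an
explicit report of names dropped on either side.

## Phylogenetic fuzzy weighting and PCPS

With patristic distances *d*, similarity is the linear kernel
*s = 1 − d/max(d)* (an exponential kernel is available but not default).
**Q** column-standardizes *s*, so column *j* is a probability vector of
phylogenetic membership in species *j*'s lineage; columns sum to 1 to
machine precision and the diagonal is each column's maximum. **P** is the
presence matrix times **Q**, rows standardized to unit sum — each cell's
phylogeny-weighted composition. Row standardization is applied after
empty-cell filtering (filtering first avoids renormalizing against cells
that are then discarded).

Ordination uses square-rooted Bray–Curtis dissimilarities and classical
scaling (double-centering −½·J·d²·J, symmetric eigendecomposition, axes
scaled by √eigenvalue). The square-root transform makes the dissimilarity
Euclidean-embeddable in practice; if negative eigenvalues still appear
they are dropped with a warning rather than Lingoes/Cailliez-corrected,
because the square root is itself the device used to avoid them. Axis
selection keeps components with strictly more than 5% of the positive
variance (`var_threshold`, strict inequality); if no axis clears the
threshold the first axis is used so the pipeline degrades gracefully.
PCoA has no out-of-sample transform, so the `PCPS` estimator only
transforms the data it was fitted to.

## Evoregion classification

`EvoregionClassifier` (a scikit-learn style clusterer; `fit` on the
selected ordination axes) runs:

1. **Elbow:** for k = 1..k_max (default 10) compute best-of-`restarts`
   (default 20) k-means within-cluster sum of squares; pick the k whose
   (k, WSS) point lies farthest from the chord joining (1, WSS₁) and
   (k_max, WSS_kmax), ties to the smaller k. All-identical input returns
   k = 1. The rule is deterministic given the seed and is asserted to sit
   on a non-increasing WSS curve.
2. **k-means:** best-of-restarts Lloyd iterations (tolerance 1e-6),
   k-means++ seeding, explicit `random_state`.
3. **DAPC:** PCA to the smallest number of components explaining ≥ 90% of
   variance (capped at n_cells/3 to protect the discriminant step from
   overfitting; with the usual 2–4 PCPS axes the cap is inactive),
   then linear discriminant analysis on the k-means labels. The LDA
   posteriors are the per-cell membership probabilities; the argmax is the
   final label. Groups are renamed A, B, … by descending cell count so
   runs are comparable (the letters carry no meaning beyond size order).

All of this is composed by `classify_evoregions(P, ...)`, which also
records provenance (k, eigenvalue spectrum, WSS curve, seeds).

## Affiliation, transition zones, species association

Affiliation of cell *c* is 1 − mean sqrt-Bray–Curtis dissimilarity to the
other cells of its region (a similarity, so high affiliation = low
turnover); a region's sole member has affiliation 1 by convention.
Averaging happens in sqrt-BC space — the same space the ordination uses —
with raw-BC available as an option. Because no numeric cutoff for
transition zones is established in the field (published zones are read off
maps), the default flags cells strictly below their region's lower
quartile of affiliation **and** 4-adjacent to a different region; both the
quantile and the adjacency requirement are configurable. Flagged cells are
grouped into 4-connected components annotated with the region labels they
border.

A species is associated with its modal evoregion when that region holds
≥ 60% of its occupied cells (inclusive threshold; ties at the maximum
resolve to widespread — only possible at ≤ 50% anyway); otherwise it is
`WIDESPREAD`. Raising the threshold can only move species toward
widespread (tested monotonicity).

## Ancestral evoregions (Mk + stochastic mapping)

The species-to-region character (region letters plus `WIDESPREAD` as a
first-class state — it is an observed state of the character, not missing
data) evolves under an equal-rates Mk model: with k states and total
departure rate λ, each off-diagonal rate is q = λ/(k−1) and
P(t) = 1/k + (I − 1/k)·e^(−kqt) in closed form. The log-likelihood is
computed by Felsenstein pruning with per-node scaling; the root prior is
uniform. λ is fitted by bounded golden-section search on log λ over
[1e-6, 1e3] (tolerance 1e-8); identical tip states pin λ to the lower
bound with a warning.

Stochastic maps are sampled exactly: node states are drawn from their
joint conditional distribution (root from its posterior, then each child
given its parent and the child's subtree likelihood), and each branch is
filled conditional on its endpoints by rejection sampling (forward
simulation, cap 1000 tries) with a uniformization fallback. Choosing the
uniformization rate equal to λ makes the virtual jump chain's diagonal
zero, so every sampled jump is a real state change and histories contain
no zero-length segments. Node posteriors are the across-map state
frequencies; the exact marginals from an up-down pruning pass are also
available (`mk_marginal_posteriors`) and the two agree within Monte-Carlo
error by construction (tested). Defaults: 100 maps, seed 0. An
all-rates-different model is deliberately not offered; the equal-rates
model is the defensible default when nothing is known about transition
asymmetries among regions.

## V-measure congruence

Two regionalizations are crossed over their shared cells into a weighted
overlap table (cell counts by default; cosine-latitude areas optional —
counts are exact when both maps live on the same equal-angle grid).
Homogeneity h = 1 − H(R|Z)/H(R), completeness c = 1 − H(Z|R)/H(Z)
(defined as 1 when the corresponding entropy is 0), V = 2hc/(h+c) (0 when
h = c = 0). Natural logarithms throughout; V is invariant to the base but
the tests pin it for exactness. Swapping the maps exchanges h and c and
leaves V unchanged; both orientations are reported by the CLI so the
"with respect to" direction is never ambiguous.

## Synthetic test bed

`ScenarioConfig` defaults define the standard test conditions: 4 latent
regions on a 12 × 12 grid of 2° cells, 120 species, mean range size 10
cells (about a quarter of a 36-cell region — narrow-ranged species
dominate real faunas), spillover probability 0.1 per growth step, 10%
widespread species, seed 7.

* **Tree.** A crown-start pure-birth (Yule, rate 1) tree rescaled to unit
  depth. Because the scenario posits one comparable, well-separated
  radiation per region, trees are rejection-sampled until the
  n_regions-lineage cut is balanced (smallest clade ≥ half a fair share)
  and all basal splits fall within 10% of the tree depth — a
  near-simultaneous basal radiation. Without this conditioning a plain
  Yule cut typically yields one dominant clade and deeply nested basal
  splits, i.e. a scenario of *poorly* separated regional clades.
* **Regions.** Contiguous rectangular blocks from the factor pair of
  n_regions closest to square (vertical strips for primes).
* **Ranges.** Contiguous blobs grown by frontier sampling from a random
  start in the clade's region; each growth step may leave the region with
  probability `spillover_prob`, capped so at least 60% of every regional
  species' cells stay inside its true region. Widespread species instead
  get two balanced half-blobs on either side of a region boundary (size
  rounded to an even number ≥ 4), so no region can claim a 60% majority —
  the ground-truth labels therefore satisfy the association rule exactly.
* **Paired scenarios.** The parasite fauna shares the host's grid; each
  parasite clade inherits the host's regional territory with probability
  given by `congruence_level`, and is otherwise placed on an independent
  random rectangle. At level 1 the recovered maps agree strongly
  (mean V ≈ 0.92 over 10 seeds); at level 0 they share only residual
  spatial structure (mean V ≈ 0.38); the mean V rises monotonically with
  the level.

What the generator does **not** emulate: environmental niches and climatic
gradients (ranges are purely spatial random blobs), range-size and
richness gradients, species abundances, sampling error in occurrences, and
macroevolutionary realism beyond Yule (no extinction, no diversification
rate shifts). Passing tests therefore demonstrate that the pipeline
recovers regional structure of the kind the method presupposes — not that
any real fauna has such structure, nor how the method behaves under strong
niche-driven range overlap.

## Problem sizes and numerical choices

The test suite and the acceptance script run the standard scenario (144
cells, 120 species) for 50 replicates, the congruence sweep at 5 levels ×
10 replicates, 2000 stochastic maps for Monte-Carlo/exact comparisons on
6-tip trees, and 100 random tree/grid pairs for the standardization
invariants; these sizes keep a full run to a couple of minutes on one CPU
while leaving the Monte-Carlo tolerances (3 standard errors) meaningful.
Key tolerances: matrix standardization 1e-12, PCoA reconstruction 1e-8,
eigenvalue floor −1e-10 after the square-root transform, pruning vs
enumeration 1e-10, ultrametricity 1e-9 relative. Degenerate inputs are
handled explicitly: identical assemblages give a single region (k = 1)
rather than an error; all-identical tip states pin the Mk rate low with a
warning; a singular within-group covariance in the discriminant step is
regularized with a warning.

## Known limitations

* The elbow rule operates on the k-means WSS curve; ecosystems whose
  turnover is strongly hierarchical (one deep split dominating the
  ordination) can register the coarse split rather than the finest
  regional structure. This mirrors the behaviour of chord-based elbow
  rules generally and is the reason the synthetic scenario conditions on
  comparable basal divergences.
* Affiliation and transition zones depend on the dissimilarity space
  (sqrt-BC here); zones are descriptive, with a configurable quantile, not
  an inferential boundary test.
* The Mk model assumes a single symmetric rate and a uniform root prior;
  regions gained and lost at different rates would violate it.
* PCoA axes are only defined for the fitted cell set; adding cells
  requires refitting the whole ordination.
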
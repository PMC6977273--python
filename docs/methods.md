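# Methods

## Scope and model

`genecontent` analyses how gene content and protein domain architecture
change along a rooted, dated (ultrametric) phylogeny. Its inputs are a
newick tree with branch durations in millions of years (My), a families x
species matrix of non-negative gene counts (one row per orthologous gene
family, absences as explicit zeros), and optionally per-species tables of
protein domain arrangements and a second, topologically identical tree with
branch lengths in substitutions per site. The package reconstructs ancestral
states, tallies and tests per-branch change, estimates per-My rates, and
classifies domain-arrangement changes into discrete event types. A
synthetic-data generator with logged ground truth stands in for real
datasets in all tests.

## Ancestral gene counts: Wagner parsimony

Gene family size is treated as an ordered integer character; the
reconstruction minimizes the total absolute change summed over branches
(Wagner criterion). The implementation is a Sankoff dynamic program over the
states 0..max(tip count): each node carries a cost vector
`c_v(s) = sum_children min_t(|s - t| + c_child(t))`, with the inner
minimization done in O(S) by a forward and a backward sweep. Multifurcating
nodes are handled by summing child contributions; polytomies are never
resolved into arbitrary binary splits.

Minimal-cost assignments are generally non-unique (optimal states form
intervals). The tie-break is: the root takes the smallest optimal state,
then each child, top-down, takes the smallest state optimal given its
parent's chosen state. This is deterministic and biases ambiguous histories
toward later gains rather than earlier gains followed by losses
(Dollo-leaning). Branch-level tallies (expansions, contractions,
extinctions, emergences) therefore depend on this documented convention
wherever the optimum is not unique; the total cost never does.

Definitions used by the tallies:

* expansion/contraction on a branch: reconstructed child count above/below
  the parent count (a family counts once per branch regardless of
  magnitude);
* extinction on a branch: parent count > 0 and child count = 0; a family
  is counted once in the "extinct in at least one lineage" aggregate however
  many branches lose it;
* origin (emergence) nodes of a family: nodes with count > 0 whose strict
  ancestors all have count 0. Families present at the root are ancestral and
  have no origin. Because the tie-break can produce disjoint presence
  islands, a family may have several candidate origins; the global
  "families emerged" aggregate counts a family once if it has at least one,
  while `emergent_families(node)` returns only families whose candidate set
  is exactly the queried node (equivalently: absent from every tip outside
  that node's clade).

The taxon jackknife removes a fixed number of random species per replicate,
prunes the tree (durations re-summed across suppressed degree-2 nodes;
suppressed labels disappear), re-reconstructs, and reports per surviving
internal node the spread of total reconstructed gene counts across
replicates. All resampling is driven by a single seeded generator.

## Rapid-change statistic

Under a stochastic birth-death view of family-size evolution, the expected
relationship between a node and its direct descendant is no change: points
(parent count, child count) fall on the one-to-one line. For each family the
per-branch differences `d_b = child - parent` are compared to that line; the
family's spread is the RMS of the differences about zero,
`sd = sqrt(mean(d_b^2))`, not about their mean, because the null is the 1:1
line itself (a `center=True` switch provides the mean-centered variant for
sensitivity analysis). A branch is flagged iff `|d_b| > k * sd` with k = 2
by default; the inequality is strict, so constant families (sd = 0) never
flag. Both branch-level flag totals and the deduplicated count of families
with at least one flag are reported. Under a symmetric constant-variance
null, Chebyshev bounds the flagged fraction at 1/k^2 = 25%; empirically it
is far lower (the discreteness of small integer noise concentrates |d| well
below 2 sd).

## Unobserved-loss (extinction) correction

Reconstructed totals at old nodes are underestimates because a gene lost in
all sampled descendants leaves no trace. The correction regresses the total
gene count at each internal node (OLS, via `scipy.stats.linregress`) on the
node's age in My. The intercept — the predicted value at age 0, the present
day — is the expected count with no unobserved loss; each node's corrected
count is `intercept + residual(node)`, i.e. the observed count shifted so
that residual structure about the fit is preserved
(`corrected = total - slope * age`). Tips are excluded (age 0 would anchor
the intercept to observed data); the root is included by default with a
toggle. The regression requires at least three internal nodes and at least
two distinct ages, else it raises a degenerate-regression error.

## Rates of change per My

All rate tables share one form: per non-root branch, a numerator divided by
the branch duration in My. Numerators are (i) branch length in
substitutions/site from the unsmoothed tree, joined to the dated tree by
child node label; (ii) the number of gene families changing on the branch
(expansions + contractions — disjoint family sets per branch); (iii) the
number of solvable domain rearrangement events. Zero-duration branches stay
in the table but are flagged undefined and excluded from summaries. Summary
mean is unweighted over branches with sample SD (ddof = 1); a time-weighted
alternative (total numerator / total duration) and an exclusion list for
known outlier lineages are available.

A caveat that matters for simulation experiments: the unweighted mean of
per-branch ratios is ill-conditioned when any branch duration approaches
zero (both its sampling variance and the parsimony attribution error on that
branch scale like 1/t). The rate-recovery experiment in
`scripts/acceptance.py` therefore conditions on simulated trees whose
branch durations are all at least 2 My.

## Domain arrangement evolution

Each protein is reduced to its domain arrangement: the N-to-C ordered tuple
of domain identifiers with consecutive repeats collapsed (A-B-B-B-C becomes
A-B-C; non-adjacent duplicates are kept). Per gene only the longest isoform
is kept (length ties break to the smallest protein id). A node's proteome is
a *set* of arrangements — copy number is ignored, consistently with repeat
collapsing.

Ancestral content uses a combined parsimony: every arrangement follows
Dollo parsimony (a specific arrangement arises once; it is present on the
minimal connected subtree spanning the tips that carry it), while every
single domain's presence/absence follows unordered binary parsimony (the
same unit-cost DP as the gene counts, over states {0,1}, ties resolved
toward absence). A node's domain set is the union over its arrangements
plus domains inferred present on their own; this lets a domain survive at a
node inside arrangements that themselves did not.

Per branch, every arrangement present at the child and absent at the parent
is tested against all single-step derivations from the parent content:

* fusion — order-respecting concatenation of two distinct parent
  arrangements (no circular permutations or interleavings);
* fission — the new arrangement is one piece of a parent arrangement split
  in two, and the sibling piece is observable at the child; the split counts
  once even though it yields two new arrangements;
* terminal loss — a parent arrangement minus one terminal domain; if the
  dropped domain survives as its own arrangement at the child the change is
  the corresponding fission instead;
* terminal emergence — a domain *novel to the parent proteome* added at
  either end of a parent arrangement;
* single-domain emergence — a novel domain appearing as its own
  arrangement;
* single-domain loss — keyed on domains rather than arrangements: a domain
  present in the parent's proteome-wide domain set and absent from the
  child's.

A change explained by exactly one derivation takes that type; zero
derivations is "unsolved", more than one (even within a type) is
"ambiguous"; both are excluded from event counts and the per-type
percentages, which are normalized over solvable events only.

## Synthetic data generator

The generator defines the study conditions for every test. Defaults: a
16-tip random coalescent-style ultrametric tree of height 500 My
(exponential merge spacings, rescaled); 500 families with root sizes
geometric with mean 3; per-family Poisson gains and per-copy exponential
survival (binomial thinning) at 6e-4 /My each, so a typical family changes
about once along a root-to-tip path — the regime in which parsimony is
meaningful; optional family origination seeded at branch midpoints, making
each originated family's origin node unambiguous. A complete event log is
kept, and replaying it from the root states must reproduce the simulated
counts exactly (tested).

Arrangement histories start from 40 random arrangements over a 500-domain
alphabet and apply the six event types at per-My Poisson rates proportioned
roughly as in real proteomes (fusions dominant, then losses, then fissions;
novel-domain emergences rare), scaled to the small simulated repertoire.
Every applied event is post-checked to be single-step identifiable from the
branch's parent/child snapshots; otherwise the branch is re-drawn (capped,
then a simulation error). The classifier round-trip on true snapshots is
therefore exact by construction — which is precisely what it is meant to
test: that classification inverts generation. What these tests do *not*
show: real proteomes contain ambiguous and multi-step changes that the
pipeline deliberately discards, and Dollo/Fitch reconstruction of deep nodes
from tips alone misplaces some events (convergent fusions, piece-wise
survival of fission products), so event proportions measured on
reconstructed (rather than true) node sets are biased; both limitations are
inherent to the method, not artifacts of the simulator.

Parsimony systematically undercounts when multiple changes hit one branch
or parallel identical changes hit sibling branches; on simulated data the
per-family parsimony cost is verified to never exceed the true number of
change units.

## Numerical and interface conventions

* Newick dialect: quoted labels and bracket comments are rejected loudly
  rather than silently normalized; branch lengths are mandatory; internal
  labels are kept verbatim, unlabeled internal nodes get their preorder
  index as label. Writers emit byte-stable output.
* Counts are dense int64; absences are explicit zeros (required by the
  extinction logic).
* All stochastic components take explicit integer seeds and use
  `numpy.random.Generator`; identical seeds give byte-identical outputs.
* The pipeline's JSON summary contains no timestamps, so reruns on the same
  inputs are byte-identical; it records the package version, seed, and a
  hash of the config.

## Problem sizes

Tests and the acceptance script run at desk scale by design: trees of 5–16
tips, hundreds of families, a few hundred simulated domain events. The
exhaustive parsimony oracle enumerates all internal assignments for trees of
up to 6 tips and counts up to 4 (at most 5^5 assignments), against which the
dynamic program is checked on 500 random instances. The implementation
itself has no small-size assumptions: cost vectors scale linearly in the
maximum count and reconstruction is linear in nodes per family.

## Known limitations

* With non-unique parsimony optima, branch-level tallies follow the
  documented tie-break; other equally parsimonious conventions give
  different (equally defensible) per-branch numbers with the same total
  cost.
* The rapid-change test is a descriptive flag, not a calibrated hypothesis
  test; its null is the 1:1 line with family-specific empirical spread.
* The unobserved-loss correction is a linear extrapolation; nothing
  enforces non-negativity or saturation of gene counts at age 0.
* The Wagner criterion weighs gains and losses equally by default;
  `gain_cost`/`loss_cost` on the reconstruction functions provide the
  asymmetric linear-cost variant for sensitivity analysis, but all reported
  tallies use the symmetric default.
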
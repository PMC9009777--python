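# Methods

## The quartet model

The model describes one alignment column on the minimal duplication tree:
a duplication node, two pre-speciation branches `b1, b2` of length `t1`,
and four post-speciation branches `b3..b6` of length `t2` leading to the
leaves `Xa, Ya, Xb, Yb` (species group X/Y × paralog copy a/b).
Assumptions:

1. equal branch lengths between the two paralog clades (`b1 = b2`,
   `b3 = b4 = b5 = b6`);
2. zero or one substitution per branch;
3. a substitution replaces the residue by one of the other 19 amino acids,
   uniformly;
4. no selection;
5. the substitution probability on a branch is `P = 1 − exp(−t)`.

Each of the `2^6 = 64` binary branch configurations has probability
`Π_b P_b^{s_b} (1 − P_b)^{1 − s_b}`. Given a configuration, the match
probability of a leaf pair is computed exactly under the uniform jump
chain `J` (`J[a][b] = 1/(A−1)` for `b ≠ a`, zero diagonal):
`m = Σ_x [J^{k_u}]_{c,x}[J^{k_v}]_{c,x}` where `k_u, k_v` count the
substitutions on each leaf's private path below the pair's most recent
common ancestor. This is independent of the ancestral state `c` and
handles the case where the match probability depends on the state of the
ancestor before speciation (e.g. substitutions on an internal branch plus
a leaf branch). The alphabet size is a parameter (default 20) so the
formulas can be cross-checked by exhaustive enumeration on tiny alphabets.

The seven outcome categories are evaluated per configuration from the pair
match probabilities (inner matches `mi` between orthologs, outer matches
`mo` otherwise):

- conserved: `mi1 · mi2 · max(mo…)` — the max over outer matches is an
  approximation of the conditional probability of all leaves matching;
- type-1 divergence: one copy conserved across species, the other not,
  with no cross matches;
- type-2 divergence: both copies conserved within themselves but differing
  from each other: `mi1 · mi2 · (1 − P_cons|conf)`;
- recent divergence: exactly one leaf differs from the other three (four
  terms, one per diverging leaf);
- inversion: `mo(Xa,Yb) · mo(Ya,Xb) · (1 − min(mi1, mi2))`;
- species-specific adaptation (SSA): `mo(Xa,Xb) · mo(Ya,Yb) · (1 − min(mi1, mi2))`;
- non-conserved: the residual `1 − Σ(others)`, clamped at zero (a clamp
  larger than 1e−9 raises a warning; because conserved/type-1 use max/min
  approximations the six explicit categories are not an exact partition).

Because match probabilities depend only on integer path counts, the
category probabilities are polynomials in `(1 − e^{−t1}, 1 − e^{−t2})`;
grid evaluation (heatmaps, the 1% rarity bound) is therefore exact and
fast. The default heatmap grid is 50×50 linear over `(0.02, 5.0]`
substitutions/site, spanning everything from near-identity to saturation.

Exactness is checked two ways: match probabilities against brute-force
path enumeration (alphabets 2, 4, 20), and category probabilities against
a Monte-Carlo simulation of the quartet (sampled branch substitutions and
uniform jumps, match rules applied to the sampled residues). Monte-Carlo
agreement is within ±0.02 per category, not exact, precisely because of
the max/min approximations above.

**Branch lengths from a real tree.** `expected_inversion_probability`
estimates `t1` as the mean path length from the duplication node (the root
split separating the paralog clades) to each paralog clade's species-split
node (the MRCA of its grouped leaves), and `t2` as the mean split-to-leaf
path length. This convention is logged on every call; other conventions
(e.g. median, or per-group split nodes) would be defensible, and the
estimate should be read as an order-of-magnitude expectation.

## Scoring

Per column, each group's residues (gaps `-` and unknowns `X` excluded)
give a length-20 frequency array. Pseudo-count smoothing is a
Dirichlet-style blend `f' = (n·f + β·g)/(n + β)` with `β = 5` by default
and the LG stationary frequencies as background `g`. The cited
pseudo-count literature admits substitution-matrix-weighted variants; the
simple blend is used here because it has one interpretable parameter
(`β` = prior observations) and the background vector is configurable.
"LG as background" is interpreted as the LG model's stationary frequency
vector.

The match probability between groups is the dot product of their arrays.
The inversion score is computed in the division-free algebraic form

```
Σ_i Xa[i]·Yb[i]·(M(Ya,Xb) − Ya[i]·Xb[i])
```

which equals the two-step form (conditional probability × both cross
matches) wherever the latter is defined and is zero when either cross
match is zero, avoiding 0/0. The SSA score is the same form with the Xb
and Yb arrays exchanged. Scores are clamped to [0, 1].

Scanning conventions:

- the gap threshold (default 60%) applies to the whole column over all
  assigned sequences, not per group; separately, a column with an empty
  group is skipped with a logged reason;
- with multiple candidate groupings each column reports the maximum
  inversion score and the grouping achieving it;
- the percentile threshold uses numpy's linear interpolation, and
  selection is *strictly above* the threshold;
- percentile thresholds are the only multiplicity control — no FDR
  machinery, matching how the score is meant to be used;
- reported positions are 1-based; the conservation columns are the modal
  residue's identity fraction over all copy-a (resp. copy-b) sequences
  jointly (mean pairwise identity is an alternative convention; the modal
  identity is cheaper and monotone in the same signal);
- if the reference row is gapped at a column, the nearest preceding
  ungapped position is reported with an `exact=False` flag.

## Simulated evolution

Null alignments evolve down the user's tree under JTT or LG
(exchangeabilities and stationary frequencies bundled as plain-text data
files). The generator `Q` is assembled as `S·diag(π)`, symmetrized rows to
zero, normalized to mean rate 1; transition kernels `exp(Q r t)` come from
the symmetrized eigendecomposition (stable for any branch length). Rate
heterogeneity is discrete gamma with equal-probability categories whose
rates are conditional bin means, so they average to 1 exactly; the default
is 4 categories, and the shape is a free parameter (the original analyses
report rate heterogeneity without printing either value). Root sequences
are drawn from the stationary distribution ("random amino acids"
interpreted as a stationary draw); a uniform draw is available via
`root_from="uniform"`. Missing branch lengths are an error — a silent
default would bias the null.

## Tree comparison

Pairwise distances: BLOSUM80 similarity summed over mutually ungapped
columns, min-max normalized per pair (upper bound = mean of the two
self-scores over the same columns; lower bound = smallest matrix entry ×
shared length), distance = 1 − normalized similarity. The normalization
convention is this package's choice (the original used a numerical
environment's default, which is not recoverable); it is documented in
output metadata and fixture-tested, not claimed identical.

Neighbor joining delegates to scikit-bio and recovers additive matrices
exactly. The Nye et al. similarity is one-sided: each internal bipartition
of the first tree scores `max` over the second tree's bipartitions of
`max` over the two consistent side pairings of `min` of the two Jaccard
overlaps; `max_score` is the first tree's internal edge count (matching a
reported denominator tied to one tree). A symmetrized average can be
computed by calling it both ways.

The bootstrap experiment excludes columns with ≥ 90% gaps, samples columns
with replacement at each requested length (resampling when a sequence
would be all-gap), and compares the inverted-sites tree's similarity to
the full tree against the shortest-length bootstrap distribution with a
one-sided one-sample t-test.

## Synthetic data

The generator defines the study conditions for all end-to-end checks:
8 + 8 species, `t1 = 0.3`, `t2 = 0.1` substitutions/site (a moderately
diverged duplication where the model's inversion probability is ~5×10⁻⁴),
2000 sites under JTT with gamma shape 1.0 (4 categories), 10 planted
inversion columns, 5% per-leaf noise on planted columns. The tree mirrors the same
balanced ultrametric species tree inside both paralog clades (paralog
stems `t1`, species-group stems `t2/2`, within-group depth `t2/2`), so
every leaf sits `t1 + t2` below the duplication node and the quartet-model
branch lengths are recovered exactly from the tree. Planted columns are a
deterministic overwrite (Xa/Yb one residue, Ya/Xb the other; the SSA
pattern analogously) plus independent per-leaf noise, giving an exact
truth set while allowing power curves.

What the generator does *not* emulate: indels beyond none at all (all
simulated columns are gap-free), domain architecture and compositional
heterogeneity of real proteins, unequal clade sizes, gene loss, and
alignment error. Passing the planted-recovery check therefore shows the
statistical machinery works at realistic divergence and noise levels — not
that real datasets with alignment artifacts will behave as cleanly.

## Problem sizes

End-to-end checks use 32-leaf trees with 2000-site alignments (20 seeds
for the recovery medians), 10^6 replicates for the Monte-Carlo category
oracle at 5 grid points, and 500 bootstrap replicates at length 20 for the
tree experiment; these sizes make the full suite run in well under a
minute while keeping Monte-Carlo error far below the tested margins.

## Known limitations

- The quartet model allows at most one substitution per branch, so
  saturated regimes (`t` ≫ 1) are summarized by the non-conserved residual
  rather than modeled in detail.
- Only binary paralog classifications and two species groups are
  supported; additional duplications (e.g. a nested whole-genome
  duplication) must be pruned or collapsed first.
- Automatic grouping requires species identities; by default they are
  derived by stripping the trailing underscore-delimited token from leaf
  labels, which matches the synthetic fixtures but real datasets will
  usually need an explicit mapping file.
- The conserved/type-1 category formulas are approximations (max/min in
  place of exact joint conditionals); the residual category absorbs the
  slack, and Monte-Carlo agreement is ±0.02, not machine precision.
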
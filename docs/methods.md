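# Methods

## The model

The package measures phylogenetic signal in binary (presence/absence)
traits on rooted phylogenies. The quantity d is the total absolute change
in estimated node values over all edges, where tips carry their observed
0/1 and every internal node carries the unweighted mean of its two
children. The D statistic standardizes the observed d between the
expectations of two null processes evaluated with the identical d operator:

    D = (d_obs − E[d | threshold-Brownian]) / (E[d | shuffle] − E[d | threshold-Brownian])

Both expectations are estimated by Monte-Carlo (default B = 1000
replicates each). The shuffle null permutes the observed values over tips,
so prevalence k is preserved exactly. The threshold-Brownian null simulates
a continuous character from the root with independent normal increments of
variance equal to branch length per edge, ranks the tips, and marks the k
highest present.

### Conventions and why they are safe

- **Nodal estimation**: unweighted mean of the two children, branch lengths
  ignored in d. The construction is self-calibrating: because the observed
  trait and every null replicate pass through the same d operator, the
  expectation of D is 0 under threshold-Brownian generation and 1 under
  shuffling *for any internally consistent nodal convention*. The
  calibration experiments assert exactly this, and the brute-force oracle
  used in the tests implements the same convention independently (exact
  rational arithmetic, direct recursion).
- **Branch lengths** enter only the Brownian simulation. Trees without
  lengths get unit lengths with a warning; a tree whose lengths are all
  zero is rejected ("no Brownian variance").
- **Root value and scale** of the Brownian simulation are fixed at 0 and
  σ² = 1; thresholding by rank makes both choices irrelevant (location/scale
  invariance, asserted by a test that scales all branch lengths).
- **Ties** in the tip ranking (possible only across zero-length edges) are
  broken by a seeded random key, keeping replicates deterministic.
- **p-values** are one-tailed empirical proportions without the +1
  correction: `p_random = #{d_shuffle ≤ d_obs}/B` (more clumped than
  random), `p_brownian = #{d_brownian ≥ d_obs}/B` (more dispersed than
  Brownian). A `plus_one` flag switches both to (r+1)/(B+1).
- **Regime labels**: S (D < 0), B0 (D = 0 exactly), W (0 < D < 1),
  R (D ≥ 1), and OD replacing R when D > 1 and the shuffle null's *upper*
  tail is below alpha (p_random > 1 − alpha). The significance flag is
  p_random < alpha (default 0.05).
- **Degenerate normalization**: if the two null means differ by less than
  1e-9 the estimate is refused rather than divided.
- **Power floor**: estimates on trees with fewer than 25 tips warn; the
  screen skips such clades by default (`min_tips = 25`), since the
  statistic has little power there.

### Tree handling

- Newick reading/writing is delegated to dendropy (quoted labels and
  bracket comments accepted); the in-memory container is a minimal rooted
  node tree validated for unique non-empty tip labels, single root, and
  non-negative lengths.
- **Polytomies** are resolved by left-to-right nesting in child order with
  zero-length internal edges. Zero-length edges add no Brownian variance
  and leave root-to-tip path lengths unchanged, so the resolution does not
  perturb the null.
- **Collapsing a species tree to families** keeps, for each family, the
  first of its tips in a postorder traversal, relabeled to the family name;
  unmapped species are pruned (count logged) and non-monophyletic families
  trigger a warning. The exemplar rule is a package decision — any
  deterministic choice of one representative per family yields the same
  family-level topology when families are monophyletic.
- **Clade extraction**: explicit member sets give the induced subtree
  rooted at the members' MRCA (stem removed, unbranched nodes suppressed
  with lengths summed); anchor pairs give the complete subtree at their
  MRCA.
- **Ages** run backward from the tips; ultrametricity is required within a
  relative tolerance of 1e-6 of tree depth (published calibrated trees
  carry rounding noise). At an exact node age the edge above the node
  counts as crossing; the root lineage counts for ages at or beyond the
  root.

### Trait matrices

Cells are ternary — present / absent / unknown — and collapse to binary
for analysis with unknown → 0, matching the survey coding rule "1 if
present in at least one taxon of the family, 0 if absent from or unclear
in all known taxa". The ternary states are stored distinctly so absence
and missing data remain separable for future re-analysis, even though the
statistic cannot distinguish them. "Usable data" means ≥ 1 class present
for the family. Family-name matching is exact after whitespace trimming;
a synonym-table hook handles taxonomy drift as data, not code guesses.

### Screening and robustness

The screen derives each cell's seed from a stable hash of (master seed,
clade name, class name), so the table is bit-for-bit reproducible and
independent of cell execution order. Ineligible cells produce
machine-readable skip rows (`min_tips`, `degenerate_prevalence`,
`clade_not_found`) rather than aborting the grid.

Subsampling demotes present cells to unknown: exactly round(fraction ×
n_present) presences are retained (half-up, minimum 1), drawn uniformly
across the whole matrix; a stratified-by-class mode exists for sensitivity
analysis. The robustness experiment's subsampling seed is hashed from
(master seed, fraction, repetition) while the screen inside each repetition
reuses the master seed, so at fraction 1.0 the experiment reproduces the
plain screen exactly — the identity the tests assert. Multiple-testing
correction is off by default (a Benjamini–Hochberg flag adds an adjusted
column).

### Temporal mapping

`trait_lineages_through_time` counts, at each age t, the branches crossing
t whose descendant tips include at least one presence — a Dollo-style
minimal mapping that needs no ancestral-state model. At t = 0 it equals
the class prevalence on the tree; it is non-increasing in t and bounded by
the plain lineage count. It is a descriptive summary of when trait-bearing
lineages proliferated, not a reconstruction of trait origins, and the
pipeline treats it as such.

## Synthetic data

The generator emulates the shape of a family-level chemotaxonomy study:

- **Tree**: Yule (pure birth) with configurable size and birth rate — no
  extinction, since the analyses make no demographic claims; expected depth
  ~ ln(n)/λ, verified by Monte-Carlo.
- **Regimes** per trait column, all returning exactly k = round(prevalence
  × n) presences:
  - `brownian_threshold` — the estimator's own null simulator (one shared
    code path; a test asserts byte-identical draws for identical seeds);
  - `random` — uniform k-subset of tips;
  - `clumped` — fill the clade whose size is nearest k, trimming to the
    clade's first k tips or topping up with the nearest outside tips by
    edge-count path distance (ties by label);
  - `overdispersed` — recursive proportional allocation of the quota
    between the two child subtrees at every node (half-up, extra to the
    left), which maximizes sister-pair disagreement at each split and
    reduces to one presence per cherry on balanced trees at half
    prevalence.
- **Preset** `paperlike`: 437 families × 8 classes with per-class presence
  counts fixed at 245/221/206/175/167/162/153/82 (prevalences are target
  counts, not probabilities, so column sums are exact), all columns
  threshold-Brownian.

What passing tests on these data do and do not show: the generator
reproduces marginal prevalences and known signal regimes, but real trait
matrices have correlated classes, phylogenetically structured missingness,
and trees with calibration error and non-random polytomies — none of which
are simulated. Calibration results transfer to real data only insofar as
the statistic's self-calibration is distribution-free over regimes, which
is the property the experiments demonstrate.

## Calibration experiments and problem sizes

All experiments live in `psmphylo.calibration` and derive every seed from
one master seed via stable hashing:

- **Self-calibration**: one 200-tip Yule tree, prevalence 0.3, B = 500,
  100 replicate traits per regime. Checks mean D ∈ (−0.1, 0.1) under
  threshold-Brownian generation, ∈ (0.9, 1.1) under shuffling, and D < 0
  for ≥ 95% of single-clade clumped traits.
- **Regime ordering**: 50 independent studies (200 tips, 4 regimes,
  B = 500); the estimated D must order clumped < brownian < random in
  ≥ 95% of studies.
- **p uniformity**: 500 shuffle-generated traits on a 200-tip tree,
  B = 200; Kolmogorov–Smirnov test of p_random against Uniform(0,1) at
  α = 0.01. (The empirical p is discrete with resolution 1/B and carries a
  small positive tie bias; both are an order of magnitude below the KS
  critical distance at these sizes.)
- **Subsampling stability**: one strongly clumped trait on 200 tips,
  95% coverage, 20 repetitions, B = 500; significance-flip rate ≤ 0.05.

These sizes put each experiment at seconds to a couple of minutes on one
core while keeping Monte-Carlo standard errors several times smaller than
the tolerance bands; they are the package's stated study conditions, not
tuning knobs.

## Known limitations

- The full-scale reproduction of the published whole-tree D values
  requires the original trait matrix and published family-level tree,
  which are external downloads; the package ships the loaders and the
  screen, and the synthetic preset reproduces the printed distribution
  counts by construction, but the printed 6-decimal D values are not
  reproducible in principle (Monte-Carlo noise at B = 1000 alone exceeds
  that precision, and the original analysis's polytomy and estimator
  conventions are unstated).
- d is purely topological; using branch-length-weighted nodal estimators
  would define a different (also self-calibrating) statistic and is not
  implemented.
- Classes are analyzed marginally; correlated evolution between classes is
  out of scope.
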
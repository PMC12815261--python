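# Methods

This note records the models, conventions and numerical choices behind
`ptbt`, and what the synthetic test conditions do and do not demonstrate.

## Wavelet basis and transform

For a rooted tree the basis contains one two-block contrast per binary
split. At a node whose split separates ℓ "left" leaves from r "right"
leaves, the wavelet takes the value +√(r/(ℓ(ℓ+r))) on every left leaf and
−√(ℓ/(r(ℓ+r))) on every right leaf: unit L2 norm, zero sum, constant
within blocks. A node with c > 2 children yields c − 1 sequential
contrasts — contrast k opposes the pooled leaves of children 1..k against
child k+1 — which keeps the total wavelet count at exactly n − 1 for any
tree (binary or multifurcating) and preserves orthonormality without
forcing an arbitrary binarization of polytomies. One wavelet is emitted
per bifurcation *including the root split*: that is what makes the count
n − 1 and the variance decomposition complete.

Conventions and properties:

- **Sign.** Earlier children weigh positive. Only coefficient magnitudes
  matter downstream (variance fractions are squares); tests compare
  against oracles up to sign.
- **Branch lengths are ignored by the basis.** The decomposition is
  purely topological; lengths enter only patristic distances and the
  Brownian-motion simulation. Trees without lengths get 1.0 per edge
  (logged) where lengths are needed.
- **Traits enter untransformed.** Variance fractions are invariant to
  affine rescaling of a trait, so no standardization is applied before
  the transform.
- **Fast path.** Coefficients are computed in a single postorder pass
  from subtree sums and counts, c = √(ℓr/(ℓ+r))·(mean_L − mean_R), O(n)
  per trait; the test suite verifies equality (1e-10, up to sign) with an
  independent dense Gram–Schmidt construction on subtree indicator
  vectors processed parents-first with each node's child indicators in
  reverse order — the ordering under which Gram–Schmidt reproduces the
  two-block weights exactly.
- **Degenerate traits.** A trait whose total sum of squares is at
  floating-point zero (relative threshold 1e-12 of n·max²) gets all-zero
  fractions and a degenerate flag rather than a division by zero.
- **Cumulation uses squared normalized coefficients** (variance
  fractions), not raw magnitudes: only squares are variances, and only
  they are guaranteed to sum to 1 by Parseval's identity.

## Selection

Per trait, wavelets with nonzero fraction are sorted by descending
fraction, ties broken by ascending wavelet id (zero-padded ids make the
lexicographic order numeric; real data essentially never ties, but
synthetic fixtures do). The shortest prefix whose cumulative fraction
reaches τ is selected, including the crossing node; a 1e-9 slack absorbs
accumulated floating-point error so τ = 1 selects every nonzero wavelet.
This makes selection monotone in τ and minimal (dropping the last
selected node falls below τ). The default τ = 0.60 keeps the collapsed
table legible while retaining most trait variance; it is a
legibility/fidelity dial, not an estimate.

## Collapse

A preorder traversal marks node N as a cell when N is a leaf, or when the
subtree rooted at N — *including N itself* — contains no protected node.
The inclusive reading matters: under the exclusive alternative
("descendants only"), protecting exactly the root would still collapse
everything into one cell, defeating the purpose of protecting it; both
readings are exercised in the unit tests and the inclusive one is the
implementation. Cells are therefore the maximal subtrees disjoint from W
(verified against an independent leaf-upward brute force), they partition
the leaves, and every protected node survives as an internal node of the
collapsed tree. Collapsing can create unary pass-through nodes; these are
suppressed with branch lengths summed, so a cell's branch length is the
full path from its retained parent down to its ancestral node. A cell is
identified by that node's clade id ("c" + zero-padded postorder index;
assignment is deterministic and idempotent).

## Brownian-motion null and the co-occurrence statistic

Traits are simulated independently along the tree (child = parent +
Normal(0, σ²·bl), σ² = 1, root value 0, 100 replicates by default); leaf
covariance equals σ² times shared root-to-leaf path length, which the
tests check by Monte Carlo. Each replicate set is pushed through the
identical transform → selection path as the observed data.

The headline statistic is **T = max over nodes of the summed per-trait
variance fractions** — the largest total variance share co-attributed to
a single split. The count of nodes selected at τ by ≥ 2 traits (S) is
computed and reported with its full histogram, but it is *not* the test
statistic, for a measured reason: under Brownian motion the expected
squared coefficients concentrate on deep, long-branch splits for every
trait, so thresholded selections already overlap heavily (null S ≈ 10 on
a 200-leaf Yule tree with six traits), while a genuine shared shift
*concentrates* each trait's selection onto a single node and so drives S
*down*, not up. T grows directly with shared signal, is calibrated by
construction (observed and null are exchangeable under the null; we
verified P(p ≤ 0.1) ≈ 0.095 over 200 runs), and detects a shared
10σ shift at the minimum attainable p (1/101) with a z-score around 6.
The empirical p-value uses the add-one estimator
p = (1 + #{null ≥ obs})/(reps + 1), so p is never 0 and is exact under
exchangeability. Binary observed traits enter selection as-is while the
null remains continuous — a documented simplification. A leaf-permutation
null (per-trait row shuffles) is available as a secondary,
tree-structure-destroying comparison.

## Layout

Patristic and trait dissimilarities are each divided by their median
off-diagonal entry (a scale-free normalization that keeps the blend
meaningful when the two matrices live on very different scales) and
combined as α·phylo + (1−α)·trait, α = 0.5 by default since neither view
is privileged. The blend is embedded with t-SNE on the precomputed
dissimilarity (perplexity 50 clamped to (m−1)/3 for small m, 4000
iterations, fixed seed; below 4 points, classical metric scaling with a
deterministic sign convention). This 2-D stochastic-neighbor embedding is
a deliberate, documented stand-in for a multi-perspective 3-D embedding
whose flattened projection would serve the same purpose — gathering cells
similar in either view — at far greater implementation cost; α exposes
the phylo/trait balance explicitly instead. Grid snapping solves the
rectangular linear assignment of cells to lattice slots spanning the
coordinate bounding box, minimizing total squared displacement (verified
exhaustively for ≤ 7 cells). k-means (10 restarts, fixed seed) labels
grid regions 1..k in reading order of their centroids. The SVG renderer
maps each trait to one channel (fill color, inner-square size, hatch
density, or a glyph for binary traits) and is byte-deterministic.

## Synthetic data: what it emulates and what it does not

`yule_tree` draws pure-birth trees (waiting time Exp(rate·k) with k
lineages; expected root-to-leaf depth Σ_{k=2..n} 1/(k·rate), checked by
Monte Carlo); `caterpillar_tree` covers the maximally unbalanced
worst case. `plant_shift_traits` adds a constant δ to every leaf under
the *first child* of the named node, on top of one Brownian-motion draw.
Naming the node whose own contrast carries the jump is the useful
convention: a constant added to a node's *entire* subtree is orthogonal
to that node's wavelet (it cancels between the blocks) and would instead
be detected at an ancestor, making "recovery of the shifted node"
ill-posed. δ is in raw trait units; `bm_root_to_leaf_sd` converts the
tree's Brownian scale so effect sizes can be stated as multiples of the
root-to-leaf standard deviation. `binarize_latent` thresholds latent
continuous traits at an empirical quantile, emulating binary calls such
as autotrophy.

Planted-shift study conditions, chosen once: shift nodes are internal
nodes whose first-child clade and opposing block each hold at least a few
leaves (≥ 4 for single-trait recovery at n = 500, ≥ 8 for the shared-
shift power setting) *and* whose first child is no larger than the
opposing block. The size floor avoids single-leaf contrasts that carry
almost none of the planted variance; the balance condition guarantees the
planted node's deterministic contribution strictly exceeds every
ancestor's (for an ancestor opposing blocks of sizes A ≥ ℓ+r and B, the
squared contribution ℓ²B/(A(A+B)) < ℓr/(ℓ+r) whenever ℓ ≤ r), so
recovery failures reflect noise, not geometry.

Passing these tests shows the machinery recovers *mean-shift* structure
planted under the model's own assumptions (ultrametric pure-birth trees,
homogeneous-rate Brownian traits, shifts on clean clades). Real microbial
trait data violate all three — horizontal transfer, rate variation,
non-ultrametric reference trees, inference error in the traits
themselves — so synthetic recovery rates are upper bounds, not forecasts.

## Problem sizes and numerical tolerances

The test and acceptance runs use: the full 50 745-leaf completeness
identity (one trait; the postorder pass makes this a seconds-scale
computation), 100 × n = 500 recovery runs, 50 calibration and 20 power
runs at n = 200 with 100 null replicates, 100 collapse-oracle instances
at n ≤ 200, and 200 assignment instances at m ≤ 7 — sizes at which every
oracle (dense Gram–Schmidt, brute-force partition, exhaustive
assignment) is exact and fast. Orthonormality and oracle agreement are
asserted at 1e-10, Parseval and reconstruction at 1e-8 relative,
Monte-Carlo moments at 3–4 standard errors, and recovery/power at the
95% rates the study design targets.

## Known limitations

- Polytomy contrasts depend on child order; two rotations of the same
  multifurcation decompose variance differently across the c − 1
  contrasts (their *sum* per node is invariant, which is why selection
  unions and the T statistic aggregate to the node level).
- The null model is homogeneous-rate Brownian motion only; no
  Ornstein–Uhlenbeck or rate-shift alternatives.
- t-SNE coordinates are seed-reproducible but not stable across library
  versions; grid assignments and cluster labels inherit that.
- Binary traits enter the continuous-null comparison untransformed.
- The layout quantifies nothing: it is presentation, and distances on
  the grid should not be read as a metric.
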
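# Methods

## Model

`mixtree` induces a binary classification tree over a samples × attributes
table with one designated class column.  Internal nodes carry one of three
test forms; instances satisfying the predicate always go to the **left**
child (a fixed convention recorded in the JSON schema so that serialised
trees are portable):

| family | predicate | attribute kinds |
|--------|-----------|-----------------|
| C4.5 threshold | `v(a) >= t` | continuous |
| C4.5 category | `v(a) == c` | nominal |
| TSP | `v(a1) < v(a2)` | both continuous |
| WTSP | `v(a1) < w · v(a2)`, `w > 0` | both continuous |

Pair comparisons are strict, so ties route right; a nominal value outside a
category test's vocabulary also routes right.  Nominal splits are binary
one-category-vs-rest tests: the tree structure is binary, so a multiway
split per category is not representable.

The TSP and WTSP families implement relative-expression analysis: the
decision depends only on the relation of two features *within* a sample.
TSP rules are invariant under any monotone transformation applied to all
features of a sample; WTSP additionally resolves proportional shifts
(`a` less than 1.5× `b`) at the cost of scale sensitivity and a much larger
search space.

## Split selection

All families are ranked by the gain ratio in bits: information gain of the
induced two-block partition divided by the split information (entropy of
the branch-size distribution).  The candidate spaces are exhaustive:

* continuous thresholds at midpoints between consecutive distinct sorted
  values present at the node;
* one `== category` test per category present at the node;
* every ordered pair of distinct non-ignored continuous attributes for TSP;
* for WTSP, per ordered pair, weights at midpoints between consecutive
  distinct per-row ratios `v1 / v2`.  Since the predicate `v1 < w·v2`
  changes value only at observed ratios, this candidate set attains the
  optimum over all real weights.  Pairs whose denominator attribute is not
  strictly positive on every node row are skipped entirely: the method
  targets expression-scale (non-negative) data, and ratio semantics are
  otherwise undefined.

Ties are broken deterministically and globally: higher gain ratio, then
higher information gain, then family order C4.5 < TSP < WTSP, then lowest
(first, then second) attribute index, then smallest threshold/weight or
earliest category.  Two runs on identical input therefore return identical
splits, trees, and serialisations.

Numerical conventions (applied identically in the test-bench oracle):

* a candidate must gain more than `1e-12` bits; this guards against float
  noise resurrecting partitions whose class distribution equals the
  parent's (mathematical gain exactly 0);
* a midpoint that does not round to a value strictly above its lower
  neighbour (adjacent floats) is discarded, so the counts used for scoring
  always equal actual predicate routing;
* WTSP candidates are scored in ratio space (`v1/v2 < w`), while routing
  evaluates `v1 < w·v2`; for weights strictly between two observed ratios
  these agree except in adversarial cases engineered at the last unit of
  precision.

`max_pairs` optionally caps the pair searches: when the number of ordered
pairs exceeds it, attributes are pre-filtered to the top-`m` by variance at
the node (largest `m` with `m(m−1) ≤ max_pairs`).  Default off — searches
are exhaustive.

## Induction and stopping rules

Top-down greedy, no post-pruning (pruning is the `fold` edit).  A node
becomes a leaf when the first of these fires, in fixed order: fewer than
`2·min_node_size` rows (no legal children possible); depth = `max_depth`;
node entropy ≤ `entropy_threshold`; internal-node budget `max_nodes`
exhausted (nodes counted in breadth-first creation order, remaining
frontier becomes leaves); no candidate with positive gain and both children
≥ `min_node_size`.  `min_node_size` is enforced on children, not the
parent, so empty children can never be installed.  Leaves predict the
majority class of their rows; ties resolve to the lowest class index, and
class indices follow first appearance in the training file.

Defaults: `min_node_size = 5`, `max_depth = 10`, `max_nodes = 50`,
`entropy_threshold = 0` bits (grow until pure), `suggestion_k = 5`,
`families = {c45}`.  These are conventional C4.5-scale settings for tables
of tens-to-hundreds of samples; the tree structure is binary but the class
count is not restricted to two (entropy and gain ratio generalise
unchanged).

## Editing semantics

All edits are pure functions returning a new tree plus train/test reports
evaluated from scratch — a returned tree never carries stale statistics,
and the input tree is never mutated.  Nodes are addressed by their
root-to-node path of left/right steps (stable under serialisation).

* `update_test` preserves all descendant structure and re-routes instances
  from the edited node down.  Descendant leaf *labels* are recomputed as
  the majority of the re-routed rows, not just the counts: keeping stale
  labels would make displayed accuracy inconsistent with displayed counts.
  A leaf left with zero training rows predicts the majority class of its
  nearest ancestor that still has rows — a state only edits can create.
* `rebuild_subtree` re-induces below the (possibly replaced) test under the
  induction config.
* `unfold_all` re-induces a leaf with depth and node budgets counted
  tree-wide.  Folding a subtree and unfolding it again with the same config
  restores it exactly whenever the node budget is not binding; if the
  original induction exhausted `max_nodes`, the breadth-first interleaving
  across subtrees cannot be reproduced from a single-subtree re-induction,
  and the restored subtree may allocate its budget differently.
* `unfold_once` installs one best split without recursion and deliberately
  ignores the depth/budget rules: it is an explicit user action for
  inspecting how a split divides the data.
* Test-set rows are routed and reported but never influence structure,
  split choice, or labels.

## Synthetic data

The generator draws i.i.d. log-normal values (default location 0, scale 1
on the log scale) — strictly positive and right-skewed like expression
intensities — and labels each sample by a planted rule (threshold, pair, or
weighted pair), then flips labels independently with probability
`noise_rate`.  Defaults are the standard recovery setting used across the
test-bench: 200 samples, 50 attributes, no noise.  A companion generator
produces a nominal column with a prescribed category → class conditional
distribution.

What this does *not* emulate: gene–gene correlation, batch and platform
effects, heteroscedastic technical noise, class imbalance beyond what the
rule induces.  Passing recovery tests therefore shows that the search
machinery is correct and identifiable under clean conditions, not that the
method wins on real cohorts.

## Serialisation

Trees export to canonical JSON (fixed key order, two-space indent,
shortest-round-trip floats, trailing newline): export is byte-stable and
export → import → export is a fixed point.  Stored class counts are
validated on import — children must sum to their parent — so a corrupted
model cannot load silently.  Node ids are derived from structure (the
root-to-node path), never trusted from the file.  Validation is structural,
implemented in the importer with JSON-path error messages;
`tree.schema.json` documents the format for external producers.

## Known limitations

* WTSP search is exhaustive in pairs × ratio cuts; at hundreds of
  attributes it is markedly slower than TSP (use `max_pairs` or prior
  feature selection).
* Missing values are rejected, never imputed — silent imputation would
  change split statistics invisibly.
* No post-pruning, ensembles, cost-sensitive weighting, oblique splits, or
  surrogate splits.
* Interoperability with other tree producers is one-directional: the JSON
  schema is published, but no importer for foreign formats is provided.
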
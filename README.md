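# mixtree

Interactive **mixed classification trees** for transcriptomic and other
omics tables: binary decision trees whose internal nodes may carry any of
three test families, selected uniformly by the **gain ratio** criterion —

* **C4.5-style univariate tests** — `attribute >= threshold` for continuous
  attributes (optimal threshold searched over midpoints between consecutive
  distinct observed values), `attribute == category` for nominal ones;
* **Top-Scoring-Pair (TSP) tests** — `attribute1 < attribute2`, the
  relative-expression rule: only the *within-sample ordering* of two
  features matters, which makes the rule robust to monotone normalisation
  differences between platforms;
* **Weighted-TSP (WTSP) tests** — `attribute1 < w * attribute2` with
  `w > 0`, detecting proportional rather than purely ordinal shifts; the
  weight is searched exhaustively over midpoints of the observed per-sample
  ratios `v1 / v2`.

For class counts `(n_1, …, n_C)` at a node, `H = −Σ p_i log2 p_i` is the
node entropy; a binary split with left/right subsets of sizes
`n_L, n_R` scores

```
gain ratio = [H(parent) − (n_L/n) H(left) − (n_R/n) H(right)]
             / [−(n_L/n) log2(n_L/n) − (n_R/n) log2(n_R/n)]
```

Induction is top-down greedy with configurable stopping rules (minimum node
size, maximum depth, maximum internal-node count, entropy threshold) and
**no automatic post-pruning** — pruning is an explicit user edit.  The
package's distinguishing surface is the interactive-editing vocabulary,
available both as library functions and as CLI subcommands:

* `fold` — collapse a subtree into a majority-class leaf;
* `unfold_once` / `unfold_all` — expand a leaf by one best split / by full
  recursive induction (optionally with a different test family);
* `update_test` — replace a node's test, keep the structure below, re-route
  the instances and refresh all counts and labels;
* `rebuild_subtree` — replace (or re-search) a test and re-induce both
  children from scratch;
* `suggest_top_splits` — the k best alternative splits at any node;
* `complete_partial_test` — fill in the free parameters of a partially
  specified test (e.g. fix one TSP attribute, search the partner).

Every edit returns a new tree plus train/test reports recomputed from
scratch; trees serialise to a canonical, byte-stable JSON format
(`tree.schema.json` documents it).

## Worked example

```
$ mixtree simulate --rule tsp --attr1 0 --attr2 1 --n-samples 60 \
    --n-attributes 5 --seed 3 --out toy.csv
wrote 60 samples x 5 attributes to toy.csv

$ mixtree induce --train toy.csv --class-col class --tests tsp --out toy.json
tree written to toy.json, reports to toy.reports.json
train accuracy: 1.0000
```

The simulated table plants the rule "class is `pos` iff `g0 < g1`" among
three decoy attributes; induction with the TSP family recovers exactly that
pair at the root (`toy.json` holds `"repr": "g0 < g1"`) and classifies the
training set perfectly — accuracy 1.0000 means all 60 samples land in pure
leaves.  Alternative splits at any node:

```
$ mixtree suggest --train toy.csv --class-col class --tests tsp,c45 --top-k 3
1.000000	g0 < g1
1.000000	g1 < g0
0.366739	g1 >= 0.5679350781026546
```

(first column: gain ratio; second: the test in the canonical grammar — the
second line is the planted rule's mirror image, which splits the same
samples with left and right exchanged).  Edits are single commands, e.g.
manually overriding the root test and re-routing the instances through the
preserved structure:

```
$ mixtree edit --train toy.csv --class-col class --tree toy.json \
    --node root --set-test "g1 >= 1.16" --update --out edited.json
tree written to edited.json, reports to edited.reports.json
train accuracy: 0.7667
```

The drop from 1.0000 to 0.7667 quantifies how much worse the hand-chosen
univariate threshold is than the planted pair rule on this data.

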
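# Methods

## Problem and notation

An instance (a gene or lncRNA, represented by a feature vector **x**) carries
a set of function terms from a rooted DAG hierarchy *H* with nodes
`0..N−1`, node 0 the namespace root. A labelling `y ∈ {0,1}^N` is
*hierarchy-consistent* (true-path rule) when every positive node has all its
parents positive; Ψ denotes the consistent set, always with `y_0 = 1` (every
instance has the root function, and the root posterior is fixed at 1 — the
parent products below require it for children of the root).

## Misclassification costs

Node importance decays away from the root: `C_0 = 1` and, because a DAG node
can have several parents, `C_i = Σ_{j∈par(i)} C_j / |child(j)|`, evaluated in
topological order. On a tree each node's cost is split exactly across its
children (conserved), and cost never increases along a root-to-leaf path. On
a DAG a multi-parent node accumulates shares from each parent, so its cost
can exceed a sibling's (the diamond's leaf has cost 1). The companion
direction weights α and β mentioned alongside the cost model enter no
formula; they are carried as configuration (default 1) and unused.

## Hierarchical loss and Bayes risk

The loss of predicting ŷ against truth y is `ℓ1+ℓ2+ℓ3+ℓ4`, the four terms
separating false negatives/positives at a node by whether its parents were
correctly predicted, each weighted `w_k · C_i` (defaults `w = (1,1,1,1)`).
The conditional risk `R(ŷ|x) = Σ_y L(y,ŷ)P(y|x)` then has a closed form in
the marginals `p_i` alone. Its derivation uses two assumptions on the label
distribution: the hierarchy constraint (`P(y_i=1, y_parent=0) = 0`) and
parent-marginal independence (`P(y_par(i)=1) = Π_j p_j`). On chain
hierarchies with the conditional joint `q_i = p_i / p_par(i)` both hold
exactly and the closed form equals the exhaustive expectation to 1e−10
relative (verified; `brute_force_risk` is the oracle). The class of joints
for which the closed form is exact beyond chains is not characterised; the
closed form is used as the decoding model, not as a density estimate.

Subtracting the risk from the ŷ-independent constant
`w2 Σ C_i p_i |par(i)|` yields the maximisation objective `LE_δ(ŷ, x)`.
The conservation identity `R + LE_δ = const` holds for every **consistent**
ŷ — its derivation uses `ŷ_i = 1 ⇒ ŷ_par(i) = 1` — and is asserted over Ψ,
not over arbitrary binary vectors.

## The σ-function and its two variants

`LE_δ` is linearised into per-node scores so decoding becomes
`argmax_{ŷ∈Ψ} Σ ŷ_i σ(i)`, with `σ(i) = σ1(i) + σ2(i)` (root: σ1 only;
childless nodes: σ1 = 0). σ2 is the node's own net expected gain:

```
σ2(i) = w1·C_i·p_i − w3·C_i·(Π_{j∈par(i)} p_j − p_i) − w4·C_i·Σ_{j∈par(i)} (1−p_j)
```

For σ1 — the node's contribution as a parent — two variants are provided:

* `sigma_mode="product"` (default):
  `σ1(i) = Σ_{j∈child(i)} w2·C_j·p_j − Π_{j∈child(i)} w1·C_j·p_j`.
  With this form `Σ ŷσ = LE_δ` exactly on chains, but the product over
  children does not expand to the matching term of `LE_δ` when a node has
  two or more children (or a child has two or more parents); the residual on
  random DAGs is measured and reported by the test suite and the acceptance
  script rather than resolved.
* `sigma_mode="direct"`:
  `σ1(i) = (w2−w1)·Σ_{j∈child(i)} C_j·p_j`, the linearisation obtained by
  grouping `LE_δ` by the node carrying ŷ; it reproduces `LE_δ` exactly on
  any single-parent hierarchy (tree) and is the variant the end-to-end
  pipeline benchmarks use, since it represents the Bayes objective
  faithfully where a linear σ exists at all. With unit weights it reduces
  to σ = σ2.

## DAGLabel decoding

Each non-root node starts as a singleton supernode valued σ(i). Repeatedly
the highest-valued pending supernode is examined (ties: smallest member
index): value ≤ 0 rejects it (strict positivity is required — a zero-sum
group cannot improve the objective and the tie-break prefers smaller label
sets); if every external parent of its members is selected or the root, the
whole group is selected; otherwise it merges with its highest-valued
unselected parent supernode (ties: smallest member index) and re-enters the
queue with summed value. Rejected groups remain available as merge targets.
The procedure is `O(N log N)` in priority-queue operations (profiled: the
operation count grows under 2.3× per doubling of N at N = 1000..4000).

On trees this greedy is exact: it attains the exhaustive optimum on 100% of
500 random trees (N ≤ 14). On multi-parent DAGs a supernode that is
ultimately rejected can swallow a node that was selectable on its own, so a
final guard pass compares the greedy labelling with top-down thresholding of
σ at 0 and keeps the better one; this guarantees the decoder never scores
below constrained thresholding while leaving tree behaviour untouched.
Optimality on general DAGs is *not* claimed; the measured attainment rate on
random DAGs (typically ~90–95%) is reported by the acceptance script.

Baselines: TOPDOWN (threshold, then zero any node with a negative parent,
root to leaves), DOWNTOP (threshold, then promote all ancestors of
positives), and TPR (bottom-up unweighted averaging of each node's score
with its above-threshold children's adjusted scores, then the top-down
pass). The default threshold is 0.5; none is prescribed by the method
descriptions these reconstruct, and TPR's child weighting is the unweighted
average variant.

## Probability models

Any estimator with `fit(X, Y)` / `predict_proba(X)` whose output columns
follow hierarchy node order can drive the decoder; the root column is forced
to 1 after prediction. Provided:

* **Logistic baseline** — independent L2-regularised logistic regression per
  node (scikit-learn); single-class training columns predict their empirical
  rate. This is the estimator the test suite and benchmarks run.
* **BiLSTM reference network** (optional, torch) — dense expansion (sigmoid,
  width 128) → layer normalisation → bidirectional LSTM (64 units per
  direction, tanh) → dropout 0.3 → sigmoid head; binary cross-entropy,
  learning rate 8e−4, batch 32, ≤ 200 epochs with early stopping (patience
  10). Each expanded feature is one recurrent time step, and labels are
  emitted in one shot by the sigmoid head (not autoregressively). The
  expansion/recurrent widths, dropout, batch and epoch budget are
  conventional values at the benchmark scale (~800 × 50) and are all
  exposed as parameters. Without torch the constructor raises a capability
  error pointing at the baseline.

Splits follow the floor-based rule: 2/3 of instances train (2/3 of those fit
the model, 1/3 validate), 1/3 test; all partitions are seeded.

## Network features

`rwr_diffuse` iterates `s ← (1−r)·W·s + r·e_i` per start node with
column-normalised W (restart probability r = 0.5 by default, tolerance
1e−10, ≤ 10⁴ iterations); isolated nodes diffuse to themselves with a
warning. `reduce_svd` compresses the diffusion matrix to `U_k √Σ_k`
(optionally after `log(x + 1/N)` smoothing, off by default), with component
signs fixed by making each component's largest-magnitude loading positive.
Column normalisation and the optional log step are the simplest reading of
the diffusion-embedding recipe this follows; full multi-network integration
is out of scope.

## Evaluation

Predictions and truths are ancestor-closed and the root is removed (it is
positive for every instance and would guarantee a hit; a flag restores it).
Micro scores pool intersections over instances; macro scores average
per-instance precision/recall/F1. Conventions for degenerate sets: an empty
prediction set contributes zero to both pooled sums (micro) and scores
precision 0 (macro); an empty truth set scores recall 0; per-instance F1 is
0 when precision + recall = 0; if both pooled denominators vanish the micro
scores are 0 with a warning.

## Synthetic benchmark

The generator emulates the curated benchmark the method targets: ~807
instances × 50 attributes over a biological-process-like DAG (default 30
nodes, spanning tree plus 15% forward cross-edges, depth ≤ 6). Labels are
sampled top-down — a node at depth d activates with probability
`base_rate · decay^d` (defaults 0.9, 0.75) only when all parents are active
— so every row is consistent by construction. Rows that come out with no
non-root term are redrawn: curated annotation datasets contain only
instances that received at least one specific term, and under the
empty-truth convention above an unannotatable instance would score zero even
when predicted exactly. Classifier posteriors are emulated by Beta noise
centred on the true labels (mean `1−flip_rate` for positives, `flip_rate`
for negatives, precision = `concentration`); the bounded, mean- and
precision-controllable Beta is the natural choice for probabilities.
Features are Gaussian with a random linear imprint of the labels. The
coexpression simulator plants modules in an lncRNA–protein network, gives
each module a GO subtree, annotates proteins with it, and transfers labels
to lncRNAs by neighbourhood counting over direct protein neighbours at a
configurable frequency threshold (the original construction's threshold is
cited, not printed, in the sources this emulates).

What passing synthetic tests shows — and does not. The generator produces
well-calibrated, conditionally independent posteriors and exactly consistent
truths; real classifier outputs are miscalibrated and correlated, and real
GO annotations are incomplete. Recovery numbers on the benchmark therefore
validate the decoding machinery, not expected field performance.

Benchmark conditions used by the acceptance harness: low noise = flip 0.05,
concentration 50; high noise = flip 0.30, concentration 4; 10 seeds each.
Proposition-level checks run on 50–100 hierarchies with N ≤ 12–14 so that
exhaustive enumeration of Ψ stays exact and the whole battery completes in
seconds on one core.

## Numerical choices

Equivalence assertions use 1e−9 relative / 1e−12 absolute (1e−10 relative
for the chain-exactness checks). Products over empty parent/child sets are
1, sums 0. The exhaustive decoder breaks ties toward fewer positive labels,
then lexicographically smallest. Probabilities are validated into [0,1] with
`p_root = 1`.

## Known limitations

* The closed-form risk is exact only under the chain-factorised joint;
  decoding on DAGs optimises an approximation.
* DAGLabel is heuristic on multi-parent DAGs (guarded, measured, but not
  optimal).
* The printed-σ variant diverges from the Bayes objective on branching
  hierarchies; both variants are kept so the divergence stays measurable.
* One DAG namespace at a time; no multi-namespace prediction, no OBO
  reasoning beyond `is_a` (+ opt-in `part_of`), no CAFA-style Fmax sweeps.
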
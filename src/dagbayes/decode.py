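"""Hierarchy-consistent decoders.

Turn per-node scores into a binary labelling that obeys the true-path rule:

* :class:`DAGLabelDecoder` — greedy supernode decoder maximising Σ ŷ_i σ(i)
  over the consistent set (optimal on trees; near-optimal on DAGs);
* :class:`BruteForceDecoder` — exhaustive oracle for small hierarchies;
* :class:`TopDownDecoder` / :class:`DownTopDecoder` /
  :class:`TruePathRuleDecoder` — classical probability-threshold baselines.

All are stateless scikit-learn transformers: ``transform`` maps an
(instances × nodes) score or probability matrix to a binary label matrix.
"""

from __future__ import annotations

import heapq

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .hierarchy import DAGHierarchy, enumerate_consistent

__all__ = [
    "daglabel_decode",
    "brute_force_decode",
    "topdown_constrain",
    "downtop_constrain",
    "tpr_constrain",
    "DAGLabelDecoder",
    "BruteForceDecoder",
    "TopDownDecoder",
    "DownTopDecoder",
    "TruePathRuleDecoder",
    "get_decoder",
]

_ROOT = -1  # sentinel group id for the (always-selected) root


def _daglabel_single(h: DAGHierarchy, s: np.ndarray):
    """One DAGLabel pass; returns (label vector, heap-operation count).

    Non-root nodes start as singleton supernodes valued σ(i).  The
    highest-valued pending supernode is repeatedly examined: a non-positive
    value rejects it; if every external parent of its members is already
    selected (or the root) it is selected whole; otherwise it merges with its
    highest-valued unselected parent supernode into a new supernode with
    summed value and re-enters the queue.

    A final guard pass compares the greedy objective with that of top-down
    thresholding of σ at 0 and keeps the better labelling: on multi-parent
    DAGs a supernode that is ultimately rejected can swallow a node that was
    selectable on its own, and the guard restores the guarantee that the
    decoder never scores below constrained thresholding (on trees the greedy
    is already optimal and the guard never fires).
    """
    n = h.n_nodes
    group_of = {0: _ROOT}
    members = {}
    value = {}
    min_member = {}
    alive = {}
    selected = set()
    heap = []
    ops = 0
    next_gid = 0
    for i in range(1, n):
        gid = next_gid
        next_gid += 1
        group_of[i] = gid
        members[gid] = [i]
        value[gid] = float(s[i])
        min_member[gid] = i
        alive[gid] = True
        heapq.heappush(heap, (-value[gid], i, gid))
        ops += 1

    def find(node: int) -> int:
        g = group_of[node]
        while g != _ROOT and not alive.get(g, False) and g in _redirect:
            g = _redirect[g]
        group_of[node] = g
        return g

    _redirect = {}

    while heap:
        negv, _, gid = heapq.heappop(heap)
        ops += 1
        if not alive.get(gid, False):
            continue
        v = -negv
        if v <= 0:
            # rejection: leaves the queue but stays mergeable
            continue
        ext = set()
        for m in members[gid]:
            for pnode in h.parents[m]:
                g = find(pnode)
                if g != gid:
                    ext.add(g)
        blocking = [g for g in ext if g != _ROOT and g not in selected]
        if not blocking:
            selected.add(gid)
            alive[gid] = False  # finalised
            continue
        target = max(blocking, key=lambda g: (value[g], -min_member[g]))
        new = next_gid
        next_gid += 1
        members[new] = members.pop(gid) + members.pop(target)
        value[new] = value[gid] + value[target]
        min_member[new] = min(min_member[gid], min_member[target])
        alive[gid] = alive[target] = False
        _redirect[gid] = _redirect[target] = new
        alive[new] = True
        heapq.heappush(heap, (-value[new], min_member[new], new))
        ops += 1

    y = np.zeros(n, dtype=np.int8)
    y[0] = 1
    for gid in selected:
        y[members[gid]] = 1

    yt = np.zeros(n, dtype=np.int8)
    yt[0] = 1
    for i in h.topo_order:
        if i and s[i] > 0 and all(yt[j] for j in h.parents[i]):
            yt[i] = 1
    ops += n
    if float(yt @ s) > float(y @ s) + 1e-12:
        return yt, ops
    return y, ops


def daglabel_decode(h: DAGHierarchy, sigma) -> np.ndarray:
    """Greedy supernode decoding of one σ vector into a consistent labelling."""
    s = _sigma_vec(h, sigma)
    y, _ = _daglabel_single(h, s)
    return y


def _sigma_vec(h, sigma) -> np.ndarray:
    if isinstance(sigma, dict):
        sigma = sigma["sigma"]
    s = np.asarray(sigma, dtype=float)
    if s.shape != (h.n_nodes,):
        raise ValueError(f"sigma has shape {s.shape}, expected ({h.n_nodes},)")
    if not np.isfinite(s).all():
        raise ValueError("sigma must be finite")
    return s


def brute_force_decode(h: DAGHierarchy, sigma, max_nodes: int = 20) -> np.ndarray:
    """Exhaustive argmax of Σ ŷ_i σ(i) over consistent vectors.

    Ties break toward fewer positive labels, then lexicographically smallest.
    Refuses hierarchies beyond ``max_nodes``.
    """
    s = _sigma_vec(h, sigma)
    cands = enumerate_consistent(h, max_nodes=max_nodes)  # sorted count, then lex
    obj = cands @ s
    best = 0
    for k in range(1, len(cands)):
        if obj[k] > obj[best] + 1e-12:
            best = k
    return cands[best].astype(np.int8)


def topdown_constrain(h: DAGHierarchy, probs, threshold: float = 0.5) -> np.ndarray:
    """Threshold, then sweep root-to-leaves zeroing nodes with a negative parent."""
    p = _prob_matrix_row(h, probs, threshold)
    y = (p >= threshold).astype(np.int8)
    y[0] = 1
    for i in h.topo_order:
        if i and y[i] and not all(y[j] for j in h.parents[i]):
            y[i] = 0
    return y


def downtop_constrain(h: DAGHierarchy, probs, threshold: float = 0.5) -> np.ndarray:
    """Threshold, then promote every ancestor of a positive node to positive."""
    p = _prob_matrix_row(h, probs, threshold)
    y = (p >= threshold).astype(np.int8)
    y[0] = 1
    for i in reversed(h.topo_order):
        if y[i]:
            for j in h.parents[i]:
                y[j] = 1
    return y


def tpr_constrain(h: DAGHierarchy, probs, threshold: float = 0.5) -> np.ndarray:
    """True-path-rule decoding: bottom-up evidence pooling, top-down pruning.

    Bottom-up, each node's score is averaged (unweighted) with the adjusted
    scores of its children that exceed the threshold; top-down, any node whose
    parents are not all positive is zeroed.
    """
    p = _prob_matrix_row(h, probs, threshold).astype(float).copy()
    for i in reversed(h.topo_order):
        pos = [j for j in h.children[i] if p[j] > threshold]
        if pos and i != 0:
            p[i] = (p[i] + sum(p[j] for j in pos)) / (1 + len(pos))
    y = (p >= threshold).astype(np.int8)
    y[0] = 1
    for i in h.topo_order:
        if i and y[i] and not all(y[j] for j in h.parents[i]):
            y[i] = 0
    return y


def _prob_matrix_row(h, probs, threshold) -> np.ndarray:
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    p = np.asarray(probs, dtype=float)
    if p.shape != (h.n_nodes,):
        raise ValueError(f"probability vector has shape {p.shape}, expected ({h.n_nodes},)")
    return p


# -- scikit-learn transformer façade --------------------------------------


class _BaseDecoder(TransformerMixin, BaseEstimator):
    """Stateless transformer turning per-instance node scores into labels."""

    def __init__(self, hierarchy=None):
        self.hierarchy = hierarchy

    def fit(self, X, y=None):
        if self.hierarchy is None:
            raise ValueError("a DAGHierarchy must be supplied")
        return self

    def _rows(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.hierarchy.n_nodes:
            raise ValueError(
                f"score matrix has {X.shape[1]} columns, hierarchy has "
                f"{self.hierarchy.n_nodes} nodes"
            )
        return X

    def transform(self, X):
        self.fit(X)
        X = self._rows(X)
        return np.vstack([self._decode_row(r) for r in X])


class DAGLabelDecoder(_BaseDecoder):
    """Greedy Bayes-decision decoder over σ scores.

    After ``transform``, ``n_ops_`` holds the cumulative priority-queue
    operation count (for complexity profiling).
    """

    def transform(self, X):
        self.fit(X)
        X = self._rows(X)
        out, ops = [], 0
        for r in X:
            y, k = _daglabel_single(self.hierarchy, _sigma_vec(self.hierarchy, r))
            out.append(y)
            ops += k
        self.n_ops_ = ops
        return np.vstack(out)


class BruteForceDecoder(_BaseDecoder):
    """Exhaustive σ decoder (oracle); refuses large hierarchies."""

    def __init__(self, hierarchy=None, max_nodes=20):
        super().__init__(hierarchy)
        self.max_nodes = max_nodes

    def _decode_row(self, r):
        return brute_force_decode(self.hierarchy, r, max_nodes=self.max_nodes)


class _ThresholdDecoder(_BaseDecoder):
    def __init__(self, hierarchy=None, threshold=0.5):
        super().__init__(hierarchy)
        self.threshold = threshold


class TopDownDecoder(_ThresholdDecoder):
    """Root-to-leaf constraint enforcement of thresholded probabilities."""

    def _decode_row(self, r):
        return topdown_constrain(self.hierarchy, r, self.threshold)


class DownTopDecoder(_ThresholdDecoder):
    """Leaf-to-root positive propagation of thresholded probabilities."""

    def _decode_row(self, r):
        return downtop_constrain(self.hierarchy, r, self.threshold)


class TruePathRuleDecoder(_ThresholdDecoder):
    """Two-pass true-path-rule baseline."""

    def _decode_row(self, r):
        return tpr_constrain(self.hierarchy, r, self.threshold)


_DECODERS = {
    "daglabel": DAGLabelDecoder,
    "oracle": BruteForceDecoder,
    "topdown": TopDownDecoder,
    "downtop": DownTopDecoder,
    "tpr": TruePathRuleDecoder,
}


def get_decoder(method: str, hierarchy: DAGHierarchy, threshold: float = 0.5):
    """Decoder factory; ``method`` one of daglabel|oracle|topdown|downtop|tpr."""
    if method not in _DECODERS:
        raise ValueError(f"unknown decode method {method!r}; choose from {sorted(_DECODERS)}")
    cls = _DECODERS[method]
    if issubclass(cls, _ThresholdDecoder):
        return cls(hierarchy, threshold=threshold)
    return cls(hierarchy)
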
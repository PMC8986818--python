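"""Synthetic benchmark generator.

Emulates the structure of curated lncRNA function-annotation benchmarks:
a GO-like DAG of function terms, hierarchy-consistent annotation matrices,
noisy classifier posteriors, informative feature vectors, and a planted-module
lncRNA–protein coexpression network whose lncRNA labels arise by
neighbourhood counting over annotated protein neighbours.  Default sizes
match the published benchmark scale (about 807 instances, 50 attributes);
everything is generated from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .hierarchy import DAGHierarchy, augment_with_ancestors, is_consistent

__all__ = [
    "SyntheticConfig",
    "random_dag",
    "sample_consistent_labels",
    "corrupt_probabilities",
    "informative_features",
    "simulate_coexpression",
    "simulate_dataset",
]


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the synthetic benchmark.

    ``n_instances=807`` and ``feature_dim=50`` mirror the published benchmark
    scale; 30 nodes gives a biological-process-like DAG depth of 4–6 at that
    scale; base activation 0.9 with decay 0.75 yields a handful of positive
    terms per instance, as GO annotation sets typically have.
    """

    n_nodes: int = 30
    extra_edge_prob: float = 0.15
    n_instances: int = 807
    feature_dim: int = 50
    base_rate: float = 0.9
    decay: float = 0.75
    flip_rate: float = 0.05
    concentration: float = 50.0
    feature_noise: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2 or self.n_instances < 1 or self.feature_dim < 1:
            raise ValueError("counts must be positive (n_nodes >= 2)")
        if not (0 <= self.flip_rate < 0.5):
            raise ValueError("flip_rate must lie in [0, 0.5)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    def to_dict(self):
        return asdict(self)


def random_dag(n_nodes: int, extra_edge_prob: float = 0.15, max_depth: int = 6,
               seed: int = 0) -> DAGHierarchy:
    """Random rooted DAG: a spanning tree plus forward cross-edges.

    Each node beyond the root attaches to a uniformly random earlier node of
    depth < ``max_depth``; each (earlier, later) non-tree pair then gains an
    extra edge with probability ``extra_edge_prob`` (kept only when it does
    not exceed ``max_depth``).  Deterministic per seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    edges = []
    depth = [0] * n_nodes
    for v in range(1, n_nodes):
        allowed = [u for u in range(v) if depth[u] < max_depth]
        u = int(rng.choice(allowed))
        edges.append((u, v))
        depth[v] = depth[u] + 1
        for u2 in range(v):
            if u2 != u and depth[u2] < depth[v] and rng.random() < extra_edge_prob:
                edges.append((u2, v))
    return DAGHierarchy(n_nodes, tuple(edges))


def sample_consistent_labels(h: DAGHierarchy, base_rate: float = 0.9,
                             decay: float = 0.75, n_instances: int = 100,
                             seed: int = 0,
                             ensure_annotated: bool = False) -> np.ndarray:
    """Hierarchy-consistent binary annotation matrix, sampled top-down.

    The root is always positive; a node at depth d whose parents are all
    positive activates with probability ``base_rate * decay**d``; a node
    with any negative parent is negative (true-path rule by construction).

    With ``ensure_annotated``, rows that come out with only the root positive
    are redrawn (up to 100 rounds), emulating curated function-annotation
    benchmarks whose instances all carry at least one specific term.
    """
    if not (0 <= base_rate <= 1 and 0 <= decay <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    d = h.depths()
    n = h.n_nodes
    order = [i for i in h.topo_order if i != 0]

    def draw(count):
        Y = np.zeros((count, n), dtype=np.int8)
        Y[:, 0] = 1
        for i in order:
            ok = np.ones(count, dtype=bool)
            for j in h.parents[i]:
                ok &= Y[:, j] == 1
            rate = base_rate * decay ** d[i]
            Y[ok, i] = (rng.random(int(ok.sum())) < rate).astype(np.int8)
        return Y

    Y = draw(n_instances)
    if ensure_annotated:
        for _ in range(100):
            bare = np.flatnonzero(Y[:, 1:].sum(axis=1) == 0)
            if bare.size == 0:
                break
            Y[bare] = draw(bare.size)
    return Y


def corrupt_probabilities(labels, concentration: float = 50.0,
                          flip_rate: float = 0.05, seed: int = 0) -> np.ndarray:
    """Beta-noise classifier posteriors centred on the true labels.

    Entries with true label 1 are drawn from a Beta with mean ``1−flip_rate``
    and precision ``concentration``; true-0 entries mirror this at mean
    ``flip_rate``.  The root column is forced to 1.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must lie in [0, 0.5)")
    Y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    mean = np.where(Y == 1, 1.0 - flip_rate, flip_rate)
    a = np.clip(mean * concentration, 1e-9, None)
    b = np.clip((1.0 - mean) * concentration, 1e-9, None)
    P = rng.beta(a, b)
    P[:, 0] = 1.0
    return P


def informative_features(labels, feature_dim: int = 50, noise: float = 0.5,
                         seed: int = 0) -> np.ndarray:
    """Gaussian feature vectors carrying a random linear imprint of the labels."""
    Y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(Y.shape[1], feature_dim)) / np.sqrt(Y.shape[1])
    return Y @ W + noise * rng.normal(size=(Y.shape[0], feature_dim))


@dataclass
class CoexpressionSimulation:
    """Planted-module network with protein annotations and derived lncRNA labels."""

    adjacency: np.ndarray
    lncrna_ids: list
    protein_ids: list
    hierarchy: DAGHierarchy
    protein_annotations: np.ndarray  # proteins × nodes, ancestor-closed
    lncrna_labels: np.ndarray        # lncRNAs × nodes, ancestor-closed
    module_of_lncrna: np.ndarray = field(default=None)
    module_of_protein: np.ndarray = field(default=None)


def simulate_coexpression(n_lncrna: int = 807, n_protein: int = 200,
                          n_modules: int = 8, within_module_edge_prob: float = 0.3,
                          between_prob: float = 0.01, hierarchy: DAGHierarchy = None,
                          neighbour_threshold: float = 0.5,
                          seed: int = 0) -> CoexpressionSimulation:
    """Planted-module lncRNA–protein network with transferred annotations.

    lncRNAs and proteins are split round-robin across modules; edges appear
    with ``within_module_edge_prob`` inside a module and ``between_prob``
    across modules (weights uniform in (0.5, 1] within, (0, 0.5] across).
    Each module owns a GO subtree (a leaf plus its ancestors) of a shared
    function DAG; every protein carries its module's ancestor-closed term set.
    Each lncRNA is annotated by neighbourhood counting: a term is assigned
    when its frequency among direct protein neighbours reaches
    ``neighbour_threshold``, then the set is ancestor-closed.  lncRNAs with
    no protein neighbour get the root-only annotation.
    """
    rng = np.random.default_rng(seed)
    if hierarchy is None:
        hierarchy = random_dag(30, extra_edge_prob=0.15, seed=seed + 1)
    h = hierarchy
    n = n_lncrna + n_protein
    mod_l = np.arange(n_lncrna) % n_modules
    mod_p = np.arange(n_protein) % n_modules
    mod = np.concatenate([mod_l, mod_p])
    same = mod[:, None] == mod[None, :]
    U = rng.random((n, n))
    Wgt = rng.random((n, n))
    A = np.where(same, (U < within_module_edge_prob) * (0.5 + 0.5 * Wgt),
                 (U < between_prob) * 0.5 * Wgt)
    A = np.triu(A, 1)
    A = A + A.T

    # assign each module a leaf term's root path as its function subtree
    leaves = [i for i in range(h.n_nodes) if not h.children[i]]
    chosen = rng.choice(len(leaves), size=n_modules, replace=len(leaves) < n_modules)
    module_terms = []
    for k in range(n_modules):
        leaf = leaves[int(chosen[k])]
        terms = {leaf} | set(h.ancestors(leaf))
        module_terms.append(sorted(terms))
    prot_ann = np.zeros((n_protein, h.n_nodes), dtype=np.int8)
    for j in range(n_protein):
        prot_ann[j, module_terms[mod_p[j]]] = 1
    prot_ann[:, 0] = 1

    lnc_lab = np.zeros((n_lncrna, h.n_nodes), dtype=np.int8)
    lnc_lab[:, 0] = 1
    A_lp = A[:n_lncrna, n_lncrna:]
    for i in range(n_lncrna):
        nb = np.flatnonzero(A_lp[i] > 0)
        if nb.size == 0:
            continue
        freq = prot_ann[nb].mean(axis=0)
        pos = np.flatnonzero(freq >= neighbour_threshold) if neighbour_threshold > 0 \
            else np.flatnonzero(freq > 0)
        closed = augment_with_ancestors(h, pos, include_root=True)
        lnc_lab[i, sorted(closed)] = 1
        lnc_lab[i, 0] = 1
    return CoexpressionSimulation(
        adjacency=A,
        lncrna_ids=[f"lnc{i:04d}" for i in range(n_lncrna)],
        protein_ids=[f"prot{j:04d}" for j in range(n_protein)],
        hierarchy=h,
        protein_annotations=prot_ann,
        lncrna_labels=lnc_lab,
        module_of_lncrna=mod_l,
        module_of_protein=mod_p,
    )


def simulate_dataset(config: SyntheticConfig = None, **overrides):
    """One-call benchmark: hierarchy, labels, posteriors, features.

    Returns a dict with keys ``hierarchy``, ``labels``, ``probabilities``,
    ``features``, ``config``.  All randomness derives from ``config.seed``.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**config.to_dict(), **overrides})
    seed = int(config.seed)
    h = random_dag(config.n_nodes, config.extra_edge_prob, seed=seed)
    Y = sample_consistent_labels(h, config.base_rate, config.decay,
                                 config.n_instances, seed=seed + 1,
                                 ensure_annotated=True)
    P = corrupt_probabilities(Y, config.concentration, config.flip_rate,
                              seed=seed + 2)
    X = informative_features(Y, config.feature_dim, config.feature_noise,
                             seed=seed + 3)
    assert all(is_consistent(h, row) for row in Y[: min(10, len(Y))])
    return {"hierarchy": h, "labels": Y, "probabilities": P, "features": X,
            "config": config}
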
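"""The Bayes-decision core: DAGH loss, closed-form conditional risk, σ scores.

The decoding model scores a candidate consistent labelling ŷ by its expected
hierarchical loss under the per-node posteriors p_i = P(y_i = 1 | x).  The
loss distinguishes four parent-context error types, each weighted by a
misclassification cost C_i that decays away from the root:

* ℓ1 — false negative at i, all parents predicted positive;
* ℓ2 — false negative at i, some true-positive parent predicted negative;
* ℓ3 — false positive at i, parents all truly and predictedly positive;
* ℓ4 — false positive at i, propagated from a truly-negative parent.

Expanding the expectation under the hierarchy constraint yields a closed-form
risk, and (up to a ŷ-independent constant) an equivalent maximisation
objective LE_δ, which a per-node score σ(i) linearises so that decoding
becomes: maximise Σ ŷ_i σ(i) over the consistent set Ψ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hierarchy import DAGHierarchy, compute_costs, enumerate_consistent, is_consistent

__all__ = [
    "LossWeights",
    "dagh_loss",
    "conditional_risk",
    "brute_force_risk",
    "node_sigma",
    "le_objective",
    "le_direct",
    "risk_constant",
]

REL_TOL = 1e-9
ABS_TOL = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Weights of the four hierarchical error types (all nonnegative).

    ``alpha`` and ``beta`` are retained as configuration for the two
    misclassification directions but enter no formula.
    """

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        for name in ("w1", "w2", "w3", "w4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_tuple(self):
        return (self.w1, self.w2, self.w3, self.w4)


def _as_weights(w) -> LossWeights:
    if isinstance(w, LossWeights):
        return w
    if w is None:
        return LossWeights()
    return LossWeights(*w)


def _check_probs(h: DAGHierarchy, p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (h.n_nodes,):
        raise ValueError(f"probability vector has shape {p.shape}, expected ({h.n_nodes},)")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isclose(p[0], 1.0):
        raise ValueError("root probability must be 1 (every instance has the root function)")
    return p


def _check_binary(h: DAGHierarchy, y, name="label vector") -> np.ndarray:
    y = np.asarray(y)
    if y.shape != (h.n_nodes,):
        raise ValueError(f"{name} has shape {y.shape}, expected ({h.n_nodes},)")
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return y.astype(float)


def dagh_loss(h, costs, w, y_true, y_pred) -> float:
    """Four-term hierarchical loss of prediction ŷ against true labels y.

    The true labels must obey the hierarchy constraint; sums run over the
    non-root nodes, and ỹ denotes the logical complement 1−y.
    """
    w = _as_weights(w)
    y = _check_binary(h, y_true, "y_true")
    yh = _check_binary(h, y_pred, "y_pred")
    if not is_consistent(h, y_true):
        raise ValueError("y_true violates the hierarchy constraint")
    c = np.asarray(costs, dtype=float)
    l1 = l2 = l3 = l4 = 0.0
    for i in range(1, h.n_nodes):
        par = h.parents[i]
        prod_yy = math.prod(y[j] * yh[j] for j in par)
        l1 += c[i] * y[i] * (1 - yh[i]) * prod_yy
        l2 += c[i] * y[i] * (1 - yh[i]) * sum(y[j] * (1 - yh[j]) for j in par)
        l3 += c[i] * (1 - y[i]) * yh[i] * prod_yy
        l4 += c[i] * (1 - y[i]) * yh[i] * sum((1 - y[j]) * yh[j] for j in par)
    return w.w1 * l1 + w.w2 * l2 + w.w3 * l3 + w.w4 * l4


def conditional_risk(h, costs, w, probs, y_pred) -> float:
    """Closed-form expected DAGH loss of ŷ given per-node posteriors.

    Valid under the hierarchy constraint on the label distribution together
    with parent-marginal independence (exact on chains; see the methods note).
    """
    w = _as_weights(w)
    p = _check_probs(h, probs)
    yh = _check_binary(h, y_pred, "y_pred")
    c = np.asarray(costs, dtype=float)
    t1 = t2 = t3 = t4 = 0.0
    for i in range(1, h.n_nodes):
        par = h.parents[i]
        prod_yh = math.prod(yh[j] for j in par)
        prod_p = math.prod(p[j] for j in par)
        t1 += c[i] * (1 - yh[i]) * p[i] * prod_yh
        t2 += c[i] * (1 - yh[i]) * p[i] * sum(1 - yh[j] for j in par)
        t3 += c[i] * yh[i] * (prod_p - p[i]) * prod_yh
        t4 += c[i] * yh[i] * sum(yh[j] * (1 - p[j]) for j in par)
    return w.w1 * t1 + w.w2 * t2 + w.w3 * t3 + w.w4 * t4


def brute_force_risk(h, costs, w, joint, y_pred) -> float:
    """Exact expected loss Σ_y L(y, ŷ)·P(y) over an explicit joint.

    ``joint`` maps label tuples (hierarchy-consistent support) to
    probabilities summing to 1.  Exhaustive oracle for small hierarchies.
    """
    total = math.fsum(joint.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"joint distribution sums to {total}, not 1")
    acc = 0.0
    for y, prob in joint.items():
        if prob == 0:
            continue
        acc += prob * dagh_loss(h, costs, w, np.asarray(y), y_pred)
    return acc


def risk_constant(h, costs, w, probs) -> float:
    """The ŷ-independent term w2·Σ C_i p_i |par(i)| linking risk and LE_δ."""
    w = _as_weights(w)
    p = _check_probs(h, probs)
    c = np.asarray(costs, dtype=float)
    return w.w2 * sum(c[i] * p[i] * len(h.parents[i]) for i in range(1, h.n_nodes))


def le_direct(h, costs, w, probs, y_pred) -> float:
    """The maximisation objective LE_δ evaluated from its three-term form.

    Satisfies conditional_risk + le_direct = w2·Σ C_i p_i |par(i)| identically.
    """
    w = _as_weights(w)
    p = _check_probs(h, probs)
    yh = _check_binary(h, y_pred, "y_pred")
    c = np.asarray(costs, dtype=float)
    a = b = d = 0.0
    for i in range(1, h.n_nodes):
        par = h.parents[i]
        a += c[i] * p[i] * sum(yh[j] for j in par)
        b += c[i] * p[i] * math.prod(yh[j] for j in par)
        d += yh[i] * (
            w.w1 * c[i] * p[i]
            - w.w3 * c[i] * (math.prod(p[j] for j in par) - p[i])
            - w.w4 * c[i] * sum(1 - p[j] for j in par)
        )
    return w.w2 * a - w.w1 * b + d


def node_sigma(h, costs, w, probs, sigma_mode: str = "product"):
    """Per-node decoding scores σ(i) with components σ1, σ2.

    σ2(i) rewards predicting i positive by its expected-gain terms; σ1(i)
    accounts for i's role as a parent.  Two σ1 variants are provided:

    * ``"product"`` — σ1(i) = Σ_{j∈child(i)} w2·C_j·p_j − Π_{j∈child(i)} w1·C_j·p_j
      (the printed form; makes Σ ŷσ equal LE_δ exactly on chain hierarchies);
    * ``"direct"`` — σ1(i) = (w2−w1)·Σ_{j∈child(i)} C_j·p_j, the linearisation
      that is exact on trees (single-parent hierarchies).

    Childless nodes have σ1 = 0; the root has no σ2.  Returns a dict with
    ``sigma``, ``sigma1``, ``sigma2`` arrays.
    """
    if sigma_mode not in ("product", "direct"):
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    w = _as_weights(w)
    p = _check_probs(h, probs)
    c = np.asarray(costs, dtype=float)
    n = h.n_nodes
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    for i in range(n):
        ch = h.children[i]
        if ch:
            if sigma_mode == "product":
                s1[i] = sum(w.w2 * c[j] * p[j] for j in ch) - math.prod(
                    w.w1 * c[j] * p[j] for j in ch
                )
            else:
                s1[i] = (w.w2 - w.w1) * sum(c[j] * p[j] for j in ch)
        if i > 0:
            par = h.parents[i]
            s2[i] = (
                w.w1 * c[i] * p[i]
                - w.w3 * c[i] * (math.prod(p[j] for j in par) - p[i])
                - w.w4 * c[i] * sum(1 - p[j] for j in par)
            )
    sigma = s1 + s2
    sigma[0] = s1[0]
    return {"sigma": sigma, "sigma1": s1, "sigma2": s2}


def le_objective(h, sigma, y_pred) -> float:
    """Linearised objective Σ_i ŷ_i·σ(i) for a consistent prediction."""
    s = sigma["sigma"] if isinstance(sigma, dict) else np.asarray(sigma, dtype=float)
    yh = _check_binary(h, y_pred, "y_pred")
    if not is_consistent(h, y_pred):
        raise ValueError("y_pred violates the hierarchy constraint")
    return float(np.dot(yh, s))


def chain_joint(h: DAGHierarchy, probs) -> dict:
    """The conditional-probability joint on a chain: q_i = p_i / p_parent.

    Requires a chain hierarchy with non-increasing marginals; the closed-form
    conditional risk is exact for this joint.
    """
    p = _check_probs(h, probs)
    n = h.n_nodes
    if any(len(h.parents[i]) != 1 or h.parents[i][0] != i - 1 for i in range(1, n)):
        raise ValueError("chain_joint requires the chain hierarchy 0→1→…→N−1")
    if np.any(np.diff(p) > 1e-12):
        raise ValueError("chain marginals must be non-increasing")
    joint = {}
    for k in range(n):  # vectors positive on the prefix 0..k
        y = tuple([1] * (k + 1) + [0] * (n - k - 1))
        prob = 1.0
        for i in range(1, n):
            q = p[i] / p[i - 1] if p[i - 1] > 0 else 0.0
            if i <= k:
                prob *= q
            elif i == k + 1:
                prob *= 1 - q
            else:
                break  # later nodes are forced 0 given a 0 parent
        joint[y] = prob
    return joint


def minimize_risk_exhaustive(h, costs, w, probs):
    """Argmin of the closed-form risk over all consistent vectors (oracle)."""
    cands = enumerate_consistent(h, max_nodes=20)
    risks = np.array([conditional_risk(h, costs, w, probs, y) for y in cands])
    return cands[int(np.argmin(risks))], risks
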
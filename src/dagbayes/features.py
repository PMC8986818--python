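"""Network-topology features: random-walk-with-restart diffusion + SVD.

Each biomolecule node in a weighted coexpression network is represented by
its RWR diffusion state — the stationary distribution of a walker that at
every step either moves to a random neighbour (probability ``1−r``) or jumps
back to its start node (restart probability ``r``).  The node×node diffusion
matrix is then compressed to a low-dimensional embedding by truncated SVD.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["validate_adjacency", "rwr_diffuse", "reduce_svd", "RWREmbedding"]


def validate_adjacency(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency weights must be nonnegative")
    if np.any(np.abs(np.diag(A)) > 1e-12):
        raise ValueError("adjacency must have a zero diagonal")
    return A


def rwr_diffuse(A, restart_prob: float = 0.5, tol: float = 1e-10,
                max_iter: int = 10_000) -> np.ndarray:
    """Column-stochastic diffusion matrix S with S[:, i] the state from node i.

    Iterates s ← (1−r)·W·s + r·e_i with W the column-normalised adjacency
    until the max-abs update falls below ``tol``.  Isolated nodes diffuse to
    themselves (unit vector) with a warning.
    """
    A = validate_adjacency(A)
    if not (0 < restart_prob <= 1):
        raise ValueError("restart_prob must lie in (0, 1]")
    n = A.shape[0]
    deg = A.sum(axis=0)
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated node(s); their diffusion is the unit vector")
    W = np.divide(A, np.where(isolated, 1.0, deg)[None, :],
                  out=np.zeros_like(A), where=np.broadcast_to(~isolated[None, :], A.shape))
    r = restart_prob
    S = np.eye(n)
    for _ in range(max_iter):
        S_new = (1 - r) * (W @ S) + r * np.eye(n)
        if np.max(np.abs(S_new - S)) < tol:
            S = S_new
            break
        S = S_new
    S[:, isolated] = np.eye(n)[:, isolated]
    return S


def reduce_svd(S, dim: int, log_transform: bool = False) -> np.ndarray:
    """Truncated-SVD embedding of a diffusion matrix: U_k · sqrt(Σ_k).

    With ``log_transform``, log(x + 1/N) is applied elementwise first
    (diffusion-state smoothing).  Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    S = np.asarray(S, dtype=float)
    if not (1 <= dim <= min(S.shape)):
        raise ValueError(f"dim must lie in [1, {min(S.shape)}], got {dim}")
    if log_transform:
        S = np.log(S + 1.0 / S.shape[0])
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    U, sv = U[:, :dim], sv[:dim]
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(dim)])
    flip[flip == 0] = 1.0
    return U * flip * np.sqrt(sv)


class RWREmbedding(TransformerMixin, BaseEstimator):
    """Transformer: adjacency matrix → RWR+SVD node embedding."""

    def __init__(self, n_components=50, restart_prob=0.5, tol=1e-10,
                 max_iter=10_000, log_transform=False):
        self.n_components = n_components
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.log_transform = log_transform

    def fit(self, X, y=None):
        self.diffusion_ = rwr_diffuse(X, self.restart_prob, self.tol, self.max_iter)
        self.embedding_ = reduce_svd(self.diffusion_, self.n_components,
                                     self.log_transform)
        return self

    def transform(self, X=None):
        if not hasattr(self, "embedding_"):
            self.fit(X)
        return self.embedding_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
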
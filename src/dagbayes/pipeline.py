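"""End-to-end hierarchical Bayes-decision classification.

:class:`HierarchicalBayesClassifier` is the package's main estimator.  Fitting
trains a per-node probability model; prediction runs the three decoding steps:
(1) per-node posteriors, (2) per-node σ scores from the cost-weighted
Bayes-risk model, (3) hierarchy-consistent decoding (DAGLabel by default).
``run_pipeline`` / ``compare_methods`` drive the same estimator from files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _io
from .classify import LogisticNodeClassifier, SplitSpec, split_dataset
from .decode import get_decoder
from .hierarchy import DAGHierarchy, compute_costs, parse_hierarchy
from .metrics import evaluate_predictions
from .risk import LossWeights, node_sigma

logger = logging.getLogger(__name__)

__all__ = ["HierarchicalBayesClassifier", "RunConfig", "run_pipeline",
           "compare_methods", "sigma_matrix", "decode_probabilities"]


def sigma_matrix(h: DAGHierarchy, P, weights=None, costs=None,
                 sigma_mode="product") -> np.ndarray:
    """σ scores for every row of a probability matrix (root column must be 1)."""
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    c = compute_costs(h) if costs is None else np.asarray(costs, dtype=float)
    w = weights if isinstance(weights, LossWeights) else LossWeights(*(weights or (1, 1, 1, 1)))
    return np.vstack([node_sigma(h, c, w, row, sigma_mode)["sigma"] for row in P])


def decode_probabilities(h: DAGHierarchy, P, method="daglabel", weights=None,
                         threshold=0.5, sigma_mode="product") -> np.ndarray:
    """Probability matrix → consistent label matrix via the chosen decoder.

    σ-based methods (daglabel, oracle) first map probabilities to σ scores;
    threshold baselines consume the probabilities directly.
    """
    dec = get_decoder(method, h, threshold=threshold)
    if method in ("daglabel", "oracle"):
        S = sigma_matrix(h, P, weights=weights, sigma_mode=sigma_mode)
        return dec.transform(S)
    return dec.transform(np.atleast_2d(np.asarray(P, dtype=float)))


class HierarchicalBayesClassifier(ClassifierMixin, BaseEstimator):
    """DAG hierarchical multi-label classifier with Bayes-decision decoding.

    Parameters
    ----------
    hierarchy : DAGHierarchy
        The label DAG (root index 0).
    estimator : object, optional
        Probability model with ``fit(X, Y)`` / ``predict_proba(X)``;
        defaults to the per-node logistic baseline.
    weights : tuple of 4 floats
        DAGH loss weights (w1, w2, w3, w4).
    decode_method : str
        daglabel | oracle | topdown | downtop | tpr.
    threshold : float
        Probability threshold for the baseline decoders.
    sigma_mode : str
        "product" (chain-exact σ1 product) or "direct" (tree-exact sum).

    Attributes
    ----------
    estimator_ : fitted probability model
    costs_ : misclassification cost per node
    """

    def __init__(self, hierarchy=None, estimator=None, weights=(1, 1, 1, 1),
                 decode_method="daglabel", threshold=0.5, sigma_mode="product"):
        self.hierarchy = hierarchy
        self.estimator = estimator
        self.weights = weights
        self.decode_method = decode_method
        self.threshold = threshold
        self.sigma_mode = sigma_mode

    def fit(self, X, Y):
        if self.hierarchy is None:
            raise ValueError("a DAGHierarchy must be supplied")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if Y.shape[1] != self.hierarchy.n_nodes:
            raise ValueError("label matrix columns must match hierarchy nodes")
        from sklearn.base import clone

        base = self.estimator if self.estimator is not None else LogisticNodeClassifier()
        self.estimator_ = clone(base)
        self.estimator_.fit(X, Y)
        self.costs_ = compute_costs(self.hierarchy)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        P = np.asarray(self.estimator_.predict_proba(np.asarray(X, dtype=float)))
        P = np.clip(P, 0.0, 1.0)
        P[:, 0] = 1.0
        return P

    def decision_function(self, X):
        """Per-node σ scores for each instance."""
        return sigma_matrix(self.hierarchy, self.predict_proba(X),
                            weights=self.weights, costs=self.costs_,
                            sigma_mode=self.sigma_mode)

    def predict(self, X):
        P = self.predict_proba(X)
        return decode_probabilities(self.hierarchy, P, self.decode_method,
                                    weights=self.weights, threshold=self.threshold,
                                    sigma_mode=self.sigma_mode)

    def score(self, X, Y):
        """Macro hierarchical F1 of the decoded predictions."""
        rep = evaluate_predictions(self.hierarchy, self.predict(X), np.asarray(Y))
        return rep["macro"]["hF1"]


@dataclass
class RunConfig:
    """File-driven pipeline configuration (serialised into the run manifest)."""

    hierarchy: str
    features: str
    labels: str
    out_dir: str = "dagbayes_run"
    estimator: str = "logistic"           # logistic | bilstm
    weights: tuple = (1.0, 1.0, 1.0, 1.0)
    decode_method: str = "daglabel"
    threshold: float = 0.5
    sigma_mode: str = "product"
    train_fraction: float = 2 / 3
    fit_fraction: float = 2 / 3
    seed: int = 0
    regularization: float = 1.0

    def to_dict(self):
        d = asdict(self)
        d["weights"] = list(self.weights)
        return d


def _load_aligned(config: RunConfig):
    """Load features and labels, aligning label columns to hierarchy names.

    Label columns are matched to hierarchy nodes by name; columns missing
    from (or absent in) the hierarchy raise an alignment error naming them.
    """
    h = parse_hierarchy(config.hierarchy)
    ids_x, X, _ = _io.read_matrix(config.features)
    ids_y, Y, node_names = _io.read_matrix(config.labels)
    if ids_x != ids_y:
        raise ValueError("feature and label files disagree on instance ids")
    if list(node_names) != list(h.names):
        missing = [n for n in h.names if n not in node_names]
        extra = [n for n in node_names if n not in h.names]
        if missing or extra:
            raise ValueError(
                "label columns do not match hierarchy node order; "
                f"missing={missing[:5]} unexpected={extra[:5]}")
        order = [node_names.index(n) for n in h.names]
        Y = Y[:, order]
    return h, ids_x, X, Y.astype(np.int8)


def _make_estimator(config: RunConfig, n_features, n_nodes):
    if config.estimator == "logistic":
        from .classify import build_logistic_baseline

        return build_logistic_baseline(n_features, n_nodes, config.regularization)
    if config.estimator == "bilstm":
        from .classify import build_reference_network

        return build_reference_network(n_features, n_nodes,
                                       random_state=config.seed)
    raise ValueError(f"unknown estimator {config.estimator!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Train, predict, σ, decode, evaluate; write predictions/report/manifest.

    The hierarchy, feature and label files must agree on node order and
    instance ids; mismatches raise with the offending columns named.
    """
    t0 = time.time()
    h, ids_x, X, Y = _load_aligned(config)
    logger.info("loaded %d instances, %d features, %d nodes",
                len(X), X.shape[1], h.n_nodes)

    spec = SplitSpec(config.train_fraction, config.fit_fraction, config.seed)
    idx = split_dataset(X, Y, spec)
    clf = HierarchicalBayesClassifier(
        hierarchy=h,
        estimator=_make_estimator(config, X.shape[1], h.n_nodes),
        weights=tuple(config.weights),
        decode_method=config.decode_method,
        threshold=config.threshold,
        sigma_mode=config.sigma_mode,
    )
    clf.fit(X[idx["fit"]], Y[idx["fit"]])
    te = idx["test"]
    P = clf.predict_proba(X[te])
    S = clf.decision_function(X[te])
    logger.debug("sigma matrix:\n%r", S)
    Y_hat = clf.predict(X[te])
    report = evaluate_predictions(h, Y_hat, Y[te])
    report["timing_s"] = round(time.time() - t0, 3)
    report["n_test"] = int(len(te))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    test_ids = [ids_x[i] for i in te]
    _io.write_matrix(out / "predictions.tsv", test_ids, Y_hat, h.names)
    _io.write_matrix(out / "probabilities.tsv", test_ids, P, h.names)
    _io.write_annotation_pairs(out / "annotations.tsv", test_ids, Y_hat, h.names)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "n_instances": len(X), "n_nodes": h.n_nodes,
                "versions": _versions()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def compare_methods(config: RunConfig, methods=("daglabel", "topdown", "downtop", "tpr")):
    """One comparison row per decode method, on identical probability inputs."""
    if not methods:
        raise ValueError("need at least one method")
    h, _, X, Y = _load_aligned(config)
    spec = SplitSpec(config.train_fraction, config.fit_fraction, config.seed)
    idx = split_dataset(X, Y, spec)
    clf = HierarchicalBayesClassifier(
        hierarchy=h, estimator=_make_estimator(config, X.shape[1], h.n_nodes),
        weights=tuple(config.weights), threshold=config.threshold,
        sigma_mode=config.sigma_mode)
    clf.fit(X[idx["fit"]], Y[idx["fit"]])
    te = idx["test"]
    P = clf.predict_proba(X[te])
    rows = []
    for m in methods:
        Y_hat = decode_probabilities(h, P, m, weights=tuple(config.weights),
                                     threshold=config.threshold,
                                     sigma_mode=config.sigma_mode)
        rep = evaluate_predictions(h, Y_hat, Y[te])
        rows.append({"method": m,
                     "micro_hPre": rep["micro"]["hPre"],
                     "micro_hRec": rep["micro"]["hRec"],
                     "micro_hF1": rep["micro"]["hF1"],
                     "macro_hPre": rep["macro"]["hPre"],
                     "macro_hRec": rep["macro"]["hRec"],
                     "macro_hF1": rep["macro"]["hF1"]})
    return rows


def _versions():
    import numpy, scipy, sklearn, networkx, pandas

    import dagbayes

    return {"dagbayes": dagbayes.__version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "networkx": networkx.__version__, "pandas": pandas.__version__}
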
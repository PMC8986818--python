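"""Hierarchical precision, recall and F1 on ancestor-augmented label sets.

Predicted and true term sets are first closed under the ancestor relation
(the root is excluded by default, since it is positive for every instance and
would otherwise guarantee a hit), then compared either pooled over all
instances (micro) or per instance and averaged (macro).
"""

from __future__ import annotations

import warnings

import numpy as np

from .hierarchy import DAGHierarchy, augment_with_ancestors

__all__ = ["micro_hf1", "macro_hf1", "evaluate_predictions", "label_matrix_to_sets"]


def _as_sets(items):
    return [frozenset(s) for s in items]


def micro_hf1(preds, trues):
    """Pooled hierarchical precision/recall/F1 over augmented label sets."""
    preds, trues = _as_sets(preds), _as_sets(trues)
    if len(preds) != len(trues):
        raise ValueError("prediction and truth lists differ in length")
    inter = sum(len(p & t) for p, t in zip(preds, trues))
    np_, nt = sum(map(len, preds)), sum(map(len, trues))
    if np_ == 0 and nt == 0:
        warnings.warn("all augmented sets empty; micro scores undefined, returning 0")
        return 0.0, 0.0, 0.0
    pre = inter / np_ if np_ else 0.0
    rec = inter / nt if nt else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return pre, rec, f1


def macro_hf1(preds, trues):
    """Instance-averaged hierarchical precision/recall/F1."""
    preds, trues = _as_sets(preds), _as_sets(trues)
    if len(preds) != len(trues):
        raise ValueError("prediction and truth lists differ in length")
    if not preds:
        raise ValueError("cannot average over zero instances")
    pres, recs, f1s = [], [], []
    for p, t in zip(preds, trues):
        inter = len(p & t)
        pre = inter / len(p) if p else 0.0
        rec = inter / len(t) if t else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
        pres.append(pre)
        recs.append(rec)
        f1s.append(f1)
    return float(np.mean(pres)), float(np.mean(recs)), float(np.mean(f1s))


def label_matrix_to_sets(h: DAGHierarchy, Y, include_root=False):
    """Rows of a binary label matrix → ancestor-augmented node sets."""
    Y = np.asarray(Y)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != h.n_nodes:
        raise ValueError("label matrix column count does not match hierarchy")
    return [
        augment_with_ancestors(h, np.flatnonzero(row), include_root=include_root)
        for row in Y
    ]


def evaluate_predictions(h: DAGHierarchy, Y_pred, Y_true, include_root=False) -> dict:
    """Full report: micro and macro hPre/hRec/hF1 plus per-instance values."""
    ps = label_matrix_to_sets(h, Y_pred, include_root)
    ts = label_matrix_to_sets(h, Y_true, include_root)
    mi = micro_hf1(ps, ts)
    ma = macro_hf1(ps, ts)
    per = []
    for p, t in zip(ps, ts):
        inter = len(p & t)
        pre = inter / len(p) if p else 0.0
        rec = inter / len(t) if t else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
        per.append({"hPre": pre, "hRec": rec, "hF1": f1})
    return {
        "micro": {"hPre": mi[0], "hRec": mi[1], "hF1": mi[2]},
        "macro": {"hPre": ma[0], "hRec": ma[1], "hF1": ma[2]},
        "per_instance": per,
    }
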
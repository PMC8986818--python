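"""Tabular I/O: instance×node TSV matrices, edge lists, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hierarchy import DAGHierarchy, hierarchy_summary


def read_matrix(path):
    """Read a TSV with instance ids in the first column.

    Returns (ids, values array, column names).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_node_matrix(path, h: DAGHierarchy):
    """Read an instance×node TSV and align its columns to the hierarchy order.

    Columns are matched by node name; a set mismatch raises, naming offenders.
    """
    ids, M, cols = read_matrix(path)
    if list(cols) == list(h.names):
        return ids, M
    missing = [n for n in h.names if n not in cols]
    extra = [n for n in cols if n not in h.names]
    if missing or extra:
        raise ValueError(f"node columns do not match hierarchy; "
                         f"missing={missing[:5]} unexpected={extra[:5]}")
    order = [cols.index(n) for n in h.names]
    return ids, M[:, order]


def write_matrix(path, ids, M, columns):
    M = np.asarray(M)
    df = pd.DataFrame(M, index=list(ids), columns=list(columns))
    df.index.name = "instance"
    df.to_csv(path, sep="\t")


def write_edges(path, h: DAGHierarchy):
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for a, b in h.to_edge_rows():
            fh.write(f"{a}\t{b}\n")


def write_summary(path, h: DAGHierarchy):
    rows = hierarchy_summary(h)
    df = pd.DataFrame(rows, columns=["node", "depth", "n_parents", "n_children", "cost"])
    df.to_csv(path, sep="\t", index=False)


def write_annotation_pairs(path, ids, Y, names):
    """Two-column (instance_id, term_id) rows for the positive, non-root labels."""
    Y = np.asarray(Y)
    with open(path, "w") as fh:
        fh.write("instance_id\tterm_id\n")
        for i, row in zip(ids, Y):
            for j in np.flatnonzero(row):
                if j != 0:
                    fh.write(f"{i}\t{names[j]}\n")
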
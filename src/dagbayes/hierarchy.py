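"""DAG label hierarchies: parsing, validation, queries, misclassification costs.

A label hierarchy is a rooted directed acyclic graph whose nodes are function
terms (e.g. Gene Ontology biological-process terms) and whose edges point from
the more general term (parent) to the more specific one (child).  Internally
nodes are the integers ``0..N-1`` with ``0`` the root; an optional name map
links internal indices to external term identifiers such as ``GO:0008150``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DAGHierarchy",
    "HierarchyError",
    "parse_hierarchy",
    "parse_edge_list",
    "parse_obo",
    "compute_costs",
    "is_consistent",
    "augment_with_ancestors",
    "enumerate_consistent",
]


class HierarchyError(ValueError):
    """Structural problem in a label hierarchy (cycle, orphan, bad edge)."""


@dataclass(frozen=True)
class DAGHierarchy:
    """A validated rooted DAG over label nodes ``0..N-1`` (root = 0).

    Parameters
    ----------
    n_nodes : int
        Number of nodes N.
    edges : tuple of (int, int)
        Parent→child edges.
    names : tuple of str, optional
        External identifier per node; defaults to the stringified index.
    """

    n_nodes: int
    edges: tuple
    names: tuple = ()
    # derived, filled in __post_init__
    parents: tuple = field(default=(), compare=False, repr=False)
    children: tuple = field(default=(), compare=False, repr=False)
    topo_order: tuple = field(default=(), compare=False, repr=False)

    def __post_init__(self):
        n = self.n_nodes
        if n < 1:
            raise HierarchyError("hierarchy needs at least a root node")
        raw = tuple(map(tuple, self.edges))
        edges = tuple(sorted(set(raw)))
        if len(edges) != len(raw):
            raise HierarchyError("duplicate edges in hierarchy")
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for u, v in edges:
            if u == v:
                raise HierarchyError(f"self-edge at node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise HierarchyError(f"edge ({u},{v}) references unknown node")
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise HierarchyError(f"hierarchy contains a cycle: {cyc}")
        if any(True for _ in g.predecessors(0)):
            raise HierarchyError("root node 0 has a parent")
        reach = {0} | nx.descendants(g, 0)
        if len(reach) != n:
            orphans = sorted(set(range(n)) - reach)
            raise HierarchyError(f"nodes unreachable from root: {orphans}")
        order = [u for u in nx.topological_sort(g)]
        parents = tuple(tuple(sorted(g.predecessors(i))) for i in range(n))
        children = tuple(tuple(sorted(g.successors(i))) for i in range(n))
        names = self.names or tuple(str(i) for i in range(n))
        if len(names) != n:
            raise HierarchyError("names length does not match n_nodes")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "parents", parents)
        object.__setattr__(self, "children", children)
        object.__setattr__(self, "topo_order", tuple(order))

    # -- queries ---------------------------------------------------------

    def _check_node(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise KeyError(f"unknown node {node}")

    def ancestors(self, node: int) -> frozenset:
        self._check_node(node)
        out, stack = set(), list(self.parents[node])
        while stack:
            u = stack.pop()
            if u not in out:
                out.add(u)
                stack.extend(self.parents[u])
        return frozenset(out)

    def descendants(self, node: int) -> frozenset:
        self._check_node(node)
        out, stack = set(), list(self.children[node])
        while stack:
            u = stack.pop()
            if u not in out:
                out.add(u)
                stack.extend(self.children[u])
        return frozenset(out)

    def siblings(self, node: int) -> frozenset:
        self._check_node(node)
        out = set()
        for p in self.parents[node]:
            out.update(self.children[p])
        out.discard(node)
        return frozenset(out)

    def relatives(self, node: int, relation: str) -> frozenset:
        """Nodes related to ``node``: parent/child/ancestor/descendant/sibling."""
        self._check_node(node)
        if relation == "parent":
            return frozenset(self.parents[node])
        if relation == "child":
            return frozenset(self.children[node])
        if relation == "ancestor":
            return self.ancestors(node)
        if relation == "descendant":
            return self.descendants(node)
        if relation == "sibling":
            return self.siblings(node)
        raise ValueError(f"unknown relation {relation!r}")

    def depths(self) -> np.ndarray:
        """Shortest-path depth from the root (root = 0)."""
        d = np.full(self.n_nodes, -1, dtype=int)
        d[0] = 0
        for u in self.topo_order:
            for v in self.children[u]:
                if d[v] < 0 or d[u] + 1 < d[v]:
                    d[v] = d[u] + 1
        return d

    def to_edge_rows(self):
        return [(self.names[u], self.names[v]) for u, v in self.edges]


# -- parsing ---------------------------------------------------------------


def _build_from_named_edges(named_edges, name_order=None) -> DAGHierarchy:
    """Relabel arbitrary named parent→child edges to 0..N-1 with a unique root.

    If several parentless terms exist, a virtual root is inserted above them.
    """
    named_edges = [(str(a), str(b)) for a, b in named_edges]
    nodes = list(dict.fromkeys(name_order or []))
    for a, b in named_edges:
        for t in (a, b):
            if t not in nodes:
                nodes.append(t)
    if not nodes:
        raise HierarchyError("empty hierarchy source")
    has_parent = {b for _, b in named_edges}
    roots = [t for t in nodes if t not in has_parent]
    if not roots:
        # every node has a parent: cycles — let the validator name one
        roots = nodes[:1]
    if len(roots) == 1:
        order = [roots[0]] + [t for t in nodes if t != roots[0]]
        idx = {t: i for i, t in enumerate(order)}
        edges = [(idx[a], idx[b]) for a, b in named_edges]
        return DAGHierarchy(len(order), tuple(edges), tuple(order))
    logger.info("inserting virtual root above %d parentless terms", len(roots))
    order = ["<root>"] + nodes
    idx = {t: i for i, t in enumerate(order)}
    edges = [(0, idx[r]) for r in roots]
    edges += [(idx[a], idx[b]) for a, b in named_edges]
    return DAGHierarchy(len(order), tuple(edges), tuple(order))


def parse_edge_list(rows) -> DAGHierarchy:
    """Build a hierarchy from two-column ``parent, child`` rows.

    Rows may be an iterable of pairs or of tab/whitespace-separated strings.
    A ``parent<TAB>child`` header row is skipped if present.
    """
    named = []
    for row in rows:
        if isinstance(row, str):
            row = row.rstrip("\n")
            if not row or row.startswith("#"):
                continue
            parts = row.split("\t") if "\t" in row else row.split()
        else:
            parts = list(row)
        if len(parts) != 2:
            raise HierarchyError(f"edge row must have 2 columns, got {parts!r}")
        if [str(p).lower() for p in parts] == ["parent", "child"]:
            continue
        named.append((parts[0], parts[1]))
    if not named:
        raise HierarchyError("no edges in source")
    return _build_from_named_edges(named)


def parse_obo(source, namespace=None, include_part_of=False) -> DAGHierarchy:
    """Parse an OBO ontology into a hierarchy.

    ``is_a`` relations always become parent→child edges; ``part_of`` only when
    ``include_part_of`` is set.  ``namespace`` keeps terms of one GO namespace
    (e.g. ``biological_process``).  Terms left unreachable from the namespace
    root after filtering are dropped with a warning.
    """
    import obonet

    g = obonet.read_obo(source)
    keep = set()
    for term, data in g.nodes(data=True):
        if namespace is None or data.get("namespace") == namespace:
            keep.add(term)
    rels = {"is_a"} | ({"part_of"} if include_part_of else set())
    named = []
    # obonet edges run child -> parent, keyed by relation
    for child, parent, rel in g.edges(keys=True):
        if rel in rels and child in keep and parent in keep:
            named.append((parent, child))
    if not named:
        raise HierarchyError("no edges after namespace/relation filtering")
    # drop terms not reachable from a parentless term via kept edges
    try:
        return _build_from_named_edges(named)
    except HierarchyError as err:
        if "unreachable" not in str(err):
            raise
        gg = nx.DiGraph(named)
        roots = [t for t in gg if gg.in_degree(t) == 0]
        reach = set(roots)
        for r in roots:
            reach |= nx.descendants(gg, r)
        dropped = [t for t in gg if t not in reach]
        logger.warning("dropping %d terms unreachable from root", len(dropped))
        named = [(a, b) for a, b in named if a in reach and b in reach]
        return _build_from_named_edges(named)


def parse_hierarchy(source, namespace=None, include_part_of=False) -> DAGHierarchy:
    """Parse a hierarchy from an OBO file/path or an edge-list.

    Dispatch: a path ending in ``.obo``, or text containing a ``[Term]``
    stanza, is treated as OBO; everything else as a two-column edge list.
    """
    if isinstance(source, DAGHierarchy):
        return source
    if isinstance(source, str) and "\n" not in source:
        if source.endswith(".obo"):
            return parse_obo(source, namespace, include_part_of)
        with open(source) as fh:
            text = fh.read()
        return parse_hierarchy(text.splitlines(), namespace, include_part_of)
    if isinstance(source, str):
        if "[Term]" in source:
            import io

            return parse_obo(io.StringIO(source), namespace, include_part_of)
        return parse_edge_list(source.splitlines())
    return parse_edge_list(source)


# -- constraint and costs --------------------------------------------------


def is_consistent(h: DAGHierarchy, y) -> bool:
    """True iff the binary vector obeys the true-path rule.

    Every positive node must have all its parents positive (root exempt);
    equivalently every negative node has only negative descendants.  Both
    clauses are the same condition; both are checked explicitly.
    """
    y = np.asarray(y)
    if y.shape != (h.n_nodes,):
        raise ValueError(f"label vector has shape {y.shape}, expected ({h.n_nodes},)")
    yb = y.astype(bool)
    down = all(all(yb[p] for p in h.parents[i]) for i in range(h.n_nodes) if yb[i])
    up = all(
        not any(yb[d] for d in h.descendants(i))
        for i in range(h.n_nodes)
        if not yb[i]
    )
    return bool(down and up)


def augment_with_ancestors(h: DAGHierarchy, labels, include_root=False) -> frozenset:
    """Close a node set under the ancestor relation; root excluded by default."""
    out = set()
    for i in labels:
        h._check_node(i)
        out.add(i)
        out |= h.ancestors(i)
    if not include_root:
        out.discard(0)
    return frozenset(out)


def compute_costs(h: DAGHierarchy) -> np.ndarray:
    """Recursive misclassification costs C_i.

    The root costs exactly 1; every other node receives each parent's cost
    divided evenly among that parent's children, summed over its parents.
    Nodes near the root are the most expensive to misclassify.
    """
    c = np.zeros(h.n_nodes)
    c[0] = 1.0
    for i in h.topo_order:
        if i == 0:
            continue
        c[i] = sum(c[j] / len(h.children[j]) for j in h.parents[i])
    return c


def enumerate_consistent(h: DAGHierarchy, max_nodes: int = 20) -> np.ndarray:
    """All hierarchy-consistent binary vectors (root always 1), as a K×N array.

    Exhaustive: refuses hierarchies larger than ``max_nodes``.
    """
    n = h.n_nodes
    if n > max_nodes:
        raise ValueError(f"enumeration refused for N={n} > {max_nodes}")
    vecs = [np.zeros(n, dtype=np.int8)]
    vecs[0][0] = 1
    for i in h.topo_order:
        if i == 0:
            continue
        new = []
        for v in vecs:
            if all(v[p] for p in h.parents[i]):
                w = v.copy()
                w[i] = 1
                new.append(w)
        vecs.extend(new)
    out = np.array(vecs, dtype=np.int8)
    # canonical order: fewest positives first, then lexicographic
    key = np.lexsort(tuple(out[:, j] for j in range(n - 1, -1, -1)) + (out.sum(1),))
    return out[key]


def hierarchy_summary(h: DAGHierarchy):
    """Per-node summary rows: name, depth, #parents, #children, cost."""
    d = h.depths()
    c = compute_costs(h)
    return [
        (h.names[i], int(d[i]), len(h.parents[i]), len(h.children[i]), float(c[i]))
        for i in range(h.n_nodes)
    ]
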
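"""Quartet-counting engines over unrooted trees.

Two independent algorithms are provided for every counting operation:

* an *exhaustive* engine that enumerates each qualifying four-taxon
  subset and classifies its induced topology with the four-point
  condition on topological (unit branch length) path distances; and
* a *fast* engine that obtains the same tallies in linear time from a
  single traversal, combining per-edge group counts combinatorially
  and subtracting a per-vertex correction so that each quartet is
  counted exactly once.

The fast engine is the default above a configurable quartet-count
threshold; the exhaustive engine doubles as its oracle in the test
suite. Both treat polytomies the same way: a quartet whose four paths
meet at a single vertex is unresolved and tallied separately.

Fast-engine correctness sketch: a quartet resolved as ab|cd is
separated by every edge on the internal path between its two Steiner
vertices (say the path has L >= 1 edges). Summing the product of
group counts over the two sides of every edge therefore counts the
quartet L times. Removing an internal vertex v splits the tree into
deg(v) components; the quartet contributes to the vertex sum exactly
when a,b fall in one component and c,d in another, which happens
precisely at the L-1 vertices strictly inside the path. The edge sum
minus the vertex sum is L - (L-1) = 1 per resolved quartet, and 0 for
unresolved quartets (no separating edge, no separating vertex).
"""

from __future__ import annotations

from itertools import combinations

import dendropy
import numpy as np

__all__ = [
    "UnrootedGraph",
    "graph_from_dendropy",
    "quad_counts_fast",
    "quad_counts_exhaustive",
    "bip_counts_fast",
    "bip_counts_exhaustive",
    "distance_matrix",
    "quartet_categories",
]


class UnrootedGraph:
    """Adjacency-list view of an unrooted tree.

    Degree-2 vertices (including the artificial bifurcating root that
    rooted newick representations introduce) are suppressed, with edge
    lengths summed, so each graph edge is one unrooted-tree branch.
    """

    __slots__ = ("adj", "lengths", "leaf_label", "label_leaf")

    def __init__(self, adj, lengths, leaf_label):
        self.adj: list[list[int]] = adj
        self.lengths: list[list[float]] = lengths
        self.leaf_label: dict[int, str] = leaf_label
        self.label_leaf: dict[str, int] = {v: k for k, v in leaf_label.items()}

    @property
    def n_vertices(self) -> int:
        return len(self.adj)

    @property
    def taxa(self) -> set[str]:
        return set(self.label_leaf)

    def rooted_order(self, root: int | None = None):
        """(order, parent) arrays for an iterative traversal from an
        internal vertex (any vertex if the tree is a single cherry).

        ``order`` lists vertices so that every vertex appears after its
        parent; iterating it in reverse is a postorder.
        """
        n = self.n_vertices
        if root is None:
            root = next(
                (v for v in range(n) if len(self.adj[v]) > 1), 0
            )
        parent = [-1] * n
        order = [root]
        parent[root] = root
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            for w in self.adj[v]:
                if w != v and parent[w] == -1:
                    parent[w] = v
                    order.append(w)
        parent[root] = -1
        return order, parent, root


def graph_from_dendropy(
    tree: dendropy.Tree, suppress_degree_two: bool = True
) -> UnrootedGraph:
    """Build the unrooted adjacency view of a dendropy tree."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[int]] = [[] for _ in range(n)]
    lengths: list[list[float]] = [[] for _ in range(n)]
    leaf_label: dict[int, str] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("leaf without a taxon label")
            leaf_label[i] = nd.taxon.label
        p = nd.parent_node
        if p is not None:
            j = index[id(p)]
            ln = nd.edge.length if nd.edge.length is not None else 0.0
            adj[i].append(j)
            lengths[i].append(ln)
            adj[j].append(i)
            lengths[j].append(ln)
    if not suppress_degree_two:
        return UnrootedGraph(adj, lengths, leaf_label)
    return _suppress_degree_two(adj, lengths, leaf_label)


def _suppress_degree_two(adj, lengths, leaf_label):
    n = len(adj)
    keep = [True] * n
    for v in range(n):
        if len(adj[v]) == 2 and v not in leaf_label:
            (a, la), (b, lb) = zip(adj[v], lengths[v])
            keep[v] = False
            # splice v out of both neighbours' lists
            ia = adj[a].index(v)
            adj[a][ia] = b
            lengths[a][ia] = la + lb
            ib = adj[b].index(v)
            adj[b][ib] = a
            lengths[b][ib] = la + lb
            adj[v] = []
            lengths[v] = []
    remap = {}
    for v in range(n):
        if keep[v]:
            remap[v] = len(remap)
    new_adj = [[remap[w] for w in adj[v]] for v in range(n) if keep[v]]
    new_len = [lengths[v] for v in range(n) if keep[v]]
    new_leaf = {remap[v]: lab for v, lab in leaf_label.items()}
    return UnrootedGraph(new_adj, new_len, new_leaf)


# ---------------------------------------------------------------------------
# fast (traversal) engine
# ---------------------------------------------------------------------------

def _group_assignment(graph: UnrootedGraph, groups) -> list[int]:
    """Vertex -> group index (-1 for internal vertices / unassigned taxa)."""
    assign = [-1] * graph.n_vertices
    for gi, gset in enumerate(groups):
        for tax in gset:
            v = graph.label_leaf.get(tax)
            if v is not None:
                assign[v] = gi
    return assign


def quad_counts_fast(graph: UnrootedGraph, groups) -> tuple[int, int, int, int]:
    """Counts of one-taxon-per-group quartets by topology class.

    Returns (n_main, n_alt1, n_alt2, n_unresolved) for groups
    (A, B, C, D), where main pairs A with B, alt1 pairs A with C and
    alt2 pairs A with D.
    """
    assign = _group_assignment(graph, groups)
    order, parent, root = graph.rooted_order()
    n = graph.n_vertices
    cnt = [None] * n
    for v in reversed(order):
        c = [0, 0, 0, 0]
        g = assign[v]
        if g >= 0:
            c[g] = 1
        for w in graph.adj[v]:
            if w != parent[v] and cnt[w] is not None:
                cw = cnt[w]
                c[0] += cw[0]
                c[1] += cw[1]
                c[2] += cw[2]
                c[3] += cw[3]
        cnt[v] = c
    tot = cnt[root]
    total_quartets = tot[0] * tot[1] * tot[2] * tot[3]
    if total_quartets == 0:
        return (0, 0, 0, 0)

    e_main = e_alt1 = e_alt2 = 0
    for v in order:
        if v == root:
            continue
        u = cnt[v]
        r = (tot[0] - u[0], tot[1] - u[1], tot[2] - u[2], tot[3] - u[3])
        e_main += u[0] * u[1] * r[2] * r[3] + r[0] * r[1] * u[2] * u[3]
        e_alt1 += u[0] * u[2] * r[1] * r[3] + r[0] * r[2] * u[1] * u[3]
        e_alt2 += u[0] * u[3] * r[1] * r[2] + r[0] * r[3] * u[1] * u[2]

    v_main = v_alt1 = v_alt2 = 0
    for v in order:
        if v in graph.leaf_label:
            continue
        comps = [cnt[w] for w in graph.adj[v] if w != parent[v]]
        if parent[v] != -1:
            u = cnt[v]
            comps.append(
                (tot[0] - u[0], tot[1] - u[1], tot[2] - u[2], tot[3] - u[3])
            )
        s_ab = sum(c[0] * c[1] for c in comps)
        s_cd = sum(c[2] * c[3] for c in comps)
        s_ac = sum(c[0] * c[2] for c in comps)
        s_bd = sum(c[1] * c[3] for c in comps)
        s_ad = sum(c[0] * c[3] for c in comps)
        s_bc = sum(c[1] * c[2] for c in comps)
        for c in comps:
            v_main += c[0] * c[1] * (s_cd - c[2] * c[3])
            v_main += c[2] * c[3] * (s_ab - c[0] * c[1])
            v_alt1 += c[0] * c[2] * (s_bd - c[1] * c[3])
            v_alt1 += c[1] * c[3] * (s_ac - c[0] * c[2])
            v_alt2 += c[0] * c[3] * (s_bc - c[1] * c[2])
            v_alt2 += c[1] * c[2] * (s_ad - c[0] * c[3])
    # each vertex ordered-pair term was accumulated twice (once from
    # the (ab, cd) orientation and once from (cd, ab)), matching the
    # two-orientation edge sum; halve to the ordered count.
    n_main = e_main - v_main // 2
    n_alt1 = e_alt1 - v_alt1 // 2
    n_alt2 = e_alt2 - v_alt2 // 2
    n_unres = total_quartets - n_main - n_alt1 - n_alt2
    return (n_main, n_alt1, n_alt2, n_unres)


def bip_counts_fast(graph: UnrootedGraph, X, Y) -> tuple[int, int, int]:
    """Counts of two-plus-two quartets across a bipartition X|Y.

    Returns (n_main, n_resolved, n_total) where n_main counts quartets
    (a,b in X; c,d in Y) displaying ab|cd and n_total counts all
    qualifying quartets.
    """
    assign = _group_assignment(graph, (X, Y))
    order, parent, root = graph.rooted_order()
    n = graph.n_vertices
    cnt = [None] * n
    for v in reversed(order):
        x = y = 0
        if assign[v] == 0:
            x = 1
        elif assign[v] == 1:
            y = 1
        for w in graph.adj[v]:
            if w != parent[v] and cnt[w] is not None:
                x += cnt[w][0]
                y += cnt[w][1]
        cnt[v] = (x, y)
    xt, yt = cnt[root]
    c2 = lambda k: k * (k - 1) // 2
    n_total = c2(xt) * c2(yt)
    if n_total == 0:
        return (0, 0, 0)

    e_main = e_mixed = 0
    for v in order:
        if v == root:
            continue
        xu, yu = cnt[v]
        xv, yv = xt - xu, yt - yu
        e_main += c2(xu) * c2(yv) + c2(xv) * c2(yu)
        e_mixed += xu * yu * xv * yv

    v_main = v_mixed = 0
    for v in order:
        if v in graph.leaf_label:
            continue
        comps = [cnt[w] for w in graph.adj[v] if w != parent[v]]
        if parent[v] != -1:
            xu, yu = cnt[v]
            comps.append((xt - xu, yt - yu))
        s_x2 = sum(c2(x) for x, _ in comps)
        s_y2 = sum(c2(y) for _, y in comps)
        s_xy = sum(x * y for x, y in comps)
        s_xy2 = sum((x * y) ** 2 for x, y in comps)
        for x, y in comps:
            v_main += c2(x) * (s_y2 - c2(y)) + c2(y) * (s_x2 - c2(x))
        v_mixed += (s_xy * s_xy - s_xy2) // 2
    n_main = e_main - v_main // 2
    n_mixed = e_mixed - v_mixed
    return (n_main, n_main + n_mixed, n_total)


# ---------------------------------------------------------------------------
# exhaustive (enumeration) engine
# ---------------------------------------------------------------------------

def distance_matrix(graph: UnrootedGraph, taxa, weighted: bool = False):
    """Pairwise path distances between the given taxa.

    Topological (unit-length) by default; patristic when ``weighted``.
    Returns (D, taxa_list) with D indexed by the returned taxon order.
    """
    taxa = [t for t in taxa if t in graph.label_leaf]
    m = len(taxa)
    D = np.zeros((m, m), dtype=float)
    for i, tax in enumerate(taxa):
        src = graph.label_leaf[tax]
        dist = _single_source(graph, src, weighted)
        for j in range(m):
            D[i, j] = dist[graph.label_leaf[taxa[j]]]
    return D, taxa


def _single_source(graph: UnrootedGraph, src: int, weighted: bool):
    n = graph.n_vertices
    dist = [np.inf] * n
    dist[src] = 0.0
    stack = [src]
    seen = [False] * n
    seen[src] = True
    while stack:
        v = stack.pop()
        for w, ln in zip(graph.adj[v], graph.lengths[v]):
            if not seen[w]:
                seen[w] = True
                dist[w] = dist[v] + (ln if weighted else 1.0)
                stack.append(w)
    return dist


def _classify(D, ia, ib, ic, id_):
    """Topology class of one quartet from unit path distances.

    0: ab|cd, 1: ac|bd, 2: ad|bc, 3: unresolved (star). By the
    four-point condition the smallest of the three pair sums is
    attained by the realized split; a three-way tie is a star.
    """
    s0 = D[ia, ib] + D[ic, id_]
    s1 = D[ia, ic] + D[ib, id_]
    s2 = D[ia, id_] + D[ib, ic]
    if s0 < s1 and s0 < s2:
        return 0
    if s1 < s0 and s1 < s2:
        return 1
    if s2 < s0 and s2 < s1:
        return 2
    return 3


def quad_counts_exhaustive(graph: UnrootedGraph, groups):
    """Brute-force tally over every one-taxon-per-group quartet."""
    present = [[t for t in g if t in graph.label_leaf] for g in groups]
    if any(not p for p in present):
        return (0, 0, 0, 0)
    taxa = sorted(set().union(*present))
    D, order = distance_matrix(graph, taxa)
    pos = {t: i for i, t in enumerate(order)}
    tally = [0, 0, 0, 0]
    for a in present[0]:
        for b in present[1]:
            for c in present[2]:
                for d in present[3]:
                    tally[_classify(D, pos[a], pos[b], pos[c], pos[d])] += 1
    return tuple(tally)


def bip_counts_exhaustive(graph: UnrootedGraph, X, Y):
    """Brute-force tally over every two-from-X, two-from-Y quartet."""
    xs = [t for t in X if t in graph.label_leaf]
    ys = [t for t in Y if t in graph.label_leaf]
    if len(xs) < 2 or len(ys) < 2:
        return (0, 0, 0)
    D, order = distance_matrix(graph, sorted(xs) + sorted(ys))
    pos = {t: i for i, t in enumerate(order)}
    n_main = n_resolved = n_total = 0
    for a, b in combinations(xs, 2):
        for c, d in combinations(ys, 2):
            n_total += 1
            cls = _classify(D, pos[a], pos[b], pos[c], pos[d])
            if cls == 0:
                n_main += 1
            if cls != 3:
                n_resolved += 1
    return (n_main, n_resolved, n_total)


def quartet_categories(D: np.ndarray, quartet_index: np.ndarray):
    """Vectorized topology classes for many quartets at once.

    ``quartet_index`` is an (m, 4) array of row indices into the unit
    path-distance matrix ``D``; the return is an (m,) int array with
    the same coding as the scalar classifier (3 = unresolved).
    """
    ia, ib, ic, id_ = quartet_index.T
    s = np.stack(
        [
            D[ia, ib] + D[ic, id_],
            D[ia, ic] + D[ib, id_],
            D[ia, id_] + D[ib, ic],
        ]
    )
    cls = np.argmin(s, axis=0)
    smin = s[cls, np.arange(s.shape[1])]
    n_at_min = (s == smin).sum(axis=0)
    cls[n_at_min > 1] = 3
    return cls
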
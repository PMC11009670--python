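"""Per-locus quartet-support statistics.

QQS (quadripartition quartet support) scores an internal branch of a
candidate species tree, encoded as four disjoint taxon groups
A.B|C.D, by the fraction of one-taxon-per-group quartets in a locus
tree that display ab|cd. Normalizing over the three possible pairings
makes the alternatives sum to one; a mean of 1/3 per alternative is
the hard-polytomy signature under the multispecies coalescent, and a
normalized QQS of exactly 1 is equivalent to mutual monophyly of A
and B among the taxa present.

BQS (branch quartet support) scores a single bipartition X|Y by the
fraction of two-plus-two quartets displaying it.

Loci in which some group has no representative yield *missing* values
(None / NaN), never zeros: downstream moving averages and window
tests are restricted to qualifying loci.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    GenomeTable,
    LocusTree,
    NormalizedQQS,
    Quadripartition,
    QuartetCounts,
    SupportTrack,
)
from .quartets import (
    UnrootedGraph,
    bip_counts_exhaustive,
    bip_counts_fast,
    distance_matrix,
    graph_from_dendropy,
    quad_counts_exhaustive,
    quad_counts_fast,
    quartet_categories,
)

__all__ = [
    "qqs",
    "bqs",
    "is_monophyletic",
    "clade_branch_length",
    "quartet_score",
    "taxon_removal_experiment",
    "tree_scale_factor",
    "qqs_track",
    "monophyly_track",
]

#: above this many qualifying quartets the linear-time traversal
#: counter is used instead of exhaustive enumeration
FAST_PATH_THRESHOLD = 30

#: conventional cutoff below which a branch's (weighted) mean QQS marks
#: a high-ILS node; carried as a labeled constant for configuration and
#: reporting -- this package does not define the weighting scheme
HIGH_ILS_QQS_THRESHOLD = 0.37


def _graph(tree) -> UnrootedGraph:
    if isinstance(tree, UnrootedGraph):
        return tree
    if isinstance(tree, LocusTree):
        return tree.graph
    return graph_from_dendropy(tree)


def _check_binary(graph: UnrootedGraph) -> None:
    for v in range(graph.n_vertices):
        deg = len(graph.adj[v])
        if deg not in (1, 3) and graph.n_vertices > 2:
            raise ValueError("strict mode: tree is not fully resolved")


def qqs(
    tree,
    quad: Quadripartition | Sequence[frozenset],
    method: str = "auto",
    strict: bool = False,
) -> NormalizedQQS | None:
    """Normalized quadripartition quartet support of one locus tree.

    Returns None (missing) when some group has no taxon in the tree or
    every qualifying quartet is unresolved. With ``strict`` a
    non-binary tree raises instead of tallying unresolved quartets.
    """
    groups = quad.groups() if isinstance(quad, Quadripartition) else tuple(quad)
    g = _graph(tree)
    if strict:
        _check_binary(g)
    present = [sum(1 for t in grp if t in g.label_leaf) for grp in groups]
    if any(p == 0 for p in present):
        return None
    n_qual = int(np.prod([float(p) for p in present]))
    if method == "fast" or (method == "auto" and n_qual > FAST_PATH_THRESHOLD):
        tally = quad_counts_fast(g, groups)
    else:
        tally = quad_counts_exhaustive(g, groups)
    counts = QuartetCounts(*tally)
    if counts.n_resolved == 0:
        return None
    r = counts.n_resolved
    return NormalizedQQS(
        q_main=counts.n_main / r,
        q_alt1=counts.n_alt1 / r,
        q_alt2=counts.n_alt2 / r,
        counts=counts,
    )


def bqs(tree, X, Y, method: str = "auto") -> float | None:
    """Branch quartet support for bipartition X|Y, or None if fewer
    than two taxa of either side are present (or nothing resolved)."""
    g = _graph(tree)
    nx = sum(1 for t in X if t in g.label_leaf)
    ny = sum(1 for t in Y if t in g.label_leaf)
    if nx < 2 or ny < 2:
        return None
    n_qual = nx * (nx - 1) // 2 * (ny * (ny - 1) // 2)
    if method == "fast" or (method == "auto" and n_qual > FAST_PATH_THRESHOLD):
        n_main, n_resolved, _ = bip_counts_fast(g, X, Y)
    else:
        n_main, n_resolved, _ = bip_counts_exhaustive(g, X, Y)
    if n_resolved == 0:
        return None
    return n_main / n_resolved


def _subtree_leaf_counts(g: UnrootedGraph, inside: set[int]):
    order, parent, root = g.rooted_order()
    n = g.n_vertices
    cnt_in = [0] * n
    cnt_all = [0] * n
    for v in reversed(order):
        ci = 1 if v in inside else 0
        ca = 1 if v in g.leaf_label else 0
        for w in g.adj[v]:
            if w != parent[v]:
                ci += cnt_in[w]
                ca += cnt_all[w]
        cnt_in[v] = ci
        cnt_all[v] = ca
    return order, parent, root, cnt_in, cnt_all


def is_monophyletic(tree, clade, outgroup) -> int | None:
    """1 if the present clade taxa are separated by some branch from
    all other present taxa (outgroup included), 0 otherwise, None if
    no clade taxon or no outgroup taxon is present."""
    clade = frozenset(clade)
    outgroup = frozenset(outgroup)
    if clade & outgroup:
        raise ValueError(
            f"clade and outgroup overlap: {sorted(clade & outgroup)}"
        )
    g = _graph(tree)
    present = {v for v, lab in g.leaf_label.items() if lab in clade}
    out_present = any(lab in outgroup for lab in g.label_leaf)
    if not present or not out_present:
        return None
    return 1 if _find_clade_edge(g, present) is not None else 0


def _find_clade_edge(g: UnrootedGraph, inside: set[int]):
    """(vertex, length) for the edge separating the ``inside`` leaves
    from all other leaves, or None."""
    n_in = len(inside)
    n_out = len(g.leaf_label) - n_in
    if n_out == 0:
        return None
    order, parent, root, cnt_in, cnt_all = _subtree_leaf_counts(g, inside)
    # prefer the clade-side edge: with a bifurcating-root newick the
    # uniting branch may be split across the root, and the clade-side
    # piece is the branch length the input tree assigns to the clade
    fallback = None
    for v in order:
        if v == root:
            continue
        below_in, below_all = cnt_in[v], cnt_all[v]
        ln = g.lengths[v][g.adj[v].index(parent[v])]
        if below_in == n_in and below_all == n_in:
            return v, ln
        if fallback is None and below_in == 0 and below_all == n_out:
            fallback = (v, ln)
    return fallback


def clade_branch_length(tree, clade, outgroup) -> float | None:
    """Length of the branch uniting the present clade taxa, in the
    tree's branch-length units; None when the clade is not
    monophyletic in this tree (or does not qualify)."""
    mono = is_monophyletic(tree, clade, outgroup)
    if not mono:
        return None
    if isinstance(tree, UnrootedGraph):
        g = tree
    else:
        dtree = tree.tree if isinstance(tree, LocusTree) else tree
        g = graph_from_dendropy(dtree, suppress_degree_two=False)
    inside = {v for v, lab in g.leaf_label.items() if lab in frozenset(clade)}
    hit = _find_clade_edge(g, inside)
    return hit[1] if hit is not None else None


def quartet_score(tree, candidate) -> float | None:
    """Fraction of the locus tree's resolved quartets (over taxa shared
    with the candidate species tree) that match the candidate's induced
    quartet topology; quartets the candidate leaves unresolved are
    excluded from the denominator."""
    g1 = _graph(tree)
    g2 = _graph(candidate)
    shared = sorted(g1.taxa & g2.taxa)
    if len(shared) < 4:
        return None
    D1, order = distance_matrix(g1, shared)
    D2, _ = distance_matrix(g2, shared)
    idx = np.array(list(combinations(range(len(shared)), 4)), dtype=np.intp)
    c1 = quartet_categories(D1, idx)
    c2 = quartet_categories(D2, idx)
    both = (c1 != 3) & (c2 != 3)
    denom = int(both.sum())
    if denom == 0:
        return None
    return float((c1[both] == c2[both]).sum() / denom)


def taxon_removal_experiment(
    trees: Iterable[LocusTree],
    candidate_a,
    candidate_b,
    removal_sets: dict[str, Iterable[str]],
) -> pd.DataFrame:
    """Per removal set, distribution of the per-locus quartet-score
    difference score(candidate_a) - score(candidate_b).

    Taxa in a removal set are pruned (ignored) in both candidates, so
    quartets touching them are excluded on both sides. A positive mean
    difference indicates that quartet-based species-tree estimation
    would favour candidate A. Loci where either score is undefined are
    excluded and counted in ``n_missing``.
    """
    ga = _graph(candidate_a)
    gb = _graph(candidate_b)
    graphs = [(lt.locus_id, _graph(lt)) for lt in trees]
    rows = []
    for label, removal in removal_sets.items():
        removal = frozenset(removal)
        keep_a = ga.taxa - removal
        keep_b = gb.taxa - removal
        diffs = []
        n_missing = 0
        a_sub = _restrict(ga, keep_a)
        b_sub = _restrict(gb, keep_b)
        for _, g in graphs:
            sa = quartet_score(g, a_sub)
            sb = quartet_score(g, b_sub)
            if sa is None or sb is None:
                n_missing += 1
                continue
            diffs.append(sa - sb)
        if not diffs:
            raise ValueError(
                f"removal {label!r}: no locus retains >=4 shared taxa"
            )
        d = np.asarray(diffs)
        rows.append(
            {
                "removal": label,
                "n_removed": len(removal),
                "n_loci": len(d),
                "n_missing": n_missing,
                "mean": d.mean(),
                "median": float(np.median(d)),
                "se": d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _restrict(g: UnrootedGraph, keep: frozenset) -> UnrootedGraph:
    """Graph restricted to the ``keep`` taxa (topology-preserving)."""
    from .io import parse_newick  # local import to avoid cycle

    newick = _graph_to_newick(g, keep)
    return graph_from_dendropy(parse_newick(newick))


def _graph_to_newick(g: UnrootedGraph, keep: frozenset | None = None) -> str:
    order, parent, root = g.rooted_order()
    keep = keep if keep is not None else frozenset(g.taxa)

    sub = {}
    for v in reversed(order):
        if v in g.leaf_label:
            lab = g.leaf_label[v]
            sub[v] = lab if lab in keep else None
            continue
        parts = []
        for w, ln in zip(g.adj[v], g.lengths[v]):
            if w == parent[v]:
                continue
            s = sub[w]
            if s is not None:
                parts.append(f"{s}:{ln:.10g}")
        if not parts:
            sub[v] = None
        elif len(parts) == 1:
            # collapse pass-through vertex; keep the child label, the
            # stitched length is irrelevant for topology-only use
            sub[v] = parts[0].rsplit(":", 1)[0]
        else:
            sub[v] = "(" + ",".join(parts) + ")"
    if sub[root] is None:
        raise ValueError("restriction removed every taxon")
    s = sub[root]
    if not s.startswith("("):
        s = f"({s})"
    return s + ";"


def tree_scale_factor(tree_a, tree_b) -> float:
    """Zero-intercept least-squares slope regressing tree_b's pairwise
    patristic distances on tree_a's, over all shared-taxon pairs.

    The slope rescales tree_a's branch lengths onto tree_b's scale,
    e.g. for correcting the compressed branch lengths of trees built
    from conserved markers.
    """
    ga = _graph(tree_a)
    gb = _graph(tree_b)
    shared = sorted(ga.taxa & gb.taxa)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared taxa; need >= 3")
    Da, _ = distance_matrix(ga, shared, weighted=True)
    Db, _ = distance_matrix(gb, shared, weighted=True)
    iu = np.triu_indices(len(shared), k=1)
    x = Da[iu]
    y = Db[iu]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all pairwise distances in tree_a are zero")
    return float(np.dot(x, y) / sxx)


# ---------------------------------------------------------------------------
# track builders
# ---------------------------------------------------------------------------

def qqs_track(
    trees: Sequence[LocusTree],
    table: GenomeTable,
    quad: Quadripartition,
    component: str = "q_main",
) -> SupportTrack:
    """Per-locus normalized QQS aligned to the genome table."""
    by_id = {lt.locus_id: lt for lt in trees}
    values = np.full(len(table), np.nan)
    for i, locus_id in enumerate(table.locus_ids):
        lt = by_id.get(locus_id)
        if lt is None:
            continue
        res = qqs(lt, quad)
        if res is not None:
            values[i] = getattr(res, component)
    return SupportTrack(table=table, values=values, name=f"qqs_{quad.name}")


def monophyly_track(
    trees: Sequence[LocusTree],
    table: GenomeTable,
    quad: Quadripartition,
) -> SupportTrack:
    """Binary mutual-monophyly (of A+B) track; a locus qualifies only
    when every side of the quadripartition has a present taxon."""
    by_id = {lt.locus_id: lt for lt in trees}
    clade = quad.A | quad.B
    rest = quad.C | quad.D
    values = np.full(len(table), np.nan)
    for i, locus_id in enumerate(table.locus_ids):
        lt = by_id.get(locus_id)
        if lt is None:
            continue
        taxa = lt.taxa
        if not all(g & taxa for g in quad.groups()):
            continue
        values[i] = float(is_monophyletic(lt, clade, rest & taxa) or 0)
    return SupportTrack(table=table, values=values, name=f"mono_{quad.name}")
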
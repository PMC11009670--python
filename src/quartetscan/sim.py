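"""Synthetic-data generator: MSC locus trees with a planted
discordance-free block, plus auxiliary population-genetic calculators.

The generator emulates the structure of a chromosome-scale locus-tree
dataset: loci ordered along chromosomes, genealogies drawn
independently from the multispecies coalescent (MSC) on a species
tree with a short focal internal branch (high incomplete lineage
sorting), per-tree topology error modelled as random
nearest-neighbour-interchange (NNI) moves, and per-taxon dropout. A
contiguous *planted block* of loci is instead drawn from an
alternative species tree whose uniting branch is long (several
coalescent units), so essentially every block locus shares a single
topology that conflicts with the background species tree -- the
signature of a recombination-suppressed, supergene-like segment.

Also provided: the expected equilibrium recombination-free window
size 1/(2*Ne*r), and a neutral Wright-Fisher simulator for the
probability that a polymorphism (e.g. a chromosomal rearrangement
segregating in an ancestral population) persists for a given number
of generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .model import GenomeTable, LocusTree

__all__ = [
    "SimConfig",
    "WrightFisherConfig",
    "SpeciesTree",
    "sample_msc_gene_tree",
    "simulate_genome",
    "recombination_free_window",
    "wf_persistence",
    "wf_persistence_exact",
    "default_species_tree",
    "default_block_tree",
    "default_clade_model",
    "default_sim_config",
]

ULTRAMETRIC_TOL = 1e-6


# ---------------------------------------------------------------------------
# species tree (coalescent units)
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted, ultrametric species tree with branch lengths in
    coalescent units (2*Ne generations), preprocessed for sampling."""

    def __init__(self, newick: str, samples_per_tip: int = 1):
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("species tree has a negative branch length")
        depth: dict[int, float] = {id(tree.seed_node): 0.0}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                depth[id(nd)] = depth[id(nd.parent_node)] + (
                    nd.edge.length or 0.0
                )
        leaf_depths = [depth[id(lf)] for lf in tree.leaf_node_iter()]
        dmax = max(leaf_depths)
        if max(leaf_depths) - min(leaf_depths) > ULTRAMETRIC_TOL:
            raise ValueError(
                "species tree must be ultrametric in coalescent units "
                f"(leaf depths range {min(leaf_depths):.6g}.."
                f"{max(leaf_depths):.6g})"
            )
        # postorder arrays
        self.children: list[list[int]] = []
        self.age: list[float] = []
        self.label: list[str | None] = []
        index: dict[int, int] = {}
        for nd in tree.postorder_node_iter():
            i = len(self.children)
            index[id(nd)] = i
            self.children.append([index[id(c)] for c in nd.child_nodes()])
            self.age.append(dmax - depth[id(nd)])
            self.label.append(nd.taxon.label if nd.is_leaf() else None)
        self.root = len(self.children) - 1
        self.samples_per_tip = samples_per_tip
        self.taxa = frozenset(l for l in self.label if l is not None)
        self.newick = newick


class _GNode:
    """Lightweight genealogy node (ages in coalescent units)."""

    __slots__ = ("children", "label", "age", "length")

    def __init__(self, children, label, age):
        self.children = children
        self.label = label
        self.age = age
        self.length = 0.0


def sample_msc_gene_tree(
    species_tree: SpeciesTree | str,
    rng: np.random.Generator,
) -> _GNode:
    """Draw one genealogy from the MSC on the species tree.

    Within each species-tree branch of length T coalescent units,
    every pair of resident lineages coalesces at rate 1; lineages
    still distinct at the top of a branch are handed to the ancestral
    branch, and the root branch extends to infinity. Returns the root
    of a binary genealogy whose node ages are in coalescent units;
    ``genealogy_to_locus_tree`` converts to substitution-unit branch
    lengths.
    """
    sp = (
        species_tree
        if isinstance(species_tree, SpeciesTree)
        else SpeciesTree(species_tree)
    )
    _ensure_parent_ages(sp)
    pending: list[list[_GNode]] = [None] * (sp.root + 1)
    for i in range(sp.root + 1):
        if not sp.children[i]:
            tip_age = sp.age[i]
            if sp.samples_per_tip == 1:
                lineages = [_GNode(None, sp.label[i], tip_age)]
            else:
                lineages = [
                    _GNode(None, f"{sp.label[i]}_{k + 1}", tip_age)
                    for k in range(sp.samples_per_tip)
                ]
        else:
            lineages = []
            for c in sp.children[i]:
                lineages.extend(pending[c])
                pending[c] = None
        t = sp.age[i]
        upper = math.inf if i == sp.root else None
        if upper is None:
            # parent age: in postorder the parent comes later; find via
            # precomputed parent ages
            upper = sp._parent_age[i]
        k = len(lineages)
        while k >= 2:
            t_next = t + rng.exponential(2.0 / (k * (k - 1)))
            if t_next >= upper:
                break
            t = t_next
            a = int(rng.integers(k))
            b = int(rng.integers(k - 1))
            if b >= a:
                b += 1
            na, nb = lineages[a], lineages[b]
            merged = _GNode([na, nb], None, t)
            lineages[min(a, b)] = merged
            lineages[max(a, b)] = lineages[k - 1]
            lineages.pop()
            k -= 1
        pending[i] = lineages
    root_lineages = pending[sp.root]
    assert len(root_lineages) == 1
    root = root_lineages[0]
    _set_lengths(root)
    return root


def _parent_ages(sp: SpeciesTree) -> list[float]:
    pa = [math.inf] * (sp.root + 1)
    for i in range(sp.root + 1):
        for c in sp.children[i]:
            pa[c] = sp.age[i]
    return pa


# attach lazily so SpeciesTree stays a plain container
def _ensure_parent_ages(sp: SpeciesTree):
    if not hasattr(sp, "_parent_age"):
        sp._parent_age = _parent_ages(sp)


def _set_lengths(root: _GNode) -> None:
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children:
            for c in nd.children:
                c.length = nd.age - c.age
                stack.append(c)
    root.length = 0.0


def _copy_gnode(nd: _GNode) -> _GNode:
    out = _GNode(
        [_copy_gnode(c) for c in nd.children] if nd.children else None,
        nd.label,
        nd.age,
    )
    out.length = nd.length
    return out


def _leaves(root: _GNode) -> list[_GNode]:
    out = []
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children:
            stack.extend(nd.children)
        else:
            out.append(nd)
    return out


def nni_perturb(root: _GNode, rng: np.random.Generator, n_moves: int) -> None:
    """Apply random NNI moves in place (gene-tree error model).

    Each move picks a random internal edge of the unrooted topology
    and swaps one subtree across it; moved subtrees keep their own
    branch lengths, so node ages need not remain ultrametric --
    mirroring how estimation error perturbs both topology and lengths.
    """
    for _ in range(n_moves):
        # internal non-root nodes with their parents
        cand = []
        stack = [(root, None)]
        while stack:
            nd, parent = stack.pop()
            if nd.children:
                if parent is not None:
                    cand.append((nd, parent))
                for c in nd.children:
                    stack.append((c, nd))
        if not cand:
            return
        v, u = cand[int(rng.integers(len(cand)))]
        siblings = [c for c in u.children if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        u.children[u.children.index(s)] = c
        v.children[v.children.index(c)] = s


def drop_taxa(
    root: _GNode, rng: np.random.Generator, p_dropout: float, min_keep: int = 4
) -> _GNode:
    """Remove each leaf independently with probability ``p_dropout``;
    if fewer than ``min_keep`` leaves would remain, a random subset of
    ``min_keep`` leaves is kept instead."""
    leaves = _leaves(root)
    keep_mask = rng.random(len(leaves)) >= p_dropout
    if keep_mask.sum() < min_keep:
        keep_idx = rng.choice(len(leaves), size=min_keep, replace=False)
        keep_mask = np.zeros(len(leaves), dtype=bool)
        keep_mask[keep_idx] = True
    keep = {leaves[i].label for i in range(len(leaves)) if keep_mask[i]}
    pruned = _prune(root, keep)
    return pruned


def _prune(nd: _GNode, keep: set) -> _GNode | None:
    if not nd.children:
        return nd if nd.label in keep else None
    new_children = []
    for c in nd.children:
        pc = _prune(c, keep)
        if pc is not None:
            new_children.append(pc)
    if not new_children:
        return None
    if len(new_children) == 1:
        child = new_children[0]
        child.length += nd.length
        return child
    nd.children = new_children
    return nd


def genealogy_to_newick(root: _GNode, scale: float = 1.0) -> str:
    """Newick string with branch lengths multiplied by ``scale``
    (e.g. expected substitutions per site per coalescent unit)."""
    parts: list[str] = []

    def rec(nd: _GNode, top: bool) -> str:
        if not nd.children:
            s = nd.label
        else:
            s = "(" + ",".join(rec(c, False) for c in nd.children) + ")"
        if top:
            return s
        return f"{s}:{nd.length * scale:.10g}"

    body = rec(root, True)
    if not body.startswith("("):
        body = f"({body})"
    return body + ";"


def _gnode_to_dendropy(root: _GNode, scale: float) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(g: _GNode) -> dendropy.Node:
        nd = dendropy.Node()
        nd.edge.length = g.length * scale
        if g.children:
            for c in g.children:
                nd.add_child(build(c))
        else:
            nd.taxon = tns.new_taxon(label=g.label)
        return nd

    tree.seed_node = build(root)
    tree.seed_node.edge.length = None
    tree.is_rooted = False
    return tree


def _gnode_to_graph(root: _GNode, scale: float):
    """Adjacency view of a genealogy, bypassing dendropy."""
    from .quartets import UnrootedGraph, _suppress_degree_two

    adj: list[list[int]] = []
    lengths: list[list[float]] = []
    leaf_label: dict[int, str] = {}
    stack = [(root, -1)]
    while stack:
        g, pi = stack.pop()
        i = len(adj)
        adj.append([])
        lengths.append([])
        if pi >= 0:
            ln = g.length * scale
            adj[i].append(pi)
            lengths[i].append(ln)
            adj[pi].append(i)
            lengths[pi].append(ln)
        if g.children:
            for c in g.children:
                stack.append((c, i))
        else:
            leaf_label[i] = g.label
    return _suppress_degree_two(adj, lengths, leaf_label)


def genealogy_to_locus_tree(
    root: _GNode, locus_id: str, scale: float = 1.0
) -> LocusTree:
    """LocusTree view of a genealogy: the adjacency graph is built
    immediately (cheap, sufficient for quartet statistics); the
    dendropy tree materializes only on first access (the hot path
    when simulating many loci never needs it)."""
    return LocusTree(
        locus_id,
        tree_factory=lambda: _gnode_to_dendropy(root, scale),
        graph=_gnode_to_graph(root, scale),
    )


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a simulated locus-tree genome.

    Branch lengths of both species trees are in coalescent units and
    must be ultrametric. The planted block spans
    [block_start, block_start + block_length) in genome-wide locus
    ordinals and must lie within one chromosome. ``mean_nni`` is the
    Poisson mean of NNI error moves per tree; ``dropout`` the
    per-taxon missingness probability; ``subs_per_coal`` converts
    coalescent units to expected substitutions per site.
    """

    species_tree: str
    block_species_tree: str | None = None
    n_loci: int = 5000
    n_chromosomes: int = 3
    locus_length: int = 1000
    locus_spacing: int = 10_000
    block_start: int | None = None
    block_length: int = 0
    mean_nni: float = 1.0
    dropout: float = 0.1
    autocorr: float = 0.0
    subs_per_coal: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("n_loci and n_chromosomes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.mean_nni < 0:
            raise ValueError("mean_nni must be >= 0")
        if self.block_length < 0 or self.block_length > self.n_loci:
            raise ValueError("block must lie within [0, n_loci]")
        if not 0.0 <= self.autocorr < 1.0:
            raise ValueError("autocorr must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _chromosome_layout(cfg: SimConfig):
    """Per-locus (chrom, start, end) plus per-chromosome locus counts."""
    base = cfg.n_loci // cfg.n_chromosomes
    counts = [base] * cfg.n_chromosomes
    for i in range(cfg.n_loci - base * cfg.n_chromosomes):
        counts[i] += 1
    chroms, starts, ends = [], [], []
    for ci, n in enumerate(counts, start=1):
        for j in range(n):
            start = 1 + j * cfg.locus_spacing
            chroms.append(f"chr{ci}")
            starts.append(start)
            ends.append(start + cfg.locus_length - 1)
    return chroms, starts, ends, counts


def simulate_genome(
    cfg: SimConfig,
) -> tuple[GenomeTable, list[LocusTree], np.ndarray]:
    """Simulate the locus-tree genome described by ``cfg``.

    Returns (table, trees, truth) where ``truth`` is a boolean array
    marking planted-block membership, aligned to the table.
    """
    rng = np.random.default_rng(cfg.seed)
    sp = SpeciesTree(cfg.species_tree)
    _ensure_parent_ages(sp)
    bsp = None
    if cfg.block_length > 0:
        if cfg.block_species_tree is None:
            raise ValueError(
                "block_length > 0 requires a block_species_tree"
            )
        bsp = SpeciesTree(cfg.block_species_tree)
        _ensure_parent_ages(bsp)
        if bsp.taxa != sp.taxa:
            raise ValueError(
                "block species tree must cover the same taxa as the "
                f"background tree (difference: "
                f"{sorted(bsp.taxa ^ sp.taxa)})"
            )
    chroms, starts, ends, counts = _chromosome_layout(cfg)

    block_start = cfg.block_start
    if cfg.block_length > 0 and block_start is None:
        # center the block on the second chromosome when there is one
        ci = 1 if cfg.n_chromosomes > 1 else 0
        offset = sum(counts[:ci])
        block_start = offset + max(0, (counts[ci] - cfg.block_length) // 2)
    truth = np.zeros(cfg.n_loci, dtype=bool)
    if cfg.block_length > 0:
        b0, b1 = block_start, block_start + cfg.block_length
        if b0 < 0 or b1 > cfg.n_loci:
            raise ValueError("block extends outside the genome")
        if chroms[b0] != chroms[b1 - 1]:
            raise ValueError("planted block must lie within one chromosome")
        truth[b0:b1] = True

    trees: list[LocusTree] = []
    rows = []
    width = len(str(cfg.n_loci))
    prev_clean = None  # (chrom, in_block, genealogy) for the autocorr knob
    for i in range(cfg.n_loci):
        locus_id = f"L{i:0{width}d}"
        src = bsp if truth[i] else sp
        if (
            cfg.autocorr > 0.0
            and prev_clean is not None
            and prev_clean[0] == chroms[i]
            and prev_clean[1] == bool(truth[i])
            and rng.random() < cfg.autocorr
        ):
            clean = prev_clean[2]
        else:
            clean = sample_msc_gene_tree(src, rng)
        if cfg.autocorr > 0.0:
            prev_clean = (chroms[i], bool(truth[i]), clean)
            g = _copy_gnode(clean)
        else:
            g = clean
        n_moves = int(rng.poisson(cfg.mean_nni))
        if n_moves:
            nni_perturb(g, rng, n_moves)
        if cfg.dropout > 0:
            g = drop_taxa(g, rng, cfg.dropout)
        trees.append(
            genealogy_to_locus_tree(g, locus_id, scale=cfg.subs_per_coal)
        )
        rows.append((locus_id, chroms[i], starts[i], ends[i]))
    table = GenomeTable(
        pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])
    )
    return table, trees, truth


# ---------------------------------------------------------------------------
# defaults emulating the study conditions
# ---------------------------------------------------------------------------

def default_species_tree(t_focal: float = 0.025) -> str:
    """Background species tree (coalescent units): four taxon groups
    A (3 tips), B (3), C (4) and outgroup O (2); B and C are sisters
    and the branch above their ancestor has length ``t_focal``, short
    enough that gene trees are highly discordant for that split."""
    a = "(A1:1.0,(A2:0.5,A3:0.5):0.5)"
    b = "(B1:1.0,(B2:0.5,B3:0.5):0.5)"
    c = "((C1:0.5,C2:0.5):0.5,(C3:0.5,C4:0.5):0.5)"
    o = "(O1:0.5,O2:0.5)"
    t = t_focal
    return (
        f"((({b}:2.0,{c}:2.0):{t:.10g},{a}:{2.0 + t:.10g}):{3.0 - t:.10g},"
        f"{o}:5.5);"
    )


def default_block_tree(block_depth: float = 5.0) -> str:
    """Planted-block species tree: A and B united by a branch of
    ``block_depth`` coalescent units (essentially discordance-free),
    conflicting with the background tree's B+C pairing; coalescences
    along that branch are correspondingly deeper."""
    a = "(A1:1.0,(A2:0.5,A3:0.5):0.5)"
    b = "(B1:1.0,(B2:0.5,B3:0.5):0.5)"
    c = "((C1:0.5,C2:0.5):0.5,(C3:0.5,C4:0.5):0.5)"
    o = "(O1:0.5,O2:0.5)"
    d = block_depth
    return (
        f"((({a}:2.0,{b}:2.0):{d:.10g},{c}:{2.0 + d:.10g}):2.0,"
        f"{o}:{4.5 + d:.10g});"
    )


def default_clade_model():
    """Clade model matching the default simulated taxa: the planted
    (A+B) branch, the background species-tree (B+C) branch, and a
    control branch internal to group C that the planted block does
    not affect."""
    from .model import Bipartition, CladeModel, Quadripartition

    A = frozenset({"A1", "A2", "A3"})
    B = frozenset({"B1", "B2", "B3"})
    C = frozenset({"C1", "C2", "C3", "C4"})
    O = frozenset({"O1", "O2"})
    groups = {"A": A, "B": B, "C": C, "O": O}
    quads = [
        Quadripartition("planted_AB", A, B, C, O),
        Quadripartition("species_BC", B, C, A, O),
        Quadripartition(
            "control_C",
            frozenset({"C1", "C2"}),
            frozenset({"C3", "C4"}),
            A | B,
            O,
        ),
    ]
    bips = [Bipartition("planted_AB", A | B, C | O)]
    return CladeModel(
        groups=groups, quadripartitions=quads, bipartitions=bips, outgroup=O
    )


def default_sim_config(
    planted: bool = True,
    seed: int = 0,
    n_loci: int | None = None,
    block_length: int = 200,
) -> SimConfig:
    """Study-condition presets.

    Null genomes default to 5,000 loci. Planted genomes default to
    8,700 loci with a 200-locus discordance-free block, so the block
    is ~2.3% of loci -- the proportion seen in empirical
    supergene-like outliers -- with 10% taxon dropout and Poisson(1)
    NNI error."""
    if n_loci is None:
        n_loci = 8700 if planted else 5000
    return SimConfig(
        species_tree=default_species_tree(),
        block_species_tree=default_block_tree() if planted else None,
        n_loci=n_loci,
        n_chromosomes=3,
        block_length=block_length if planted else 0,
        mean_nni=1.0,
        dropout=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# auxiliary calculators
# ---------------------------------------------------------------------------

def recombination_free_window(Ne: float, r: float) -> float:
    """Expected equilibrium length, in bp, of a genomic window sharing
    a single genealogy: 1 / (2 * Ne * r) for effective population
    size Ne and per-bp per-generation recombination rate r."""
    if Ne <= 0 or r <= 0:
        raise ValueError("Ne and r must be positive")
    return 1.0 / (2.0 * Ne * r)


@dataclass
class WrightFisherConfig:
    """Neutral Wright-Fisher persistence simulation.

    A biallelic polymorphism starts at count ``k0`` out of ``2N``
    chromosomes in a diploid population of size ``N`` and drifts by
    binomial resampling for ``t`` generations. The default initial
    frequency is 0.5 (k0 = N), the natural choice for a newly
    balanced rearrangement with no stated starting frequency.
    """

    N: int
    t: int
    k0: int | None = None
    replicates: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.k0 is None:
            self.k0 = self.N
        if not 0 <= self.k0 <= 2 * self.N:
            raise ValueError("k0 must be in [0, 2N]")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def wf_persistence(cfg: WrightFisherConfig) -> tuple[float, float]:
    """Monte-Carlo probability that the allele is still polymorphic
    (count not in {0, 2N}) after t generations; returns (estimate,
    binomial standard error)."""
    two_n = 2 * cfg.N
    if cfg.k0 in (0, two_n):
        return 0.0, 0.0
    rng = np.random.default_rng(cfg.seed)
    counts = np.full(cfg.replicates, cfg.k0, dtype=np.int64)
    for _ in range(cfg.t):
        alive = (counts > 0) & (counts < two_n)
        if not alive.any():
            break
        counts[alive] = rng.binomial(two_n, counts[alive] / two_n)
    p = float(np.mean((counts > 0) & (counts < two_n)))
    se = math.sqrt(p * (1.0 - p) / cfg.replicates)
    return p, se


def wf_persistence_exact(N: int, k0: int, t: int) -> float:
    """Exact persistence probability from the (2N+1)-state binomial
    transition matrix (feasible for small populations; serves as the
    analytic oracle for the Monte-Carlo estimator)."""
    two_n = 2 * N
    if k0 in (0, two_n):
        return 0.0
    from scipy.stats import binom

    states = np.arange(two_n + 1)
    P = binom.pmf(states[None, :], two_n, (states / two_n)[:, None])
    P[0, :] = 0.0
    P[0, 0] = 1.0
    P[two_n, :] = 0.0
    P[two_n, two_n] = 1.0
    v = np.zeros(two_n + 1)
    v[k0] = 1.0
    for _ in range(t):
        v = v @ P
    return float(v[1:two_n].sum())
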
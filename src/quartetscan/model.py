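"""Shared data model for locus-tree genome scans.

The pipeline operates on collections of *locus trees* -- unrooted,
edge-weighted genealogies estimated for consecutive genomic windows --
tied to a genome table of coordinates, and on a clade configuration
naming the taxon groups whose quartet support is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LocusTree",
    "GenomeTable",
    "CladeModel",
    "Quadripartition",
    "Bipartition",
    "SupportTrack",
    "NormalizedQQS",
    "QuartetCounts",
    "OutlierRegion",
]


class LocusTree:
    """An unrooted genealogy for one genomic locus.

    Branch lengths, when present, are in expected substitutions per
    site. The tree may be non-binary; quartet statistics count
    unresolved quartets separately.

    The dendropy ``tree`` may be supplied lazily via ``tree_factory``
    (the simulator generates many loci and most consumers only need
    the adjacency ``graph``, which is much cheaper to build).
    """

    __slots__ = ("locus_id", "_tree", "_tree_factory", "_graph")

    def __init__(
        self,
        locus_id: str,
        tree: "dendropy.Tree | None" = None,
        *,
        tree_factory=None,
        graph=None,
    ):
        if (tree is None) == (tree_factory is None):
            raise ValueError("provide exactly one of tree / tree_factory")
        self.locus_id = locus_id
        self._tree = tree
        self._tree_factory = tree_factory
        self._graph = graph
        if tree is not None:
            self._validate(tree)

    def _validate(self, tree) -> None:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError(
                f"locus {self.locus_id}: duplicate leaf labels in tree"
            )

    @property
    def tree(self) -> dendropy.Tree:
        if self._tree is None:
            self._tree = self._tree_factory()
            self._tree_factory = None
            self._validate(self._tree)
        return self._tree

    @property
    def graph(self):
        """Cached unrooted adjacency view (see ``quartetscan.quartets``)."""
        if self._graph is None:
            from .quartets import graph_from_dendropy

            self._graph = graph_from_dendropy(self.tree)
        return self._graph

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.graph.leaf_label.values())

    def __repr__(self) -> str:
        return f"LocusTree({self.locus_id!r}, {len(self.taxa)} taxa)"


class GenomeTable:
    """Ordered loci with chromosome and 1-based inclusive coordinates.

    Rows are sorted by (chromosome, start); chromosome order follows
    first appearance in the input. One row per locus_id.
    """

    COLUMNS = ("locus_id", "chrom", "start", "end")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.COLUMNS)].copy()
        if df["locus_id"].duplicated().any():
            dups = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise ValueError(f"duplicate locus_id in table: {dups[:5]}")
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"locus {row['locus_id']}: start ({row['start']}) must be "
                f"< end ({row['end']}); coordinates are 1-based inclusive"
            )
        # stable sort preserving first-appearance chromosome order
        chrom_order = {c: i for i, c in enumerate(df["chrom"].unique())}
        df = df.sort_values(
            by=["chrom", "start"],
            key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.df["locus_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous row slices per chromosome, in table order."""
        out = []
        chroms = self.chroms
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out.append((chroms[i], slice(i, j)))
            i = j
        return out


@dataclass(frozen=True)
class Quadripartition:
    """Four disjoint taxon groups A.B|C.D around an internal branch.

    The main topology pairs A with B (and C with D); the two
    alternatives pair A with C and A with D. Outgroup taxa belong to
    partition D by convention.
    """

    name: str
    A: frozenset
    B: frozenset
    C: frozenset
    D: frozenset

    def groups(self) -> tuple[frozenset, frozenset, frozenset, frozenset]:
        return (self.A, self.B, self.C, self.D)

    def __post_init__(self):
        sets = self.groups()
        for s in sets:
            if not s:
                raise ValueError(f"quadripartition {self.name}: empty group")
        for i in range(4):
            for j in range(i + 1, 4):
                inter = sets[i] & sets[j]
                if inter:
                    raise ValueError(
                        f"quadripartition {self.name}: taxa {sorted(inter)} "
                        "appear in two groups"
                    )


@dataclass(frozen=True)
class Bipartition:
    """Two disjoint taxon groups X|Y on either side of a branch."""

    name: str
    X: frozenset
    Y: frozenset

    def __post_init__(self):
        if not self.X or not self.Y:
            raise ValueError(f"bipartition {self.name}: empty side")
        if self.X & self.Y:
            raise ValueError(
                f"bipartition {self.name}: overlapping sides "
                f"{sorted(self.X & self.Y)}"
            )


@dataclass
class CladeModel:
    """Named taxon groups plus the quadripartitions/bipartitions to score."""

    groups: dict[str, frozenset]
    quadripartitions: list[Quadripartition] = field(default_factory=list)
    bipartitions: list[Bipartition] = field(default_factory=list)
    outgroup: frozenset = frozenset()

    def quadripartition(self, name: str) -> Quadripartition:
        for q in self.quadripartitions:
            if q.name == name:
                return q
        raise KeyError(name)


@dataclass
class SupportTrack:
    """Per-locus statistic values aligned to a GenomeTable.

    Missing values (locus did not qualify for the statistic) are NaN,
    which is distinct from an observed value of 0.
    """

    table: GenomeTable
    values: np.ndarray
    name: str = "support"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.table):
            raise ValueError(
                f"track length {len(self.values)} != table length "
                f"{len(self.table)}"
            )

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class QuartetCounts:
    """Raw quartet tallies for a quadripartition in one locus tree."""

    n_main: int
    n_alt1: int
    n_alt2: int
    n_unresolved: int

    @property
    def n_total(self) -> int:
        return self.n_main + self.n_alt1 + self.n_alt2 + self.n_unresolved

    @property
    def n_resolved(self) -> int:
        return self.n_main + self.n_alt1 + self.n_alt2


@dataclass(frozen=True)
class NormalizedQQS:
    """Quadripartition quartet support normalized over resolved quartets.

    q_main + q_alt1 + q_alt2 == 1 whenever defined; q_main == 1 exactly
    when the A and B groups are mutually monophyletic among present
    taxa.
    """

    q_main: float
    q_alt1: float
    q_alt2: float
    counts: QuartetCounts


@dataclass(frozen=True)
class OutlierRegion:
    """A run of significant windows merged into one genomic interval."""

    chrom: str
    start: int
    end: int
    n_windows: int
    n_loci: int
    min_p_adj: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")
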
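"""Shared fixtures: random tree generation and small clade models."""

import random

import numpy as np
import pytest

from quartetscan.io import parse_newick
from quartetscan.model import CladeModel, Quadripartition


def random_newick(
    rng: random.Random, n_taxa: int, polytomies: bool = False, prefix: str = "t"
) -> str:
    """Random tree by repeated joins, with random branch lengths; with
    ``polytomies`` some joins take three subtrees."""
    nodes = [f"{prefix}{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        k = 3 if polytomies and len(nodes) >= 3 and rng.random() < 0.3 else 2
        picks = sorted(rng.sample(range(len(nodes)), k), reverse=True)
        subs = [nodes[i] for i in picks]
        for i in picks:
            nodes.pop(i)
        joined = ",".join(f"{s}:{rng.uniform(0.01, 2.0):.6f}" for s in subs)
        nodes.append(f"({joined})")
    return nodes[0] + ";"


def random_groups(rng: random.Random, taxa, n_groups: int = 4):
    """Shuffle taxa into n_groups nonempty disjoint groups."""
    taxa = list(taxa)
    rng.shuffle(taxa)
    sizes = [len(taxa) // n_groups] * n_groups
    for i in range(len(taxa) - sum(sizes)):
        sizes[i] += 1
    groups, pos = [], 0
    for s in sizes:
        groups.append(frozenset(taxa[pos : pos + s]))
        pos += s
    return groups


@pytest.fixture
def rng():
    return random.Random(20251001)


@pytest.fixture
def nprng():
    return np.random.default_rng(20251001)


@pytest.fixture
def simple_quartet_tree():
    return parse_newick("((a,b),(c,d));")


@pytest.fixture
def singleton_quad():
    return Quadripartition(
        "q",
        frozenset({"a"}),
        frozenset({"b"}),
        frozenset({"c"}),
        frozenset({"d"}),
    )
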
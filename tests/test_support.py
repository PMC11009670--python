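"""Per-locus quartet statistics: examples, oracles, and invariants."""

import random
from itertools import combinations

import dendropy
import numpy as np
import pytest

from quartetscan.io import parse_newick
from quartetscan.model import LocusTree, Quadripartition
from quartetscan.quartets import (
    bip_counts_exhaustive,
    bip_counts_fast,
    graph_from_dendropy,
    quad_counts_exhaustive,
    quad_counts_fast,
)
from quartetscan.support import (
    bqs,
    clade_branch_length,
    is_monophyletic,
    qqs,
    quartet_score,
    taxon_removal_experiment,
    tree_scale_factor,
)

from conftest import random_groups, random_newick


class TestQQS:
    def test_single_concordant_quartet(self, simple_quartet_tree, singleton_quad):
        r = qqs(simple_quartet_tree, singleton_quad)
        assert (r.q_main, r.q_alt1, r.q_alt2) == (1.0, 0.0, 0.0)

    def test_normalization_and_engine_agreement(self, rng):
        """Fast and exhaustive counters agree and normalized values sum
        to one on random trees with and without polytomies."""
        for trial in range(40):
            n = rng.randint(8, 14)
            tree = parse_newick(random_newick(rng, n, polytomies=trial % 2 == 0))
            g = graph_from_dendropy(tree)
            groups = random_groups(rng, g.taxa)
            assert quad_counts_fast(g, groups) == quad_counts_exhaustive(g, groups)
            quad = Quadripartition("q", *groups)
            r_fast = qqs(tree, quad, method="fast")
            r_ex = qqs(tree, quad, method="exhaustive")
            if r_fast is None:
                assert r_ex is None
                continue
            assert r_fast.counts == r_ex.counts
            assert r_fast.q_main + r_fast.q_alt1 + r_fast.q_alt2 == pytest.approx(
                1.0, abs=1e-12
            )

    def test_missing_group_yields_missing_not_zero(self, simple_quartet_tree):
        quad = Quadripartition(
            "q",
            frozenset({"a"}),
            frozenset({"b"}),
            frozenset({"c"}),
            frozenset({"zz"}),  # absent from the tree
        )
        assert qqs(simple_quartet_tree, quad) is None

    def test_all_unresolved_yields_missing(self, singleton_quad):
        star = parse_newick("(a,b,c,d);")
        assert qqs(star, singleton_quad) is None

    def test_symmetry_under_group_swaps(self, rng):
        """Swapping A-B or C-D fixes q_main; swapping B-C exchanges
        q_main with q_alt1."""
        for _ in range(20):
            tree = parse_newick(random_newick(rng, 12))
            g = graph_from_dendropy(tree)
            A, B, C, D = random_groups(rng, g.taxa)
            base = qqs(tree, Quadripartition("q", A, B, C, D))
            swap_ab = qqs(tree, Quadripartition("q", B, A, C, D))
            swap_cd = qqs(tree, Quadripartition("q", A, B, D, C))
            swap_bc = qqs(tree, Quadripartition("q", A, C, B, D))
            assert base.q_main == pytest.approx(swap_ab.q_main)
            assert base.q_main == pytest.approx(swap_cd.q_main)
            assert base.q_main == pytest.approx(swap_bc.q_alt1)
            assert base.q_alt1 == pytest.approx(swap_bc.q_main)

    def test_strict_mode_rejects_polytomy(self):
        tree = parse_newick("((a,b,c),d,e);")
        quad = Quadripartition(
            "q", frozenset("a"), frozenset("b"), frozenset("c"), frozenset("d")
        )
        with pytest.raises(ValueError, match="strict"):
            qqs(tree, quad, strict=True)


class TestBQS:
    def test_concordant_cherry(self, simple_quartet_tree):
        assert bqs(simple_quartet_tree, {"a", "b"}, {"c", "d"}) == 1.0

    def test_caterpillar_single_discordant_quartet(self):
        tree = parse_newick("(a,(c,(b,d)));")
        assert bqs(tree, {"a", "b"}, {"c", "d"}) == 0.0

    def test_brute_force_agreement_large_bipartition(self, rng):
        tree = parse_newick(random_newick(rng, 14))
        g = graph_from_dendropy(tree)
        taxa = sorted(g.taxa)
        X, Y = set(taxa[:5]), set(taxa[5:])
        fast = bip_counts_fast(g, X, Y)
        ex = bip_counts_exhaustive(g, X, Y)
        assert fast == ex
        assert fast[2] == 10 * 36  # C(5,2) * C(9,2) qualifying quartets

    def test_too_few_taxa_missing(self, simple_quartet_tree):
        assert bqs(simple_quartet_tree, {"a"}, {"c", "d"}) is None


class TestMonophyly:
    def test_clade_recovered(self):
        tree = parse_newick("((f,g),((p,q),o));")
        assert is_monophyletic(tree, {"f", "g"}, {"o"}) == 1

    def test_clade_broken(self):
        tree = parse_newick("((f,p),((g,q),o));")
        assert is_monophyletic(tree, {"f", "g"}, {"o"}) == 0

    def test_missing_outgroup_disqualifies(self):
        tree = parse_newick("((f,g),(p,q));")
        assert is_monophyletic(tree, {"f", "g"}, {"o"}) is None

    def test_overlap_with_outgroup_rejected(self):
        tree = parse_newick("((f,g),(p,o));")
        with pytest.raises(ValueError, match="overlap"):
            is_monophyletic(tree, {"f", "o"}, {"o"})

    def test_monophyly_iff_qqs_one(self, rng):
        """With one present taxon per group, mutual monophyly of A+B is
        exactly the QQS == 1 condition."""
        n_checked = 0
        for _ in range(200):
            tree = parse_newick(random_newick(rng, 10))
            g = graph_from_dendropy(tree)
            A, B, C, D = random_groups(rng, g.taxa)
            r = qqs(tree, Quadripartition("q", A, B, C, D))
            mono = is_monophyletic(tree, A | B, (C | D) & g.taxa)
            assert (r.q_main == 1.0) == (mono == 1)
            n_checked += 1
        assert n_checked == 200


class TestCladeBranchLength:
    def test_spec_of_uniting_branch(self):
        tree = parse_newick("((f:1,g:1):0.5,(p:1,o:1):0.2);")
        assert clade_branch_length(tree, {"f", "g"}, {"o"}) == pytest.approx(0.5)

    def test_single_present_taxon_terminal_edge(self):
        tree = parse_newick("((f:1.5,p:1):0.5,(q:1,o:1):0.2);")
        assert clade_branch_length(tree, {"f", "g"}, {"o"}) == pytest.approx(1.5)

    def test_non_monophyletic_missing(self):
        tree = parse_newick("((f:1,p:1):0.5,((g:1,q:1):0.3,o:1):0.2);")
        assert clade_branch_length(tree, {"f", "g"}, {"o"}) is None

    def test_simulated_recovery_of_planted_length(self, nprng):
        """Sample mean of the uniting-branch length over noisy trees
        recovers the planted 0.01 within 3 standard errors."""
        vals = []
        for _ in range(300):
            ln = 0.01 + nprng.normal(0, 0.002)
            ln = max(ln, 0.0)
            tree = parse_newick(
                f"((f:1,g:1):{ln:.8f},((p:1,q:1):0.3,o:1):0.2);"
            )
            vals.append(clade_branch_length(tree, {"f", "g"}, {"o"}))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.01) < 3 * se + 1e-9


def _quartet_topology_dendropy(tree: dendropy.Tree, four):
    """Independent quartet-topology oracle via dendropy restriction."""
    sub = tree.extract_tree_with_taxa_labels(four)
    sub.is_rooted = False
    sub.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
    for bip in sub.bipartition_encoding:
        leafset = bip.leafset_taxa(sub.taxon_namespace)
        labels = frozenset(t.label for t in leafset)
        if len(labels) == 2:
            return labels
    return None  # star


class TestQuartetScore:
    def test_identical_trees_score_one(self, rng):
        tree = parse_newick(random_newick(rng, 6))
        assert quartet_score(tree, tree) == 1.0

    def test_fully_conflicting_quartet(self):
        t = parse_newick("((a,b),(c,d));")
        c = parse_newick("((a,c),(b,d));")
        assert quartet_score(t, c) == 0.0

    def test_matches_dendropy_restriction_oracle(self, rng):
        t1 = parse_newick(random_newick(rng, 8))
        t2 = parse_newick(random_newick(rng, 8))
        taxa = sorted({l.taxon.label for l in t1.leaf_node_iter()})
        n_match = n_def = 0
        for four in combinations(taxa, 4):
            q1 = _quartet_topology_dendropy(t1, four)
            q2 = _quartet_topology_dendropy(t2, four)
            if q1 is None or q2 is None:
                continue
            n_def += 1
            # same split iff the cherry pair matches or complements
            fourset = frozenset(four)
            pairs1 = {q1, fourset - q1}
            if q2 in pairs1:
                n_match += 1
        assert n_def == 70  # C(8,4), both trees binary
        assert quartet_score(t1, t2) == pytest.approx(n_match / n_def)

    def test_too_few_shared_taxa_missing(self):
        t = parse_newick("((a,b),(c,d));")
        c = parse_newick("((a,b),(x,y));")
        assert quartet_score(t, c) is None


class TestTaxonRemoval:
    def test_all_loci_equal_candidate_a(self, rng):
        nw = random_newick(rng, 8)
        cand_a = parse_newick(nw)
        cand_b = parse_newick(random_newick(rng, 8))
        trees = [LocusTree(f"L{i}", parse_newick(nw)) for i in range(5)]
        res = taxon_removal_experiment(trees, cand_a, cand_b, {"none": []})
        row = res.iloc[0]
        score_b = quartet_score(parse_newick(nw), cand_b)
        assert row["mean"] == pytest.approx(1.0 - score_b)
        assert row["mean"] > 0

    def test_mixture_sign_flips_with_proportions(self, rng):
        nw_a = random_newick(rng, 8)
        nw_b = random_newick(rng, 8)
        cand_a, cand_b = parse_newick(nw_a), parse_newick(nw_b)
        mk = lambda frac_a: [
            LocusTree(
                f"L{i}", parse_newick(nw_a if i < int(10 * frac_a) else nw_b)
            )
            for i in range(10)
        ]
        hi = taxon_removal_experiment(mk(0.8), cand_a, cand_b, {"none": []})
        lo = taxon_removal_experiment(mk(0.2), cand_a, cand_b, {"none": []})
        assert hi.iloc[0]["mean"] > 0 > lo.iloc[0]["mean"]

    def test_pruning_distinguishing_taxa_zeroes_difference(self):
        """When the only taxa separating the two candidates are pruned,
        the remaining quartets agree and the difference vanishes."""
        cand_a = parse_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        cand_b = parse_newick("(((a,c),(b,d)),((e,f),(g,h)));")
        trees = [
            LocusTree("L1", parse_newick("(((a,b),(c,d)),((e,f),(g,h)));")),
            LocusTree("L2", parse_newick("(((a,b),(c,d)),((e,g),(f,h)));")),
        ]
        res = taxon_removal_experiment(
            trees, cand_a, cand_b, {"none": [], "drop": ["a", "b"]}
        )
        base = res[res["removal"] == "none"].iloc[0]
        drop = res[res["removal"] == "drop"].iloc[0]
        assert base["mean"] != 0.0
        assert drop["mean"] == pytest.approx(0.0)


class TestTreeScaleFactor:
    def test_uniform_doubling(self, rng):
        nw = random_newick(rng, 10)
        a = parse_newick(nw)
        b = parse_newick(nw)
        for e in b.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2.0
        assert tree_scale_factor(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_identity(self, rng):
        nw = random_newick(rng, 10)
        assert tree_scale_factor(parse_newick(nw), parse_newick(nw)) == pytest.approx(1.0)

    def test_too_few_shared_taxa(self):
        with pytest.raises(ValueError, match="shared"):
            tree_scale_factor(parse_newick("((a:1,b:1),(c:1,x:1));"),
                              parse_newick("((a:1,b:1),(y:1,z:1));"))
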
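"""Reference experiments validating the pipeline on synthetic data.

Each function runs one self-contained experiment with known ground
truth -- closed-form MSC expectations, exact Markov chains, planted
simulation parameters -- and returns plain numbers. The test suite
asserts on them at fixed tolerances and the reproduction script
reports them; both go through the same code paths a user of the
package would.
"""

from __future__ import annotations

import random

import numpy as np

from .model import Quadripartition
from .quartets import (
    bip_counts_exhaustive,
    bip_counts_fast,
    graph_from_dendropy,
    quad_counts_exhaustive,
    quad_counts_fast,
)
from .scan import ScanParams, scan_track
from .sim import (
    SpeciesTree,
    WrightFisherConfig,
    default_clade_model,
    default_sim_config,
    genealogy_to_locus_tree,
    sample_msc_gene_tree,
    simulate_genome,
    wf_persistence,
    wf_persistence_exact,
)
from .support import qqs, qqs_track, tree_scale_factor

__all__ = [
    "polytomy_qqs_means",
    "concordance_curve",
    "quartet_engine_agreement",
    "null_scan_calibration",
    "planted_block_recovery",
    "planted_recovery_rate",
    "wf_mc_vs_exact",
    "scale_factor_recovery",
]

_SINGLETON_QUAD = Quadripartition(
    "q", frozenset("a"), frozenset("b"), frozenset("c"), frozenset("d")
)


def _quartet_species_tree(T: float) -> SpeciesTree:
    return SpeciesTree(f"((a:1,b:1):{T:.10g},c:{1 + T:.10g},d:{1 + T:.10g});")


def polytomy_qqs_means(n_trees: int = 10_000, seed: int = 0):
    """Mean normalized QQS per alternative over MSC gene trees drawn
    at internal branch length 0 (a hard polytomy). Each alternative's
    expectation is 1/3. Returns (means[3], monte_carlo_se)."""
    rng = np.random.default_rng(seed)
    sp = _quartet_species_tree(0.0)
    sums = np.zeros(3)
    for _ in range(n_trees):
        lt = genealogy_to_locus_tree(sample_msc_gene_tree(sp, rng), "x")
        r = qqs(lt, _SINGLETON_QUAD)
        sums += (r.q_main, r.q_alt1, r.q_alt2)
    means = sums / n_trees
    se = float(np.sqrt((1 / 3) * (2 / 3) / n_trees))
    return means, se


def concordance_curve(
    T_values=(0.0, 0.5, 1.0, 2.0), n_draws: int = 50_000, seed: int = 0
):
    """Observed vs expected quartet concordance 1 - (2/3)exp(-T).

    Returns a list of dicts with observed, expected, and the
    Monte-Carlo standard error at each branch length."""
    out = []
    for i, T in enumerate(T_values):
        rng = np.random.default_rng(seed + 1000 * i + 1)
        sp = _quartet_species_tree(T)
        m = 0.0
        for _ in range(n_draws):
            lt = genealogy_to_locus_tree(sample_msc_gene_tree(sp, rng), "x")
            m += qqs(lt, _SINGLETON_QUAD).q_main
        expected = 1.0 - (2.0 / 3.0) * np.exp(-T)
        se = float(np.sqrt(expected * (1 - expected) / n_draws))
        out.append(
            {
                "T": T,
                "observed": m / n_draws,
                "expected": expected,
                "se": se,
                "n": n_draws,
            }
        )
    return out


def _random_newick(rng: random.Random, n_taxa: int, polytomies: bool) -> str:
    nodes = [f"t{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        k = 3 if polytomies and len(nodes) >= 3 and rng.random() < 0.3 else 2
        picks = sorted(rng.sample(range(len(nodes)), k), reverse=True)
        subs = [nodes[i] for i in picks]
        for i in picks:
            nodes.pop(i)
        joined = ",".join(f"{s}:{rng.uniform(0.01, 2.0):.6f}" for s in subs)
        nodes.append(f"({joined})")
    return nodes[0] + ";"


def quartet_engine_agreement(n_trees: int = 200, seed: int = 0) -> int:
    """Number of random trees (4-14 taxa, half with polytomies) on
    which the traversal counters agree *exactly* with brute-force
    enumeration, for both quadripartition and bipartition tallies."""
    from .io import parse_newick

    rng = random.Random(seed)
    n_agree = 0
    for trial in range(n_trees):
        n = rng.randint(4, 14)
        g = graph_from_dendropy(
            parse_newick(_random_newick(rng, n, polytomies=trial % 2 == 0))
        )
        taxa = sorted(g.taxa)
        rng.shuffle(taxa)
        sizes = [n // 4] * 4
        for i in range(n - sum(sizes)):
            sizes[i] += 1
        groups, pos = [], 0
        for s in sizes:
            groups.append(frozenset(taxa[pos : pos + s]))
            pos += s
        ok = quad_counts_fast(g, groups) == quad_counts_exhaustive(g, groups)
        X, Y = set(taxa[: n // 2]), set(taxa[n // 2 :])
        ok = ok and bip_counts_fast(g, X, Y) == bip_counts_exhaustive(g, X, Y)
        n_agree += ok
    return n_agree


def null_scan_calibration(
    n_genomes: int = 4, seed: int = 0, alpha: float = 0.05, bh_alpha: float = 0.01
):
    """Rejection rates of the windowed test on null (block-free)
    genomes: the raw min-form p is two-tailed, so P(p < alpha) should
    be ~2*alpha; BH-adjusted rejections at bh_alpha should be rare."""
    quad = default_clade_model().quadripartition("planted_AB")
    n_raw = n_bh = n_win = 0
    for i in range(n_genomes):
        cfg = default_sim_config(planted=False, seed=seed + i)
        table, trees, _ = simulate_genome(cfg)
        track = qqs_track(trees, table, quad)
        windows, _, _, _ = scan_track(track, ScanParams())
        n_raw += int((windows["p"] < alpha).sum())
        n_bh += int((windows["p_adj"] < bh_alpha).sum())
        n_win += len(windows)
    return {
        "raw_rate": n_raw / n_win,
        "expected_raw_rate": 2 * alpha,
        "bh_fraction": n_bh / n_win,
        "n_windows": n_win,
    }


def planted_block_recovery(seed: int) -> dict:
    """Simulate one planted-block genome under the study conditions
    and scan the planted branch; report whether a called outlier
    region overlaps the true block and the boundary error in loci."""
    cfg = default_sim_config(planted=True, seed=seed)
    table, trees, truth = simulate_genome(cfg)
    quad = default_clade_model().quadripartition("planted_AB")
    track = qqs_track(trees, table, quad)
    _, regions, _, _ = scan_track(track, ScanParams())
    rows = np.flatnonzero(truth)
    tchrom = table.chroms[rows[0]]
    tstart, tend = table.starts[rows[0]], table.ends[rows[-1]]
    sel = table.chroms == tchrom
    starts, ends = table.starts[sel], table.ends[sel]
    t_first = int(np.searchsorted(starts, tstart))
    t_last = int(np.searchsorted(ends, tend))
    boundary_error = None
    for r in regions:
        if r.chrom == tchrom and r.start < tend and r.end > tstart:
            first = int(np.searchsorted(starts, r.start))
            last = int(np.searchsorted(ends, r.end))
            be = max(abs(first - t_first), abs(last - t_last))
            if boundary_error is None or be < boundary_error:
                boundary_error = be
    return {
        "n_regions": len(regions),
        "overlapped": boundary_error is not None,
        "boundary_error": boundary_error,
    }


def planted_recovery_rate(
    n_seeds: int = 100, seed0: int = 0, max_boundary_error: int = 20
):
    """Fraction of seeded planted-block genomes in which the scan
    localizes the block to within ``max_boundary_error`` loci."""
    n_ok = 0
    errors = []
    for s in range(n_seeds):
        res = planted_block_recovery(seed0 + s)
        errors.append(res["boundary_error"])
        if (
            res["overlapped"]
            and res["boundary_error"] <= max_boundary_error
        ):
            n_ok += 1
    return {"rate": n_ok / n_seeds, "n_seeds": n_seeds, "errors": errors}


def wf_mc_vs_exact(
    N: int = 5, k0: int = 5, t: int = 10, replicates: int = 100_000, seed: int = 0
):
    """Monte-Carlo Wright-Fisher persistence vs the exact absorbing
    Markov chain for a small population."""
    mc, se = wf_persistence(
        WrightFisherConfig(N=N, t=t, k0=k0, replicates=replicates, seed=seed)
    )
    exact = wf_persistence_exact(N, k0, t)
    return {"mc": mc, "se": se, "exact": exact}


def scale_factor_recovery(
    n_taxa: int = 30, factor: float = 1.877, noise_sd: float = 0.1, seed: int = 0
):
    """Recover a planted branch-length scale factor from a noisy
    rescaling of a random tree via the zero-intercept patristic
    regression. Returns (exact_double_check, recovered_factor)."""
    from .io import parse_newick

    rng = random.Random(seed)
    nw = _random_newick(rng, n_taxa, polytomies=False)
    base = parse_newick(nw)
    doubled = parse_newick(nw)
    for e in doubled.preorder_edge_iter():
        if e.length is not None:
            e.length *= 2.0
    exact_double = tree_scale_factor(base, doubled)
    noisy = parse_newick(nw)
    nrng = np.random.default_rng(seed)
    for e in noisy.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor * float(np.exp(nrng.normal(0.0, noise_sd)))
    recovered = tree_scale_factor(base, noisy)
    return {"exact_double": exact_double, "recovered": recovered, "planted": factor}
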
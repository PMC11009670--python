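# Methods

## Quartet-support statistics

An internal branch of an unrooted species-tree hypothesis, together
with its four adjacent subtrees, partitions the taxa into four
disjoint groups `A·B|C·D`. For a locus tree `t`, the quadripartition
quartet support (QQS) counts the quartets with exactly one taxon per
group whose induced topology in `t` is `ab|cd`, and normalizes by the
number of *resolved* qualifying quartets, so the three pairings
(`A·B|C·D`, `A·C|B·D`, `A·D|B·C`) sum to one. Outgroup taxa are
placed in partition D, which makes `q_main = 1` exactly equivalent to
mutual monophyly of A and B among the taxa present in `t`. Branch
quartet support (BQS) is the two-plus-two analogue for a single
bipartition `X|Y`. Loci in which some group has no representative get
*missing* values, never zeros; every downstream average and window is
taken over qualifying loci only.

Polytomies are accepted: a quartet whose four paths meet at one
vertex is unresolved and excluded from the normalization denominator
(a strict mode rejects non-binary trees instead). This preserves the
sum-to-one contract on real, partially resolved inputs.

### Counting engines

Two independent algorithms compute every tally:

* **Exhaustive**: enumerate each qualifying four-taxon subset and
  classify its topology with the four-point condition on topological
  (unit branch length) path distances — a three-way tie is a star.
* **Fast**: one rooted traversal accumulates per-subtree group
  counts; summing the two-sided count products over edges counts each
  resolved quartet once per edge of its internal path (`L` times),
  and subtracting a per-vertex term (components around each internal
  vertex) removes the `L−1` strictly interior vertices, leaving
  exactly 1 per quartet and 0 for star quartets. Linear time per
  statistic.

The exhaustive engine is the oracle; exact agreement between the two
is asserted on hundreds of random trees (with polytomies) in the test
suite. Above `FAST_PATH_THRESHOLD = 30` qualifying quartets the fast
engine is the default (a timing choice only — both are exact).

`quartet_score(t, candidate)` classifies all shared-taxon quartets in
both trees via vectorized four-point sums on unit path-distance
matrices; quartets unresolved in either tree are excluded from the
denominator. `tree_scale_factor` is the zero-intercept least-squares
slope `Σxy/Σx²` over all shared-pair patristic distances, the
standard correction when branch lengths estimated from conserved
markers are compressed relative to a genome-wide tree.

`clade_branch_length` returns the length of the branch uniting the
present clade taxa. When the input newick is written with a
bifurcating root that splits the uniting branch in two, the
clade-side piece is reported (identical to the unrooted edge for the
usual trifurcating-root encoding of unrooted trees).

## The windowed MSC-conformity test

Under the multispecies coalescent, per-locus quartet support for a
fixed branch is (approximately exchangeably) distributed around a
genome-wide mean; its average `Q_i` over `w = 20` consecutive
qualifying loci concentrates, and the standardized deviate
`Z_i = (Q_i − μ_Q)/σ_Q` is approximately standard normal. Each window
gets `p_i = min(F(Z_i), 1−F(Z_i))` (`F` the standard normal CDF), a
min-form p-value that is two-tailed with size `2α` at threshold `α`
and bounded by 0.5. Benjamini–Hochberg correction is applied per
branch across all of that branch's windows, and maximal runs of
windows with `p_adj < α = 0.01` are merged into outlier regions
(default `max_gap_loci = 0`: only overlapping/contiguous runs merge).

Estimation choices:

* `μ_Q` is the genome-wide mean of the per-locus statistic; `σ_Q` is
  the standard deviation of the window means over all windows, which
  makes `Z` standard normal by construction under the null. The
  per-locus SD is available via `sigma_mode="locus"` (it is an
  overestimate of the window-mean SD by roughly `√w` and makes the
  test conservative).
* Windows never span chromosomes, slide one qualifying locus at a
  time, and always contain exactly `w` defined values (missing loci
  are dropped before windowing, keeping `Q_i` comparable).
* Sex chromosomes (default `chrZ`, `chrW`) are excluded from both
  moment estimation and testing; the list is configurable.
* The focal region's own windows are *included* in `μ_Q`/`σ_Q`. This
  is the intended genome-wide estimator, but it means a discordant
  block inflates `σ_Q` in proportion to the block's share of windows;
  the test retains power when the block is a few percent of the
  genome (as in the empirical datasets this mirrors), and the
  synthetic defaults below follow that proportion.

Moving-average tracks (defaults `k ∈ {50, 200}`) are trailing means
of the `k` most recent qualifying loci within a chromosome, i.e. the
percent of preceding loci recovering a clade when applied to binary
monophyly tracks.

## Coalescent-HMM post-processing

A four-taxon coalescent HMM emits per-site posteriors over four
states: shallow coalescence matching the species tree (S), deep but
concordant (D1), and the two discordant deep states (D2, D3). This
package consumes a TSV of those posteriors (it never runs the HMM),
assigns each site to its maximum-a-posteriori state (ties break
S > D1 > D2 > D3, a measure-zero event for continuous posteriors),
tiles sites into fixed 100-kb windows from coordinate 0, and reports
`main = (S+D1)/total`, `alt2`, `alt3`, plus the shallow/deep split of
`main`. `ils_level` reports both the deep fraction `(D1+D2+D3)/total`
and the discordant-only fraction `(D2+D3)/total`; the admissibility
check uses the discordant-only fraction, since under the MSC the two
discordant topologies together have probability `2·(1/3)·e^{−T}`,
whose supremum (at `T → 0`) is 2/3 — the bound is computed from that
closed form, not hard-coded. A region above the bound cannot be
produced by ILS alone.

## Synthetic-data generator

`simulate_genome` emulates the structure of a chromosome-scale
locus-tree dataset:

* **Species tree** (coalescent units, ultrametric): 12 taxa in groups
  A (3), B (3), C (4) and outgroup O (2). The background tree pairs
  B with C above a *focal branch* of 0.025 coalescent units, so the
  scored branch `A·B|C·O` has expected support `(1/3)e^{−T} ≈ 1/3` —
  the high-ILS regime where every topology is nearly equally common.
* **Planted block**: a contiguous run of loci drawn instead from an
  alternative species tree uniting A+B by a 5-coalescent-unit branch:
  per-topology discordance `(1/3)e^{−5} ≈ 0.002`, i.e. essentially
  discordance-free, with correspondingly deeper coalescences on the
  uniting branch (emulating the roughly two-fold longer uniting
  branches seen in empirical recombination-suppressed regions).
* **Gene-tree error**: a Poisson(1) number of random NNI moves per
  tree (moved subtrees keep their branch lengths). This directly
  controls topology error without simulating sequences.
* **Dropout**: each taxon missing independently with probability 0.1;
  if fewer than 4 taxa would remain, a random 4 are kept.
* **Layout**: loci evenly split over 3 chromosomes, 10-kb spacing,
  1-kb length; the block is centered on chromosome 2 and must lie
  within one chromosome. Branch lengths are emitted in substitution
  units via `subs_per_coal = 0.002`.
* **Sizes**: null genomes default to 5,000 loci; planted genomes to
  8,700 loci with a 200-locus block, i.e. ~2.3% of loci — the
  proportion of the empirical outlier regions this design mirrors.
  These sizes are the package's chosen study conditions for its
  validation experiments.

Loci are independent MSC draws (no linkage between adjacent loci):
the windowed test's null treats loci as exchangeable, and
independence is the conservative null for it. The generator therefore
does *not* reproduce autocorrelation from shared ancestral
recombination graphs, estimation error correlated with locus length
or information content, or lineage-specific rate variation; passing
tests show the statistics and the scan behave correctly under the MSC
and detect planted violations, not that any particular empirical
dataset is free of those complications.

The MSC sampler itself follows the standard hierarchical coalescent:
within each species-tree branch, every lineage pair coalesces at rate
1 per coalescent unit; survivors merge in ancestral branches and the
root branch extends to infinity. It is validated against the
closed-form concordance `1 − (2/3)e^{−T}` over `T ∈ {0, 0.5, 1, 2}`
and the Exp(1) pairwise waiting time.

## Auxiliary calculators

* `recombination_free_window(Ne, r) = 1/(2·Ne·r)` bp — the expected
  equilibrium length of a genealogically homogeneous window; 5 bp to
  ~4,167 bp over bird-like ranges (`10⁵ ≤ Ne ≤ 10⁶`,
  `1.2×10⁻⁹ ≤ r ≤ 10⁻⁷`).
* `wf_persistence`: neutral Wright–Fisher binomial resampling of a
  biallelic polymorphism; reports the Monte-Carlo probability of
  remaining polymorphic after `t` generations with its binomial SE.
  The default initial frequency is 0.5 (`k0 = N`) — an explicit
  assumption, since a newly arisen balanced rearrangement has no
  canonical starting frequency. An exact absorbing-Markov-chain
  version (`wf_persistence_exact`) is provided for small populations
  and serves as the simulator's oracle. Large-`N` questions should be
  rescaled to the diffusion timescale (`t/2N` fixed) rather than
  simulated directly.

## Numerical and degenerate-input choices

* Missing statistic values are NaN in tracks and `None` from scalar
  functions, serialized as `NA`; they are never conflated with 0.
* Locus-table coordinates are 1-based inclusive; BED output is
  0-based half-open.
* `σ_Q = 0` (a degenerate, variation-free genome) is an error rather
  than infinite Z-scores.
* Posterior rows must sum to 1 within 10⁻⁶; species trees must be
  ultrametric within 10⁻⁶ coalescent units.
* All simulation randomness flows from one integer seed through a
  single `numpy` generator; identical seeds give bit-identical
  datasets.

## Validation experiments

`quartetscan.validation` packages the reference experiments used by
the test suite and `scripts/acceptance.py`: polytomy QQS means
(expect 1/3 per alternative), the simulated concordance curve vs its
closed form, exact fast-vs-exhaustive counter agreement on random
trees, null calibration of the windowed test (raw rate ≈ 2α,
BH-adjusted rejections near zero), 100-seed planted-block recovery
(region overlapping truth within 20 loci), Wright–Fisher Monte Carlo
vs the exact chain, and recovery of a planted patristic scale factor
(1.877) under multiplicative branch-length noise.

## Known limitations

* The scan assumes enough qualifying loci per chromosome to form
  windows and estimate moments; chromosomes with fewer than `w`
  qualifying loci are skipped with a notice.
* BQS values are not comparable across different clades (the mix of
  nearly-trivial quartets differs); compare them across loci for a
  fixed clade only.
* Region boundaries are window-resolution objects: calls extend a few
  loci beyond a true block where overlapping windows still mix block
  loci in.
* The planted block forces a topology rather than modelling any
  rearrangement mechanism; it reproduces the observable (a
  discordance-free run), not its cause.
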
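# quartetscan

Genome scans for gene-tree discordance that *violates* the
multispecies coalescent (MSC) — the signature of recombination-
suppressed, supergene-like chromosomal blocks.

## The problem

Across most of a genome, the genealogy of any short locus is a noisy
draw from the MSC: for a species-tree branch of length `T` coalescent
units, a quartet of lineages follows the species-tree topology with
probability `1 − (2/3)·e^{−T}` and each alternative with
`(1/3)·e^{−T}`. Recombination keeps the stretches of genome sharing
one genealogy short — about `1/(2·Ne·r)` bp at equilibrium, thousands
of bp at most for bird-like parameter ranges. A *megabase*-scale
region in which essentially every locus tree agrees on a single
topology is therefore incompatible with ILS alone and points to
suppressed recombination (e.g. an ancestral rearrangement segregating
as a polymorphism). `quartetscan` provides the statistics and tests
to find and characterize such regions from per-locus trees, plus a
simulator that plants such a block so the whole pipeline can be
validated against known truth.

## What it computes

* **QQS** (quadripartition quartet support): for an internal branch
  encoded as four disjoint taxon groups `A·B|C·D`, the fraction of
  one-taxon-per-group quartets in a locus tree displaying `ab|cd`,
  normalized so the three pairings sum to 1. `QQS = 1` ⇔ mutual
  monophyly of A and B among present taxa; a mean of 1/3 per
  alternative is the hard-polytomy signature.
* **BQS** (branch quartet support): the two-plus-two analogue for a
  single bipartition `X|Y`.
* **Monophyly tracks, clade branch lengths, quartet scores** of
  candidate species trees, taxon-removal experiments, and the
  zero-intercept patristic regression for branch-length rescaling.
* **The windowed MSC test**: per chromosome, sliding windows of
  `w = 20` consecutive qualifying loci; `Z_i = (Q_i − μ_Q)/σ_Q` with
  `p = min(F(Z_i), 1−F(Z_i))`, Benjamini–Hochberg correction per
  branch, and merging of significant runs into outlier regions (BED).
* **Coalescent-HMM post-processing**: per-site posteriors over the
  four states {S, D1, D2, D3} → max-a-posteriori labels → 100-kb
  window fractions, ILS levels, and the MSC admissibility check
  (discordant fraction > 2/3 is impossible under ILS alone).
* **Simulation**: MSC locus trees along chromosomes with a planted
  discordance-free block, NNI gene-tree error, taxon dropout; plus a
  neutral Wright–Fisher persistence simulator and the `1/(2Ner)`
  calculator.

## Worked example

Simulate a 3,000-locus genome over three chromosomes with a planted
70-locus block (~2.3% of loci, the proportion of the empirical
outlier regions), then scan it:

```sh
quartetscan simulate --n-loci 3000 --block-length 70 --seed 11 --out-dir sim
quartetscan scan --trees sim/locus_trees.txt --table sim/locus_table.tsv \
    --clades clades.yaml --out-dir scan
```

with `clades.yaml` naming the simulated groups:

```yaml
groups:
  A: [A1, A2, A3]
  B: [B1, B2, B3]
  C: [C1, C2, C3, C4]
outgroup: [O1, O2]
quadripartitions:
  - {name: planted, A: A, B: B, C: C, D: []}
```

The scan prints a per-branch summary (`scan/rejection_summary.tsv`):

```
branch   n_windows  n_rejected  pct_rejected       n_regions
planted  2901       59          2.033781454670803  1
```

and calls one outlier region (`scan/regions_planted.bed`):

```
#chrom  start    end      name      min_p_adj
chr2    4610000  5381000  region_1  0.000161199
```

Read: of 2,901 20-locus windows, 59 reject the MSC null after BH at
0.01, and they form a single region on chr2 covering the planted
block (true span chr2:4,650,001–5,341,000 in 1-based coordinates;
BED is 0-based, and the call extends a few loci past the block where
overlapping windows still mix block loci in). Genome-wide mean
support for the planted branch is ~1/3 (high ILS); inside the region
it approaches 1.

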
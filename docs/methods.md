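# Methods

## Operon model

A putative operon is a maximal group of ≥ 2 genes on one contig and strand
such that (a) every pair of member profiles is closer than the Jaccard
distance cutoff, (b) consecutive members (genomic order) are within the
proximity window, and (c) all members carry the same differential-
expression call. The three criteria are deliberately independent: profile
similarity captures shared inheritance, proximity and strand capture
transcriptional architecture, and co-regulation captures shared response.

**Distance cutoff (default 0.001, strict `<`).** With binary profiles
over *n* genomes the smallest achievable nonzero Jaccard distance is
1/*n* (≈ 0.006 at *n* = 163, 0.026 at *n* = 40), so the default cutoff
admits only identical profiles. This is intentional and documented rather
than hidden: the cutoff becomes a real similarity tolerance only for much
larger panels or for weighted profile variants. Distances are computed in
exact integer arithmetic (intersection and union counts) with a single
final division, so comparisons against the cutoff are reproducible across
platforms; no epsilon is needed.

**Proximity (default 10,000 bp).** Measured as the closest-edge gap
(start of the downstream gene minus end of the upstream gene, minus one;
0 for overlap), applied between consecutive members, not all pairs — an
operon may span more than the window in total. An all-pairs variant is
available (`proximity_all_pairs`). Adjacency is geometric, not ordinal:
two genes flanking an excluded gene may still pair if their mutual gap
fits the window.

**Co-regulation.** Members must be significant DEGs of the same
direction. Requiring significance (not merely sign agreement) is the
default because "concordant differential expression" without significance
would let noise genes join groups; a flag (`require_significance=False`)
relaxes this to sign concordance for sensitivity analyses.

**Grouping semantics.** Discovery is single-linkage (union-find over the
pairwise relation), because chaining matches the intuition of walking
along the genome. Chaining can, at loose cutoffs, connect genes whose
mutual distance violates the cutoff; each component is therefore verified
all-pairs and, if needed, split by repeatedly removing the member with
the largest mean internal distance, then re-splitting on proximity. At
the default cutoff the all-pairs check is vacuous (identity is
transitive), and inference provably equals exhaustive enumeration of
maximal valid groups — the test suite checks this equivalence on small
instances by brute force.

## Differential expression

The DE stage follows the classic exact-test workflow for two-condition,
small-replicate count data.

- **TMM normalization.** Reference sample: the one whose library-scaled
  upper quartile is closest to the panel mean. Per-gene log-ratios M and
  abundances A on genes nonzero in both samples; two-sided trimming (30%
  on M, 5% on A); inverse-variance (delta-method) weights; factors
  rescaled to geometric mean 1. The implementation agrees with the
  Bioconductor TMM reference to ~1e-7 on simulated matrices (checked in
  the test suite via an independent `Rscript` oracle when R is present).
- **Common dispersion.** A single NB dispersion φ shared by all genes,
  estimated by *conditional* maximum likelihood: counts are rescaled to a
  common effective library size (geometric mean) and rounded, and within
  each condition the likelihood conditions on each gene's replicate
  total, which removes the unknown per-gene means from the likelihood.
  The simpler profile likelihood (plugging in fitted means) is biased low
  by roughly (n − k)/n at 3+3 replicates — measured ≈ 0.06 for a true
  φ = 0.1 — which in turn makes the exact test anti-conservative; the
  conditional form recovers φ within ±0.01 and restores type-I
  calibration. Optimization is a log-spaced grid over [1e-4, 4] followed
  by bounded scalar refinement; Poisson data drive the estimate to the
  lower grid edge.
- **Exact test.** Counts are rescaled to the common effective library
  size, summed per condition and rounded. Conditional on the total, the
  control-sum of two NB sums with a common probability parameter follows
  a negative hypergeometric law that is free of that parameter; the
  two-sided p-value doubles the smaller tail (capped at 1). φ = 0 uses
  the binomial (Poisson) limit. The rounding step replaces the reference
  implementation's quantile adjustment; its effect is at most one count
  per condition and invisible at the calibration level the tests check.
- **Fold changes.** log2 of normalized per-condition means with a prior
  count of 0.125 per sample (stabilizes low counts; avoids log 0).
  `fc_signed` reports the signed linear convention (−1.61 ⇒ 1.61-fold
  down) alongside `log2fc`.
- **Calls.** Strict thresholds: |FC| must exceed `min_abs_fc` (default
  2.0; 1.5 supported) and FDR must be strictly below `max_fdr` (0.05).
  Boundary values are NS. BH adjustment is the textbook step-up,
  checked exactly against an independent oracle and statsmodels.

Users who want reference-implementation numbers can feed a precomputed DE
table (`read_de_table`); calls are always recomputed from the thresholds.

## Synthetic studies

The generator emulates the study design the pipeline is meant for:
a focal strain in a panel of related genomes, a treatment-vs-control
RNA-seq contrast in triplicate, and a handful of qPCR confirmations.

Defaults (one value each, chosen once): 40 genomes (desk-scale; 163 is a
supported setting echoing full-size panels), 500 focal genes, 12 planted
operons of 2–6 genes, |log2FC| = 2 with a random per-operon sign, NB
dispersion 0.1, mean expression 200 counts (log-normal spread, sdlog 0.5),
3 replicates per condition, 900 bp genes with 200 bp gaps on one contig.
Planted operon members receive identical presence/absence patterns
(optionally perturbed by `profile_noise_flips`); background genes draw
independent Bernoulli(0.5) patterns, and collisions with planted patterns
are allowed — they exercise the proximity/strand/DE criteria rather than
being excluded by construction. At least one background gene separates
successive operon blocks. qPCR Ct values follow
Ct = baseline − log_E(expression) + N(0, σ²) with σ = 0.15 cycles and
E = 2 by default; reference genes are planted at zero fold change.

What the generator does **not** emulate: orthology-call errors beyond
uniform bit flips, operon-internal promoters or partial co-regulation,
multi-contig assemblies (single contig by default; proximity is
intra-contig by definition), GC/length biases in counts, or
dose–response structure. Passing tests therefore demonstrate correctness
of the machinery and calibration under the stated model, not robustness
to real-data artifacts such as systematic orthology errors.

All four generators draw from independent streams of one seed
(`numpy` `SeedSequence` spawning), so outputs are byte-identical across
reruns and any single stage can be regenerated alone.

## Scoring recovery

`score_recovery` reports **precision** as the fraction of inferred
candidates whose member set lies inside a single planted operon, and
**recall** as the fraction of planted operons recovered with exactly
their member set. The asymmetric definitions reflect DE stochasticity: a
member gene that narrowly misses the fold-change cutoff leaves a smaller
— still correct — candidate, which should not count as a false positive,
but the operon is no longer recovered exactly. At the default design the
per-gene DEG power is ≈ 0.97–0.99, so a 4-gene operon is recovered
exactly with probability ≈ 0.9; measured mean recall across 20 studies
is ≈ 0.89–0.95 with precision 1.0.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use desk-scale designs — 500
genes × 40 genomes for recovery (20 seeds), 2,000 genes for null
calibration, 60-gene instances for exhaustive-search equivalence, 500
Monte-Carlo replicates for qPCR calibration — sizes at which every
statistical check is stable yet the whole suite runs in well under a
minute. All randomness is seeded; property tests are derandomized.

## Known limitations

- The identical-profile consequence of the default cutoff means panel
  composition matters more than the cutoff value; a gene family lost in
  a single panel genome breaks a group.
- Common dispersion only: no tagwise/trended dispersion, no GLM or
  multi-factor designs. Contrasts are analyzed one treatment-vs-control
  pair at a time.
- COG summaries are counts, not enrichment tests (none is implied).
- qPCR efficiencies are taken from the input table, not estimated from
  dilution series.
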
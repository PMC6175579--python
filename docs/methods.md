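# Methods

## The measurement model

A pooled library of barcoded transposon insertion mutants is inoculated
(the T0 reference), grown in each condition, harvested at successive
timepoints and sequenced by barcode PCR (BarSeq). The read count `n` of a
barcode is a multinomial sample of its strain's relative abundance, so for
strain `s` in harvest sample `h` the **strain fitness** is the log2 change
in depth-normalized abundance against the shared T0:

    f_s = log2((n_h + ψ) / (n_0 + ψ)) − log2(N_h / N_0)

with sample totals `N` taken over retained barcodes. The pseudocount ψ
guards zeros. Its default is **0.1**, deliberately small: the T0 filter
(below) bounds `n_0` away from zero, but harvest counts of strongly
deleterious mutants are routinely below one read, and the bias a
pseudocount adds to a deleterious gene grows as `log2(1 + ψ/n_h)` — at
ψ = 1 this is ≈ +0.15 log2 units for a fourfold-depleted gene at typical
desk-scale depth, enough to push a true −2 effect outside ±0.3 recovery;
at ψ = 0.1 the bias is ≈ +0.02.

**Filters** (all defaults configurable in `FitnessConfig`): only
insertions in the central 10–90% of a gene's coding sequence count
(boundaries inclusive; the fraction is measured from the translational
start, strand-aware), barcodes need ≥ 3 T0 reads, and genes need ≥ 30 T0
reads across retained barcodes to be scored.

**Gene fitness** is the weighted mean of its retained strains' fitnesses
with `w_s = 1/(1/(1+n_0) + 1/(1+n_h))`, the inverse of the Poisson
delta-method variance of a log count ratio (up to the `1/ln2²` constant),
so well-sampled strains dominate.

**Normalization** happens per replicate, in two stages. First the running
median of raw gene fitness over a window of `W = 251` genes in chromosome
order is subtracted (circular wrap on circular scaffolds, truncated
windows on linear ones, scaffold-wide median when fewer than `W` genes are
scored): genes near the replication fork have extra copies in dividing
cells, which shows up as a smooth positional trend that the median tracks
while leaving isolated gene effects intact. Then the mode of the resulting
distribution — the argmax of a Gaussian KDE (Silverman bandwidth) on a
512-point grid — is subtracted, on the assumption that disrupting most
genes has no fitness effect, so the bulk of the distribution marks zero.
Replicates are normalized separately and then averaged; normalizing first
keeps each replicate's copy-number trend and mode where that replicate
actually put them.

## The moderated t-score

The t-score is gene fitness divided by a variance-stabilized standard
deviation. Per replicate the gene variance is the larger of

- the weighted strain spread `Σ w²(f_s − f_g)² / (Σ w)²`, and
- a Poisson floor `(1/ln2)² (1/(1+N0_g) + 1/(1+Nh_g))` from the gene's
  read totals (this is also what makes single-strain genes well-defined).

Two aggregation choices matter and were made deliberately:

1. **Shared-T0 covariance.** Every replicate is ratioed against the same
   T0 sample, so the T0 counting noise `V0 = (1/ln2)²/(1+N0_g)` is
   perfectly correlated across replicates and does not shrink with R. The
   variance of the replicate mean is therefore
   `V_g = V0 + Σ_r (V_r − V0)/R²`. Treating replicates as independent
   (`Σ V_r / R²`) understates the variance by nearly a factor of two at
   R = 3 and, in null simulations, inflates stdev(t) to ≈ 1.33 and the
   false-positive rate to ≈ 1.2%.

2. **One-sided moderation.** `V_mod = max(V_g, (V_g + Ṽ)/2)` with `Ṽ` the
   across-genes median of `V_g`. Moderation exists to stabilize
   *under-estimated* variances (a noisy χ² spread estimate from ~16
   strains); pulling genuinely *high* variances down toward the median
   rewards poorly measured genes with inflated t-scores and measurably
   fattens the null tail (symmetric moderation gave null false-positive
   rates up to 0.24%, above the ≈ 0.2% the significance rule is supposed
   to deliver).

With both choices the null t-distribution is calibrated: stdev(t) ≈
0.9–1.0 and 0.09–0.10% of scored genes are flagged significant-negative
(|t| ≥ 3, f̄ < 0) per condition-timepoint under a no-effect simulation.

Note the shared T0 makes per-condition tests *correlated*: a gene whose
one T0 draw lands ~3σ unlucky carries the same ≈ −0.3 offset into every
harvest comparison, so its (few) false flags cluster across conditions.
This is a property of the single-reference design, not of the estimator.

## Interaction classification

A gene is *required* in a condition if |t| ≥ 3 (inclusive) and fitness is
negative at ≥ 1 timepoint (sets pool by union over timepoints). Against
the alone set A and contexts S1..Sk: conserved = A ∩ ⋂Si, alleviated =
A \ ⋂Si, induced = ⋃Si \ A. The default conserved rule requires presence
in *all* contexts; an "any" rule is available behind a flag because mixed
partner patterns make the two readings genuinely different and either is
defensible. Cross-classifying a family (induced or alleviated) between
pairwise and community contexts splits it into conserved /
pairwise-specific / community-specific pieces; the higher-order summary
reports conserved pieces as pairwise-derived interactions and the
specific pieces as higher-order, with integer percentages
(round-half-to-even) always accompanied by raw counts.

## Expression sets and enrichment

DE tables from any external tool are consumed as (gene, contrast,
timepoint, log2FC, padj). Thresholds: padj < 0.01 and |log2FC| ≥ 1, the
fold-change boundary inclusive (a strict-greater flag exists). The
amplified-response screen applies the same thresholds to a
community-vs-pairwise contrast restricted to the conserved set; those
thresholds are a package choice, not an externally fixed constant.
Enrichment is the exact hypergeometric upper tail
`p = Σ_{i≥k} C(K,i)C(M−K,n−i)/C(M,n)` with BH correction across
categories (enriched iff padj < 0.05); the implementation uses the scipy
survival function and is tested against a direct combinatorial summation.

## Competition assays

Mutant fraction p = mutant CFU / total CFU from paired selective/total
plates; fitness f = log2(p_day1/p_T0); confidence z = mean/(sd/√R) with
sample sd. The default call uses the normal reference (z ≤ −1.645 for 95%
one-sided); a Student-t option (critical value at R−1 df) is provided and
is the statistically honest choice at R = 3, where the z statistic is
t-distributed with 2 df and the normal cutoff realizes ≈ 12% type-I error
instead of 5%. Zero spread with nonzero mean yields an infinite z of the
matching sign; a single replicate yields no call.

## The synthetic-data generator

The generator emulates the study design, not sequencing chemistry:

- **Genome**: one circular 4.6 Mb scaffold, 3,300 non-overlapping genes
  with uniform lengths of 400–2000 bp (~86% coding density, matching
  bacterial gene-length statistics while leaving realistic intergenic
  space).
- **Pool**: 55,000–73,000 mutants (median ≈ 12–16 central insertions per
  gene, mirroring the per-gene statistics of a ~150k-mutant library at
  desk scale), unique random 20 nt barcodes, 10% intergenic insertions.
- **T0 abundances**: log-normal with σ = 0.5 (uneven library
  representation, which exercises the count-based weights and filters).
- **Effects**: truth is parameterized directly as cumulative log2
  abundance effects φ per condition and timepoint (not growth rates), so
  the estimator's target *is* the planted value; by default a constant
  per-day effect compounds across timepoints (φ at day d = d × effect).
  Categories (conserved, alone-required, pairwise-induced,
  pairwise-alleviated, community-specific induced/alleviated) are
  disjoint random gene subsets whose φ patterns define them.
- **Counts**: harvest weight `w = a0 · 2^φ · 2^(b·cos(2πx/L))` with
  b = 0.3 emulating replication-associated copy-number bias (harvest
  samples only — the inoculum is not dividing); each sample is one
  multinomial draw of the design depth, default 2×10⁶ reads (sequencing
  depth for real libraries of this kind is typically 1.5–7.5 million
  reads per sample).
- **Reads**: pad + 5' flank + barcode + 3' flank + pad, constant quality;
  extraction is exactly invertible, which the round-trip tests exploit.

Not modeled: sequencing errors and PCR duplicates (an optional
single-substitution rescue exists in the extractor but is off by
default), partner genomes (partner presence is a condition label), strain
dropout biology, spatial structure. Passing tests therefore demonstrate
the estimator and classifier are correct for multinomial counting noise
over a structured library — they do not certify robustness to chemistry
artifacts real data can contain.

## Problem sizes and determinism

Simulation-based tests run at 3,300 genes × ~73k mutants × 2×10⁶ reads
(the desk-scale mirror of the study design) for calibration and recovery
checks, and at a few hundred genes for narrative examples; the full
simulate → count → fit → classify chain at study scale runs in well under
a minute per seed on one CPU. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; no global random state is used
anywhere, and identical seeds give bit-identical outputs.

## Known limitations

- With a single shared T0, false positives correlate across conditions
  (see above); designs with per-replicate T0 references would decorrelate
  them but are not what the assay produces.
- The exact-match barcode extractor is intentionally strict; real
  datasets with appreciable sequencing error need the substitution-rescue
  flag or upstream error correction.
- The running-median window (251 genes) assumes copy-number trends vary
  slowly relative to the window; plasmids or scaffolds with few scored
  genes fall back to a scaffold-wide median.
- Positive fitness values are computed but the classification layer
  targets negative fitness (growth requirements) only.
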
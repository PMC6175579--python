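"""Simulate a small pooled-library study and count barcodes from its reads.

Builds a toy genome and barcoded insertion pool, plants conserved fitness
defects, draws multinomial BarSeq counts, writes per-sample FASTQ and then
re-extracts the barcodes — demonstrating that extraction is lossless.
"""

import tempfile
from pathlib import Path

import barseqfit as bf

genome = bf.make_genome(n_genes=50, scaffold_length=100_000, seed=1)
pool = bf.make_pool(genome, n_mutants=1_000, seed=2)
design = bf.SimDesign(
    conditions=("alone", "pairwise_1", "community"),
    timepoints=("day1",),
    replicates=2,
    depth=30_000,
    seed=3,
)
truth = bf.make_truth(genome, design, {"conserved": 0.1}, effect_size=-2.0, seed=4)
counts = bf.simulate_counts(pool, truth, design, genome.scaffold_lengths)
print(f"pool: {len(pool)} mutants, {pool['central'].sum()} central insertions")
print(f"count matrix: {counts.counts.shape[0]} barcodes x {counts.counts.shape[1]} samples")

with tempfile.TemporaryDirectory() as td:
    paths = bf.emit_barseq_fastq(counts, pool, seed=5, outdir=Path(td))
    per_sample, unmatched = {}, {}
    for sample, path in paths.items():
        per_sample[sample], unmatched[sample] = bf.extract_barcodes(path)
    rebuilt = bf.assemble_count_matrix(per_sample, counts.samples, pool, unmatched)

identical = (rebuilt.counts.loc[counts.counts.index, counts.counts.columns]
             == counts.counts).all().all()
print(f"reads emitted per sample: {design.depth}; unmatched on re-extraction: "
      f"{int(rebuilt.unmatched.sum())}")
print(f"round trip reproduces the count matrix exactly: {identical}")
# every sequencing read carries one barcode between fixed vector flanks, so
# counting barcodes recovers mutant abundances with zero loss
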
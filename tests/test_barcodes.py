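"""Barcode extraction, count assembly, insertion annotation, pool building."""

import io as stdio

import pandas as pd
import pytest

import barseqfit as bf

LAYOUT = bf.ReadLayout(preseq="GAGGTCTCT", postseq="CGTACGCTGC", barcode_length=20,
                       min_offset=0, max_offset=8)
BC = "ACGTACGTACGTACGTACGT"


def fastq(*seqs: str) -> stdio.StringIO:
    return stdio.StringIO(
        "".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs))
    )


class TestExtractBarcodes:
    def test_exact_read_counted(self):
        counts, unmatched = bf.extract_barcodes(
            fastq("ACT" + LAYOUT.preseq + BC + LAYOUT.postseq + "AAAA"), LAYOUT
        )
        assert counts == {BC: 1} and unmatched == 0

    def test_read_without_preseq_unmatched(self):
        counts, unmatched = bf.extract_barcodes(fastq("A" * 50), LAYOUT)
        assert counts == {} and unmatched == 1

    @pytest.mark.parametrize("offset", [0, 4, 8])
    def test_all_allowed_offsets_found(self, offset):
        read = "T" * offset + LAYOUT.preseq + BC + LAYOUT.postseq
        counts, unmatched = bf.extract_barcodes(fastq(read), LAYOUT)
        assert counts == {BC: 1} and unmatched == 0

    def test_offset_beyond_window_unmatched(self):
        read = "T" * (LAYOUT.max_offset + 1) + LAYOUT.preseq + BC + LAYOUT.postseq
        counts, unmatched = bf.extract_barcodes(fastq(read), LAYOUT)
        assert counts == {} and unmatched == 1

    def test_ambiguous_base_in_barcode_unmatched(self):
        bad = BC[:-1] + "N"
        counts, unmatched = bf.extract_barcodes(
            fastq(LAYOUT.preseq + bad + LAYOUT.postseq), LAYOUT
        )
        assert counts == {} and unmatched == 1

    def test_postseq_truncated_by_read_end_still_matches(self):
        read = LAYOUT.preseq + BC + LAYOUT.postseq[:3]
        counts, unmatched = bf.extract_barcodes(fastq(read), LAYOUT)
        assert counts == {BC: 1} and unmatched == 0

    def test_wrong_postseq_unmatched(self):
        read = LAYOUT.preseq + BC + "TTTTTTTTTT"
        counts, unmatched = bf.extract_barcodes(fastq(read), LAYOUT)
        assert counts == {} and unmatched == 1

    def test_conservation_matched_plus_unmatched(self):
        reads = [LAYOUT.preseq + BC + LAYOUT.postseq, "A" * 40, "C" * 40]
        counts, unmatched = bf.extract_barcodes(fastq(*reads), LAYOUT)
        assert sum(counts.values()) + unmatched == len(reads)

    def test_malformed_fastq_names_record(self):
        broken = stdio.StringIO("@r0\nACGT\nNOPLUS\nIIII\n")
        with pytest.raises(ValueError, match="index 0"):
            bf.extract_barcodes(broken, LAYOUT)


class TestRoundTrip:
    def test_emit_then_extract_is_identity(self, small_genome, small_pool, tmp_path):
        design = bf.SimDesign(
            conditions=("alone", "community"), timepoints=("day1",), replicates=2,
            depth=20_000, seed=31,
        )
        truth = bf.make_truth(small_genome, design, {"conserved": 0.1}, seed=32)
        counts = bf.simulate_counts(small_pool, truth, design, small_genome.scaffold_lengths)
        paths = bf.emit_barseq_fastq(counts, small_pool, seed=33, outdir=tmp_path)
        per, unm = {}, {}
        for sample, path in paths.items():
            per[sample], unm[sample] = bf.extract_barcodes(path)
        rebuilt = bf.assemble_count_matrix(per, counts.samples, small_pool, unm)
        assert (rebuilt.counts.loc[counts.counts.index, counts.counts.columns]
                == counts.counts).all().all()
        assert (rebuilt.unmatched == 0).all()

    def test_zero_count_sample_gives_empty_fastq(self, small_pool, tmp_path):
        counts = bf.CountMatrix(
            counts=pd.DataFrame(
                {"T0": [3, 2], "s1": [0, 0]},
                index=pd.Index(small_pool["barcode"].iloc[:2], name="barcode"),
            ),
            samples=bf.containers.sample_sheet(
                [{"sample": "T0", "condition": "", "timepoint": "", "replicate": 0,
                  "role": "T0"},
                 {"sample": "s1", "condition": "alone", "timepoint": "day1",
                  "replicate": 1, "role": "harvest"}]
            ),
        )
        paths = bf.emit_barseq_fastq(counts, small_pool, seed=1, outdir=tmp_path)
        assert paths["s1"].read_text() == ""

    def test_unknown_barcode_in_counts_raises(self, small_pool, tmp_path):
        counts = bf.CountMatrix(
            counts=pd.DataFrame({"T0": [1]}, index=pd.Index(["A" * 20], name="barcode")),
            samples=bf.containers.sample_sheet(
                [{"sample": "T0", "condition": "", "timepoint": "", "replicate": 0,
                  "role": "T0"}]
            ),
        )
        with pytest.raises(ValueError, match="absent from the pool"):
            bf.emit_barseq_fastq(counts, small_pool, outdir=tmp_path)


class TestAssembleCountMatrix:
    SHEET = bf.containers.sample_sheet(
        [{"sample": "T0", "condition": "", "timepoint": "", "replicate": 0, "role": "T0"},
         {"sample": "s1", "condition": "alone", "timepoint": "day1", "replicate": 1,
          "role": "harvest"}]
    )

    def test_stray_barcode_goes_to_unmatched(self, small_pool):
        bc = small_pool["barcode"].iloc[0]
        matrix = bf.assemble_count_matrix(
            {"T0": {bc: 5, "T" * 20: 7}, "s1": {bc: 2}}, self.SHEET, small_pool
        )
        assert matrix.counts.loc[bc, "T0"] == 5
        assert matrix.unmatched["T0"] == 7 and matrix.unmatched["s1"] == 0

    def test_all_zero_sample_column_retained(self, small_pool):
        matrix = bf.assemble_count_matrix(
            {"T0": {small_pool["barcode"].iloc[0]: 5}, "s1": {}}, self.SHEET, small_pool
        )
        assert (matrix.counts["s1"] == 0).all()
        assert matrix.counts.shape == (len(small_pool), 2)

    def test_missing_t0_role_raises(self, small_pool):
        sheet = bf.containers.sample_sheet(
            [{"sample": "s1", "condition": "alone", "timepoint": "day1", "replicate": 1,
              "role": "harvest"}]
        )
        with pytest.raises(ValueError, match="T0"):
            bf.assemble_count_matrix({"s1": {}}, sheet, small_pool)


class TestAnnotateInsertions:
    GENOME = bf.GenomeAnnotation(
        scaffolds=pd.DataFrame({"name": ["c"], "length": [3000], "circular": [False]}),
        genes=pd.DataFrame(
            {"locus_tag": ["gPlus", "gMinus"], "scaffold": ["c", "c"],
             "start": [1001, 2001], "end": [2000, 2501], "strand": ["+", "-"]}
        ),
    )

    @pytest.mark.parametrize(
        "pos,locus,fraction,central",
        [
            (1500, "gPlus", 499 / 999, True),    # mid-gene
            (1050, "gPlus", 49 / 999, False),    # before the 10% boundary
            (500, "", None, False),              # intergenic
            (2451, "gMinus", 0.1, True),         # exactly 10% on the - strand
            (2001, "gMinus", 1.0, False),        # translational stop of a - gene
        ],
    )
    def test_fraction_and_central_flag(self, pos, locus, fraction, central):
        lt, frac, cen = bf.annotate_insertions(pos, "c", self.GENOME)
        assert lt == locus and cen == central
        if fraction is None:
            assert frac is None
        else:
            assert frac == pytest.approx(fraction)

    def test_out_of_bounds_position_raises(self):
        with pytest.raises(ValueError, match="outside scaffold"):
            bf.annotate_insertions(3001, "c", self.GENOME)


@pytest.fixture(scope="module")
def genome_and_seqs():
    genome = bf.make_genome(10, 20_000, seed=41)
    return genome, bf.make_genome_sequence(genome, seed=42)


class TestBuildPoolFromTnseq:

    def test_consistent_reads_retained(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        frag = seqs["chr1"][4999:5059]
        pool = bf.build_pool_from_tnseq([("B1", frag)] * 3, seqs, genome)
        assert list(pool["barcode"]) == ["B1"]
        assert pool["pos"].iloc[0] == 5000

    def test_split_votes_dropped(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        reads = [("B1", seqs["chr1"][4999:5059]), ("B1", seqs["chr1"][9999:10059])]
        pool = bf.build_pool_from_tnseq(reads, seqs, genome, min_reads=2,
                                        majority_fraction=0.75)
        assert len(pool) == 0

    def test_single_read_dropped_at_default_min(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        pool = bf.build_pool_from_tnseq([("B1", seqs["chr1"][4999:5059])], seqs, genome)
        assert len(pool) == 0

    def test_reverse_complement_fragment_located(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        frag = seqs["chr1"][4999:5059]
        rc = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pool = bf.build_pool_from_tnseq([("B1", rc)] * 2, seqs, genome)
        assert pool["pos"].iloc[0] == 5000 and pool["strand"].iloc[0] == "-"

    def test_ambiguous_fragment_discarded(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        repeated = {"c1": seqs["chr1"][:6000] + seqs["chr1"][4999:5059] + "ACGT" * 10}
        genome2 = bf.GenomeAnnotation(
            scaffolds=pd.DataFrame(
                {"name": ["c1"], "length": [len(repeated["c1"])], "circular": [False]}
            ),
            genes=genome.genes.iloc[:1].assign(scaffold="c1"),
        )
        pool = bf.build_pool_from_tnseq(
            [("B1", seqs["chr1"][4999:5059])] * 2, repeated, genome2
        )
        assert len(pool) == 0

    def test_deterministic(self, genome_and_seqs):
        genome, seqs = genome_and_seqs
        reads = [("B1", seqs["chr1"][4999:5059])] * 2 + [("B2", seqs["chr1"][999:1059])] * 3
        a = bf.build_pool_from_tnseq(reads, seqs, genome)
        b = bf.build_pool_from_tnseq(reads, seqs, genome)
        pd.testing.assert_frame_equal(a, b)
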
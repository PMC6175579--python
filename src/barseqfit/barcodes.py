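"""Barcode extraction from BarSeq reads and pool-table construction.

BarSeq reads carry a 20 nt random barcode between two fixed vector flanks;
counting barcodes per sample measures the abundance of each insertion
mutant. Extraction here is exact-match and deterministic: the 5' flank is
searched at a small range of start offsets (sequencing pads vary by a few
bases), the barcode must be clean ACGT, and the bases after it must match
the 3' flank as far as the read extends.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import CountMatrix, GenomeAnnotation, validate_pool

_ACGT = frozenset("ACGT")

#: Default flanks of the barcode in the transposon-vector amplicon.
#: The upstream protocol's vector is fixed but its flank sequences are
#: configuration, not printed constants; override for other designs.
DEFAULT_PRESEQ = "GAGGTCTCT"
DEFAULT_POSTSEQ = "CGTACGCTGC"


@dataclass(frozen=True)
class ReadLayout:
    """Where the barcode sits inside a read.

    ``preseq``/``postseq`` flank the barcode immediately 5' and 3';
    ``barcode_length`` defaults to the 20 bp barcodes of the pooled Tn5
    vector library; the 5' flank may start anywhere in
    ``[min_offset, max_offset]``.
    """

    preseq: str = DEFAULT_PRESEQ
    postseq: str = DEFAULT_POSTSEQ
    barcode_length: int = 20
    min_offset: int = 0
    max_offset: int = 8

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        for name in ("preseq", "postseq"):
            s = getattr(self, name)
            if not s or set(s) - _ACGT:
                raise ValueError(f"{name} must be a non-empty ACGT string")
        if not 0 <= self.min_offset <= self.max_offset:
            raise ValueError("need 0 <= min_offset <= max_offset")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def extract_barcodes(
    fastq, layout: ReadLayout | None = None, rescue_one_mismatch: bool = False
) -> tuple[Counter, int]:
    """Count barcodes in a FASTQ stream.

    ``fastq`` is a path or an open text handle of 4-line FASTQ records.
    For each read the 5' flank is searched (exact match) at every allowed
    offset; on a hit, the following ``barcode_length`` bases are taken as
    the barcode if they are clean ACGT and are followed by the 3' flank
    (compared only as far as the read extends). Reads failing any step are
    tallied as unmatched, so ``sum(counts) + unmatched == total reads``.

    With ``rescue_one_mismatch`` an extracted barcode one substitution
    away from exactly one already-seen barcode is folded into it after the
    first pass (off by default; exact counting is the contract).
    """
    layout = layout or ReadLayout()
    own = False
    if isinstance(fastq, (str, Path)):
        fastq = _open_maybe_gzip(fastq)
        own = True
    counts: Counter = Counter()
    unmatched = 0
    try:
        iterator = FastqGeneralIterator(fastq)
        index = 0
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            if item is None:
                break
            _, seq, _ = item
            index += 1
            bc = _extract_one(seq.upper(), layout)
            if bc is None:
                unmatched += 1
            else:
                counts[bc] += 1
    finally:
        if own:
            fastq.close()
    if rescue_one_mismatch:
        counts = _rescue(counts)
    return counts, unmatched


def _extract_one(seq: str, layout: ReadLayout) -> str | None:
    pre, post, blen = layout.preseq, layout.postseq, layout.barcode_length
    for off in range(layout.min_offset, layout.max_offset + 1):
        if not seq.startswith(pre, off):
            continue
        start = off + len(pre)
        end = start + blen
        if end > len(seq):
            continue
        bc = seq[start:end]
        if set(bc) - _ACGT:
            continue
        tail = seq[end : end + len(post)]
        if post.startswith(tail) or tail.startswith(post):
            return bc
    return None


def _rescue(counts: Counter) -> Counter:
    """Fold singleton barcodes into a unique 1-substitution neighbour."""
    keep = Counter()
    strong = {bc for bc, c in counts.items() if c > 1}
    for bc, c in counts.items():
        if bc in strong:
            keep[bc] += c
            continue
        neighbours = [s for s in strong if _hamming1(bc, s)]
        if len(neighbours) == 1:
            keep[neighbours[0]] += c
        else:
            keep[bc] += c
    return keep


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def assemble_count_matrix(
    sample_counts: Mapping[str, Mapping[str, int]],
    sheet: pd.DataFrame,
    pool: pd.DataFrame,
    unmatched: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Assemble per-sample barcode counts into a CountMatrix over the pool.

    Rows are restricted to pool barcodes; reads for barcodes absent from
    the pool are added to that sample's unmatched tally; pool barcodes
    unseen in a sample get 0. ``sheet`` is indexed by sample id with a
    ``role`` column designating exactly one T0.
    """
    validate_pool(pool)
    if not sheet.index.is_unique:
        raise ValueError("duplicate sample ids in sample sheet")
    missing = set(sheet.index) - set(sample_counts)
    if missing:
        raise ValueError(f"sample sheet rows without counts: {sorted(missing)}")
    known = pd.Index(pool["barcode"], name="barcode")
    known_set = set(known)
    columns = {}
    stray_tally = {}
    for sample in sheet.index:
        cmap = sample_counts[sample]
        columns[sample] = pd.Series(cmap, dtype=np.int64).reindex(known, fill_value=0)
        stray_tally[sample] = sum(c for bc, c in cmap.items() if bc not in known_set)
    counts = pd.DataFrame(columns, index=known)
    tally = pd.Series(stray_tally, name="unmatched")
    if unmatched is not None:
        tally = tally.add(pd.Series(unmatched), fill_value=0).astype(np.int64)
    return CountMatrix(counts=counts, samples=sheet, unmatched=tally)


def annotate_insertions(
    pos: int, scaffold: str, annotation: GenomeAnnotation
) -> tuple[str, float | None, bool]:
    """Locate an insertion position relative to the gene annotation.

    Returns ``(locus_tag, gene_fraction, central)``. The fraction is
    measured from the translational start: ``(pos-start)/(end-start)`` on
    the + strand, ``(end-pos)/(end-start)`` on the - strand, so "central"
    (0.1 <= fraction <= 0.9, boundaries inclusive) means central in the
    coding sequence. Intergenic positions return ``("", None, False)``.
    Coordinates are 1-based inclusive.
    """
    length = annotation.scaffold_lengths.get(scaffold)
    if length is None:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside scaffold {scaffold!r} (1..{length})")
    genes = annotation.genes_on(scaffold)
    starts = genes["start"].to_numpy()
    idx = int(np.searchsorted(starts, pos, side="right")) - 1
    if idx >= 0:
        g = genes.iloc[idx]
        if pos <= int(g["end"]):
            frac = _strand_fraction(pos, int(g["start"]), int(g["end"]), str(g["strand"]))
            return str(g["locus_tag"]), frac, 0.1 <= frac <= 0.9
    return "", None, False


def _strand_fraction(pos: int, start: int, end: int, strand: str) -> float:
    span = end - start
    if span == 0:
        return 0.5
    return (end - pos) / span if strand == "-" else (pos - start) / span


def build_pool_from_tnseq(
    reads: Iterable[tuple[str, str]],
    genome_seqs: Mapping[str, str],
    annotation: GenomeAnnotation,
    min_reads: int = 2,
    majority_fraction: float = 0.75,
) -> pd.DataFrame:
    """Build a pool table from (barcode, genomic fragment) TnSeq reads.

    Lite mode for synthetic data: each fragment is located by exact string
    match against the genome (forward, then reverse complement; fragments
    matching more than one position are discarded as ambiguous). A barcode
    is retained iff it has at least ``min_reads`` reads and at least
    ``majority_fraction`` of them agree on one location; it is then
    annotated via :func:`annotate_insertions`. Deterministic.
    """
    votes: dict[str, Counter] = defaultdict(Counter)
    ambiguous = 0
    for barcode, fragment in reads:
        loc = _locate_fragment(fragment.upper(), genome_seqs)
        if loc is None:
            ambiguous += 1
            continue
        votes[barcode][loc] += 1
    rows = []
    for barcode in sorted(votes):
        tally = votes[barcode]
        total = sum(tally.values())
        if total < min_reads:
            continue
        (loc, top) = tally.most_common(1)[0]
        if top / total < majority_fraction:
            continue
        scaffold, pos, strand = loc
        locus_tag, frac, central = annotate_insertions(pos, scaffold, annotation)
        rows.append(
            {
                "barcode": barcode,
                "scaffold": scaffold,
                "strand": strand,
                "pos": pos,
                "locus_tag": locus_tag,
                "gene_fraction": np.nan if frac is None else frac,
                "central": central,
            }
        )
    pool = pd.DataFrame(
        rows,
        columns=["barcode", "scaffold", "strand", "pos", "locus_tag", "gene_fraction", "central"],
    )
    return validate_pool(pool)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _locate_fragment(
    fragment: str, genome_seqs: Mapping[str, str]
) -> tuple[str, int, str] | None:
    """Unique exact-match location of a fragment, or None if 0 or >1 hits.

    Position is the 1-based coordinate of the fragment's first genome base.
    """
    hits: list[tuple[str, int, str]] = []
    rc = fragment.translate(_COMPLEMENT)[::-1]
    for name, seq in genome_seqs.items():
        for query, strand in ((fragment, "+"), (rc, "-")):
            start = 0
            while True:
                i = seq.find(query, start)
                if i < 0:
                    break
                hits.append((name, i + 1, strand))
                if len(hits) > 1:
                    return None
                start = i + 1
    return hits[0] if len(hits) == 1 else None
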
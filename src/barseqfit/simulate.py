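"""Synthetic study generator for pooled-library fitness experiments.

Emulates the design of a barcoded transposon (RB-TnSeq) fitness study of a
bacterium grown alone, in pairwise co-culture with each of three partners,
and with the full community: a pooled insertion library sampled at T0,
grown in every condition in triplicate, harvested at three timepoints and
sequenced by barcode amplification (BarSeq). Ground-truth per-gene log2
abundance effects are planted in structured categories (conserved /
induced / alleviated / community-specific) so that every downstream stage
— barcode extraction, fitness estimation, interaction classification — can
be tested for exact recovery without any external data.

All randomness flows from explicit integer seeds through
:func:`numpy.random.default_rng`; no global random state is touched.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import ReadLayout
from .containers import CountMatrix, GenomeAnnotation, sample_sheet, validate_pool

#: Study conditions: growth alone, three pairwise co-cultures, full community.
DEFAULT_CONDITIONS = ("alone", "pairwise_1", "pairwise_2", "pairwise_3", "community")
#: Harvests at 24 h, 48 h and 72 h.
DEFAULT_TIMEPOINTS = ("day1", "day2", "day3")

#: Ground-truth effect categories. Each names a distinct pattern of which
#: conditions a gene is required in (see :func:`effect_conditions`).
CATEGORIES = (
    "neutral",
    "alone_required",
    "conserved",
    "pairwise_induced",
    "pairwise_alleviated",
    "community_specific_induced",
    "community_specific_alleviated",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimDesign:
    """Experimental design of a simulated fitness study.

    Parameters
    ----------
    conditions
        Condition labels; the first is growth alone, the last the full
        community, anything between a pairwise co-culture.
    timepoints
        Harvest timepoints, in temporal order.
    replicates
        Replicates per condition x timepoint (the study used triplicates).
    depth
        Sequencing reads per sample. The study reports 1.5-7.5 million
        reads per condition; the default sits inside that range.
    position_bias_amplitude
        Multiplicative log2 amplitude ``b`` of a cosine copy-number bias
        along the chromosome, applied to harvest samples only (genes near
        the replication origin have extra copies in dividing cells).
    t0_sigma
        Log-normal sigma of T0 strain abundances (uneven library
        representation).
    seed
        Integer seed; every draw derives from it.
    """

    conditions: Sequence[str] = DEFAULT_CONDITIONS
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    depth: int = 2_000_000
    position_bias_amplitude: float = 0.3
    t0_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.position_bias_amplitude < 0:
            raise ValueError("position_bias_amplitude must be >= 0")
        if len(self.conditions) < 1 or len(self.timepoints) < 1:
            raise ValueError("need at least one condition and one timepoint")


def effect_conditions(
    category: str,
    conditions: Sequence[str],
    induced_in_community: bool = True,
) -> frozenset[str]:
    """Conditions in which a gene of ``category`` carries its fitness effect.

    With conditions (alone, P1..Pk, community) the patterns are:

    ==============================  =======================================
    category                        effect present in
    ==============================  =======================================
    neutral                         nowhere
    alone_required                  alone only (alleviated by any partner
                                    and by the community)
    conserved                       every condition
    pairwise_induced                all pairwise conditions, plus the
                                    community when ``induced_in_community``
    pairwise_alleviated             alone and community (relieved only in
                                    pairwise co-culture)
    community_specific_induced      community only
    community_specific_alleviated   alone and all pairwise (relieved only
                                    by the full community)
    ==============================  =======================================
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    alone = conditions[0]
    community = conditions[-1] if len(conditions) > 1 else None
    pairwise = list(conditions[1:-1])
    if category == "neutral":
        return frozenset()
    if category == "conserved":
        return frozenset(conditions)
    if category == "alone_required":
        return frozenset({alone})
    if category == "pairwise_induced":
        on = set(pairwise)
        if induced_in_community and community is not None:
            on.add(community)
        return frozenset(on)
    if category == "pairwise_alleviated":
        on = {alone}
        if community is not None:
            on.add(community)
        return frozenset(on)
    if category == "community_specific_induced":
        return frozenset({community} if community is not None else set())
    # community_specific_alleviated
    return frozenset({alone, *pairwise})


@dataclass
class TruthTable:
    """Planted ground truth of a simulation.

    ``phi`` is a long table (locus_tag, condition, timepoint, phi) of true
    cumulative log2 relative-abundance effects (0 = neutral); ``categories``
    maps every locus_tag to its planted category label.
    """

    phi: pd.DataFrame
    categories: pd.Series

    def phi_lookup(self, condition: str, timepoint: str) -> pd.Series:
        sub = self.phi[(self.phi["condition"] == condition) & (self.phi["timepoint"] == timepoint)]
        return sub.set_index("locus_tag")["phi"]

    def nonneutral(self) -> pd.Series:
        return self.categories[self.categories != "neutral"]

    def effect_pattern(self, locus_tag: str) -> frozenset[str]:
        """Conditions in which the gene has a nonzero planted effect."""
        sub = self.phi[(self.phi["locus_tag"] == locus_tag) & (self.phi["phi"] != 0)]
        return frozenset(sub["condition"])


def make_genome(
    n_genes: int,
    scaffold_length: int = 4_600_000,
    circular: bool = True,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (400, 2000),
    scaffold_name: str = "chr1",
) -> GenomeAnnotation:
    """Lay ``n_genes`` non-overlapping genes on a single scaffold.

    Gene lengths are uniform over ``gene_length_range`` (default roughly
    matches a bacterial gene-length distribution at ~86% coding density on
    the default 4.6 Mb chromosome); leftover space is distributed randomly
    as intergenic gaps. Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    total = int(lengths.sum())
    if total > scaffold_length:
        raise ValueError(
            f"{n_genes} genes of total span {total} bp do not fit in "
            f"a {scaffold_length} bp scaffold"
        )
    slack = scaffold_length - total
    # n_genes + 1 gaps (before, between, after); multinomial keeps the sum exact
    gaps = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    starts = np.empty(n_genes, dtype=np.int64)
    cursor = 0
    for i in range(n_genes):
        cursor += int(gaps[i])
        starts[i] = cursor + 1  # 1-based inclusive
        cursor += int(lengths[i])
    genes = pd.DataFrame(
        {
            "locus_tag": [f"g{i:05d}" for i in range(n_genes)],
            "scaffold": scaffold_name,
            "start": starts,
            "end": starts + lengths - 1,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )
    scaffolds = pd.DataFrame(
        {"name": [scaffold_name], "length": [scaffold_length], "circular": [circular]}
    )
    return GenomeAnnotation(scaffolds=scaffolds, genes=genes)


def make_genome_sequence(genome: GenomeAnnotation, seed: int = 0) -> dict[str, str]:
    """Random nucleotide sequence for each scaffold (for FASTA / TnSeq fixtures)."""
    rng = np.random.default_rng(seed)
    return {
        str(row["name"]): "".join(rng.choice(_BASES, size=int(row["length"])))
        for _, row in genome.scaffolds.iterrows()
    }


def _random_barcodes(n: int, length: int, rng: np.random.Generator, max_tries: int = 50) -> list[str]:
    if 4**length < n:
        raise RuntimeError(f"barcode space 4^{length} cannot hold {n} unique barcodes")
    seen: set[str] = set()
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("barcode generation exceeded collision retry limit")
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in _BASES[batch]:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def make_pool(
    genome: GenomeAnnotation,
    n_mutants: int = 55_000,
    layout: ReadLayout | None = None,
    intergenic_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a barcoded insertion pool over ``genome``.

    A fraction ``intergenic_fraction`` of insertions lands uniformly in
    intergenic space, the rest uniformly within genes (gene picked with
    probability proportional to its length). Barcodes are unique random
    sequences of ``layout.barcode_length``. Each insertion is annotated
    with its gene, the strand-aware within-gene fraction and the central
    (10%-90%) flag. Deterministic given ``seed``.
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    if not 0 <= intergenic_fraction < 1:
        raise ValueError("intergenic_fraction must be in [0, 1)")
    layout = layout or ReadLayout()
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(n_mutants, layout.barcode_length, rng)

    # genic and intergenic interval tables per scaffold
    rows: list[dict] = []
    scaffold_names = list(genome.scaffolds["name"])
    genic_iv = []  # (scaffold, start, end, row of gene)
    inter_iv = []  # (scaffold, start, end)
    for sc in scaffold_names:
        genes = genome.genes_on(sc)
        length = genome.scaffold_lengths[sc]
        cursor = 1
        for _, g in genes.iterrows():
            if g["start"] > cursor:
                inter_iv.append((sc, cursor, int(g["start"]) - 1))
            genic_iv.append((sc, int(g["start"]), int(g["end"]), g))
            cursor = int(g["end"]) + 1
        if cursor <= length:
            inter_iv.append((sc, cursor, length))

    genic_sizes = np.array([e - s + 1 for _, s, e, _ in genic_iv], dtype=float)
    inter_sizes = np.array([e - s + 1 for _, s, e in inter_iv], dtype=float)
    n_inter = int(round(intergenic_fraction * n_mutants)) if len(inter_iv) else 0
    n_genic = n_mutants - n_inter

    strands = rng.choice(["+", "-"], size=n_mutants)
    k = 0
    if n_genic:
        picks = rng.choice(len(genic_iv), size=n_genic, p=genic_sizes / genic_sizes.sum())
        offsets = rng.random(n_genic)
        for pick, off in zip(picks, offsets):
            sc, s, e, g = genic_iv[pick]
            pos = s + int(off * (e - s + 1))
            frac = _gene_fraction(pos, int(g["start"]), int(g["end"]), str(g["strand"]))
            rows.append(
                {
                    "barcode": barcodes[k],
                    "scaffold": sc,
                    "strand": strands[k],
                    "pos": pos,
                    "locus_tag": str(g["locus_tag"]),
                    "gene_fraction": frac,
                    "central": 0.1 <= frac <= 0.9,
                }
            )
            k += 1
    if n_inter:
        picks = rng.choice(len(inter_iv), size=n_inter, p=inter_sizes / inter_sizes.sum())
        offsets = rng.random(n_inter)
        for pick, off in zip(picks, offsets):
            sc, s, e = inter_iv[pick]
            pos = s + int(off * (e - s + 1))
            rows.append(
                {
                    "barcode": barcodes[k],
                    "scaffold": sc,
                    "strand": strands[k],
                    "pos": pos,
                    "locus_tag": "",
                    "gene_fraction": np.nan,
                    "central": False,
                }
            )
            k += 1
    pool = pd.DataFrame(rows).sort_values(["scaffold", "pos"], kind="stable").reset_index(drop=True)
    return validate_pool(pool)


def _gene_fraction(pos: int, start: int, end: int, strand: str) -> float:
    """Within-gene fraction measured from the translational start (strand-aware)."""
    span = end - start
    if span == 0:
        return 0.5
    if strand == "-":
        return (end - pos) / span
    return (pos - start) / span


def make_truth(
    genome: GenomeAnnotation,
    design: SimDesign,
    category_fractions: Mapping[str, float] | None = None,
    effect_size: float = -2.0,
    seed: int = 0,
    cumulative: bool = True,
    induced_in_community: bool = True,
) -> TruthTable:
    """Plant per-gene fitness effects in structured interaction categories.

    ``category_fractions`` maps non-neutral categories to the fraction of
    genes assigned to each (disjoint random subsets; remainder neutral).
    ``effect_size`` is the per-day log2 abundance effect (< 0 deleterious).
    With ``cumulative`` (default) the planted effect at the d-th timepoint
    is ``d * effect_size`` — a constant growth handicap compounds over
    successive harvests; otherwise it is ``effect_size`` at every
    timepoint. Deterministic given ``seed``.
    """
    fractions = dict(category_fractions or {})
    unknown = set(fractions) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("category fractions must be >= 0")
    if sum(fractions.values()) > 1:
        raise ValueError("category fractions sum to more than 1")

    rng = np.random.default_rng(seed)
    locus_tags = list(genome.genes["locus_tag"])
    order = rng.permutation(len(locus_tags))
    categories = pd.Series("neutral", index=pd.Index(locus_tags, name="locus_tag"), name="category")
    cursor = 0
    for cat in CATEGORIES:  # fixed order for determinism
        if cat == "neutral" or cat not in fractions:
            continue
        take = math.floor(fractions[cat] * len(locus_tags))
        chosen = [locus_tags[i] for i in order[cursor : cursor + take]]
        categories.loc[chosen] = cat
        cursor += take

    day_factor = {tp: (i + 1 if cumulative else 1) for i, tp in enumerate(design.timepoints)}
    on_sets = {
        cat: effect_conditions(cat, design.conditions, induced_in_community) for cat in CATEGORIES
    }
    records = []
    for lt, cat in categories.items():
        on = on_sets[cat]
        for cond in design.conditions:
            for tp in design.timepoints:
                records.append(
                    {
                        "locus_tag": lt,
                        "condition": cond,
                        "timepoint": tp,
                        "phi": effect_size * day_factor[tp] if cond in on else 0.0,
                    }
                )
    return TruthTable(phi=pd.DataFrame(records), categories=categories)


def simulate_counts(
    pool: pd.DataFrame,
    truth: TruthTable,
    design: SimDesign,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Draw multinomial BarSeq read counts for a full study design.

    T0 strain abundances are log-normal (``design.t0_sigma``). The harvest
    weight of strain ``s`` in gene ``g`` at (condition, timepoint) is::

        w = a0_s * 2**phi_g * 2**(b * cos(2*pi*pos/L))

    where the cosine term models chromosomal copy-number bias (harvest
    samples only; the inoculum is not dividing). Each sample is one
    multinomial draw of ``design.depth`` reads over strains, so column sums
    equal the depth exactly. Strains in genes missing from the truth table
    and intergenic strains are treated as neutral. Deterministic given
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = len(pool)
    a0 = rng.lognormal(mean=0.0, sigma=design.t0_sigma, size=n)

    if scaffold_lengths is None:
        scaffold_lengths = pool.groupby("scaffold")["pos"].max().to_dict()
    lengths = pool["scaffold"].map(scaffold_lengths).to_numpy(dtype=float)
    b = design.position_bias_amplitude
    bias = 2.0 ** (b * np.cos(2 * np.pi * pool["pos"].to_numpy(dtype=float) / lengths))

    columns: dict[str, np.ndarray] = {}
    rows = [{"sample": "T0", "condition": "", "timepoint": "", "replicate": 0, "role": "T0"}]
    columns["T0"] = rng.multinomial(design.depth, a0 / a0.sum())

    locus = pool["locus_tag"].fillna("")
    for cond in design.conditions:
        for tp in design.timepoints:
            phi = truth.phi_lookup(cond, tp)
            strain_phi = locus.map(phi).fillna(0.0).to_numpy()
            w = a0 * (2.0**strain_phi) * bias
            p = w / w.sum()
            for rep in range(1, design.replicates + 1):
                name = f"{cond}_{tp}_r{rep}"
                columns[name] = rng.multinomial(design.depth, p)
                rows.append(
                    {
                        "sample": name,
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": rep,
                        "role": "harvest",
                    }
                )
    counts = pd.DataFrame(columns, index=pd.Index(pool["barcode"], name="barcode"))
    return CountMatrix(counts=counts, samples=sample_sheet(rows))


def emit_barseq_fastq(
    counts: CountMatrix,
    pool: pd.DataFrame,
    layout: ReadLayout | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
) -> dict[str, Path]:
    """Write one FASTQ file per sample realizing the count matrix.

    Every read is ``pad5 + preseq + barcode + postseq + pad3`` with a
    random 5' pad whose length is uniform over the layout's allowed
    offsets, a fixed 4 nt 3' pad and constant quality ``I``. Reads are
    shuffled within each sample. Round-tripping through
    :func:`barseqfit.barcodes.extract_barcodes` reproduces ``counts``
    exactly.
    """
    layout = layout or ReadLayout()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = set(pool["barcode"])
    stray = set(counts.counts.index) - known
    if stray:
        raise ValueError(f"count matrix contains barcodes absent from the pool: {sorted(stray)[:3]}")
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    barcodes = counts.counts.index.to_numpy()
    for sample in counts.counts.columns:
        col = counts.counts[sample].to_numpy()
        reads = np.repeat(barcodes, col)
        rng.shuffle(reads)
        pad_lens = rng.integers(layout.min_offset, layout.max_offset + 1, size=len(reads))
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, (bc, pl) in enumerate(zip(reads, pad_lens)):
                pad5 = "".join(rng.choice(_BASES, size=int(pl)))
                pad3 = "".join(rng.choice(_BASES, size=4))
                seq = pad5 + layout.preseq + bc + layout.postseq + pad3
                fh.write(f"@{sample}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


def simulate_de_table(
    genes: Sequence[str],
    planted_up: Iterable[str] = (),
    planted_down: Iterable[str] = (),
    logfc_magnitude: float = 2.0,
    seed: int = 0,
    contrast: str = "pairwise_1_vs_alone",
    timepoint: str = "day1",
) -> pd.DataFrame:
    """Emulate a differential-expression result table (gene, log2FC, padj).

    Planted genes receive |log2FC| >= ``logfc_magnitude`` with the matching
    sign and padj < 0.001; null genes get log2FC ~ Normal(0, 0.2) and padj
    ~ Uniform(0.2, 1). Only the output columns of a DE tool are emulated —
    no count model is fitted.
    """
    up, down = set(planted_up), set(planted_down)
    if up & down:
        raise ValueError(f"planted sets overlap: {sorted(up & down)[:3]}")
    stray = (up | down) - set(genes)
    if stray:
        raise ValueError(f"planted genes not in gene list: {sorted(stray)[:3]}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if g in up or g in down:
            mag = logfc_magnitude + abs(rng.normal(0, 0.3))
            lfc = mag if g in up else -mag
            padj = rng.uniform(1e-6, 1e-4)
        else:
            lfc = rng.normal(0, 0.2)
            padj = rng.uniform(0.2, 1.0)
        rows.append(
            {
                "locus_tag": g,
                "contrast": contrast,
                "timepoint": timepoint,
                "log2FC": lfc,
                "padj": padj,
            }
        )
    return pd.DataFrame(rows)
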
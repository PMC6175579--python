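"""Shared in-memory containers for the pipeline.

Tables are plain :class:`pandas.DataFrame` objects with documented schemas;
the thin dataclass wrappers below exist where several tables have to travel
together and stay mutually consistent (counts + sample metadata, scaffolds +
genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a pool table (one row per barcoded insertion mutant).
POOL_COLUMNS = [
    "barcode",
    "scaffold",
    "strand",
    "pos",
    "locus_tag",
    "gene_fraction",
    "central",
]

#: Columns of a sample sheet.
SAMPLE_COLUMNS = ["sample", "condition", "timepoint", "replicate", "role"]


@dataclass
class GenomeAnnotation:
    """A minimal genome annotation: scaffolds plus non-overlapping genes.

    ``scaffolds`` has columns ``name`` (str), ``length`` (bp, int) and
    ``circular`` (bool). ``genes`` has columns ``locus_tag``, ``scaffold``,
    ``start``, ``end`` (1-based inclusive) and ``strand`` (``+``/``-``).
    Genes on a scaffold must be non-overlapping and lie within the scaffold.
    """

    scaffolds: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sc = self.scaffolds
        genes = self.genes
        if sc["name"].duplicated().any():
            raise ValueError("duplicate scaffold names")
        if not genes["locus_tag"].is_unique:
            raise ValueError("locus_tags are not unique")
        lengths = sc.set_index("name")["length"]
        unknown = set(genes["scaffold"]) - set(lengths.index)
        if unknown:
            raise ValueError(f"genes reference unknown scaffolds: {sorted(unknown)}")
        if (genes["start"] > genes["end"]).any():
            raise ValueError("gene with start > end")
        if (genes["start"] < 1).any():
            raise ValueError("gene start below 1 (coordinates are 1-based)")
        ends = genes["scaffold"].map(lengths)
        if (genes["end"] > ends).any():
            raise ValueError("gene extends beyond its scaffold")
        for _, sub in genes.groupby("scaffold"):
            ordered = sub.sort_values("start")
            if (ordered["start"].values[1:] <= ordered["end"].values[:-1]).any():
                raise ValueError("overlapping genes on a scaffold")

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(zip(self.scaffolds["name"], self.scaffolds["length"].astype(int)))

    @property
    def circular_scaffolds(self) -> dict[str, bool]:
        return dict(zip(self.scaffolds["name"], self.scaffolds["circular"].astype(bool)))

    def genes_on(self, scaffold: str) -> pd.DataFrame:
        """Genes of one scaffold in coordinate order."""
        sub = self.genes[self.genes["scaffold"] == scaffold]
        return sub.sort_values("start").reset_index(drop=True)


@dataclass
class CountMatrix:
    """Barcode x sample read counts plus the sample sheet.

    ``counts`` is indexed by barcode with one integer column per sample;
    ``samples`` is indexed by sample id with columns ``condition``,
    ``timepoint``, ``replicate`` and ``role`` (``T0`` or ``harvest``);
    ``unmatched`` tallies reads per sample that could not be assigned to a
    pool barcode.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmatched: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unmatched is None:
            self.unmatched = pd.Series(0, index=self.counts.columns, name="unmatched")
        self.validate()

    def validate(self) -> None:
        if not self.samples.index.is_unique:
            raise ValueError("duplicate sample ids in sample sheet")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"count columns without sample metadata: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        n_t0 = int((self.samples["role"] == "T0").sum())
        if n_t0 != 1:
            raise ValueError(f"expected exactly one T0 sample, found {n_t0}")

    @property
    def t0_sample(self) -> str:
        return self.samples.index[self.samples["role"] == "T0"][0]

    @property
    def harvest_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["role"] == "harvest"]

    def samples_for(self, condition: str, timepoint: str) -> list[str]:
        """Harvest sample ids of one condition/timepoint, replicate order."""
        sub = self.harvest_samples
        sub = sub[(sub["condition"] == condition) & (sub["timepoint"] == timepoint)]
        return list(sub.sort_values("replicate").index)


def validate_pool(pool: pd.DataFrame) -> pd.DataFrame:
    """Check pool-table invariants and return the table unchanged."""
    missing = set(POOL_COLUMNS) - set(pool.columns)
    if missing:
        raise ValueError(f"pool table missing columns: {sorted(missing)}")
    if not pool["barcode"].is_unique:
        raise ValueError("duplicate barcodes in pool table")
    genic = pool["locus_tag"].fillna("") != ""
    frac = pool.loc[genic, "gene_fraction"].astype(float)
    if frac.isna().any() or ((frac < 0) | (frac > 1)).any():
        raise ValueError("genic insertions need gene_fraction in [0, 1]")
    if pool.loc[~genic, "gene_fraction"].notna().any():
        raise ValueError("intergenic insertions must have empty gene_fraction")
    expected_central = genic & (pool["gene_fraction"] >= 0.1) & (pool["gene_fraction"] <= 0.9)
    if not (pool["central"].astype(bool) == expected_central).all():
        raise ValueError("central flag inconsistent with the 10%-90% rule")
    return pool


def sample_sheet(rows: list[dict]) -> pd.DataFrame:
    """Build a sample sheet indexed by sample id from row dicts."""
    sheet = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    return sheet.set_index("sample")


def as_int_counts(counts: pd.DataFrame) -> pd.DataFrame:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        counts = counts.round().astype(np.int64)
    return counts
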
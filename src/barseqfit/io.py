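"""Readers and writers for the pipeline's tabular and sequence formats.

Everything is plain text: TSV for tables, FASTA/GFF3 (1-based inclusive)
for genomes, 4-line FASTQ for reads. Sequence formats go through
Biopython.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, GenomeAnnotation, validate_pool


def write_pool(pool: pd.DataFrame, path: str | Path) -> None:
    validate_pool(pool).to_csv(path, sep="\t", index=False)


def read_pool(path: str | Path) -> pd.DataFrame:
    pool = pd.read_csv(
        path, sep="\t", dtype={"barcode": str, "scaffold": str, "locus_tag": str}
    )
    pool["locus_tag"] = pool["locus_tag"].fillna("")
    pool["central"] = pool["central"].astype(bool)
    return validate_pool(pool)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.reset_index().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str, "timepoint": str})
    return sheet.set_index("sample")


def write_counts(counts: CountMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write a CountMatrix as ``<prefix>.counts.tsv``, ``<prefix>.samples.tsv``
    and ``<prefix>.unmatched.tsv``."""
    prefix = Path(prefix)
    paths = {
        "counts": prefix.with_suffix(".counts.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
        "unmatched": prefix.with_suffix(".unmatched.tsv"),
    }
    counts.counts.to_csv(paths["counts"], sep="\t")
    write_sample_sheet(counts.samples, paths["samples"])
    counts.unmatched.rename_axis("sample").rename("unmatched").to_csv(
        paths["unmatched"], sep="\t"
    )
    return paths


def read_counts(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="barcode")
    samples = read_sample_sheet(prefix.with_suffix(".samples.tsv"))
    unmatched_path = prefix.with_suffix(".unmatched.tsv")
    unmatched = None
    if unmatched_path.exists():
        unmatched = pd.read_csv(unmatched_path, sep="\t", index_col="sample")["unmatched"]
    return CountMatrix(counts=counts.astype(np.int64), samples=samples, unmatched=unmatched)


def write_truth(truth, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    paths = {
        "phi": prefix.with_suffix(".truth_phi.tsv"),
        "categories": prefix.with_suffix(".truth_categories.tsv"),
    }
    truth.phi.to_csv(paths["phi"], sep="\t", index=False)
    truth.categories.rename_axis("locus_tag").to_csv(paths["categories"], sep="\t")
    return paths


def write_genome_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write the gene annotation as GFF3 (1-based inclusive coordinates)."""
    circ = genome.circular_scaffolds
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, sc in genome.scaffolds.iterrows():
            fh.write(f"##sequence-region {sc['name']} 1 {int(sc['length'])}\n")
        for _, g in genome.genes.iterrows():
            attrs = f"ID={g['locus_tag']};locus_tag={g['locus_tag']}"
            if circ.get(str(g["scaffold"]), False):
                attrs += ";circular_scaffold=true"
            fh.write(
                f"{g['scaffold']}\tbarseqfit\tgene\t{int(g['start'])}\t{int(g['end'])}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene features and sequence-region pragmas back into a
    GenomeAnnotation."""
    scaffolds: dict[str, dict] = {}
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, name, _, end = line.split()
                scaffolds[name] = {"name": name, "length": int(end), "circular": False}
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            scaffold, _, _, start, end, _, strand, _, attrs = fields
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            genes.append(
                {
                    "locus_tag": attr.get("locus_tag", attr.get("ID")),
                    "scaffold": scaffold,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            )
            if attr.get("circular_scaffold") == "true" and scaffold in scaffolds:
                scaffolds[scaffold]["circular"] = True
    genes_df = pd.DataFrame(genes)
    for name in set(genes_df["scaffold"]) - set(scaffolds):
        scaffolds[name] = {
            "name": name,
            "length": int(genes_df.loc[genes_df["scaffold"] == name, "end"].max()),
            "circular": False,
        }
    return GenomeAnnotation(
        scaffolds=pd.DataFrame(list(scaffolds.values())), genes=genes_df
    )


def write_fitness(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_fitness(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"locus_tag": str, "condition": str, "timepoint": str})


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"locus_tag": str, "contrast": str})
    required = {"locus_tag", "contrast", "log2FC", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return table


def read_category_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (locus_tag, category); multiple rows per gene allowed."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        out.setdefault(row.iloc[0], []).append(row.iloc[1])
    return out


def read_plate_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mutant": str, "timepoint": str, "plate": str})
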
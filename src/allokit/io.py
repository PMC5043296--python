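"""Readers and writers for the toolkit's file surface.

FASTA sequence sets, GFF3 annotations, splice-junction tables, raw-count
matrices with transcript lengths, sample sheets and JSON run configuration.
External conventions (GFF3 1-based inclusive) are converted to the internal
0-based half-open coordinates here and nowhere else.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

VALID_GROUPS = ("vegetative", "reproductive", "seed")
_NUCLEOTIDES = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# sequences


def read_sequence_set(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercased nucleotide string map.

    Duplicate record ids and non-ACGTN characters are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in _NUCLEOTIDES), None)
        if bad is not None:
            raise ValueError(
                f"non-nucleotide character {seq[bad]!r} at position {bad} "
                f"of record {record.id!r}"
            )
        sequences[record.id] = seq
    return sequences


def write_sequence_set(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Library -> (tissue, replicate, group) design of the expression assay."""

    frame: pd.DataFrame  # columns: library, tissue, replicate, group

    def __post_init__(self) -> None:
        required = ["library", "tissue", "replicate", "group"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        if self.frame["library"].duplicated().any():
            dup = self.frame.loc[self.frame["library"].duplicated(), "library"]
            raise ValueError(f"duplicate library ids: {sorted(set(dup))}")
        bad_groups = set(self.frame["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}")
        if (self.frame["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive")
        per_tissue = self.frame.groupby("tissue")["group"].nunique()
        split = per_tissue[per_tissue > 1]
        if not split.empty:
            raise ValueError(
                f"tissues mapped to multiple groups: {list(split.index)}"
            )

    @property
    def libraries(self) -> list[str]:
        return list(self.frame["library"])

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.frame["tissue"]))

    def libraries_for_tissue(self, tissue: str) -> list[str]:
        return list(self.frame.loc[self.frame["tissue"] == tissue, "library"])

    def tissues_for_group(self, group: str) -> list[str]:
        sub = self.frame.loc[self.frame["group"] == group, "tissue"]
        return list(dict.fromkeys(sub))

    def group_of(self, tissue: str) -> str:
        sub = self.frame.loc[self.frame["tissue"] == tissue, "group"]
        if sub.empty:
            raise KeyError(tissue)
        return sub.iloc[0]


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"library": str, "tissue": str})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    """gene / mRNA / exon features in internal coordinates.

    Validates the parent chain: every mRNA's gene exists, every exon lies
    inside its parent mRNA's interval.
    """

    genes: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    mrnas: list[tuple[str, str, GenomicInterval]] = field(default_factory=list)
    exons: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        gene_ids = {g for g, _ in self.genes}
        mrna_by_id = {}
        for mrna_id, parent, iv in self.mrnas:
            if parent not in gene_ids:
                raise ValueError(f"mRNA {mrna_id!r} has unknown parent {parent!r}")
            mrna_by_id[mrna_id] = iv
        for parent, iv in self.exons:
            if parent not in mrna_by_id:
                raise ValueError(f"exon {iv} has unknown parent mRNA {parent!r}")
            if not mrna_by_id[parent].contains(iv):
                raise ValueError(
                    f"exon {iv} not contained in its mRNA {parent!r} "
                    f"{mrna_by_id[parent]}"
                )

    def exons_of(self, mrna_id: str) -> list[GenomicInterval]:
        return sorted(iv for parent, iv in self.exons if parent == mrna_id)

    def mrnas_of(self, gene_id: str) -> list[str]:
        return [m for m, parent, _ in self.mrnas if parent == gene_id]


def _to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    if end_inclusive < start_1based:
        raise ValueError(f"feature end {end_inclusive} < start {start_1based}")
    return start_1based - 1, end_inclusive


def read_annotation(path: str | os.PathLike) -> AnnotationSet:
    """Read gene/mRNA/exon features from GFF3 into an AnnotationSet."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes, mrnas, exons = [], [], []
    for feat in db.all_features():
        start, end = _to_internal(feat.start, feat.end)
        strand = feat.strand if feat.strand in ("+", "-") else "?"
        iv = GenomicInterval(feat.seqid, start, end, strand)
        if feat.featuretype == "gene":
            genes.append((feat.id, iv))
        elif feat.featuretype == "mRNA":
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise ValueError(f"mRNA {feat.id!r} lacks a Parent attribute")
            mrnas.append((feat.id, parents[0], iv))
        elif feat.featuretype == "exon":
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise ValueError(f"exon at {iv} lacks a Parent attribute")
            exons.append((parents[0], iv))
    return AnnotationSet(genes=genes, mrnas=mrnas, exons=exons)


def write_annotation(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write an AnnotationSet back to GFF3 (1-based inclusive)."""

    def line(iv, ftype, attrs):
        strand = iv.strand if iv.strand != "?" else "."
        return "\t".join(
            [iv.chrom, "allokit", ftype, str(iv.start + 1), str(iv.end),
             ".", strand, ".", attrs]
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, iv in annotation.genes:
            fh.write(line(iv, "gene", f"ID={gene_id}") + "\n")
            for mrna_id, parent, miv in annotation.mrnas:
                if parent != gene_id:
                    continue
                fh.write(line(miv, "mRNA", f"ID={mrna_id};Parent={gene_id}") + "\n")
                for exon_parent, eiv in annotation.exons:
                    if exon_parent == mrna_id:
                        fh.write(line(eiv, "exon", f"Parent={mrna_id}") + "\n")


# ---------------------------------------------------------------------------
# splice junctions


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction: the intron as a 0-based half-open interval.

    ``start`` is the first intronic base, ``end`` one past the last, with
    per-library supporting read counts in sample-sheet order.
    """

    chrom: str
    start: int
    end: int
    strand: str
    counts: tuple[int, ...]

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def read_junction_table(
    path: str | os.PathLike, sheet: SampleSheet
) -> list[JunctionRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "start", "end", "strand"]
    missing = [c for c in meta if c not in frame.columns]
    if missing:
        raise ValueError(f"junction table missing columns {missing}")
    libs = sheet.libraries
    extra = [c for c in frame.columns if c not in meta and c not in libs]
    if extra:
        raise ValueError(f"count columns not in sample sheet: {extra}")
    absent = [lib for lib in libs if lib not in frame.columns]
    if absent:
        raise ValueError(f"sample-sheet libraries missing from table: {absent}")
    counts = frame[libs].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative junction count")
    records: dict[tuple[str, int, int], JunctionRecord] = {}
    for i, row in frame.iterrows():
        strand = row["strand"] if row["strand"] in ("+", "-") else "?"
        key = (row["chrom"], int(row["start"]), int(row["end"]))
        row_counts = tuple(int(c) for c in counts[i])
        if key in records:
            logger.warning("duplicate junction %s: counts summed", key)
            prev = records[key]
            row_counts = tuple(a + b for a, b in zip(prev.counts, row_counts))
            strand = prev.strand if prev.strand != "?" else strand
        records[key] = JunctionRecord(key[0], key[1], key[2], strand, row_counts)
    return list(records.values())


def write_junction_table(
    junctions: list[JunctionRecord], sheet: SampleSheet, path: str | os.PathLike
) -> None:
    rows = []
    for j in junctions:
        row = {"chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand}
        row.update(dict(zip(sheet.libraries, j.counts)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts / lengths / config


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a raw count matrix (transcripts x libraries).

    Upstream quantifiers emit fractional expected counts; values are rounded
    half-to-even to integers at ingestion.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    rounded = frame.to_numpy(dtype=float)
    if (rounded < 0).any():
        raise ValueError("negative count")
    return pd.DataFrame(
        np.rint(rounded).astype(np.int64), index=frame.index, columns=frame.columns
    )


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t")


def read_lengths(path: str | os.PathLike) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    lengths = frame.iloc[:, 0].astype(np.int64)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    return lengths


def write_lengths(lengths: pd.Series, path: str | os.PathLike) -> None:
    lengths.rename("length").to_csv(path, sep="\t")


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_bed(intervals: list[tuple[GenomicInterval, str, float]],
              path: str | os.PathLike) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            strand = iv.strand if iv.strand != "?" else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n"
            )
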
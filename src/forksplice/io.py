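"""Readers and writers for the standard formats the pipeline touches.

FASTA and GFF3 parsing go through Biopython and gffutils; bedGraph and the
sample manifest go through pandas.  BED12 block arithmetic is implemented
directly (spliced long-read alignments are consumed as BED12 blocks — the
upstream alignment step itself is out of scope).  GFF3 is 1-based closed on
disk and converted to 0-based half-open here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO

from .core import AnnotationError, DataError, Gene, GenomeModel, Interval


class FormatError(DataError):
    """Malformed file content."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TrackBin:
    """One bin of a binned genomic count track (bedGraph line)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"TrackBin {self.chrom}:{self.start}-{self.end}: empty bin")
        if self.value < 0:
            raise FormatError("TrackBin value must be non-negative")


@dataclass(frozen=True)
class AlignedRead:
    """One spliced long read as ordered aligned blocks plus sample metadata."""

    read_id: str
    chrom: str
    strand: str
    blocks: Tuple[Interval, ...]
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if len(self.blocks) < 1:
            raise FormatError(f"read {self.read_id}: needs at least one block")
        for s, e in self.blocks:
            if e <= s:
                raise FormatError(f"read {self.read_id}: empty block {s}-{e}")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"read {self.read_id}: blocks must be sorted with gaps >= 1"
                )

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def gaps(self) -> Tuple[Interval, ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]))

    @property
    def sample_key(self) -> Tuple[str, str, int]:
        return (self.sample_id, self.condition, self.replicate)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> Dict[str, str]:
    """Read FASTA into name -> sequence; names truncated at first whitespace."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str) -> List[Gene]:
    """Read gene models from GFF3 (gene/mRNA/exon[, CDS] with ID/Parent).

    One Gene per mRNA feature; exons are sorted into transcription order and
    converted to 0-based half-open coordinates.  When CDS features are
    present, ``cds_start_offset`` is the transcript coordinate of the first
    CDS base; otherwise 0.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise FormatError(f"exon at {exon.seqid}:{exon.start}-{exon.end} has no Parent")

    genes: List[Gene] = []
    for mrna in db.features_of_type("mRNA"):
        exon_feats = list(db.children(mrna, featuretype="exon"))
        if not exon_feats:
            raise FormatError(f"mRNA {mrna.id} has no exons")
        exons = sorted((f.start - 1, f.end) for f in exon_feats)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"mRNA {mrna.id}: overlapping exons")
        if mrna.strand == "-":
            exons = exons[::-1]
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        offset = 0
        if cds_feats:
            offset = _cds_offset(exons, mrna.strand, cds_feats)
        genes.append(
            Gene(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_start_offset=offset,
            )
        )
    return genes


def _cds_offset(exons: Sequence[Interval], strand: str, cds_feats) -> int:
    """Transcript coordinate of the 5'-most CDS base."""
    if strand == "+":
        pos = min(f.start - 1 for f in cds_feats)
    else:
        pos = max(f.end for f in cds_feats) - 1
    offset = 0
    for s, e in exons:  # transcription order
        if s <= pos < e:
            offset += (pos - s) if strand == "+" else (e - 1 - pos)
            return offset
        offset += e - s
    raise FormatError("CDS start does not fall inside an exon")


def write_gff3(genome: GenomeModel, path: str, source: str = "forksplice") -> None:
    """Write gene/mRNA/exon (+ CDS when cds_start_offset is used) features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes:
            lo, hi = gene.span
            gid = gene.gene_id
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID=gene:{gid}\n"
            )
            fh.write(
                f"{gene.chrom}\t{source}\tmRNA\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={gid};Parent=gene:{gid}\n"
            )
            for i, (s, e) in enumerate(sorted(gene.exons), start=1):
                fh.write(
                    f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.exon{i};Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# BED12


def read_bed12(
    path: str, sample_id: str = "", condition: str = "", replicate: int = 0
) -> List[AlignedRead]:
    """Read spliced alignments from BED12; blocks become absolute genomic
    0-based half-open intervals."""
    reads: List[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, chrom_start = fields[0], int(fields[1])
            name, strand = fields[3], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            reads.append(
                AlignedRead(
                    read_id=name,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    sample_id=sample_id,
                    condition=condition,
                    replicate=replicate,
                )
            )
    return reads


def write_bed12(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            start, end = read.span
            sizes = ",".join(str(e - s) for s, e in read.blocks)
            starts = ",".join(str(s - start) for s, _ in read.blocks)
            fh.write(
                f"{read.chrom}\t{start}\t{end}\t{read.read_id}\t0\t{read.strand}\t"
                f"{start}\t{end}\t0\t{len(read.blocks)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str) -> List[TrackBin]:
    """Read a 4-column bedGraph; unsorted input is accepted and sorted, but
    overlapping bins are an error."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            rows.append(line.split()[:4])
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    bins = [TrackBin(r.chrom, r.start, r.end, r.value) for r in df.itertuples()]
    for a, b in zip(bins, bins[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise FormatError(
                f"overlapping bedGraph bins at {a.chrom}:{a.start}-{a.end} / {b.start}"
            )
    return bins


def write_bedgraph(bins: Iterable[TrackBin], path: str) -> None:
    ordered = sorted(bins, key=lambda b: (b.chrom, b.start))
    with open(path, "w") as fh:
        for b in ordered:
            value = int(b.value) if float(b.value).is_integer() else b.value
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{value}\n")


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = ["path", "sample_id", "condition", "replicate"]


def read_manifest(path: str) -> pd.DataFrame:
    """Read a tab-delimited sample manifest (path, sample_id, condition,
    replicate).  Paths are resolved relative to the manifest's directory."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path}: missing columns {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    df["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"].astype(str)
    ]
    df["replicate"] = df["replicate"].astype(int)
    return df


def load_reads(manifest_path: str) -> List[AlignedRead]:
    """Load all BED12 files listed in a manifest, tagging reads with their
    sample metadata."""
    manifest = read_manifest(manifest_path)
    reads: List[AlignedRead] = []
    for row in manifest.itertuples():
        reads.extend(
            read_bed12(
                row.path,
                sample_id=row.sample_id,
                condition=row.condition,
                replicate=row.replicate,
            )
        )
    return reads
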
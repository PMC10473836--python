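"""Shared domain model: genomes, spliced genes, introns and isoform translation.

Coordinates are 0-based half-open throughout the package; GFF3's 1-based
closed convention is converted at the I/O boundary.  Exons are stored in
transcription order, so for a minus-strand gene the first exon carries the
highest genomic coordinates.  Intron indices are 1-based in transcription
order, matching the convention used for fission-yeast loci (rtf1 intron 2,
intron 6, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

Interval = Tuple[int, int]

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ForkspliceError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(ForkspliceError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(ForkspliceError):
    """Invalid or unusable input data (CLI exit code 3)."""


class AnnotationError(DataError):
    """Gene or genome structures violating their invariants."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate DNA to protein with the standard nuclear code, stopping at
    the first stop codon.  Trailing partial codons are ignored."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def _check_interval(iv: Interval, label: str) -> None:
    s, e = iv
    if not (isinstance(s, int) and isinstance(e, int)) or e <= s or s < 0:
        raise AnnotationError(f"{label}: invalid interval {iv!r}")


@dataclass(frozen=True)
class Gene:
    """A spliced gene model.

    ``exons`` are genomic intervals ordered 5'->3' in transcription
    direction.  ``cds_start_offset`` is the transcript coordinate of the
    first codon (0 = translation starts at the transcript 5' end).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if len(self.exons) < 1:
            raise AnnotationError(f"{self.gene_id}: gene needs at least one exon")
        if self.cds_start_offset < 0:
            raise AnnotationError(f"{self.gene_id}: negative cds_start_offset")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        for iv in self.exons:
            _check_interval(iv, self.gene_id)
        # consecutive exons must leave a gap of >= 1 (the intron)
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                if b[0] <= a[1]:
                    raise AnnotationError(
                        f"{self.gene_id}: exons overlap or abut in transcription order"
                    )
            else:
                if b[1] >= a[0]:
                    raise AnnotationError(
                        f"{self.gene_id}: exons overlap or abut in transcription order"
                    )

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class Intron:
    """One intron, indexed 1-based in transcription order.

    ``upstream_exon``/``downstream_exon`` are the flanking exons in
    transcription direction (downstream = the exon that follows the intron
    in the mature transcript, i.e. the "subsequent exonic sequence").
    """

    gene_id: str
    index: int
    chrom: str
    start: int
    end: int
    strand: str
    upstream_exon: Interval
    downstream_exon: Interval

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id} intron {self.index}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> Tuple[str, int]:
        return (self.gene_id, self.index)


@dataclass(frozen=True)
class IsoformSpec:
    """A transcript isoform: the gene plus the set of retained introns."""

    gene_id: str
    retained_introns: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained_introns", frozenset(self.retained_introns))


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene annotation; the coordinate backbone
    shared by all pipeline stages."""

    chromosomes: Dict[str, str]
    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise AnnotationError(f"chromosome {name}: invalid bases {sorted(bad)}")
        for gene in self.genes:
            if gene.chrom not in self.chromosomes:
                raise AnnotationError(f"{gene.gene_id}: unknown chromosome {gene.chrom}")
            lo, hi = gene.span
            if hi > len(self.chromosomes[gene.chrom]):
                raise AnnotationError(f"{gene.gene_id}: exceeds chromosome bounds")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate gene_ids in genome model")

    @property
    def gene_map(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise AnnotationError(f"gene {gene_id!r} not found in annotation")


def build_introns(gene: Gene) -> List[Intron]:
    """Derive introns (the inter-exon gaps) from a gene model.

    Returns one Intron per gap, indexed 1..n-1 in transcription order; a
    single-exon gene yields an empty list.  For minus-strand genes intron 1
    is the gap nearest the transcription start, i.e. the highest genomic
    coordinates.
    """
    introns: List[Intron] = []
    for i, (up, down) in enumerate(zip(gene.exons, gene.exons[1:]), start=1):
        if gene.strand == "+":
            start, end = up[1], down[0]
        else:
            start, end = down[1], up[0]
        introns.append(
            Intron(
                gene_id=gene.gene_id,
                index=i,
                chrom=gene.chrom,
                start=start,
                end=end,
                strand=gene.strand,
                upstream_exon=up,
                downstream_exon=down,
            )
        )
    return introns


def all_introns(genome: GenomeModel) -> List[Intron]:
    """All introns of all genes, in gene order."""
    out: List[Intron] = []
    for gene in genome.genes:
        out.extend(build_introns(gene))
    return out


def isoform_sequence(genome: GenomeModel, spec: IsoformSpec) -> str:
    """The mature transcript sequence for an isoform: exons in transcription
    order with any retained introns inserted at their genomic positions.
    Minus-strand output is reverse-complemented."""
    gene = genome.gene(spec.gene_id)
    introns = {it.index: it for it in build_introns(gene)}
    bad = set(spec.retained_introns) - set(introns)
    if bad:
        raise AnnotationError(
            f"{gene.gene_id}: retained intron indices {sorted(bad)} out of range"
        )
    pieces: List[Interval] = list(gene.exons)
    pieces += [(introns[i].start, introns[i].end) for i in spec.retained_introns]
    pieces.sort()
    chrom_seq = genome.chromosomes[gene.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in pieces)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


@dataclass(frozen=True)
class IsoformComparison:
    """Outcome of translating a spliced vs an intron-retained isoform.

    ``in_frame`` is true when the retained sequence length is a multiple of
    three and introduces no premature stop; ``inserted_residues`` is the
    protein-length difference (negative when the retained isoform is
    truncated by a new stop codon); ``insertion_position`` is the index
    (1-based residue count) of the last residue shared before divergence.
    """

    in_frame: bool
    inserted_residues: int
    insertion_position: int
    truncated: bool


def compare_isoform_proteins(
    genome: GenomeModel, spec_spliced: IsoformSpec, spec_retained: IsoformSpec
) -> IsoformComparison:
    """Predict the protein-level consequence of intron retention.

    Both isoforms are translated from the gene's ``cds_start_offset`` with
    the standard code, stopping at the first stop codon.  A retained intron
    whose length is a multiple of 3 and which is free of in-frame stops
    yields an in-frame internal insertion (e.g. a 45-bp intron inserts 15
    residues); any other case is reported out of frame and/or truncated.
    """
    if spec_spliced.gene_id != spec_retained.gene_id:
        raise AnnotationError("isoform specs refer to different genes")
    gene = genome.gene(spec_spliced.gene_id)
    off = gene.cds_start_offset
    seq_spliced = isoform_sequence(genome, spec_spliced)
    seq_retained = isoform_sequence(genome, spec_retained)
    prot_spliced = translate(seq_spliced[off:])
    prot_retained = translate(seq_retained[off:])

    retained_len = len(seq_retained) - len(seq_spliced)
    shared = 0
    for a, b in zip(prot_spliced, prot_retained):
        if a != b:
            break
        shared += 1
    inserted = len(prot_retained) - len(prot_spliced)
    if retained_len % 3 == 0:
        expected = len(prot_spliced) + retained_len // 3
        truncated = len(prot_retained) != expected
        in_frame = not truncated
    else:
        truncated = len(prot_retained) < len(prot_spliced)
        in_frame = False
    return IsoformComparison(
        in_frame=in_frame,
        inserted_residues=inserted,
        insertion_position=shared,
        truncated=truncated,
    )
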
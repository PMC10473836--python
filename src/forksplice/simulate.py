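"""Synthetic data generators for every pipeline stage.

These emulate, at desk scale, the statistical structure the analyses
assume: a toy genome with canonical GT..AG introns (optionally with a
GC-poor window around the branch point / 3' splice site of selected
genes); 3'-anchored polyA long-read cDNA alignments with per-intron
retention probabilities and exponential 5'-end degradation; four-track
Pu-seq counts under a mixture of canonical (epsilon/delta) and restarted
(delta/delta) forks around a polar barrier; and colony counts for the
replication-slippage plating assay.  All generators are deterministic
given their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ConfigError,
    Gene,
    GenomeModel,
    Interval,
    IsoformSpec,
    build_introns,
    reverse_complement,
)
from .io import AlignedRead
from .puseq import PuseqTrackSet
from .slippage import PlateExperiment, SlippageExperiment

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> List[str]:
    """Random DNA with the given expected GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(_BASES[rng.choice(4, size=n, p=p)])


def _subseed(seed: int, *parts) -> List[int]:
    """Derive a reproducible child seed sequence from a base seed plus
    arbitrary labels (strings hashed with adler32 for stability)."""
    out = [int(seed) % (2**31)]
    for part in parts:
        if isinstance(part, str):
            out.append(zlib.adler32(part.encode()) % (2**31))
        else:
            out.append(int(part) % (2**31))
    return out


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_genes: int = 20,
    exon_len_range: Interval = (80, 300),
    intron_len_range: Interval = (40, 120),
    n_exons_range: Interval = (2, 4),
    gc_dip_group: FrozenSet[str] = frozenset(),
    seed: int = 0,
    gc_background: float = 0.40,
    gc_dip: float = 0.25,
    dip_intron_window: int = 40,
    dip_exon_window: int = 100,
    intergenic: int = 300,
    chrom_name: str = "chrS",
) -> GenomeModel:
    """Random toy genome with spliced genes on alternating strands.

    Introns carry canonical GT..AG boundaries (in transcription direction).
    Genes named in ``gc_dip_group`` have their GC fraction lowered to
    ``gc_dip`` in a window spanning the last ``dip_intron_window`` bases of
    each intron and the first ``dip_exon_window`` bases of the downstream
    exon — the sequence signature associated with retention-prone introns.
    Gene ids are ``g001 .. gNNN``.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    for lo, hi, label in [
        (*exon_len_range, "exon_len_range"),
        (*intron_len_range, "intron_len_range"),
        (*n_exons_range, "n_exons_range"),
    ]:
        if lo < 1 or hi < lo:
            raise ConfigError(f"infeasible {label}: ({lo}, {hi})")
    if intron_len_range[0] < 4:
        raise ConfigError("introns need length >= 4 for GT..AG boundaries")
    if not (0 < gc_background < 1 and 0 < gc_dip < 1):
        raise ConfigError("GC fractions must lie in (0, 1)")

    rng = np.random.default_rng(_subseed(seed, "genome"))
    chrom_parts: List[str] = []
    genes: List[Gene] = []
    cursor = 0
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            intron_len_range[0], intron_len_range[1] + 1, size=max(0, n_exons - 1)
        )

        # build the gene in transcription direction as mutable piece lists
        exon_seqs = [_random_seq(rng, int(n), gc_background) for n in exon_lens]
        intron_seqs = [_random_seq(rng, int(n), gc_background) for n in intron_lens]
        if gene_id in gc_dip_group:
            for k, iseq in enumerate(intron_seqs):
                w = min(dip_intron_window, len(iseq))
                iseq[len(iseq) - w :] = _random_seq(rng, w, gc_dip)
                eseq = exon_seqs[k + 1]
                w = min(dip_exon_window, len(eseq))
                eseq[:w] = _random_seq(rng, w, gc_dip)
        for iseq in intron_seqs:
            iseq[0:2] = ["G", "T"]
            iseq[-2:] = ["A", "G"]

        pieces: List[List[str]] = []
        piece_is_exon: List[bool] = []
        for k, eseq in enumerate(exon_seqs):
            pieces.append(eseq)
            piece_is_exon.append(True)
            if k < len(intron_seqs):
                pieces.append(intron_seqs[k])
                piece_is_exon.append(False)
        tx_seq = "".join("".join(p) for p in pieces)
        gene_len = len(tx_seq)

        gap = _random_seq(rng, intergenic, gc_background)
        chrom_parts.append("".join(gap))
        g0 = cursor + intergenic

        # piece offsets in transcription direction
        offsets = np.concatenate([[0], np.cumsum([len(p) for p in pieces])])
        exon_coords: List[Interval] = []
        if strand == "+":
            chrom_parts.append(tx_seq)
            for k, is_exon in enumerate(piece_is_exon):
                if is_exon:
                    exon_coords.append((g0 + int(offsets[k]), g0 + int(offsets[k + 1])))
        else:
            chrom_parts.append(reverse_complement(tx_seq))
            for k, is_exon in enumerate(piece_is_exon):
                if is_exon:
                    exon_coords.append(
                        (g0 + gene_len - int(offsets[k + 1]), g0 + gene_len - int(offsets[k]))
                    )
        cursor = g0 + gene_len
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=chrom_name,
                strand=strand,
                exons=tuple(exon_coords),
                cds_start_offset=0,
            )
        )
    chrom_parts.append("".join(_random_seq(rng, intergenic, gc_background)))
    return GenomeModel(chromosomes={chrom_name: "".join(chrom_parts)}, genes=genes)


# ---------------------------------------------------------------------------
# long reads


@dataclass
class ReadSimConfig:
    """Parameters of the long-read cDNA simulator.

    ``retention_prob`` maps (gene_id, intron_index, condition) to the
    probability that a read from that condition retains that intron;
    unlisted introns fall back to ``default_retention``.
    ``p5_degradation_mean`` is the mean (exponential) truncation from the
    transcript 5' end, emulating degradation of polyA cDNA 5' ends.
    """

    depth_per_gene: float = 100.0
    retention_prob: Mapping[Tuple[str, int, str], float] = field(default_factory=dict)
    default_retention: float = 0.0
    p5_degradation_mean: float = 200.0
    min_read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_gene <= 0:
            raise ConfigError("depth_per_gene must be positive")
        if self.p5_degradation_mean < 0:
            raise ConfigError("p5_degradation_mean must be non-negative")
        probs = list(self.retention_prob.values()) + [self.default_retention]
        if any(not (0 <= p <= 1) for p in probs):
            raise ConfigError("retention probabilities must lie in [0, 1]")


def _transcript_pieces(
    gene: Gene, retained: FrozenSet[int]
) -> List[Tuple[int, int, int, int]]:
    """Pieces of the mature transcript in transcription order, each as
    (tx_start, tx_end, genomic_start, genomic_end)."""
    introns = {it.index: it for it in build_introns(gene)}
    segs: List[Interval] = []
    for k, exon in enumerate(gene.exons):
        segs.append(exon)
        if (k + 1) in introns and (k + 1) in retained:
            it = introns[k + 1]
            segs.append((it.start, it.end))
    # in transcription order a retained intron sits between its exons; for
    # minus-strand genes transcription order is descending genomic order
    if gene.strand == "-":
        segs_sorted = sorted(segs, key=lambda iv: -iv[0])
    else:
        segs_sorted = sorted(segs)
    out = []
    tx = 0
    for s, e in segs_sorted:
        out.append((tx, tx + (e - s), s, e))
        tx += e - s
    return out


def _blocks_for_window(
    gene: Gene, pieces: Sequence[Tuple[int, int, int, int]], tx_from: int, tx_to: int
) -> Tuple[Interval, ...]:
    """Genomic blocks covered by the transcript window [tx_from, tx_to)."""
    blocks: List[Interval] = []
    for t0, t1, g0, g1 in pieces:
        lo, hi = max(t0, tx_from), min(t1, tx_to)
        if lo >= hi:
            continue
        if gene.strand == "+":
            blocks.append((g0 + (lo - t0), g0 + (hi - t0)))
        else:
            blocks.append((g1 - (hi - t0), g1 - (lo - t0)))
    blocks.sort()
    merged: List[Interval] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return tuple(merged)


def simulate_long_reads(
    genome: GenomeModel,
    config: ReadSimConfig,
    condition: str,
    replicate: int = 1,
    sample_id: Optional[str] = None,
) -> List[AlignedRead]:
    """3'-anchored spliced long reads with per-intron retention.

    Per gene, Poisson(depth) reads are drawn; each read independently
    retains each intron with its configured probability, then loses an
    Exponential(p5_degradation_mean) stretch from the transcript 5' end
    (clipped so at least ``min_read_length`` bases remain) while staying
    anchored at the polyA 3' end.  Retained introns merge their flanking
    exonic blocks in the emitted genomic alignment.
    """
    if sample_id is None:
        sample_id = f"{condition}_r{replicate}"
    rng = np.random.default_rng(_subseed(config.seed, "reads", condition, replicate))
    reads: List[AlignedRead] = []
    for gene in genome.genes:
        introns = build_introns(gene)
        probs = np.array(
            [
                config.retention_prob.get(
                    (gene.gene_id, it.index, condition), config.default_retention
                )
                for it in introns
            ]
        )
        n_reads = rng.poisson(config.depth_per_gene)
        for ri in range(n_reads):
            retained = frozenset(
                it.index
                for it, keep in zip(introns, rng.random(len(introns)) < probs)
                if keep
            )
            pieces = _transcript_pieces(gene, retained)
            tx_len = pieces[-1][1]
            trunc = int(rng.exponential(config.p5_degradation_mean))
            trunc = min(trunc, max(0, tx_len - config.min_read_length))
            blocks = _blocks_for_window(gene, pieces, trunc, tx_len)
            reads.append(
                AlignedRead(
                    read_id=f"{gene.gene_id}.{condition}.r{replicate}.{ri}",
                    chrom=gene.chrom,
                    strand=gene.strand,
                    blocks=blocks,
                    sample_id=sample_id,
                    condition=condition,
                    replicate=replicate,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Pu-seq counts


@dataclass
class ForkSimConfig:
    """Generative model of polymerase usage around a polar fork barrier.

    A rightward canonical fork approaching the barrier arrests with
    probability ``arrest_prob`` and restarts as a delta/delta fork that
    runs for ``restart_tract_len`` bases downstream (~10 kb in the studied
    locus).  Each bin is replicated by a leftward canonical fork with
    probability ``leftward_fraction``.  Per bin: p_restart =
    arrest_prob * (1 - leftward_fraction) inside the tract, else 0;
    p_left = leftward_fraction; p_right = 1 - p_left - p_restart.
    Expected per-track fractions follow from which polymerase makes each
    strand: delta_top = p_left + p_restart, epsilon_top = p_right,
    delta_bottom = p_right + p_restart, epsilon_bottom = p_left.
    Counts are Poisson(depth * fraction + background).
    """

    region: Interval = (0, 30000)
    bin_size: int = 300
    barrier_pos: int = 9000
    arrest_prob: float = 0.0
    restart_tract_len: int = 10000
    leftward_fraction: float = 0.0
    depth: float = 200.0
    background: float = 0.0
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.region[0] <= self.barrier_pos < self.region[1]):
            raise ConfigError("barrier_pos must lie inside region")
        if not (0 <= self.arrest_prob <= 1 and 0 <= self.leftward_fraction <= 1):
            raise ConfigError("arrest_prob and leftward_fraction must lie in [0, 1]")
        if self.bin_size < 1 or self.depth <= 0 or self.background < 0:
            raise ConfigError("bin_size/depth/background out of range")

    @property
    def restart_window(self) -> Interval:
        return (self.barrier_pos, self.barrier_pos + self.restart_tract_len)


def expected_fractions(config: ForkSimConfig) -> Dict[Tuple[str, str], np.ndarray]:
    """Noise-free per-bin polymerase fractions under the fork mixture model."""
    starts = np.arange(config.region[0], config.region[1], config.bin_size)
    in_tract = (starts >= config.barrier_pos) & (
        starts < config.barrier_pos + config.restart_tract_len
    )
    p_rr = np.where(in_tract, config.arrest_prob * (1 - config.leftward_fraction), 0.0)
    p_l = np.full_like(p_rr, config.leftward_fraction)
    p_r = 1.0 - p_l - p_rr
    return {
        ("delta", "top"): p_l + p_rr,
        ("epsilon", "top"): p_r,
        ("delta", "bottom"): p_r + p_rr,
        ("epsilon", "bottom"): p_l,
    }


def simulate_puseq_counts(config: ForkSimConfig) -> PuseqTrackSet:
    """Four-track Pu-seq counts (delta/epsilon strain x top/bottom strand)
    over a shared bin grid.  Both simulated strains are sequenced at the
    same per-fork depth, so library_scale is 1.0 for each."""
    rng = np.random.default_rng(_subseed(config.seed, "puseq"))
    starts = np.arange(config.region[0], config.region[1], config.bin_size)
    ends = np.minimum(starts + config.bin_size, config.region[1])
    bins = np.stack([starts, ends], axis=1)
    fractions = expected_fractions(config)
    counts = {
        key: rng.poisson(config.depth * frac + config.background).astype(float)
        for key, frac in fractions.items()
    }
    return PuseqTrackSet(
        chrom=config.chrom,
        bins=bins,
        counts=counts,
        library_scale={"delta": 1.0, "epsilon": 1.0},
    )


# ---------------------------------------------------------------------------
# slippage plating


@dataclass
class SlippageSimConfig:
    """Plating-assay simulator: a culture with per-cell reversion
    probability ``true_slip_freq`` is plated (100 ul aliquots) in duplicate
    on selective and non-selective plates at separate dilutions."""

    true_slip_freq: float = 2.5e-4
    n_cells_plated: float = 2e6
    dilution_selective: float = 10.0
    dilution_nonselective: float = 1e4
    n_plates: int = 2
    n_experiments: int = 3
    strain_id: str = "sim"
    condition: str = "ON"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.true_slip_freq <= 1):
            raise ConfigError("true_slip_freq must lie in [0, 1]")
        if self.dilution_selective < 1 or self.dilution_nonselective < 1:
            raise ConfigError("dilution factors must be >= 1")
        if self.n_cells_plated <= 0 or self.n_plates < 1 or self.n_experiments < 1:
            raise ConfigError("plating sizes must be positive")


def simulate_slippage_counts(config: SlippageSimConfig) -> SlippageExperiment:
    """Colony counts: selective plates ~ Poisson(N/D_sel * freq) (the
    Poisson approximation to Binomial), non-selective ~ Poisson(N/D_non)."""
    rng = np.random.default_rng(_subseed(config.seed, "slippage"))
    experiments = []
    for _ in range(config.n_experiments):
        sel = rng.poisson(
            config.n_cells_plated / config.dilution_selective * config.true_slip_freq,
            size=config.n_plates,
        )
        non = rng.poisson(
            config.n_cells_plated / config.dilution_nonselective, size=config.n_plates
        )
        experiments.append(
            PlateExperiment(
                selective=tuple(int(c) for c in sel),
                dilution_selective=config.dilution_selective,
                nonselective=tuple(int(c) for c in non),
                dilution_nonselective=config.dilution_nonselective,
            )
        )
    return SlippageExperiment(
        strain_id=config.strain_id, condition=config.condition, experiments=experiments
    )


# ---------------------------------------------------------------------------
# deterministic frame-preserving toy gene


_CODON_CYCLE = ["GCT", "GAA", "TTC", "GGT", "CAT", "ATC", "AAA", "CTG"]  # no stops, no Val


def toy_insertion_genome() -> Tuple[GenomeModel, IsoformSpec, IsoformSpec]:
    """A deterministic toy gene whose second intron is 45 bp, stop-free in
    frame, and placed exactly at the codon 202/203 boundary.

    Retaining intron 2 therefore yields an in-frame 15-residue insertion
    between residues 202 and 203 — the situation of a short frame-preserving
    intron inside a coding exon junction.  Returns (genome, spliced
    isoform, intron-2-retained isoform).
    """
    coding = ["ATG"] + [_CODON_CYCLE[i % len(_CODON_CYCLE)] for i in range(251)] + ["TAA"]
    cds = "".join(coding)  # 253 codons incl. stop -> 252-residue protein
    exon1 = cds[: 100 * 3]
    exon2 = cds[100 * 3 : 202 * 3]
    exon3 = cds[202 * 3 :]
    intron1 = "GT" + "C" * 44 + "AG"  # 48 bp, never retained here
    # 45 bp = 15 in-frame codons, none a stop; starts GT, ends AG
    intron2_codons = ["GTA"] + ["CGT"] * 13 + ["AAG"]
    intron2 = "".join(intron2_codons)
    assert len(intron2) == 45 and intron2[:2] == "GT" and intron2[-2:] == "AG"

    chrom = exon1 + intron1 + exon2 + intron2 + exon3
    e1 = (0, len(exon1))
    e2 = (e1[1] + len(intron1), e1[1] + len(intron1) + len(exon2))
    e3 = (e2[1] + len(intron2), e2[1] + len(intron2) + len(exon3))
    gene = Gene(
        gene_id="toy_rtf1_like",
        chrom="toy",
        strand="+",
        exons=(e1, e2, e3),
        cds_start_offset=0,
    )
    genome = GenomeModel(chromosomes={"toy": chrom}, genes=[gene])
    spliced = IsoformSpec(gene_id=gene.gene_id)
    retained = IsoformSpec(gene_id=gene.gene_id, retained_introns=frozenset({2}))
    return genome, spliced, retained
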
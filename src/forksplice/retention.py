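"""Intron-retention calling and quantification from spliced long reads.

A read supports retention of an intron when its aligned blocks cover >70%
of the intron and of each flanking exon, including the exon downstream in
transcription direction (retention is only counted when the subsequent
exonic sequence is also present, so a read that simply runs out inside an
intron is not mistaken for retention).  A read supports splicing when one
of its block gaps coincides with the intron's junctions.  Everything else
is ambiguous or uncovered and excluded from the retention fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import DataError, Gene, Intron, Interval, build_introns
from .io import AlignedRead


class IntronStatus(str, Enum):
    RETAINED = "RETAINED"
    SPLICED = "SPLICED"
    AMBIGUOUS = "AMBIGUOUS"
    NOT_COVERED = "NOT_COVERED"


@dataclass(frozen=True)
class IntronReadCall:
    read_id: str
    intron_key: Tuple[str, int]
    status: IntronStatus


def _covered_fraction(blocks: Sequence[Interval], feature: Interval) -> float:
    s, e = feature
    covered = 0
    for bs, be in blocks:
        covered += max(0, min(be, e) - max(bs, s))
    return covered / (e - s)


def call_read_intron_status(
    read: AlignedRead,
    intron: Intron,
    overlap_threshold: float = 0.70,
    junction_slack: int = 5,
) -> IntronReadCall:
    """Classify one read against one intron.

    RETAINED: blocks cover more than ``overlap_threshold`` of the intron
    and of both flanking exons (including the downstream, transcription-
    direction exon).  SPLICED: a block gap matches both intron junctions
    within ``junction_slack`` bp and both flanking exons are covered.
    NOT_COVERED: the read does not touch the intron or its flanks (or is
    on another chromosome).  Otherwise AMBIGUOUS.
    """
    key = intron.key
    if read.chrom != intron.chrom:
        return IntronReadCall(read.read_id, key, IntronStatus.NOT_COVERED)
    region_lo = min(intron.start, intron.upstream_exon[0], intron.downstream_exon[0])
    region_hi = max(intron.end, intron.upstream_exon[1], intron.downstream_exon[1])
    span = read.span
    if span[1] <= region_lo or span[0] >= region_hi:
        return IntronReadCall(read.read_id, key, IntronStatus.NOT_COVERED)

    cov_intron = _covered_fraction(read.blocks, (intron.start, intron.end))
    cov_up = _covered_fraction(read.blocks, intron.upstream_exon)
    cov_down = _covered_fraction(read.blocks, intron.downstream_exon)
    exons_ok = cov_up > overlap_threshold and cov_down > overlap_threshold

    if cov_intron > overlap_threshold and exons_ok:
        return IntronReadCall(read.read_id, key, IntronStatus.RETAINED)
    for g0, g1 in read.gaps:
        if abs(g0 - intron.start) <= junction_slack and abs(g1 - intron.end) <= junction_slack:
            if exons_ok:
                return IntronReadCall(read.read_id, key, IntronStatus.SPLICED)
    return IntronReadCall(read.read_id, key, IntronStatus.AMBIGUOUS)


RETENTION_COLUMNS = [
    "gene_id",
    "intron_index",
    "chrom",
    "start",
    "end",
    "sample_id",
    "condition",
    "replicate",
    "n_retained",
    "n_spliced",
    "ir_fraction",
]


def quantify_retention(
    reads: Sequence[AlignedRead],
    introns: Sequence[Intron],
    min_reads: int = 10,
    overlap_threshold: float = 0.70,
    junction_slack: int = 5,
) -> pd.DataFrame:
    """Per-intron, per-sample retained/spliced counts and IR fractions.

    Ambiguous and uncovered calls enter neither numerator nor denominator;
    ``ir_fraction`` is reported missing (NaN) when fewer than ``min_reads``
    informative reads support an intron in a sample.
    """
    trees: Dict[str, IntervalTree] = {}
    intron_by_idx: List[Intron] = list(introns)
    for i, it in enumerate(intron_by_idx):
        lo = min(it.start, it.upstream_exon[0], it.downstream_exon[0])
        hi = max(it.end, it.upstream_exon[1], it.downstream_exon[1])
        trees.setdefault(it.chrom, IntervalTree()).addi(lo, hi, i)

    samples = sorted({r.sample_key for r in reads})
    counts: Dict[Tuple[int, Tuple[str, str, int]], List[int]] = {
        (i, s): [0, 0] for i in range(len(intron_by_idx)) for s in samples
    }
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        lo, hi = read.span
        for hit in tree.overlap(lo, hi):
            it = intron_by_idx[hit.data]
            call = call_read_intron_status(
                read, it, overlap_threshold=overlap_threshold, junction_slack=junction_slack
            )
            if call.status == IntronStatus.RETAINED:
                counts[(hit.data, read.sample_key)][0] += 1
            elif call.status == IntronStatus.SPLICED:
                counts[(hit.data, read.sample_key)][1] += 1

    rows = []
    for (i, sample), (n_ret, n_spl) in sorted(counts.items()):
        it = intron_by_idx[i]
        denom = n_ret + n_spl
        rows.append(
            {
                "gene_id": it.gene_id,
                "intron_index": it.index,
                "chrom": it.chrom,
                "start": it.start,
                "end": it.end,
                "sample_id": sample[0],
                "condition": sample[1],
                "replicate": sample[2],
                "n_retained": n_ret,
                "n_spliced": n_spl,
                "ir_fraction": (n_ret / denom) if denom >= min_reads else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RETENTION_COLUMNS)


@dataclass
class DifferentialIR:
    """Per-intron differential retention: mutant replicate IR minus pooled
    wild-type IR, in fraction units."""

    gene_id: str
    intron_index: int
    deltas: Dict[int, float]  # mutant replicate -> delta (NaN if missing)
    mean_delta: float
    n_consistent: int = 0
    flagged: bool = False

    @property
    def key(self) -> Tuple[str, int]:
        return (self.gene_id, self.intron_index)


def differential_retention(
    table: pd.DataFrame,
    wt_condition: str,
    mut_condition: str,
    min_delta: float = 0.20,
    min_reps: int = 2,
) -> Tuple[List[DifferentialIR], Dict[str, float]]:
    """Differential retention per intron plus a Gaussian fit of the
    distribution of nonzero mean differences.

    The wild-type baseline pools retained/spliced counts across WT
    replicates; each mutant replicate's IR fraction is compared to it.
    The fitted ``{"mu", "sigma", "n"}`` uses moment estimators over introns
    whose mean delta is defined and nonzero (introns showing no difference
    are excluded from the fitted distribution).
    """
    wt = table[table["condition"] == wt_condition]
    mut = table[table["condition"] == mut_condition]
    if wt.empty or mut.empty:
        raise DataError("need rows for both conditions")

    pooled = wt.groupby(["gene_id", "intron_index"])[["n_retained", "n_spliced"]].sum()
    wt_ir: Dict[Tuple[str, int], float] = {}
    for key, row in pooled.iterrows():
        denom = row["n_retained"] + row["n_spliced"]
        wt_ir[key] = row["n_retained"] / denom if denom > 0 else np.nan

    diffs: List[DifferentialIR] = []
    replicates = sorted(mut["replicate"].unique())
    for key, grp in mut.groupby(["gene_id", "intron_index"]):
        base = wt_ir.get(key, np.nan)
        deltas = {int(r): np.nan for r in replicates}
        for row in grp.itertuples():
            deltas[int(row.replicate)] = row.ir_fraction - base
        defined = [d for d in deltas.values() if not np.isnan(d)]
        mean_delta = float(np.mean(defined)) if defined else np.nan
        n_consistent = sum(1 for d in defined if d >= min_delta)
        diffs.append(
            DifferentialIR(
                gene_id=key[0],
                intron_index=int(key[1]),
                deltas=deltas,
                mean_delta=mean_delta,
                n_consistent=n_consistent,
                flagged=n_consistent >= min_reps,
            )
        )

    nonzero = np.array(
        [d.mean_delta for d in diffs if not np.isnan(d.mean_delta) and d.mean_delta != 0.0]
    )
    if len(nonzero):
        fit = {
            "mu": float(nonzero.mean()),
            "sigma": float(nonzero.std(ddof=0)),
            "n": int(len(nonzero)),
        }
    else:
        fit = {"mu": np.nan, "sigma": np.nan, "n": 0}
    return diffs, fit


def consistent_retention_genes(
    diffs: Iterable[DifferentialIR], min_delta: float = 0.20, min_reps: int = 2
) -> List[str]:
    """Genes with at least one intron whose retention increased by at least
    ``min_delta`` (fraction units; 0.20 = 20 percentage points) in at least
    ``min_reps`` mutant replicates."""
    genes = set()
    for d in diffs:
        n = sum(1 for v in d.deltas.values() if not np.isnan(v) and v >= min_delta)
        if n >= min_reps:
            genes.add(d.gene_id)
    return sorted(genes)


# ---------------------------------------------------------------------------
# minimal transcript classification (reference-match subset)

CLASS_CODES = ("=", "m", "n", "u", "other")


@dataclass(frozen=True)
class TranscriptClass:
    read_id: str
    code: str


def classify_transcript(
    read: AlignedRead, gene: Optional[Gene], junction_slack: int = 5
) -> TranscriptClass:
    """Minimal reference-comparison class codes for one read.

    '='  every gap matches a reference intron and the matched introns form
         a suffix of the intron chain in transcription order (tolerating
         5'-truncated reads), with no intron retained;
    'm'  at least one reference intron fully retained, all gaps matching
         reference introns;
    'n'  retention combined with a gap that matches no reference intron;
    'u'  no gene overlap;
    'other'  anything else.
    """
    if gene is None:
        return TranscriptClass(read.read_id, "u")
    lo, hi = gene.span
    span = read.span
    if read.chrom != gene.chrom or span[1] <= lo or span[0] >= hi:
        return TranscriptClass(read.read_id, "u")

    introns = build_introns(gene)
    matched: List[int] = []
    any_unmatched = False
    for g0, g1 in read.gaps:
        hit = None
        for it in introns:
            if abs(g0 - it.start) <= junction_slack and abs(g1 - it.end) <= junction_slack:
                hit = it.index
                break
        if hit is None:
            any_unmatched = True
        else:
            matched.append(hit)

    retained = [
        it.index
        for it in introns
        if it.index not in matched
        and _covered_fraction(read.blocks, (it.start, it.end)) == 1.0
    ]

    if retained:
        return TranscriptClass(read.read_id, "n" if any_unmatched else "m")
    if any_unmatched:
        return TranscriptClass(read.read_id, "other")
    # suffix rule: a 3'-anchored truncated read sees the last k introns in
    # transcription order
    n = len(introns)
    k = len(matched)
    if sorted(matched) == list(range(n - k + 1, n + 1)):
        return TranscriptClass(read.read_id, "=")
    return TranscriptClass(read.read_id, "other")


def assign_reads_to_genes(
    reads: Sequence[AlignedRead], genes: Sequence[Gene]
) -> List[Optional[Gene]]:
    """Most-overlap gene assignment (ties broken by gene_id)."""
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = g.span
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
    out: List[Optional[Gene]] = []
    for read in reads:
        tree = trees.get(read.chrom)
        best: Optional[Gene] = None
        best_ov = 0
        if tree is not None:
            lo, hi = read.span
            for hit in tree.overlap(lo, hi):
                g: Gene = hit.data
                ov = sum(
                    max(0, min(be, g.span[1]) - max(bs, g.span[0]))
                    for bs, be in read.blocks
                )
                if ov > best_ov or (ov == best_ov and best and g.gene_id < best.gene_id):
                    best, best_ov = g, ov
        out.append(best if best_ov > 0 else None)
    return out


def classify_reads(
    reads: Sequence[AlignedRead], genes: Sequence[Gene], junction_slack: int = 5
) -> pd.DataFrame:
    """Classify every read against its best-overlap gene."""
    assigned = assign_reads_to_genes(reads, genes)
    rows = []
    for read, gene in zip(reads, assigned):
        cls = classify_transcript(read, gene, junction_slack=junction_slack)
        rows.append(
            {
                "read_id": read.read_id,
                "sample_id": read.sample_id,
                "condition": read.condition,
                "replicate": read.replicate,
                "gene_id": gene.gene_id if gene else "",
                "code": cls.code,
            }
        )
    return pd.DataFrame(
        rows, columns=["read_id", "sample_id", "condition", "replicate", "gene_id", "code"]
    )


def class_proportions(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fraction of reads in each class code (rows sum to 1)."""
    if classes.empty:
        raise DataError("no classified reads")
    table = (
        classes.groupby(["sample_id", "condition", "replicate"])["code"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for code in CLASS_CODES:
        if code not in table.columns:
            table[code] = 0.0
    return table[list(CLASS_CODES)].reset_index()
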
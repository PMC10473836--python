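"""Sequence-level features of retained introns.

GC-richness profiles around the 3' splice site (covering the branch-point
region on the intronic side and the first ~100 bp of the downstream exon),
a bootstrap null band from a random sample of intron:exon sequences, the
intron-length vs retention-change correlation, and per-gene expression
(counts-per-million) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, Gene, GenomeModel, Intron
from .io import AlignedRead
from .retention import DifferentialIR, assign_reads_to_genes


@dataclass
class GCProfile:
    """Mean GC fraction by position relative to the 3' splice site.

    Offsets are negative inside the intron (-intron_window..-1, the branch
    point typically lies in -40..-10) and non-negative in the downstream
    exon (0..exon_window-1).  ``ci_low``/``ci_high`` hold the bootstrap
    95% band when computed.
    """

    positions: np.ndarray
    gc: np.ndarray
    n_sequences: int
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None


def intron_context_gc(
    genome: GenomeModel,
    intron: Intron,
    intron_window: int = 120,
    exon_window: int = 100,
) -> np.ndarray:
    """Per-position GC indicator (1/0, NaN where the feature is shorter
    than the window) across the 3'SS, oriented in transcription direction."""
    chrom = genome.chromosomes[intron.chrom]
    iw, ew = intron_window, exon_window
    out = np.full(iw + ew, np.nan)
    if intron.strand == "+":
        n = min(iw, intron.length)
        iseq = chrom[intron.end - n : intron.end]
        out[iw - n : iw] = _gc_indicator(iseq)
        d0, d1 = intron.downstream_exon
        n = min(ew, d1 - d0)
        out[iw : iw + n] = _gc_indicator(chrom[d0 : d0 + n])
    else:
        n = min(iw, intron.length)
        iseq = chrom[intron.start : intron.start + n][::-1]
        out[iw - n : iw] = _gc_indicator(iseq)
        d0, d1 = intron.downstream_exon
        n = min(ew, d1 - d0)
        out[iw : iw + n] = _gc_indicator(chrom[d1 - n : d1][::-1])
    return out


def _gc_indicator(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.where((arr == ord("G")) | (arr == ord("C")), 1.0, 0.0)
    return np.where((arr == ord("N")), np.nan, out)


def _smooth_rows(mat: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window mean along each row, truncated at edges;
    positions that are themselves missing stay missing."""
    if window <= 1:
        return mat
    df = pd.DataFrame(mat.T)
    sm = df.rolling(window, center=True, min_periods=1).mean().to_numpy().T
    return np.where(np.isnan(mat), np.nan, sm)


def profile_matrix(
    gc_rows: Sequence[np.ndarray], smooth: int = 11
) -> np.ndarray:
    """Stack per-sequence GC indicator rows and apply window smoothing."""
    mat = np.vstack(list(gc_rows))
    return _smooth_rows(mat, smooth)


def gc_profile(
    genome: GenomeModel,
    introns: Sequence[Intron],
    intron_window: int = 120,
    exon_window: int = 100,
    smooth: int = 11,
) -> GCProfile:
    """Group-mean GC profile across the 3'SS for a set of introns."""
    if len(introns) == 0:
        raise DataError("gc_profile: empty intron group")
    rows = [
        intron_context_gc(genome, it, intron_window, exon_window) for it in introns
    ]
    mat = profile_matrix(rows, smooth=smooth)
    positions = np.arange(-intron_window, exon_window)
    gc = _nan_colmean(mat)
    return GCProfile(positions=positions, gc=gc, n_sequences=len(introns))


def _nan_colmean(mat: np.ndarray) -> np.ndarray:
    """Column nanmean; all-NaN columns (positions padded out on every
    sequence) stay NaN silently."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=0)


def bootstrap_band(
    mat: np.ndarray, level: float = 0.95, n_boot: int = 1000, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap band for the column-mean of a profile matrix.

    Returns (mean, low, high).  Rows are resampled with replacement; for
    complete (NaN-free) matrices a multinomial-weight matrix product keeps
    this fast at large n_boot.
    """
    n = mat.shape[0]
    rng = np.random.default_rng(seed)
    alpha = (1 - level) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if not np.isnan(mat).any():
            weights = rng.multinomial(n, np.full(n, 1 / n), size=n_boot) / n
            boot_means = weights @ mat
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            boot_means = np.nanmean(mat[idx], axis=1)
        mean = np.nanmean(mat, axis=0)
        low = np.nanpercentile(boot_means, 100 * alpha, axis=0)
        high = np.nanpercentile(boot_means, 100 * (1 - alpha), axis=0)
    return mean, low, high


def null_band(
    genome: GenomeModel,
    all_introns: Sequence[Intron],
    n_sample: int = 100,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    intron_window: int = 120,
    exon_window: int = 100,
    smooth: int = 11,
) -> GCProfile:
    """Null GC band: a random sample of ``n_sample`` intron:exon sequences,
    bootstrap-resampled ``n_boot`` times to a per-position percentile band."""
    if len(all_introns) < n_sample:
        raise DataError(
            f"only {len(all_introns)} introns available; reduce n_sample "
            f"(requested {n_sample})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_introns), size=n_sample, replace=False)
    rows = [
        intron_context_gc(genome, all_introns[i], intron_window, exon_window)
        for i in chosen
    ]
    mat = profile_matrix(rows, smooth=smooth)
    mean, low, high = bootstrap_band(
        mat, level=level, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    return GCProfile(
        positions=np.arange(-intron_window, exon_window),
        gc=mean,
        n_sequences=n_sample,
        ci_low=low,
        ci_high=high,
    )


def length_vs_delta(
    diffs: Sequence[DifferentialIR], introns: Sequence[Intron]
) -> Dict[str, float]:
    """Spearman rank correlation of intron length against mean retention
    change (a negative control: length should not drive retention)."""
    lengths = {it.key: it.length for it in introns}
    xs, ys = [], []
    for d in diffs:
        if d.key in lengths and not np.isnan(d.mean_delta):
            xs.append(lengths[d.key])
            ys.append(d.mean_delta)
    if len(xs) < 3:
        raise DataError("need at least 3 introns for a rank correlation")
    rho, p = stats.spearmanr(xs, ys)
    return {"spearman_rho": float(rho), "p": float(p), "n": len(xs)}


EXPRESSION_COLUMNS = ["gene_id", "cpm_wt", "cpm_mut", "log2fc"]


def expression_table(
    reads: Sequence[AlignedRead],
    genes: Sequence[Gene],
    wt_condition: str,
    mut_condition: str,
) -> pd.DataFrame:
    """Per-gene counts-per-million, averaged within condition, with log2
    fold changes (NaN where either condition has zero reads)."""
    assigned = assign_reads_to_genes(reads, genes)
    rows = [
        {"gene_id": g.gene_id, "sample": r.sample_key, "condition": r.condition}
        for r, g in zip(reads, assigned)
        if g is not None
    ]
    if not rows:
        raise DataError("no reads assigned to genes")
    df = pd.DataFrame(rows)
    counts = df.groupby(["sample", "condition"])["gene_id"].value_counts().rename("n")
    counts = counts.reset_index()
    counts["cpm"] = counts.groupby("sample")["n"].transform(lambda x: x / x.sum() * 1e6)
    by_cond = (
        counts.groupby(["gene_id", "condition"])["cpm"].mean().unstack(fill_value=0.0)
    )
    for cond in (wt_condition, mut_condition):
        if cond not in by_cond.columns:
            raise DataError(f"no reads for condition {cond!r}")
    out = pd.DataFrame(
        {
            "gene_id": by_cond.index,
            "cpm_wt": by_cond[wt_condition].to_numpy(),
            "cpm_mut": by_cond[mut_condition].to_numpy(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2fc"] = np.log2(out["cpm_mut"] / out["cpm_wt"])
    out.loc[(out["cpm_wt"] == 0) | (out["cpm_mut"] == 0), "log2fc"] = np.nan
    return out.reset_index(drop=True)
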
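"""Polymerase-usage analysis of binned rNMP count tracks.

Pu-seq sequences rNMPs laid down by ribonucleotide-permissive Pol-delta and
Pol-epsilon mutant strains, giving four binned count tracks (2 strains x 2
strands).  From these we compute per-strand Pol-delta usage, the combined
polymerase-bias track (50 = canonical epsilon/delta fork, 100 = delta/delta
restarted fork), the barrier switch point, and the fraction of forks that
arrested and restarted via recombination-dependent replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import DataError, Interval
from .io import TrackBin

STRAINS = ("delta", "epsilon")
STRANDS = ("top", "bottom")
TrackKey = Tuple[str, str]  # (strain, strand)


@dataclass
class PuseqTrackSet:
    """Four binned count vectors over a shared bin grid.

    ``library_scale`` carries known per-strain normalization factors (e.g.
    from genome-wide library totals computed upstream, or exactly 1.0 for
    simulated strains sequenced at identical per-fork depth).  When absent,
    :func:`compute_usage` falls back to equalizing strain totals over the
    analysed region.
    """

    chrom: str
    bins: np.ndarray  # (n, 2) start/end
    counts: Dict[TrackKey, np.ndarray]
    library_scale: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        n = len(self.bins)
        for strain in STRAINS:
            for strand in STRANDS:
                key = (strain, strand)
                if key not in self.counts:
                    raise DataError(f"missing Pu-seq track {key}")
                vec = np.asarray(self.counts[key], dtype=float)
                if len(vec) != n:
                    raise DataError(f"track {key}: length {len(vec)} != {n} bins")
                if (vec < 0).any():
                    raise DataError(f"track {key}: negative counts")
                self.counts[key] = vec

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_trackbins(self, key: TrackKey) -> List[TrackBin]:
        return [
            TrackBin(self.chrom, int(s), int(e), float(v))
            for (s, e), v in zip(self.bins, self.counts[key])
        ]


@dataclass
class UsageTrack:
    """Per-strand Pol-delta usage fractions (Pol-epsilon usage = 1 - delta).
    NaN marks bins below the depth cutoff."""

    chrom: str
    bins: np.ndarray
    usage_delta_top: np.ndarray
    usage_delta_bottom: np.ndarray
    library_scale: Dict[str, float] = field(default_factory=dict)


@dataclass
class BiasTrack:
    """Strand-combined polymerase bias in percent: 100 * mean of the two
    per-strand Pol-delta usages.  Canonical replication gives 50,
    full delta/delta restart gives 100."""

    chrom: str
    bins: np.ndarray
    bias_pct: np.ndarray
    smoothing_window: int = 1


def compute_usage(
    tracks: PuseqTrackSet, min_depth: int = 20, pseudocount: float = 0.5
) -> UsageTrack:
    """Per-bin, per-strand Pol-delta usage from the four count tracks.

    Counts are first scaled per strain by ``tracks.library_scale`` when
    provided, otherwise by factors that equalize the two strains' totals
    (both strands) over the region.  Usage is a pseudocount-regularized
    ratio; bins whose raw delta+epsilon count on a strand is below
    ``min_depth`` are flagged missing (NaN).

    The pseudocount shrinks the ratio toward 0.5 by a factor T/(T + 2 pc)
    at depth T, which is visible at extreme bias; quantitative restart
    estimation should use ``pseudocount=0`` (the raw ratio is unbiased
    given the bin total, and ``min_depth`` already guards 0/0).
    """
    totals = {
        strain: float(
            tracks.counts[(strain, "top")].sum() + tracks.counts[(strain, "bottom")].sum()
        )
        for strain in STRAINS
    }
    if tracks.library_scale is not None:
        scale = dict(tracks.library_scale)
        for strain in STRAINS:
            if scale.get(strain, 0) <= 0:
                raise DataError(f"library_scale for strain {strain!r} must be positive")
    else:
        for strain, tot in totals.items():
            if tot == 0:
                raise DataError(f"strain {strain!r}: all-zero track, unusable library")
        target = float(np.mean(list(totals.values())))
        scale = {strain: target / totals[strain] for strain in STRAINS}

    usage = {}
    for strand in STRANDS:
        raw_d = tracks.counts[("delta", strand)]
        raw_e = tracks.counts[("epsilon", strand)]
        nd = raw_d * scale["delta"]
        ne = raw_e * scale["epsilon"]
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (nd + pseudocount) / (nd + ne + 2 * pseudocount)
        u = np.where(raw_d + raw_e < min_depth, np.nan, u)
        usage[strand] = u
    return UsageTrack(
        chrom=tracks.chrom,
        bins=tracks.bins,
        usage_delta_top=usage["top"],
        usage_delta_bottom=usage["bottom"],
        library_scale=scale,
    )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges; a bin that is itself
    missing stays missing, missing neighbours are skipped."""
    if window <= 1:
        return values.copy()
    smoothed = (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return np.where(np.isnan(values), np.nan, smoothed)


def compute_bias(usage: UsageTrack, smoothing_window: int = 3) -> BiasTrack:
    """Combined polymerase-bias track: the per-bin mean of top- and
    bottom-strand Pol-delta usage, x100, moving-average smoothed."""
    raw = 100.0 * (usage.usage_delta_top + usage.usage_delta_bottom) / 2.0
    return BiasTrack(
        chrom=usage.chrom,
        bins=usage.bins,
        bias_pct=_moving_average(raw, smoothing_window),
        smoothing_window=smoothing_window,
    )


def detect_switch_point(
    bias: BiasTrack, threshold_pct: float = 60.0, min_run_bins: int = 3
) -> Optional[int]:
    """Leftmost bin start at which the bias stays >= threshold for at least
    ``min_run_bins`` consecutive bins (the abrupt switch to Pol-delta usage
    at an active barrier); None when no such run exists."""
    above = bias.bias_pct >= threshold_pct  # NaN compares False
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run_bins:
            return int(bias.bins[i - min_run_bins + 1][0])
    return None


@dataclass(frozen=True)
class RestartEstimate:
    """Estimated fraction of forks that restarted as delta/delta, with a
    bin-resampling bootstrap standard error."""

    f: float
    f_se: float
    n_bins: int


def estimate_restart_fraction(
    bias: BiasTrack,
    window: Interval,
    n_boot: int = 1000,
    seed: int = 0,
) -> RestartEstimate:
    """Restart fraction over a window downstream of the barrier.

    A population in which a fraction f of forks restarted as delta/delta
    has expected bias 50 + 50 f, so f = (mean bias - 50) / 50, clipped to
    [0, 1].  The SE comes from bootstrap resampling of bins.

    Pass an unsmoothed bias track (smoothing_window=1): the window mean is
    already an average, and moving-average smoothing only bleeds flanking
    canonical bins into the tract edges.
    """
    starts = bias.bins[:, 0]
    mask = (starts >= window[0]) & (starts < window[1]) & ~np.isnan(bias.bias_pct)
    vals = bias.bias_pct[mask]
    if len(vals) == 0:
        raise DataError(f"no defined bias bins in window {window}")

    def _f(v: np.ndarray) -> float:
        return float(np.clip((np.mean(v) - 50.0) / 50.0, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boot = np.clip((vals[idx].mean(axis=1) - 50.0) / 50.0, 0.0, 1.0)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")
    return RestartEstimate(f=_f(vals), f_se=se, n_bins=int(len(vals)))


def relative_restart(f_mut: float, f_wt: float) -> float:
    """Restart fraction of a mutant relative to a reference strain."""
    if f_wt <= 0:
        raise DataError("reference restart fraction must be positive")
    return f_mut / f_wt
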
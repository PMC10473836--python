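"""Replication-slippage (reversion-frequency) assay statistics.

A ura4 allele carrying a 20-bp tandem duplication (ura4-sd20) placed
downstream of the barrier reverts to uracil prototrophy when the restarted
fork slips and deletes one repeat.  Each independent experiment plates one
culture at two dilutions: two selective (uracil-dropout) plates and two
non-selective plates.  The reversion frequency is the dilution-corrected
ratio of the two mean colony counts; conditions are compared with a
two-tailed equal-variance Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError


@dataclass(frozen=True)
class PlateExperiment:
    """One independent experiment: duplicate plate counts at each dilution.

    A dilution factor D means the plated aliquot contains 1/D of the
    culture's cells, so counts are multiplied by D to recover totals.
    """

    selective: Tuple[int, ...]
    dilution_selective: float
    nonselective: Tuple[int, ...]
    dilution_nonselective: float

    def __post_init__(self) -> None:
        for counts in (self.selective, self.nonselective):
            if len(counts) < 1 or any(c < 0 or int(c) != c for c in counts):
                raise DataError("plate counts must be non-negative integers")
        if self.dilution_selective < 1 or self.dilution_nonselective < 1:
            raise DataError("dilution factors must be >= 1")


@dataclass
class SlippageExperiment:
    """A set of independent plating experiments for one strain/condition."""

    strain_id: str
    condition: str
    experiments: List[PlateExperiment]


@dataclass(frozen=True)
class ReversionFrequency:
    """Per-experiment reversion frequencies with their mean and SD."""

    frequencies: Tuple[float, ...]
    mean: float
    sd: float


def reversion_frequency(exp: SlippageExperiment) -> ReversionFrequency:
    """Dilution-corrected Ura+ reversion frequency.

    Per experiment: frequency = (mean selective count x selective dilution)
    / (mean non-selective count x non-selective dilution).  Experiments are
    aggregated to mean +/- SD (sample SD across experiments).
    """
    freqs = []
    for i, plate in enumerate(exp.experiments):
        mean_non = float(np.mean(plate.nonselective))
        if mean_non == 0:
            raise DataError(
                f"{exp.strain_id}/{exp.condition} experiment {i}: zero viable count "
                "(failed plating)"
            )
        mean_sel = float(np.mean(plate.selective))
        freqs.append(
            (mean_sel * plate.dilution_selective)
            / (mean_non * plate.dilution_nonselective)
        )
    arr = np.asarray(freqs)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
    return ReversionFrequency(
        frequencies=tuple(freqs), mean=float(arr.mean()), sd=sd
    )


FreqInput = Union[ReversionFrequency, Sequence[float]]


def _as_array(group: FreqInput) -> np.ndarray:
    if isinstance(group, ReversionFrequency):
        return np.asarray(group.frequencies, dtype=float)
    return np.asarray(group, dtype=float)


def compare_frequencies(group_a: FreqInput, group_b: FreqInput) -> Dict[str, float]:
    """Two-sample equal-variance Student's t-test, two-tailed.

    Returns ``{"t", "df", "p_two_tailed", "degenerate"}``.  When the pooled
    variance is zero with unequal means the statistic diverges; this is
    flagged degenerate with p reported as 0.
    """
    a, b = _as_array(group_a), _as_array(group_b)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need at least 2 experiments per group for the t-test")
    df = len(a) + len(b) - 2
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(df), "p_two_tailed": 1.0, "degenerate": False}
        t = float("-inf") if a.mean() < b.mean() else float("inf")
        return {"t": t, "df": float(df), "p_two_tailed": 0.0, "degenerate": True}
    res = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p_two_tailed": float(res.pvalue),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# TSV round trip

SLIPPAGE_COLUMNS = [
    "strain_id",
    "condition",
    "experiment",
    "selective_1",
    "selective_2",
    "dilution_selective",
    "nonselective_1",
    "nonselective_2",
    "dilution_nonselective",
]


def write_slippage_tsv(experiments: Sequence[SlippageExperiment], path: str) -> None:
    rows = []
    for exp in experiments:
        for i, plate in enumerate(exp.experiments, start=1):
            rows.append(
                {
                    "strain_id": exp.strain_id,
                    "condition": exp.condition,
                    "experiment": i,
                    "selective_1": plate.selective[0],
                    "selective_2": plate.selective[1],
                    "dilution_selective": plate.dilution_selective,
                    "nonselective_1": plate.nonselective[0],
                    "nonselective_2": plate.nonselective[1],
                    "dilution_nonselective": plate.dilution_nonselective,
                }
            )
    pd.DataFrame(rows, columns=SLIPPAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_slippage_tsv(path: str) -> List[SlippageExperiment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SLIPPAGE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"slippage table {path}: missing columns {sorted(missing)}")
    out: List[SlippageExperiment] = []
    for (strain, condition), grp in df.groupby(["strain_id", "condition"], sort=False):
        plates = [
            PlateExperiment(
                selective=(int(r.selective_1), int(r.selective_2)),
                dilution_selective=float(r.dilution_selective),
                nonselective=(int(r.nonselective_1), int(r.nonselective_2)),
                dilution_nonselective=float(r.dilution_nonselective),
            )
            for r in grp.sort_values("experiment").itertuples()
        ]
        out.append(
            SlippageExperiment(strain_id=str(strain), condition=str(condition), experiments=plates)
        )
    return out
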
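"""Per-read intron status, retention quantification, differential calling
and minimal transcript classification."""

import numpy as np
import pandas as pd
import pytest

from forksplice import (
    AlignedRead,
    DifferentialIR,
    Gene,
    IntronStatus,
    call_read_intron_status,
    class_proportions,
    classify_reads,
    classify_transcript,
    consistent_retention_genes,
    differential_retention,
    quantify_retention,
)
from forksplice.core import build_introns


@pytest.fixture
def gene3():
    """+ strand gene: exons [0,100), [150,250), [300,400)."""
    return Gene(
        gene_id="g3", chrom="c1", strand="+", exons=((0, 100), (150, 250), (300, 400))
    )


@pytest.fixture
def intron1(gene3):
    return build_introns(gene3)[0]  # [100,150)


def read(blocks, chrom="c1", **kw):
    kw.setdefault("read_id", "r")
    kw.setdefault("strand", "+")
    return AlignedRead(chrom=chrom, blocks=tuple(blocks), **kw)


class TestCallStatus:
    def test_full_coverage_is_retained(self, intron1):
        r = read([(0, 250)])
        assert call_read_intron_status(r, intron1).status == IntronStatus.RETAINED

    def test_exact_gap_is_spliced(self, intron1):
        r = read([(0, 100), (150, 250)])
        assert call_read_intron_status(r, intron1).status == IntronStatus.SPLICED

    def test_gap_within_slack_is_spliced(self, intron1):
        r = read([(0, 103), (147, 250)])
        assert call_read_intron_status(r, intron1, junction_slack=5).status == (
            IntronStatus.SPLICED
        )

    def test_partial_intron_coverage_is_ambiguous(self, intron1):
        # read enters 60% of the intron then stops: not retained, not spliced
        r = read([(0, 130)])
        assert call_read_intron_status(r, intron1).status == IntronStatus.AMBIGUOUS

    def test_retention_requires_downstream_exon(self, intron1):
        # intron fully covered but only 10% of the subsequent exon present
        r = read([(0, 160)])
        assert call_read_intron_status(r, intron1).status == IntronStatus.AMBIGUOUS

    def test_distant_read_not_covered(self, intron1):
        r = read([(5000, 5100)])
        assert call_read_intron_status(r, intron1).status == IntronStatus.NOT_COVERED

    def test_other_chromosome_not_covered(self, intron1):
        r = read([(0, 250)], chrom="c9")
        assert call_read_intron_status(r, intron1).status == IntronStatus.NOT_COVERED


class TestQuantify:
    def _reads(self, gene3, n_ret, n_spl, **kw):
        out = []
        for i in range(n_ret):
            out.append(read([(0, 250)], read_id=f"ret{i}", **kw))
        for i in range(n_spl):
            out.append(read([(0, 100), (150, 250)], read_id=f"spl{i}", **kw))
        return out

    def test_fraction_and_min_reads(self, gene3, intron1):
        meta = dict(sample_id="s1", condition="WT", replicate=1)
        table = quantify_retention(
            self._reads(gene3, 0, 10, **meta), [intron1], min_reads=10
        )
        row = table.iloc[0]
        assert (row.n_retained, row.n_spliced, row.ir_fraction) == (0, 10, 0.0)

        table = quantify_retention(
            self._reads(gene3, 5, 5, **meta), [intron1], min_reads=10
        )
        assert table.iloc[0].ir_fraction == pytest.approx(0.5)

        table = quantify_retention(
            self._reads(gene3, 3, 3, **meta), [intron1], min_reads=10
        )
        assert np.isnan(table.iloc[0].ir_fraction)

    def test_shard_additivity_and_order_invariance(self, gene3, intron1):
        meta = dict(sample_id="s1", condition="WT", replicate=1)
        reads = self._reads(gene3, 7, 13, **meta)
        full = quantify_retention(reads, [intron1], min_reads=1)
        a = quantify_retention(reads[:10], [intron1], min_reads=1)
        b = quantify_retention(reads[10:], [intron1], min_reads=1)
        assert (
            full.iloc[0].n_retained == a.iloc[0].n_retained + b.iloc[0].n_retained
        )
        assert full.iloc[0].n_spliced == a.iloc[0].n_spliced + b.iloc[0].n_spliced
        shuffled = quantify_retention(reads[::-1], [intron1], min_reads=1)
        pd.testing.assert_frame_equal(full, shuffled)


def _table_row(gene_id, idx, condition, replicate, n_ret, n_spl):
    return {
        "gene_id": gene_id,
        "intron_index": idx,
        "chrom": "c1",
        "start": 0,
        "end": 1,
        "sample_id": f"{condition}_r{replicate}",
        "condition": condition,
        "replicate": replicate,
        "n_retained": n_ret,
        "n_spliced": n_spl,
        "ir_fraction": n_ret / (n_ret + n_spl) if n_ret + n_spl else np.nan,
    }


class TestDifferential:
    def test_identical_conditions_all_zero_and_excluded_from_fit(self):
        rows = []
        for cond in ("WT", "MUT"):
            for rep in (1, 2):
                rows.append(_table_row("gA", 1, cond, rep, 10, 90))
        diffs, fit = differential_retention(pd.DataFrame(rows), "WT", "MUT")
        assert all(v == 0.0 for d in diffs for v in d.deltas.values())
        assert fit["n"] == 0 and np.isnan(fit["mu"])

    def test_moment_fit_closed_form(self):
        # three introns with mean deltas -0.1, 0, +0.1; zero excluded
        rows = [
            _table_row("gA", 1, "WT", 1, 20, 80),
            _table_row("gA", 1, "MUT", 1, 10, 90),
            _table_row("gB", 1, "WT", 1, 20, 80),
            _table_row("gB", 1, "MUT", 1, 20, 80),
            _table_row("gC", 1, "WT", 1, 20, 80),
            _table_row("gC", 1, "MUT", 1, 30, 70),
        ]
        _, fit = differential_retention(pd.DataFrame(rows), "WT", "MUT")
        assert fit["n"] == 2
        assert fit["mu"] == pytest.approx(0.0, abs=1e-12)
        assert fit["sigma"] == pytest.approx(0.1, abs=1e-12)

    def test_planted_delta_recovered(self):
        rng = np.random.default_rng(12)
        rows = []
        n = 200
        for rep in (1, 2, 3):
            rows.append(_table_row("gA", 1, "WT", rep, int(rng.binomial(n, 0.1)), 0))
            rows[-1]["n_spliced"] = n - rows[-1]["n_retained"]
            rows[-1]["ir_fraction"] = rows[-1]["n_retained"] / n
            rows.append(_table_row("gA", 1, "MUT", rep, int(rng.binomial(n, 0.5)), 0))
            rows[-1]["n_spliced"] = n - rows[-1]["n_retained"]
            rows[-1]["ir_fraction"] = rows[-1]["n_retained"] / n
        diffs, _ = differential_retention(pd.DataFrame(rows), "WT", "MUT")
        assert diffs[0].mean_delta == pytest.approx(0.4, abs=5 * np.sqrt(0.25 / n))


class TestConsistencyFilter:
    def _diff(self, gene, deltas):
        return DifferentialIR(
            gene_id=gene,
            intron_index=1,
            deltas={i + 1: d for i, d in enumerate(deltas)},
            mean_delta=float(np.mean(deltas)),
        )

    def test_two_of_three_rule(self):
        included = self._diff("gA", [0.25, 0.22, 0.05])
        excluded = self._diff("gB", [0.25, 0.10, 0.10])
        genes = consistent_retention_genes([included, excluded])
        assert genes == ["gA"]

    def test_boundary_is_inclusive(self):
        exactly = self._diff("gC", [0.20, 0.20, 0.0])
        assert consistent_retention_genes([exactly]) == ["gC"]


class TestClassify:
    def test_perfect_splice_matches_reference(self, gene3):
        r = read([(0, 100), (150, 250), (300, 400)])
        assert classify_transcript(r, gene3).code == "="

    def test_truncated_read_suffix_still_matches(self, gene3):
        # 5'-degraded read covering only the last junction
        r = read([(200, 250), (300, 400)])
        assert classify_transcript(r, gene3).code == "="

    def test_retained_intron_is_m(self, gene3):
        r = read([(0, 100), (150, 400)])  # intron 2 retained
        assert classify_transcript(r, gene3).code == "m"

    def test_retention_plus_novel_gap_is_n(self, gene3):
        # novel gap (50,80) plus intron 2 fully retained
        r = read([(0, 50), (80, 100), (150, 400)])
        assert classify_transcript(r, gene3).code == "n"

    def test_intergenic_read_is_u(self, gene3):
        r = read([(5000, 5400)])
        assert classify_transcript(r, gene3).code == "u"
        assert classify_transcript(r, None).code == "u"

    def test_non_suffix_match_is_other(self, gene3):
        # only the FIRST junction spliced; a 3'-anchored read should show a
        # suffix of the intron chain, so matching intron 1 alone is 'other'
        r = read([(0, 100), (150, 250)])
        assert classify_transcript(r, gene3).code == "other"

    def test_proportions_sum_to_one(self, gene3):
        reads = [
            read([(0, 100), (150, 250), (300, 400)], read_id="a",
                 sample_id="s1", condition="WT", replicate=1),
            read([(0, 400)], read_id="b", sample_id="s1", condition="WT", replicate=1),
            read([(5000, 5100)], read_id="c", sample_id="s1", condition="WT",
                 replicate=1),
        ]
        props = class_proportions(classify_reads(reads, [gene3]))
        total = props[["=", "m", "n", "u", "other"]].sum(axis=1)
        assert np.allclose(total, 1.0)
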
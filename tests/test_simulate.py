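"""Synthetic-data generators: determinism and planted statistical structure."""

import numpy as np
import pytest
from scipy import stats

from forksplice import (
    ConfigError,
    ForkSimConfig,
    ReadSimConfig,
    SlippageSimConfig,
    all_introns,
    build_introns,
    expected_fractions,
    reverse_complement,
    simulate_genome,
    simulate_long_reads,
    simulate_puseq_counts,
    simulate_slippage_counts,
)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        g1 = simulate_genome(n_genes=5, seed=4)
        g2 = simulate_genome(n_genes=5, seed=4)
        assert g1.chromosomes == g2.chromosomes
        assert g1.genes == g2.genes

    def test_introns_have_canonical_boundaries(self, sim_genome):
        for gene in sim_genome.genes:
            chrom = sim_genome.chromosomes[gene.chrom]
            for it in build_introns(gene):
                seq = chrom[it.start : it.end]
                if gene.strand == "-":
                    seq = reverse_complement(seq)
                assert seq[:2] == "GT" and seq[-2:] == "AG"

    def test_gc_dip_group_has_lower_gc(self, sim_genome):
        """Direct base counting over the implanted window: dip-group genes
        must be GC-poorer than background genes around the 3'SS."""

        def window_gc(intron):
            chrom = sim_genome.chromosomes[intron.chrom]
            if intron.strand == "+":
                seq = (
                    chrom[max(intron.start, intron.end - 40) : intron.end]
                    + chrom[
                        intron.downstream_exon[0] : intron.downstream_exon[0] + 100
                    ]
                )
            else:
                seq = (
                    chrom[intron.start : min(intron.end, intron.start + 40)]
                    + chrom[
                        max(
                            intron.downstream_exon[0],
                            intron.downstream_exon[1] - 100,
                        ) : intron.downstream_exon[1]
                    ]
                )
            return sum(1 for b in seq if b in "GC") / len(seq)

        dip_group = {"g001", "g002", "g003"}
        dip = [window_gc(it) for it in all_introns(sim_genome) if it.gene_id in dip_group]
        bg = [
            window_gc(it)
            for it in all_introns(sim_genome)
            if it.gene_id not in dip_group
        ]
        assert np.mean(dip) < np.mean(bg) - 0.05

    def test_infeasible_ranges_error(self):
        with pytest.raises(ConfigError):
            simulate_genome(n_genes=1, exon_len_range=(100, 50))
        with pytest.raises(ConfigError):
            simulate_genome(n_genes=1, intron_len_range=(2, 3))


class TestSimulateLongReads:
    def test_zero_retention_gaps_match_annotated_introns(self, sim_genome):
        cfg = ReadSimConfig(depth_per_gene=30, default_retention=0.0, seed=1)
        reads = simulate_long_reads(sim_genome, cfg, "WT", 1)
        intron_set = {
            (it.chrom, it.start, it.end) for it in all_introns(sim_genome)
        }
        assert reads
        for read in reads:
            for gap in read.gaps:
                assert (read.chrom, gap[0], gap[1]) in intron_set

    def test_full_retention_removes_gaps(self, sim_genome):
        introns = all_introns(sim_genome)
        probs = {(it.gene_id, it.index, "MUT"): 1.0 for it in introns}
        cfg = ReadSimConfig(depth_per_gene=30, retention_prob=probs, seed=1)
        reads = simulate_long_reads(sim_genome, cfg, "MUT", 1)
        assert reads and all(len(r.blocks) == 1 for r in reads)

    def test_retention_rate_within_exact_binomial_interval(self, sim_genome):
        """Planted p=0.3 at depth 200: the fraction of reads retaining the
        3'-most intron must fall inside the exact binomial 95% interval."""
        gene = sim_genome.genes[0]
        introns = build_introns(gene)
        target = introns[-1]  # 3'-proximal: immune to 5' degradation
        probs = {(gene.gene_id, target.index, "WT"): 0.3}
        cfg = ReadSimConfig(depth_per_gene=200, retention_prob=probs, seed=9)
        reads = [
            r
            for r in simulate_long_reads(sim_genome, cfg, "WT", 1)
            if r.read_id.startswith(gene.gene_id + ".")
        ]
        n = k = 0
        for read in reads:
            covers = any(
                bs <= target.start and be >= target.end for bs, be in read.blocks
            )
            gap = any(g == (target.start, target.end) for g in read.gaps)
            if covers or gap:
                n += 1
                k += covers
        lo = stats.binom.ppf(0.025, n, 0.3)
        hi = stats.binom.ppf(0.975, n, 0.3)
        assert lo <= k <= hi

    def test_degradation_monotonically_reduces_5prime_coverage(self, sim_genome):
        """More 5' degradation can only lose informative reads for the most
        5'-proximal intron (same seed: truncations scale monotonically)."""

        def informative(deg):
            cfg = ReadSimConfig(
                depth_per_gene=60, default_retention=0.2, p5_degradation_mean=deg, seed=3
            )
            reads = simulate_long_reads(sim_genome, cfg, "WT", 1)
            count = 0
            for gene in sim_genome.genes:
                first = build_introns(gene)[0]
                for r in reads:
                    if not r.read_id.startswith(gene.gene_id + "."):
                        continue
                    covers = any(
                        bs <= first.start and be >= first.end for bs, be in r.blocks
                    )
                    gap = (first.start, first.end) in r.gaps
                    count += covers or gap
            return count

        assert informative(800) <= informative(100)


class TestSimulatePuseq:
    def test_fractions_normalized_per_bin(self):
        cfg = ForkSimConfig(arrest_prob=0.4, leftward_fraction=0.2, seed=0)
        frac = expected_fractions(cfg)
        top = frac[("delta", "top")] + frac[("epsilon", "top")]
        bottom = frac[("delta", "bottom")] + frac[("epsilon", "bottom")]
        assert np.allclose(top, 1.0) and np.allclose(bottom, 1.0)

    def test_no_arrest_pure_rightward(self):
        cfg = ForkSimConfig(arrest_prob=0.0, leftward_fraction=0.0, seed=2)
        tracks = simulate_puseq_counts(cfg)
        assert tracks.counts[("delta", "top")].sum() == 0
        assert tracks.counts[("epsilon", "bottom")].sum() == 0
        mean_e_top = tracks.counts[("epsilon", "top")].mean()
        assert abs(mean_e_top - cfg.depth) < 5 * np.sqrt(cfg.depth / tracks.n_bins)

    def test_full_arrest_silences_epsilon_downstream(self):
        cfg = ForkSimConfig(arrest_prob=1.0, seed=2)
        tracks = simulate_puseq_counts(cfg)
        starts = tracks.bins[:, 0]
        tract = (starts >= cfg.barrier_pos) & (
            starts < cfg.barrier_pos + cfg.restart_tract_len
        )
        assert tracks.counts[("epsilon", "top")][tract].sum() == 0
        assert tracks.counts[("epsilon", "bottom")][tract].sum() == 0

    def test_half_arrest_gives_half_delta_share_downstream(self):
        cfg = ForkSimConfig(arrest_prob=0.5, depth=500, seed=8)
        tracks = simulate_puseq_counts(cfg)
        starts = tracks.bins[:, 0]
        tract = (starts >= cfg.barrier_pos) & (
            starts < cfg.barrier_pos + cfg.restart_tract_len
        )
        d = tracks.counts[("delta", "top")][tract].sum()
        e = tracks.counts[("epsilon", "top")][tract].sum()
        assert abs(d / (d + e) - 0.5) < 0.02

    def test_deterministic(self):
        a = simulate_puseq_counts(ForkSimConfig(seed=5))
        b = simulate_puseq_counts(ForkSimConfig(seed=5))
        for key in a.counts:
            assert np.array_equal(a.counts[key], b.counts[key])


class TestSimulateSlippage:
    def test_zero_frequency_gives_zero_selective_counts(self):
        exp = simulate_slippage_counts(SlippageSimConfig(true_slip_freq=0.0, seed=1))
        assert all(sum(p.selective) == 0 for p in exp.experiments)

    def test_deterministic(self):
        a = simulate_slippage_counts(SlippageSimConfig(seed=3))
        b = simulate_slippage_counts(SlippageSimConfig(seed=3))
        assert a.experiments == b.experiments
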
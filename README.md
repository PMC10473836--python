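# forksplice

Analysis toolkit for studies of replication-fork barriers and their
splicing-dependent control in fission yeast. It covers the four
computational stages such a study needs, end to end, with a synthetic-data
generator so every stage runs on a laptop:

1. **Polymerase-usage (Pu-seq) bias tracks and restart estimation.**
   Pu-seq sequences ribonucleotides laid down by rNTP-permissive Pol δ and
   Pol ε mutant strains, giving four binned count tracks (2 strains × 2
   strands). Per strand, Pol δ usage is the normalized ratio
   u = n_δ / (n_δ + n_ε); the strand-combined **polymerase bias** is
   100 · (u_top + u_bottom)/2. A canonical ε/δ fork gives 50, a
   recombination-restarted δ/δ fork gives 100, and a population in which a
   fraction *f* of forks restarted gives 50 + 50·*f* — so
   *f* = (bias − 50)/50, with a bin-resampling bootstrap SE. The toolkit
   also detects the switch point where the bias jumps at an active polar
   barrier (such as *RTS1*), and compares restart fractions between
   strains.

2. **Intron retention from spliced long reads.** From 3′-anchored cDNA
   alignments (BED12 blocks) and a GFF3 annotation, each read is called
   RETAINED / SPLICED / AMBIGUOUS / NOT_COVERED per intron: retention
   requires aligned blocks to cover >70% of the intron *and* of each
   flanking exon, including the subsequent (downstream) exon; splicing
   requires a block gap at the intron junctions. Per-intron IR fractions,
   mutant−wild-type differences with a fitted Gaussian, the
   replicate-consistency gene filter (≥20 percentage points higher
   retention in ≥2 of 3 replicates), and a minimal transcript
   classification ('=', 'm', 'n', 'u') follow.

3. **Splice-site GC profiling.** Mean GC fraction by position across the
   branch-point region, 3′ splice site and first ~100 bp of downstream
   exon for a group of introns, against a 95% percentile-bootstrap band
   from a random sample of intron:exon sequences.

4. **Replication-slippage statistics.** Dilution-corrected Ura⁺ reversion
   frequencies from duplicate selective/non-selective plate counts,
   aggregated as mean ± SD over independent experiments and compared with
   a two-tailed equal-variance Student's t-test.

A deterministic toy-gene constructor reproduces the protein-level
consequence of retaining a short frame-preserving intron: a stop-free
45-bp intron at the codon 202/203 boundary inserts exactly 15 residues
between residues 202 and 203.

## Worked example

The `demo` subcommand simulates a genome, long reads for two conditions ×
three replicates, Pu-seq tracks for a strong-restart and a weak-restart
strain, and plating counts — then runs every analysis and compares
recovered to planted parameters:

```sh
forksplice demo --seed 7 --out demo_out
cat demo_out/report.txt
```

```
forksplice demo: planted vs recovered parameters

[intron retention] planted delta-IR 0.40 in genes g001,g002,g003,g004
[intron retention] fitted nonzero-delta distribution: mu=0.090 sigma=0.173 (n=42)
[intron retention] consistent-retention genes called: g001,g002,g003,g004

[gc profile] planted-dip group mean GC over BP..+100: 0.279; null band lower edge 0.321; below band: True

[puseq WT] planted arrest_prob=0.9: recovered f=0.902 +/- 0.003, switch point 8700
[puseq MUT] planted arrest_prob=0.3: recovered f=0.298 +/- 0.006, switch point 9300
[puseq] relative restart MUT/WT: recovered 0.330 (planted 0.333)

[slippage ON] planted frequency 2.50e-04: recovered 2.43e-04 +/- 4.59e-05
[slippage OFF] planted frequency 1.00e-05: recovered 1.65e-05 +/- 5.07e-06
[slippage] ON vs OFF Student's t: t=8.509, p=0.00105
```

Reading the report: the four genes simulated with a 0.40 increase in
intron-retention probability are exactly the genes the consistency filter
calls; their splice-site GC profile falls below the bootstrap null band
(the planted GC dip); the restart-fraction estimator recovers the planted
arrest probabilities (0.9 and 0.3) and their ratio (≈1/3); and the
slippage assay recovers the planted reversion frequencies with a clearly
significant ON/OFF difference. `summary.json` holds the same numbers in
machine-readable form; bedGraph/BED12/GFF3/TSV intermediates are written
alongside for inspection with standard genome-browser tooling.

Individual stages run from files via `forksplice simulate {genome,puseq,
slippage}`, `forksplice puseq`, `forksplice ir`, `forksplice gc` and
`forksplice slippage` (see `--help` for each).

Library use mirrors the CLI:

```python
import forksplice as fs

cfg = fs.ForkSimConfig(arrest_prob=0.9, seed=1)
tracks = fs.simulate_puseq_counts(cfg)
bias = fs.compute_bias(fs.compute_usage(tracks, pseudocount=0.0), smoothing_window=1)
est = fs.estimate_restart_fraction(bias, cfg.restart_window, seed=1)
print(est.f, est.f_se)   # 0.900 0.003  (planted 0.9)
```

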
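# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Coordinate and annotation conventions

All intervals are 0-based half-open internally; GFF3 (1-based closed) is
converted at the I/O boundary. Exons are stored 5′→3′ in transcription
order, so intron indices are 1-based transcriptional (intron 1 nearest the
transcription start), matching how fission-yeast introns are usually
numbered. Spliced long-read alignments are consumed as BED12 blocks rather
than BAM: basecalling and alignment are upstream of this package's scope,
and BED12 keeps the contract dependency-light. Sample metadata (condition,
replicate) travels in a tab-delimited manifest next to the alignment
files.

## Fork mixture model and Pu-seq tracks

Each genomic bin is replicated by one of three fork types: a rightward
canonical ε/δ fork (probability p_R), a leftward canonical fork (p_L =
`leftward_fraction`), or a rightward restarted δ/δ fork (p_rr). Within a
restart tract of `restart_tract_len` (default 10 kb, matching the ~10 kb
tract downstream of a polar barrier) p_rr = a·(1−p_L) where a =
`arrest_prob`; elsewhere p_rr = 0, and p_R absorbs the remainder so the
three sum to 1 in every bin. Which polymerase made each strand follows
directly: δ on the top strand comes from leftward canonical plus restarted
forks, δ on the bottom from rightward canonical plus restarted forks, and
ε takes the complements. Counts are Poisson(depth · fraction +
background); the default bin size is 300 bp (common Pu-seq practice —
the bin size is configurable because it is a property of the upstream
counting pipeline, not of this model), default depth 200 per bin per
track.

**Usage and normalization.** Per strand, Pol δ usage is the ratio of
scaled δ to δ+ε counts with a pseudocount (default 0.5) and a per-bin
depth cutoff (`min_depth` 20, flagged NaN below). Scaling: when the track
set carries known per-strain library factors (`library_scale` — the
simulator emits 1.0 because both strains are sequenced at the same
per-fork depth; in real data the factors come from genome-wide totals
computed upstream), those are used. When absent, the fallback equalizes
the two strains' totals over the analysed region. The fallback is *not*
appropriate when the analysed window itself contains substantial restart
signal: a δ/δ tract genuinely gives the δ strain more counts, and
equalizing totals then shrinks the recovered restart fraction (for a
region that is entirely tract, f̂ = a/(2a+1) instead of a). Carrying the
library factors resolves this; the fallback exists for quick looks at
regions dominated by canonical replication.

**Bias, smoothing and estimation.** The bias track is 100 · (u_top +
u_bottom)/2, centered-moving-average smoothed (default 3 bins, edges
truncated, missing bins stay missing). Smoothing serves display and
switch-point detection; window means — the restart-fraction estimator in
particular — use the unsmoothed track, because a window mean is already an
average and smoothing only bleeds flanking canonical bins into the tract
edges. Likewise the estimator uses pseudocount 0: the raw ratio is
unbiased given the bin total (the depth cutoff already guards 0/0), while
a pseudocount pc shrinks usage toward 0.5 by T/(T+2pc), a deterministic
offset visible at extreme bias (≈0.25 bias points per strand at depth
200). The displayed usage/bias tracks keep pc = 0.5.

The switch point is the leftmost run of ≥3 consecutive bins with bias ≥60;
the restart window defaults to barrier → barrier + 10 kb; the restart
fraction is clip((mean bias − 50)/50, 0, 1) with a 1000-replicate
bin-resampling bootstrap SE.

## Long-read simulator and intron-retention calling

Reads are 3′-anchored (polyA-selected cDNA): per gene, Poisson(depth)
reads each independently retain each intron with its configured
probability, then lose an exponential stretch (mean 200 nt by default)
from the transcript 5′ end — the distribution is a modelling choice; the
phenomenon (5′ degradation causing under-counting of 5′-proximal introns)
is what matters, and informative coverage of 5′-proximal introns is
provably non-increasing in the degradation mean under the shared random
stream. The simulator draws Poisson/binomial counts only; it does not
model sequencing errors, alignment wobble beyond the junction slack, or
replicate-level overdispersion of IR fractions, so passing tests show
estimator correctness under binomial sampling, not robustness to
basecalling artefacts.

The ">70%" in the retention rule is read feature-centric — the read's
blocks must cover more than 70% of the feature's bases — applied to the
intron and both flanking exons, with the downstream-exon clause making
retention conditional on the subsequent exonic sequence being present.
Junction matching for spliced calls tolerates 5 bp of wobble
(configurable). IR fractions need ≥10 informative reads (ambiguous and
uncovered calls count for neither side). The wild-type baseline for
differential retention pools WT counts across replicates (no pairing is
assumed between replicates of different strains); per mutant replicate,
Δr = IR_mut,r − IR_wt,pooled. The Gaussian fitted to the distribution of
mean differences uses moment estimators over introns with nonzero
difference. The consistency gene call — ≥0.20 (20 percentage points, the
natural reading of "occurring 20% more often") in ≥2 replicates — is an
effect-size-plus-replication filter; no multiple-testing correction is
applied because no p-values are computed.

Transcript classes are a minimal reference-comparison subset: '=' (all
gaps match reference introns and form a transcription-order suffix of the
intron chain, tolerating 5′ truncation of 3′-anchored reads), 'm'
(retention with otherwise matching gaps), 'n' (retention plus a novel
gap), 'u' (no gene overlap), 'other'. Full class-code parity with
assembly-comparison tools is out of scope.

## GC profile and bootstrap band

Profiles are indexed by offset from the 3′ splice site: −120..−1 intronic
(covering the typical branch-point region, −40..−10 in yeast — the window
extends to −120 since exact branch points are not annotated) and 0..+99
into the downstream exon. Features shorter than the window contribute
missing values, not zeros. Per-sequence GC indicators are smoothed with an
11-nt centered window (truncated edges), then averaged across the group.
The null band draws `n_sample` (default 100) introns uniformly at random,
bootstraps the group-mean profile (default 1000 resamples) and takes
percentile 2.5/97.5 per position — percentile rather than
normal-approximation intervals, since per-position GC means of 100
sequences are bounded and can be skewed. For NaN-free profile matrices the
bootstrap uses a multinomial-weight matrix product, which is exactly
row-resampling but fast. Intron length vs retention change uses Spearman
rank correlation (lengths are heavy-tailed). Expression comparisons are
counts-per-million per sample, averaged within condition, with log2 fold
changes undefined (NaN) at zero counts.

The synthetic GC dip lowers the GC fraction from 0.40 to 0.25 across the
last 40 intronic bases and first 100 exonic bases of dip-group genes —
values chosen to be comfortably separable at a few dozen sequences while
staying in the range of real yeast splice-site composition.

## Slippage assay statistics

Per independent experiment, the reversion frequency is (mean selective
count × selective dilution) / (mean non-selective count × non-selective
dilution); duplicate plates are averaged first, experiments aggregate to
mean ± SD (SD, not SEM, across experiments). Conditions are compared with
the classical equal-variance two-tailed Student's t (not Welch), on the
raw frequency scale (no log transform). The simulator draws plate counts
as Poisson approximations to the underlying binomials; defaults (2×10⁶
cells plated per 100 µl aliquot, selective dilution 10, non-selective
10⁴, 2 plates each, 3 experiments) give colony counts in the
tens-to-hundreds range a plate count would realistically have. The
frequency is reported per plating, not per generation: no
fluctuation-analysis (Luria–Delbrück) correction is applied.

## Isoform translation

Translation uses the standard nuclear code from the annotated CDS start,
stopping at the first stop codon; no codon-usage or NMD modelling. A
retained intron is in frame iff its length is a multiple of 3 and the
retained protein reaches exactly the expected length (spliced + length/3)
— otherwise it is flagged out of frame and/or truncated, with the
insertion point reported as the last residue shared before divergence.
The bundled deterministic toy gene places a stop-free 45-bp intron at the
codon 202/203 boundary; the real locus's exon coordinates are not bundled,
so the 15-residue insertion between residues 202–203 is demonstrated on
this constructed gene, built from a varied codon cycle so the divergence
point is unambiguous.

## Problem sizes and determinism

Simulated checks use 100 × 300-bp bins at depth 200 per track for fork
tracks, 100 single-intron genes at read depth 100 × 3 replicates per
condition for the consistency filter, 100 sequences × 1000 bootstrap
resamples (200 replications) for band coverage, and 1000 Monte-Carlo
repetitions for the slippage estimator — sizes at which the binomial/
Poisson standard errors are small enough to resolve the planted effects.
Every stochastic component takes an explicit seed; identical seeds give
byte-identical outputs (the demo's TSV/JSON files included). Child seeds
for named subprocesses are derived from the base seed plus stable string
hashes, so adding a stage never reshuffles another stage's stream.

## Known limitations

- The fallback equal-total normalization biases restart estimates when the
  analysed region is mostly restart tract (see above); provide library
  scales in that case.
- The retention caller assumes clean block boundaries up to the junction
  slack; it has not been tuned against real aligner soft-clipping
  behaviour.
- Transcript classification implements four codes plus 'other'; reads
  spanning multiple genes are assigned to the single most-overlapping
  gene.
- The GC null band samples introns uniformly; expression-matched sampling
  is not implemented.
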
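# Methods

## Overview

epitempo analyzes temporal MeRIP-seq designs: paired IP/input libraries
at ordered developmental stages (default P7, P14, P21, P60) in two
conditions (wild type everywhere, a knockout compared at the first
stage). The analysis chain is: per-peak quantification and retention →
cross-stage merged atlas → ON/OFF switches and CMR/SMR classes →
KO-vs-WT differential methylation → metagene placement → methylation–
expression correlation. A synthetic generator with planted truth drives
the end-to-end validation; every stage is also checked against an
independent oracle (exhaustive definitions, per-nucleotide labeling,
exact tests, or the bedtools CLI).

## Peak quantification

A peak's ip FPKM, input FPKM and enrichment score follow the standard
peak-normalized densities a = A·10⁹/(B·C), b = D·10⁹/(E·C), c = a/b.
Counting uses coverageBed semantics: a read counts iff ≥ 50 % (inclusive)
of its aligned length overlaps the peak on the same strand; spliced reads
contribute block-wise overlap relative to their summed block length.
Strandless reads under strand-matching raise an error rather than being
silently dropped.

Degenerate inputs: C ≤ 0 or B/E ≤ 0 are errors; A = 0 gives a = c = 0;
D = 0 flags the score undefined (infinite sentinel when A > 0). Undefined
scores are excluded from distribution comparisons and from per-RNA
methylation levels but still count toward presence, since a peak with
input dropout and IP signal is evidence of methylation, not absence.

Retention requires all of FDR < 0.05, a > 1, c > 1.5, with every
inequality strict exactly as stated; the same strictness convention
applies to the preprocessing thresholds ("longer than 70", "more than
70 %", "quality score > 25", "< 20") and to the expression cutoff
(FPKM > 0.2).

## Candidate peak caller (plumbing)

The built-in caller is deliberately simple and clearly labeled plumbing:
100-nt windows stepping by 50 along each reference transcript's exons;
per window a one-sided binomial test of the IP share conditional on the
window total, null proportion B/(B+E); BH across all windows; adjacent
significant windows merge, the peak FDR being the member minimum.
Pipelines accept external peak calls (BED + FDR) in its place; on null
data the caller plus retention filter passes ≈ 0 peaks.

For count-table workflows the same binomial test applied per candidate
region per sample (BH within sample) supplies the per-sample FDR.

## Preprocessing

Three filters in order: (1) truncate at the leftmost AGATCGGAAG
occurrence with at most two mismatched bases — full 10-mer matches by
default, with an optional mode that also trims a ≥ 5-nt read suffix
matching the adapter prefix at a proportional mismatch budget
(⌊2k/10⌋ for overlap k), since partially sequenced adapters at the 3′
end are otherwise invisible; (2) strip 3′ bases while quality < 20;
(3) retain reads longer than 70 nt with more than 70 % of bases above
Q25. N bases never match the adapter and never count as high-quality.
Preprocessing is idempotent, and on planted fixtures recovers 100 % of
≤ 2-mismatch adapters at their recorded offsets while never touching
3-mismatch plants.

## Reference transcriptome and the five-region partition

The reference keeps, per gene, the transcript maximizing summed exon
length, ties broken to the lexicographically smaller transcript id.
Coordinates convert from GTF (1-based inclusive) to 0-based half-open on
parse; the annotated CDS is taken stop-codon inclusive.

The codon windows are anchored at the **first nucleotide** of the start
and stop codons, spanning anchor−150…anchor+150 (300 nt), clipped at
transcript ends. Anchoring at the first base keeps the full codon inside
its window and matches common metagene practice; nothing downstream is
sensitive to a one- or two-base shift of the anchor. When a short CDS
makes the windows collide, they split at the midpoint between the two
anchors with the start window taking the left half (ties to the start
side). After carving, the five regions are disjoint and cover the
transcript exactly — asserted per partition and verified against a
per-nucleotide brute-force labeler.

Two deliberately different partitions serve the two summaries: the
100-bin metagene profile stretches the plain 5′UTR/CDS/3′UTR segments
(no codon windows) to 100 bins each, bin = ⌊fraction·100⌋ capped at 99,
normalized to sum to 100 % (per-curve max normalization available); the
five-region counts use the carved partition. A peak is represented by
its genomic midpoint projected through the exon chain (midpoints falling
in an intron snap to the nearest exonic base within the peak's overlap);
non-coding transcripts are excluded from both summaries but keep their
methylation calls.

## Temporal comparison

Merging is single-linkage union of overlapping or book-ended same-strand
intervals (mergeBed default semantics, cross-checked against the CLI).
Presence of a stage at a merged peak requires ≥ 1 nt same-strand overlap
by a retained peak of that stage — the weakest rule consistent with
interval union, and monotone: adding IP reads can only strengthen a
peak's quantification, never delete presence. ON/OFF switches are the
presence differences over adjacent stage pairs; a peak may emit events
at several transitions. CMR/SMR/other/unmethylated labels are mutually
exclusive by construction.

Differential methylation (KO vs WT) over the common atlas: log₂FC of the
two enrichment scores; p-value from Fisher's exact test on the IP/input
count split with the input column rescaled by each condition's B/E ratio
(rounded), putting both margins on the IP scale — a transparent stand-in
for a peak caller's internal GLM, using identical decision thresholds
(BH FDR < 0.05 and |log₂FC| > 1, both strict). Peaks retained in exactly
one condition are gain/loss rather than tested; an RNA-level gain/loss
report (methylated in exactly one condition) is emitted alongside the
peak-level one, since the two aggregation levels answer different
questions.

## Correlation screen

Per RNA, the per-stage methylation level is the maximum retained-peak
enrichment score at that stage (mean aggregation available); stages
without a retained peak contribute 0 so every methylated RNA has a full
trajectory. Expression is FPKM from the input libraries; RNAs expressed
(FPKM > 0.2) at no stage are excluded, as are zero-variance trajectories.
Pearson r over the 4 paired values with two-sided P from t with 2 df;
positive/negative classes at r > 0.95 / r < −0.95 with P < 0.05. With
n = 4 the null distribution of r is uniform on [−1, 1], so the |r| > 0.95
gate has an analytic 5 % null tail and almost exactly coincides with the
P < 0.05 gate (t₀.₀₂₅,₂ = 4.303 ⇔ |r| = 0.94997) — a useful calibration
check the tests exploit.

## Synthetic generator

The generator emulates the data structures the analysis assumes, not
sequencing physics. One synthetic chromosome carries the configured
number of genes (default 1,000): coding genes with 5′UTR 100–300 nt,
CDS 300–1,500 nt, 3′UTR 200–600 nt; 1–3 exons (introns 200–800 nt);
5 % non-coding genes (exercising metagene exclusion); 10 % of genes get
a strictly shorter second isoform (exercising longest-transcript
selection).

Methylation classes are drawn per gene: 40 % CMR, 5 % per-stage SMR
(×4), 20 % switching (one status change, uniformly among the four
two-block schedules), remainder unmethylated. One peak site per gene
(length uniform 100–300 nt, matching ~100–150-nt fragmentation with
merged windows), placed within a single exon at a region drawn
start/stop-codon-heavy (5/25/30/30/10 % over
5′UTR/start/CDS/stop/3′UTR) as observed in neural tissue; unmethylated
genes keep a decoy site so detection is never trivial. Enrichment
factors are uniform on 3–10 per gene.

Counts: input D ~ Poisson(e·E·C/10⁹) inverts the FPKM identity so
measured input FPKM is unbiased for the planted expression e; IP
multiplies the rate by the planted factor (1 where unmethylated) with
the IP total B. Library totals are declared metadata — the simulated
regions are a subsample of each library — which keeps the enrichment
score unbiased for the planted factor and makes library-size invariance
exact. A negative-binomial option (gamma-mixed Poisson, dispersion
configurable) is available; Poisson is the default noise law.

The knockout perturbs the first stage only: among eligible non-coupled
genes, 5 % hyper (WT factor 3–4, KO ×4), 5 % hypo (WT 8–10, KO ÷4),
5 % loss, and 10 % of first-stage-unmethylated genes gain (factor 6–10).
Expression trajectories are log-normal (median 20 FPKM, mild per-stage
wobble); 30 % of CMR genes are expression-coupled, their factor
trajectory a monotone ramp over 3–10 and their expression exactly affine
in it (half positive, half negative), with baseline expression spanning
a broad range (log-normal, median 60 FPKM) so the screen is exercised
both where counting noise is negligible and where it attenuates r below
the 0.95 cutoff.

**High-signal coupled RNAs.** Planted trajectories are perfectly
collinear, so the measured r is attenuated purely by counting noise; by
the delta method the expected r is 1/√((1+q_m)(1+q_e)) with q the
noise-to-signal variance ratios of the score and FPKM trajectories,
computable from planted means alone. A plant is *high-signal* when this
expected |r| ≥ 0.98 — counting noise consumes at most half the margin
between perfect collinearity and the 0.95 cutoff. Sign recovery is
≥ 0.9 (typically 1.0) on high-signal plants and ~0.93–0.97 over all
plants; the shortfall on noisy plants is a property of 4-point Pearson
screening at |r| > 0.95, not of the implementation.

FASTQ fixtures plant the adapter (0–2 substitutions at a recorded
offset) in a fraction of reads, optionally 3-substitution copies that
must not be trimmed; backgrounds are rejection-sampled so no spurious
≤ 2-mismatch occurrence exists, keeping the truth unambiguous. Qualities
are high (≈ Q38) with a low-quality 3′ tail on 20 % of reads.

What the generator does **not** model: alignment artifacts, PCR
duplicates, sequence motifs (no UGGACU content), fragment-level coverage
shape, biological replicates (one library pair per stage/condition, as
the analysis treats them), or overdispersion between animals. Passing
recovery tests therefore demonstrates the correctness of the decision
logic under the stated count model, not robustness to mapping artifacts
or replicate variability.

## Problem sizes and determinism

The test suite and the acceptance script use: 10,000 random tuples for
formula fidelity (tolerance 10⁻¹²), a 50,000-read preprocessing fixture,
200 random transcripts (every nucleotide labeled) for the partition
oracle, 1,000 random presence vectors for switch/class logic, 200 null
replicates for rank-sum calibration, and the 1,000-gene default study
for planted-parameter recovery — sizes at which every check runs in
seconds to a couple of minutes on one CPU. All randomness flows from
explicit seeds; rerunning any pipeline with the same config and seed
reproduces byte-identical outputs.

## Known limitations

- The caller is a screening heuristic, not a replacement for a
  model-based peak caller; its FDR is calibrated only under the
  conditional-binomial null.
- Fisher's exact test with rounded library-offset inputs is slightly
  conservative at very low counts.
- Presence is binary per stage; partial methylation shifts below the
  retention thresholds are invisible to switch/class logic (they surface
  only in the differential-methylation scores).
- With one library per stage/condition, no within-stage variance is
  estimable; all significance statements are conditional on the count
  model.
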
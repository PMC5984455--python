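# epitempo

Temporal analysis of the m⁶A epitranscriptome from MeRIP-seq (m⁶A-seq)
data: peak-level IP/input enrichment scoring, ON/OFF methylation switches
across developmental stages, continuous vs stage-specific methylation
classes, wild-type vs knockout differential methylation, transcript
metagene profiling, and a methylation–expression correlation screen — all
exercised end to end on a synthetic generator with planted ground truth.

## Who this is for

MeRIP-seq profiles RNA methylation by sequencing an antibody-enriched
(IP) library alongside its input. Comparing methylation **across time**
(e.g. postnatal developmental stages P7, P14, P21, P60 of a tissue) and
**across genotypes** (wild type vs a demethylase knockout) requires a
chain of decisions — how to score a peak, when to call it present, how to
compare presence across samples — that this package implements as a
tested, reusable pipeline with explicit thresholds.

## The statistics at the core

For peak *i* in biological sample *j*, with A/D the IP/input read counts
on the peak, B/E the total mapped reads of the IP/input libraries and C
the peak length:

    ip FPKM       a_ij = A_ij · 10⁹ / (B_j · C_ij)
    input FPKM    b_ij = D_ij · 10⁹ / (E_j · C_ij)
    enrichment    c_ij = a_ij / b_ij

Reads are counted with `coverageBed -s -split -counts -F 0.50` semantics
(strand-matched, ≥ 50 % of the read's aligned length on the peak). A peak
is **retained** when caller FDR < 0.05, a > 1 and c > 1.5 (all strict).
Retained peaks from all stages merge (strand-aware, `mergeBed`-style
union) into an atlas; a merged peak absent at one stage and present at
the next is an **ON switch** (the reverse, **OFF**). An RNA methylated at
every stage is a **CMR** (continuously methylated RNA); methylated at
exactly one stage, an **SMR**. KO-vs-WT peaks are tested by Fisher's
exact test with a library-size offset (BH-corrected; differential at
FDR < 0.05 and |log₂FC| > 1, with gain/loss when a peak is retained in
only one condition). Peak positions project through the exon structure of
each gene's longest transcript onto a 100-bin-per-segment metagene
profile and a five-region partition (5′UTR, 300-nt start-codon window,
CDS, 300-nt stop-codon window, 3′UTR). Finally, per-RNA enrichment-score
and FPKM trajectories are screened by 4-point Pearson correlation
(|r| > 0.95, two-sided P < 0.05, df = 2).

Read preprocessing implements three filters: truncate at the leftmost
`AGATCGGAAG` occurrence with ≤ 2 mismatches, trim Q < 20 bases off the 3′
end, and retain reads > 70 nt with > 70 % of bases above Q25.

## Worked example

The numbered drivers under `analysis/` run a 1,000-gene synthetic study
(four stages, WT + KO at P7, one IP/input pair per sample) and write
summary tables to `results/`. For example:

```bash
cd analysis && python 04_temporal_classes.py
```

prints (abridged):

```
ON/OFF switches per adjacent-stage transition:
transition direction  n_events
   P14-P21       OFF        88
   P14-P21        ON        87
   P21-P60       OFF       103
   P21-P60        ON        64
    P7-P14       OFF        66
    P7-P14        ON       100

Methylation classes (detected):
           class  n_rnas
             CMR     377
         SMR:P14      45
         SMR:P21      53
         SMR:P60      57
          SMR:P7      53
methylated_total     802

Recovery vs planted truth: CMR/SMR macro F1 = 0.963, switch sensitivity = 0.996
```

The switch counts are the ON/OFF events between adjacent stages over the
merged atlas; the class tally counts RNAs by their detected presence
schedule; the recovery lines compare both against what the generator
planted. The same study is available programmatically:

```python
from epitempo import SimConfig, generate_truth, simulate_counts
from epitempo.pipeline import run_count_analysis

truth = generate_truth(SimConfig(n_genes=1000, seed=1))
counts = simulate_counts(truth)
result = run_count_analysis(truth.peaks, counts.peak_counts,
                            counts.libstats, truth.reference,
                            transcript_counts=counts.transcript_counts,
                            ko_stage="P7")
print(result.report)
```

A thin CLI wraps the same functions
(`epitempo simulate|preprocess|quantify|compare|metagene|correlate|run-all`).

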
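# mztseq

Analysis of the **maternal-to-zygotic transition (MZT)** from paired
poly(A)-selected and rRNA-depleted RNA-seq count tables, with a fully
specified forward simulator that provides ground truth for every inference
the pipeline makes.

Early embryos start life running on maternally deposited mRNA. Two things
then happen at once: the embryonic genome switches on (zygotic genome
activation), and much of the maternal mRNA pool is cleared — first by
poly(A)-tail shortening (deadenylation), later by nucleolytic degradation.
Poly(A)+ RNA-seq alone cannot tell these apart, because oligo-dT capture
efficiency depends on tail length: a transcript whose tail shortens "loses"
reads without losing molecules, and one that is readenylated after
fertilization "gains" them. Comparing a poly(A)+ library with a parallel
rRNA-depleted (tail-independent) library from the same sample separates
tail dynamics from true abundance changes. This package implements the
bespoke computations of that study design:

- **Expression core** — TPM, median-of-ratios size factors, a
  self-contained negative-binomial Wald test with across-gene dispersion
  moderation and Benjamini–Hochberg FDR, exact/approximate Wilcoxon
  signed-rank, Pearson chi-squared (`mztseq.stats`).
- **Genome-activation calling** — exonic activation thresholds
  (adjusted P < 0.05, fold > 2, TPM > 1, rRNA-depleted protocol only), an
  intron count table (pre-mRNA minus exon counts, intronic RPKM ≥ 0.5
  gate) that detects re-activation of maternally provided genes from
  nascent pre-mRNA signal, per-gene categories, and a 10-kb window scan
  (`mztseq.activation`).
- **Maternal clearance** — per-gene first significant ≥2-fold decrease in
  each protocol (deadenylation before degradation shows up as a poly(A)+
  decrease preceding the rRNA-depleted one), an oscillation screen, a
  stable maternal reference set (<1.25-fold over 4–7 h.p.f., Triptolide
  non-responsive), and Wilcoxon tests for transcription-dependent clearance
  under the RNA-Pol-II inhibitor Triptolide (`mztseq.clearance`).
- **Histone metrics** — transcriptome share per histone class
  (replication-dependent histone mRNAs lack poly(A) tails and are only
  visible in rRNA-depleted data) and the cross-species "net activation"
  trajectory with a trimmed-RPM option (`mztseq.histones`).
- **Codon adaptation** — empirical codon-usage table from the top-100
  expressed stable maternal mRNA; CAI as the geometric mean of relative
  adaptiveness w, excluding the initiator and single-codon families;
  3'UTR extraction (> 20 nt) (`mztseq.codon`).
- **Stage specificity** — peak-stage clustering (<1 TPM in one stage,
  >5 TPM in another, significant vs egg) and per-GO-term 2×k chi-squared
  stage enrichment with BH correction (`mztseq.stages`).
- **miRNA discovery** — seeded ungapped homology scan against reference
  mature miRNAs, maximum-base-pairing (Nussinov) stem-loop validation,
  activation/Triptolide filters, and full-complementarity target search
  with G:U wobble scoring — cnidarian miRNAs pair near-fully with their
  targets, unlike the 6–8-nt seed matches of bilaterians (`mztseq.mirna`).
- **Simulator** — `mztseq.simulate` generates the paired count matrices,
  exon/pre-mRNA tables, sequences, and per-gene truth labels for eight gene
  classes (stable maternal, readenylated, deadenylated-only,
  deadenylated-then-degraded, re-activated maternal, de novo zygotic,
  histone-like, miRNA target) under a Hill-function model of oligo-dT tail
  capture.

## Worked example

The numbered drivers under `analysis/` run each stage on the default
simulated dataset (2000 genes, 9 timepoints from unfertilized egg to
7 h.p.f., 2 replicates, 1e6 reads per library, Triptolide/DMSO arm at
7 h.p.f.) and write tables under `results/`:

```bash
cd analysis
python 01_simulate.py --seed 1
python 02_activation.py --seed 1
python 04_clearance.py --seed 1
```

`02_activation.py` prints, among other things:

```
re-activated maternal genes recovered: intron 100%, exon-only 0%
(100% invisible to exonic signal alone)
```

meaning every simulated maternal gene with renewed zygotic transcription is
found through its intron (nascent pre-mRNA) signal, while exon-level
differential expression misses essentially all of them — their exonic
increase sits on a large pre-existing maternal pool. `04_clearance.py`
prints the two-protocol timing matrix and

```
deadenylated-then-degraded genes below the diagonal (polyA before ribo): 100.0%
Triptolide vs DMSO, late-cleared, ribo: median shift +1.99 log2, p = 1.94e-20 (stabilized)
```

the first line saying that deadenylation is always detected before
degradation for genes simulated with both, the second that blocking
transcription stabilizes late-cleared mRNA — their decay requires zygotic
factors. `03_histones.py` reports the histone-like class expanding from
1.8% of the egg transcriptome to about one third (an ~19-fold share
increase) by 4 h.p.f.

The same stages are available as a CLI (`mztseq simulate|de|activation|
clearance|cai|mirna|histone|stages|demo`); `mztseq demo --seed 0 --outdir
out/` runs everything end to end and writes per-stage manifests with output
checksums (reruns with the same seed are byte-identical).

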
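# Methods

## The measurement model

Libraries are simulated at the count-table level; no reads are generated.
For gene *g* with true abundance *A_g(t)* (arbitrary molar units), union-exon
length *l_g*, and poly(A)-tail length *L_g(t)* (nt), the expected count in a
library of depth *D* is

- rRNA-depleted: `D · A_g l_g / Σ_j A_j l_j`
- poly(A)+: `D · A_g l_g c(L_g) / Σ_j A_j l_j c(L_j)`

where the oligo-dT capture probability is a Hill saturation
`c(L) = L^h / (L^h + K^h)` with defaults `K = 30 nt`, `h = 2` — smooth,
monotone, `c(0) = 0`, `c(K) = 0.5`, asymptotically below 1, matching the
intuition that capture saturates once a tail comfortably exceeds the
oligo-dT footprint. Counts are negative-binomial with mean *m* and variance
`m + α m²`; `α = 0` degenerates to Poisson. The default `α = 0.01`
represents parallel libraries prepared from one pooled-embryo RNA sample —
close to technical replication. TPM is compositional by construction, so
wholesale transcriptome remodeling (e.g. the histone expansion) shifts
every gene's TPM; analyses that screen TPM ratios re-center them by the
across-gene median ratio (see below).

Each output matrix (truth, poly(A)+, ribo, exon/intron, sequences) draws
from its own child of the master seed (`SeedSequence(seed, spawn_key=(k,))`
with a fixed per-matrix k), so generating or skipping one matrix never
perturbs another, and identical (config, seed) reruns are byte-identical.

## Gene classes and trajectories

Class fractions (defaults, of 2000 genes): stable maternal 0.28,
readenylated 0.14, deadenylated-only 0.16, deadenylated-then-degraded 0.16,
re-activated maternal 0.14, de novo zygotic 0.06, histone-like 0.04, miRNA
target 0.02. Allocation is deterministic (floor + largest remainders), so
class counts are within one gene of fraction × n. The maternal
contribution (egg TPM ≥ 1) covers ~94% of simulated genes: the simulation
models the *expressed* gene universe, not whole-genome annotation, where the
maternal fraction is ~half.

- Maternal abundance is log-normal (median 50, log-sd 1); de novo zygotic
  genes start at a trace level (true egg TPM < 0.5, the de novo
  definition).
- Tails: stable 60 nt; readenylated 15 → 80 nt over one hour around 1–2
  h.p.f.; deadenylated classes 80 → 10 nt over the hour before their onset
  (2–5 h.p.f. for deadenylated-then-degraded, 2–4 for deadenylated-only,
  5 for miRNA targets), so the full poly(A)+ drop (≈8.8-fold in capture) is
  visible *at* the labeled onset.
- Degradation follows deadenylation: abundance halves per hour starting one
  hour before the decay onset (≥ 5 h.p.f., strictly after deadenylation).
- Zygotic production ramps linearly over one hour from its onset (3–4
  h.p.f. de novo, 4–5 re-activated). Re-activated genes gain 20% of their
  maternal level exonically but 10× that increment as intron signal — the
  regime in which exonic detection fails and intron detection succeeds.
- Histone-like genes are intronless, clustered on one scaffold,
  non-adenylated (tail 5 nt, capture ≈ 0.03), start at 1.8% of the egg
  transcriptome, double by 3 h.p.f., and reach a configured one-third share
  of total abundance at 4 h.p.f.; the zygotic amplitude that achieves the
  share is solved in closed form from the other classes' trajectories.
- Triptolide (transcription inhibition): zygotic production is zeroed,
  degradation is suppressed (decay requires zygotically encoded factors),
  and late (≥ 5 h.p.f.) deadenylation is suppressed, while early
  deadenylation and readenylation are maternal and persist. A
  `triptolide_effective=False` switch produces the null configuration for
  calibration.
- Intron signal: nascent transcription contributes
  `nascent_intron_fraction = 0.3` of zygotic signal for de novo genes, the
  10× increment for re-activated genes, plus a 1% background for all genes;
  the exon table and intron increment are drawn separately and summed into
  the pre-mRNA table, so exon ≤ pre-mRNA holds exactly.

Sequences: CDS are sampled per gene from one of two codon-usage tables —
uniform within each synonymous family, or high-bias (0.9 on one codon per
family) — assigned to 20% of genes independently of clearance class, so
CAI separates the bias groups but shows no cleared-vs-stable difference.
Each pri-miRNA host (a de novo zygotic gene) carries a perfect 22-bp
stem-loop with an 8-nt loop; mature arms alternate 5p/3p. Reference mature
sequences differ from the implants by 0–1 mismatches (configurable). Target
sites are reverse complements of the mature with configurable mismatch /
G:U edits implanted in 3'UTRs of miRNA-target genes; decoy sites with 5
mismatches go into stable genes.

## Statistical choices

**NB test.** Size factors are median-of-ratios over genes nonzero in all
samples. Per-gene dispersion is method-of-moments pooled over the two
groups with a small-sample bias correction of the squared-mean denominator
(`m̄² − s²/n` estimates μ²), clipped to [−1, 10], then moderated toward the
across-gene mean with prior weight 20 (degrees of freedom of the per-gene
estimate count as its weight). This information sharing is what keeps a
Wald z calibrated at n = 3 per group: verified type-I rates are 0.043–0.052
across dispersions {0, 0.05, 0.1} and means {10, 50, 200}. When both groups
are single libraries, a configured prior dispersion (0.1) replaces the
estimate. Group means of zero are floored at 0.5 normalized counts for the
fold and variance terms — this is what makes intron entries with an all-zero
egg baseline testable. Known limitation: no mean–dispersion trend is
fitted, so datasets mixing very low and high counts are mildly conservative
for the high-count genes.

**Wilcoxon signed-rank.** Zeros dropped, midranks for ties. Exact p for
n ≤ 25 from the full null distribution of W⁺ (generating-function
convolution over doubled midranks — identical to 2ⁿ enumeration, verified
against it for n ≤ 12); beyond that, normal approximation with tie and
continuity corrections.

**BH.** Textbook step-up, verified against brute force and statsmodels.

**Folding.** Nussinov maximum base pairing (WC + optional G:U, minimum
loop 3, deterministic traceback preferring the smallest closing index), a
self-contained and brute-force-verifiable stand-in for thermodynamic
folding; it scores pairing capacity, not free energy, and is used only to
ask whether a mature sequence sits on one arm of a stem (≥ 14 of its
positions paired).

**Thresholds** all surface in `PipelineConfig`-style keyword arguments with
the study's stated values as defaults: DE padj < 0.05; activation fold
strictly > 2 with TPM > 1 (rRNA-depleted protocol enforced); de novo egg
TPM < 0.5; maternal egg TPM ≥ 1, with egg TPM in [0.5, 1) plus activation
evidence labeled `ambiguous` (the source thresholds leave this gap open);
intronic RPKM ≥ 0.5 in at least one sample (exclusion requires failure
everywhere, so one active timepoint preserves testability); clearance
decrease ≥ 2-fold (boundary inclusive, unlike activation's strict >, each
as stated for its screen); oscillation rise strictly > 1.5-fold; stability
< 1.25-fold over 4–7 h.p.f.; CAI reference top-100; UTR length > 20 nt;
miRNA scan word size 7 with ≤ 2 mismatches; target scan word size 4 with
paired fraction ≥ 0.85 (the numeric surrogate for "extensive
complementarity"; E-value machinery is replaced by these explicit,
reproducible cutoffs). TPM-space fold screens use a 0.1-TPM pseudocount;
count-space fold changes from the NB fit use none.

**Compositional correction in the stability screen.** The < 1.25-fold
stable-reference screen divides each timepoint's TPM ratios by their
across-gene median before applying the band. Without this, the histone
expansion alone shifts every flat gene's raw TPM ratio by ~1.5-fold and the
screen empties. Even with it, a 1.25-fold band at dispersion 0.01 retains
~88% of truly stable genes per the normal bound (z = ln 1.25 / 0.1 ≈ 2.2
per timepoint, four screens), so the property test asserts ≤ 15% false
exclusion at study-scale depth with ≥ 95% purity, and the recovery analyses
run at the default 1e6 depth.

**Clearance modes vs. profile groups.** The three-way mode classification
(stable / deadenylated-only / deadenylated-then-degraded) is computed from
first-decrease timing alone. The oscillation screen remains a separate
profile label: at 1e6 reads the strictly-greater-than-1.5 stage-to-stage
screen trips on Poisson noise for low-count genes, and folding it into the
mode label would only inject that noise.

**Stage pooling.** Peak-stage clusters pool adjacent sparse stages by
cumulative gene count into at most five nonempty groups (the same
low-gene-count pooling the enrichment design assumes); the chi-squared
enrichment test requires the configured group count and skips terms with
zero expected cells.

## What the simulation does and does not emulate

It reproduces the statistical structure the analyses rely on: the
tail-capture confound between protocols, delayed and initially
histone-dominated activation, intron-borne re-activation signal,
deadenylation-before-degradation timing, transcription-dependent late
clearance, codon-bias signal orthogonal to clearance, and implanted
hairpin/target sequence relationships. It does not emulate read-level
artifacts (mapping ambiguity, positional coverage bias, rRNA carryover),
isoform structure beyond one transcript per gene, biological replicate
variance beyond a single NB dispersion, partial drug efficacy, or
free-energy RNA structure. Passing tests therefore demonstrate correctness
of the computations under the stated generative model, not robustness to
alignment- or chemistry-level artifacts in real libraries.

## Problem sizes

Default analyses and the acceptance script use 2000 genes, 9 timepoints,
2 replicates, 1e6 reads per library; calibration uses 1000 null NB
simulations per dispersion and 200 label shuffles for the GO null; module
tests use 200–400-gene configurations. The full test suite runs in well
under a minute of CPU plus a few seconds per simulated dataset fixture.
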
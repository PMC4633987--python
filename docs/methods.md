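# Methods

This note defines the statistical models and algorithmic conventions
implemented in `chromdyn`, the parameters of the synthetic-data generator,
and the numerical choices that affect results. It makes no empirical claims
beyond what the code computes.

## Window enrichment

The genome is tiled with sliding windows of size 1000 bp and step 500 bp
(tiles start at 0; a terminal partial window is dropped). Each sequencing
tag is shifted 60 bp in its 3′ direction (plus-strand tags downstream,
minus-strand tags upstream) toward the fragment midpoint and assigned to
every window containing the shifted position — on a sliding grid one tag
can contribute to two windows.

Libraries are normalized by scaling each sample's counts by
`mean(total) / total_sample`, so all post-normalization library sizes equal
the mean raw size. The per-window statistic is

```
E = log2((n_chip + 8) / (n_input + 8))
```

computed as a single ratio (not as a difference of logarithms, which is not
bit-identical in floating point). The pseudo-count of 8 shrinks ratios
toward zero in sparsely covered windows. Replicates are scored separately
against the shared input and averaged arithmetically on the log2 scale.

Windows with `E >= 1.5` (inclusive) are enriched. Enriched windows are
merged when they share at least one base; book-ended windows (end == next
start, half-open coordinates) are *not* merged. A region's score under any
track is the maximum over all windows overlapping the region.

## Enhancer calling and classification

Promoters are `[TSS − 1000, TSS + 1000)` with TSS = txStart on the plus
strand and txEnd on the minus strand; intervals are processed in coordinate
order and any interval overlapping a previously accepted one is dropped
(first kept wins), yielding a non-overlapping promoter set.

A merged H3K4me1 region is a putative enhancer iff it shares **no base**
with any promoter interval and its H3K4me3 region score is **strictly
below 1.0**. Classification is a total function of the region scores:

| H3K27ac ≥ 1.5 | H3K27me3 ≥ 1.5 | state |
| --- | --- | --- |
| yes | — | active (dual-marked regions also set an audit flag) |
| no | yes | poised |
| no | no | primed |

Without an H3K27me3 track the poised state cannot be detected; affected
candidates fall back to primed, the score column is NaN, and the pipeline
emits a warning.

## Expression and gene linking

Per-gene expression is the exonic read count normalized to depth and
length: `count × (mean library total / total) × (mean exonic length /
length)`, where a gene's exonic length is the length of the union of its
exon intervals (shared bases counted once). Genes are binarized
expressed/silent at the antimode of the pooled log2(x+1) distribution: a
Gaussian KDE is evaluated on a 512-point grid and the threshold is the
density minimum between the two highest local maxima (midpoint of the
log-range if the density is unimodal). The comparison is inclusive
(`value ≥ threshold` ⇒ expressed).

Enhancers are linked to promoters by midpoint-to-TSS distance, capped at
500 kb, in two passes: all active enhancers first, each to its nearest
promoter; promoters that received an active enhancer are then withheld
while primed and poised enhancers are assigned. Distance ties go to the
promoter with the lower genomic coordinate. Multiple active enhancers may
share one promoter.

## Cross-stage dynamics

A source stage's called enhancer regions are re-scored **at fixed
coordinates** in a later stage's tracks (no re-calling, so boundary drift
is deliberately ignored) and classified: H3K4me1 below cutoff ⇒ *closed*
regardless of other marks (regions keeping H3K27ac without H3K4me1 are
counted closed and reported in a separate audit column); otherwise active
if H3K27ac ≥ 1.5, else poised if an H3K27me3 track is supplied and scores
≥ 1.5, else primed. Repertoire-level comparisons use (i) a binary presence
matrix over the merged union of all stages' regions (an entry is true iff
the union region overlaps ≥ 1 called region of that stage) and (ii)
base-level pairwise Jaccard similarity of the merged repertoires.

## Heterochromatin HMM

H3K9me2 enrichment over consecutive 5 kb windows is modelled by a
two-state hidden Markov chain (state 0 depleted, state 1 enriched) with
per-state Gaussian emissions on the log2 scale. Initialization: start
probabilities (0, 1), stay probability 0.9 in both states, emissions
N(−1, 0.5) and N(+1, 0.5) (variances).

Fitting is Baum–Welch with all recursions in log space. The convergence
check runs immediately after each E-step likelihood evaluation and before
the M-step, so the recorded log-likelihood trace is non-decreasing and its
last entry is the returned model's likelihood; iteration stops when the
relative improvement is ≤ 1e-6 or after 500 iterations. Variances are
floored at 1e-3; an effectively constant input returns a flagged
degenerate model. After fitting, states are permuted so the larger-mean
state is "enriched" (index 1). The model is trained on the first
chromosome and decoded per chromosome genome-wide with exact Viterbi
(argmax ties break toward the lower-numbered state).

Maximal runs of enriched windows become domains; when a coverage mask is
supplied, the decoding is defined over retained windows only and a dropped
window flanked by enriched neighbours is bridged into a single domain.
Chromosome boundaries are never bridged. Stages are compared by an exact
base-level Venn partition computed by coordinate compression (cells sum to
the union size exactly) and by Pearson correlation of the paired
enrichment vectors.

## Synthetic-data generator

All randomness descends from one integer seed. Each subsystem draws from a
child generator keyed by `SeedSequence([seed, crc32(tag)])`, so results do
not depend on the order in which subsystems are simulated.

**Genome and annotation.** Default genome: two chromosomes of 5 Mb. 300
genes are placed with TSSs ≥ 6 kb apart, bodies of 2–10 kb split into 2–5
exons at random breakpoints. 500 enhancers of width 1500 bp are placed ≥ 4
kb from every TSS (which also keeps their merged H3K4me1 regions clear of
promoter-proximal signal) and ≥ 3 kb from each other (so distinct
enhancers never merge into one region).

**Enhancer states.** Each enhancer's state follows a four-state Markov
chain over stages (active, primed, poised, closed) with initial
distribution (0.336, 0.452, 0.012, 0.200) and a transition matrix whose
primed→active entry is 0.04. Three stages are simulated by default.

**ChIP counts.** Window counts are Poisson (optionally negative binomial)
with background mean 40 reads per 1 kb window. Windows overlapping a
feature have their mean multiplied by the mark's fold: H3K4me1 16× at
non-closed enhancers (5× at promoters), H3K27ac 16× at active enhancers,
H3K27me3 12× at poised enhancers, H3K4me3 16× at promoters; folds combine
by maximum. Two replicates per mark (one for H3K4me3) share one input per
stage. Because enhancer/promoter signal occupies a non-trivial fraction of
the small synthetic genome, library-size normalization compresses observed
enrichments below the nominal `log2(fold)`; the default depth and folds
are chosen so that true features sit well above the 1.5 cutoff and
background sits well below it *after* this compression.

**Domains.** Latent domain states follow a two-state chain with stay
probability 0.9 over 5 kb windows, restarted per chromosome. Stages share
one base realization; per stage, a fraction 0.1 of windows is re-simulated
in blocks of 40 windows, so domains are mostly but not perfectly shared.
Emissions are Gaussian with means ±1 and variance 0.5. 15% of enhancers
that transition to closed at stage 2 are placed inside a stage-2 domain
(with a 5 kb interior margin so ±1-window decoding error cannot flip the
overlap); the rest are placed ≥ 5 kb away from any domain.

**RNA.** A gene is expressed with probability 0.95 / 0.5 / 0.1 depending
on whether it has an active / only marked / no nearby enhancer (nearest
TSS assignment). Expressed genes draw negative-binomial counts
(dispersion 0.1) with mean `500 × (exonic length / mean length) × (1 +
0.75 × n_active)`; silent genes have mean 2.

## Numerical choices and limitations

- Enrichment uses the single-ratio `log2` form so the statistic is
  bit-identical to the printed formula.
- HMM forward/backward/Viterbi run entirely in log space; `logsumexp` is
  used for all marginalizations. Zero start probabilities are handled via
  `-inf` log entries.
- Interval arithmetic is exact integer arithmetic on half-open intervals;
  the Venn partition uses coordinate compression, not sampling.
- Binomial-noise comparisons in the test suite use 3-SD bounds, with
  autocorrelation-adjusted effective sample sizes where windows are
  serially dependent.
- Limitations: the generator paints rectangular signal (no shoulders or
  fragment-length smearing), uses a shared input per stage (no
  replicate-specific input), simulates mappability-free uniform
  background, and couples expression to enhancer counts through a single
  multiplicative boost. The HMM assumes homoscedastic Gaussian emissions
  per state; heavy-tailed enrichment noise would call for a different
  emission family. Enhancer-promoter assignment is purely distance-based
  and ignores insulation or contact data.
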
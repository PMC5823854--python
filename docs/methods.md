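# Methods

This note documents the statistical procedures implemented in
`allelescan`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical conventions
that make results reproducible bit for bit.

## Coordinates and formats

Intervals are 0-based half-open (BED convention); variant positions are
1-based in tables (VCF convention) and converted to 0-based indices only
at sequence-indexing boundaries.  PWMs are read from MEME minimal motif
files; probabilities are regularized as `(p + c) / (1 + 4c)` with
pseudocount `c = 0.001` and renormalized per position, which keeps every
log-odds score finite.  The MEME parser is hand-written because the
error contract (reject probability rows that do not sum to 1 within
0.01 *before* regularization) needs the raw values, which general motif
libraries normalize away on input.

## Zygosity calling and discSNPs

A site is callable only above a minimum depth (default: more than 5
reads).  Above it, the variant read fraction is banded: ≥ 0.9 homozygous
variant, ≤ 0.1 homozygous reference, 0.35–0.65 heterozygous, anything
else ambiguous.  The bands deliberately favour precision over recall —
a miscalled discSNP contaminates every downstream allele comparison,
while a dropped site merely shrinks the event set — and they are
configurable (`ZygosityThresholds`) because reasonable callers differ
here.

Ambiguous calls are rescued by block smoothing: consecutive calls with
gaps up to 50 kb are greedily merged into candidate blocks, and a block
with at least 10 calls of which at least 90% are homozygous variant has
its ambiguous members reassigned to homozygous variant.  Greedy
run-merging replaces a full segmentation algorithm; it honours the same
block contract, is idempotent, and needs no extra dependency.  Maximal
gap-limited runs cannot overlap, so no tie-break between blocks is ever
exercised.

A discSNP requires one line homozygous variant and the other homozygous
reference; two lines homozygous for *different* variants at one site do
not qualify (no allele is the reference context).  A site absent from
one line's table counts as homozygous reference there only when that
line's pileup covers it with at least 6 reads; otherwise the site is
skipped rather than inferred from missing data.  A discSNP is flagged
`isolated` when no other discSNP lies within 1 kb — isolated events are
the cleanest single-variant comparisons.

## Motif-disruption scoring

Scores are log2 odds against a uniform 0.25 background (bits), summed
per position; both strands are scanned and placements containing N are
skipped.  For each (discSNP, motif) pair, a 40-bp window centred on the
SNP (clipped at contig ends) is enumerated over all SNP-containing
placements and strands, and the placement maximizing the *better*
allele's score is selected, so the intact motif anchors the comparison
and disruption is measured as loss relative to the best intact match.
Placement ties (scores equal to 1e-9, which also absorbs float
summation-order noise) go to the earliest start, then the forward
strand.  `position_in_motif`, intact and variant bases are reported in
motif-strand orientation.

Disruptions are called at `Score_max ≥ 7.5` and `DiffScore ≥ 2.5`.
Because the bit scale of a PWM score depends on the scoring convention,
these are configuration defaults, not physical constants.  They can be
re-derived by `optimize_thresholds`: per run, thresholds start uniform
in [0, 20] × [0, 10] and take Gaussian steps (sd 0.5, 150 steps),
accepting a step only when the objective improves; the objective is the
median percent signal loss of called events on held-out folds (10-fold
assignment) plus a small coverage bonus (5 percentage points per unit
called fraction), invalid when fewer than 20 events are called.  The
coverage term matters: the median loss is identical for every threshold
pair that calls only truly lossy events, so without it the walk wanders
a plateau; with it, the optimum is the *least stringent* thresholds
achieving maximal median loss, which is the boundary one wants.  The
final estimate is the element-wise median over 100 runs, and a
`converged` flag records whether any step was ever accepted (it is not
on effect-free data).

Family merging (e.g. all GATA-family PWMs into one event per discSNP)
keeps the member with the highest `Score_max`, breaking ties by higher
`DiffScore`, then lexicographic motif id.  Motif enrichment between two
peak sets is a per-motif Fisher exact test on presence/absence (a peak
is positive when any placement reaches `Score_thres`), BH-corrected
across motifs — a deliberately simple replacement for specialised motif
enrichment suites, preserving the foreground-vs-background contract.

## Signal normalization and impact statistics

ChIP intensity is `max(0, ip·(ref/lib_ip) − input·(ref/lib_input))`
with `ref` the mean library size; accessibility uses library scaling
followed by rank-mean quantile normalization (ties receive the mean of
the quantile means at their average ranks).  Flooring at zero prevents
negative intensities from producing undefined percentages.

Percent residual binding is `100 · I_disrupted / I_intact`.  Events
whose intact-allele intensity falls below ε = 1.0 normalized units are
excluded — with a near-zero denominator the ratio is numerically
meaningless — as are events whose alleles tie in motif score (no
disrupted allele is defined).  An alternative convention, loss relative
to the *stronger signal* allele rather than the motif-intact allele, is
available by passing the per-event intensities accordingly; the default
keeps the motif-based definition so that sign conventions follow the
sequence, not the noise.

Groups (by motif, position, variant base, distance bin or peak class)
of at least 5 events are summarized by the median residual, a bootstrap
95% CI (percentiles of 1,000 resampled medians), and a two-sided
one-sample Wilcoxon signed-rank test against 100%; an all-identical
group reports p = 1.  Multiple testing uses maxT label permutation:
group labels are shuffled over the pooled events (sizes preserved),
all group p-values recomputed per permutation, and the minimum recorded;
`q = (1 + #{null min-p ≤ observed p}) / (N + 1)` with N = 1,000, the +1
smoothing avoiding exact zeros.  Inside the permutation machinery both
observed and null p-values come from the same vectorized normal
approximation of the signed-rank test (tie- and zero-corrected,
Pratt-style); maxT only requires that observed and null p-values be
computed identically, and the vectorization is what makes a
1,000-permutation × many-group analysis interactive.  Because the null
is built from the pooled events, the correction is conservative when
*most* groups carry real effects — the permuted null is then
contaminated by true signal, and only the strongest groups survive.
This is visible in the worked example and is a property of the method,
not a defect.

Distance effects use sliding bins `[s, s + 10)` for s = 0, 5, …, 95 —
exactly 20 bins covering 0–100 bp, each event falling in up to two —
with distance defined as the edge-to-edge gap (0 when intervals
overlap).  Peak breadth classes: occupied in more than 60% of tissues =
constitutive; fewer than 20% = variable; variable peaks occupied in all
erythroid and no non-erythroid tissues = erythroid-specific; of those,
absent in the undifferentiated and present in the differentiated member
of every differentiation pair = differentiation-induced.

Correlations use Pearson's r with Fisher-Z confidence intervals
(`z ± 1.96/√(n−3)`) and z-difference comparison tests.  The
binding-vs-expression curves threshold peaks on a differential-binding
q computed by a two-sided binomial test of allele IP counts against the
library-size ratio, BH-corrected — a lightweight stand-in for a full
dispersion-modelled differential-binding test that preserves the
contract (a per-peak q to threshold on).

## CRISPR deletion scanning

Reads are globally aligned to the wild-type amplicon with affine gap
penalties: gap open 10, gap extend 0.5, match +5, mismatch −4 (standard
DNA scoring), a gap of length L costing `open + (L−1)·extend`, end gaps
penalized.  The alignment is computed by Biopython's `PairwiseAligner`;
the test suite verifies it against an independent brute-force dynamic
program under the same convention.  Identity counts identical columns
over the full alignment length.  Reads at ≤ 80% identity are discarded;
a read with no gaps is wild type; exactly one reference gap and no
insertions is a single-deletion allele; everything else is discarded.

Alleles are tallied by exact deletion interval (off-by-one deletions
are distinct).  Per replicate, enrichment is
`(ip_d / ip_WT) / (input_d / input_WT)` — the wild-type ratio is 1 by
construction — then averaged across replicates.  Alleles with input
counts below 50 reads in any replicate are flagged low-coverage and
excluded from statistics; the threshold is configurable since it trades
noise against yield.  Deletion–motif overlap is classified full /
partial / none, and 1–2-bp deletions are assigned to every 2-bp window
they intersect (step 1 bp), each window tested one-sided for
enrichment < 1.

## Contextual binding prediction

Positives are anchor-motif hits inside peaks; negative candidates are
hits outside all peaks whose library-normalized IP count in the 400-bp
window around the hit does not exceed the normalized input count (no
evidence of binding).  Negatives are greedily matched 1:1 to positives
by Euclidean distance in 20-dimensional composition space (4 mono- +
16 di-nucleotide frequencies of the hit ± 100 bp), without replacement
— greedy nearest-neighbour is deterministic and adequate at these set
sizes.  Peaks containing anchor-motif discSNP disruptions are excluded
from both classes, since their binding status is confounded by the
variant itself.

Features are the anchor score plus, per contextual motif, the best
log-odds score among placements within 100 bp edge-to-edge of the
anchor (0 when nothing reaches the score floor — the natural "no
match" encoding that keeps the model linear).  Contextual motifs are
admitted only when they beat column-shuffled versions of their own PWM
(shuffling positions preserves per-position information content
exactly) in more than 90% of runs × shuffles, each run re-drawing the
negative set; inside this selection loop a single CV repetition is used
per fit for tractability, while final model comparisons use the full
10 runs.  Models are plain maximum-likelihood logistic regressions
(ridge available for separable corner cases), evaluated by stratified
10-fold cross-validation with out-of-fold probabilities pooled into one
ROC per run and 10 runs of re-drawn folds.  AUC differences are tested
with DeLong's paired method on per-example out-of-fold scores averaged
across runs (DeLong requires one paired score per example; runs are not
independent replicates).  `sensitivity_at_fdr` scans unique score
thresholds in descending order and reports the best sensitivity whose
empirical FDR `FP/(FP+TP)` stays at or below the target.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
as a pure function of configuration and seed:

- **Genomes**: one contig, widely spaced 200-bp peaks (central summit),
  each carrying one anchor-motif consensus at its summit; discSNPs are
  substitutions (never indels), so both lines share one coordinate
  system.  Motif SNPs land at configured offsets and replace the
  consensus base with the lowest-probability alternative; background
  SNPs are drawn from a >1-kb-spaced grid so every planted SNP is
  isolated.  The disrupted line is chosen at random per SNP.
- **Pileups**: depth ~ Poisson(mean depth); variant reads ~
  Binomial(depth, 1−e) at a line's variant sites and Binomial(depth, e)
  at its reference sites.
- **ChIP counts**: negative binomial with Var = μ + αμ² (default
  dispersion α = 0.2, a typical ChIP-seq overdispersion; α = 0 gives
  the Poisson limit used by oracle tests).  The IP mean is
  `lib × (background + base × Π effects)` where the background equals
  the input library's mean (default 5% of base intensity) and the
  multiplicative effects come from the line's disrupted motifs;
  contextual effects apply only when the planted context motif lies
  within its active distance window.  Modelling the IP mean as
  background *plus* signal (rather than scaling the whole IP mean)
  makes input subtraction unbiased, so percent residual binding
  recovers the planted effect exactly in expectation; with zero
  background the two parameterizations coincide.
- **Deletion libraries**: deletion lengths ~ Poisson around 26 bp
  centred near the motif; input counts multinomial over allele
  abundances (wild type up-weighted), IP counts multinomial with
  probabilities ∝ abundance × retention (default retention 0.05 for
  full motif deletions, 0.3 partial, 1.0 non-overlapping); reads are
  the amplicon with the deletion applied.
- **Binding sites** (for the predictor): anchor instances sampled from
  the anchor PWM's own distribution, a context consensus planted within
  100 bp in a configurable fraction of sites, and labels Bernoulli with
  logit = intercept + 0.5·anchor score + 1.5·context indicator.  The
  defaults give roughly balanced classes, an anchor-only AUC around
  0.65 and a clear contextual gain — a regime where context matters but
  does not trivially separate.

What the generator does *not* emulate: read-level alignment artefacts
(mappability, duplicates, fragment-length effects), GC or accessibility
bias, heterozygous sites, trans-environment differences between lines,
and correlated noise between IP and input.  Passing tests therefore
demonstrate that the statistical machinery is correct under its stated
assumptions, not that those assumptions hold in any particular real
dataset.

## Numerical conventions and edge cases

- Signed-rank tests on all-identical values report p = 1 rather than
  erroring; degenerate Fisher tables report odds ratio NaN.
- Bootstrap and permutation machinery derive all randomness from
  explicit integer seeds; every simulation function is deterministic
  given (config, seed).
- The problem sizes used by the statistical test suite (2,000 peaks ×
  100 replicates for effect recovery; 200 replicates × 1,000
  permutations for error control; 4,000 sites for the predictor;
  10,000 sites for variant calling) were chosen to bound the
  Monte-Carlo error of each check well below its assertion margin.

## Known limitations

- The zygosity bands are stand-ins exposed in configuration; with the
  default 0.9 homozygous-variant band, a site with an unlucky cluster
  of sequencing errors (e.g. 3 errors in 29 reads) is flagged ambiguous
  by design — at 0.3% error this affects roughly 6 sites per 100,000.
- maxT q-values are conservative when most groups carry true effects
  (contaminated permutation null); interpret q jointly with the
  bootstrap CIs in that regime.
- The greedy composition matcher does not guarantee globally optimal
  matching; at the set sizes used here the residual composition gap is
  far below biologically meaningful differences.
- The deletion scanner keys alleles by aligned deletion interval; in
  repetitive sequence, distinct deletions producing identical reads are
  indistinguishable and collapse onto one canonical interval.
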
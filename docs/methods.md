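# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## The prediction problem

Trans (inter-chromosomal) Hi-C contacts are sparse: they account for a
minority of read pairs spread over a much larger coordinate space than cis
contacts, so single-experiment counts are unreliable. The package therefore
frames trans-contact prediction as binary classification over pairs of
100 kb genomic windows (5 kb at toy scale), with labels derived from
replicate consensus rather than from any single contact map.

## Replicate-consensus labels

Ten replicate experiments are split into a *labels* group and a
*predictions* group of five donors each. Within the labels group:

1. **Coverage filter.** The five matrices are summed and bins in the top
   0.1% and bottom 1% of genome-wide trans coverage are removed (both
   fractions configurable). Ranking ties break by global bin index —
   bottom set takes the lowest indices, top set the highest — so the mask
   is deterministic. The same mask is applied to the prediction group.
2. **Positives.** A trans bin pair is positive when it has count ≥ *i* in
   ≥ *m* of the five replicates.
3. **Negatives.** Within each chromosome-pair map, rows and columns that
   are empty in the summed label-group matrix are dropped (those loci
   never interact with the partner chromosome); remaining pairs with
   count ≤ *j* in ≥ *n* replicates, and not already positive, are
   negative.

The operating point (*i*=2, *m*=3, *j*=1, *n*=4 at 100 kb) is selected by a
sweep: each candidate labels the data, the summed prediction-group count
ranks the labeled pairs, and the candidate's AUROC is recorded. Ties break
toward fewer labeled pairs, then lexicographically. Candidates producing an
empty class are flagged and excluded from the argmax. The (TPR, FPR) of one
group's labels scored against the other's bounds achievable performance;
it is computed on pairs labeled by both groups.

Cross-validation folds partition chromosomes (19/2/2 at genome scale,
proportional at toy scale, Y and mitochondrial chromosomes excluded by
default), and pairs are formed only within a set so no chromosome leaks
across sets.

## Network

Both windows pass through one shared 1D convolutional encoder organized as
block pairs: a non-linear block (two convolutions, each followed by batch
normalization and ReLU) and a linear block (max-pool, then two
convolution + batch-norm stages without activation). Pool factors across
the pairs multiply to `window_bp / 5`, leaving a latent of 128 channels × 5
positions at full scale. The two latents A and B combine by **outer
addition**, `z[c, p, q] = A[c, p] + B[c, q]`, lifting the pair into a 2D
interaction tensor that a stack of dilated 3×3 convolutional block pairs
decodes. The classification head is a 1×1 convolution to one channel, a
spatial mean, and a sigmoid, giving a contact score in (0, 1). The
regression variant takes 640 kb windows (eight encoder pairs), skips the
sigmoid, and emits the 5×5 block of log observed-over-expected values at
128 kb resolution.

The non-linear block precedes the linear block within each pair, so the
first convolutions see base-resolution sequence before any pooling; this
conv-before-pool order follows the architecture lineage the encoder is
derived from and is what lets first-layer filters act as motif detectors.
An optional `first_conv_kernel` widens only the very first convolution
(default 11 at toy scale) so a single filter spans a complete ~10 bp
binding site.

Default full-scale widths: encoder channels ramp 32→64→96→128 (kernel 5,
pools 5,5,5,5,2,2,2,2,2,1) and the 19 decoder pairs use 76 channels
(kernel 3, dilation doubling 1…64 then cycling). These defaults realize
6,546,733 trainable parameters — 6.5 M at one decimal — counted
analytically per layer (`analytic_parameter_count`) and verified against
the instantiated tensors. A 128-wide decoder, for comparison, would alone
cost ~11.2 M parameters.

The network, backpropagation and the Adam optimizer are implemented
directly in NumPy (float32): stride-1 same-padded convolutions via strided
tap views and einsum, with downsampling confined to pooling layers so
every input gradient is again a stride-1 convolution with the
channel-transposed, tap-flipped kernel. All layer gradients are verified
against central finite differences in the test suite.

## Training

Classification minimizes binary cross-entropy (scores clipped at 1e-7)
under Adam with betas (0.9, 0.999) and no weight decay; batch 16; at full
scale the reference learning rate is 1e-2 (the toy runs use 2.5e-3, which
is stable for the much smaller network). Batches are sampled dynamically:
class-balanced by default (uniform-over-pairs retained as a mode), windows
fetched from the one-hot store at batch time, and each pair's orientation
randomized (contact is symmetric in window order). Validation average
precision is computed every 200 batches on a fixed seeded subsample and
the best state is checkpointed. Regression minimizes mean squared error at
learning rate 9e-4 over 5×5 target blocks.

Evaluation: ROC/AUROC (trapezoid over a descending unique-threshold sweep;
ties move together) and average precision via scikit-learn; AUROC equals
the normalized Mann-Whitney U statistic, which the tests verify against a
pair-counting oracle. The GC baseline scores a pair by the mean GC
fraction of its two windows. Spearman correlation is the Pearson
correlation of mid-ranks. Chromosome-pair score grids reuse each locus
embedding (encode once, decode all pairs), which is numerically identical
to pairwise forward passes.

## Compartments

A/B calls per chromosome follow the standard eigenvector pipeline:
distance-expected o/e on the cis map (expected = mean count per diagonal,
zero-expected diagonals masked), Pearson correlation matrix over unmasked
bins, PCA, and sign orientation of each eigenvector so GC-rich bins score
positive. The first eigenvector is used when its Pearson correlation with
the per-bin ATAC signal exceeds 0.30 (guarding against whole-arm
solutions); otherwise the second; if neither passes, the first is used
with a warning. Per-bin ATAC signal is the peak-coverage fraction at the
working resolution. Five donor tracks combine by majority vote — at least
four agreeing donors (NA donors shrink the pool), 3–2 splits become NA.
Trans pairs stratify symmetrically into AA, AB/BA, BB (NA if either side
is NA), and ROC metrics are computed per stratum.

## Interpretation

**Substitution experiments.** Test-set locus pairs are ranked by predicted
score; the top 10% and next 30% (floor sizes, coordinate tie-break) form
donor and recipient sets. Accessible-peak intervals are intersected with
the donor windows, merged where overlapping, and the donor's bases are
copied into the same offsets of a randomly drawn recipient pair
("insert"), or replaced by the recipient's bases in the donor pair
("strip"). Donors without peak overlap are skipped. Reported: per-pair
before/after scores, the fraction that increased, and the mean change.

**Integrated Gradients.** Midpoint-Riemann path integral from an all-zero
one-hot baseline (the absence-of-sequence reference) to the input, applied
jointly to both windows; 128 steps by default. For classification networks
the attributed quantity is the pre-sigmoid logit: up to the sigmoid the
network is piecewise linear, so the completeness identity (attributions
sum to F(input) − F(baseline)) holds to well under 0.1% at 512 steps, and
the monotone sigmoid preserves importance ordering. Per-base importance is
the attribution summed over the four channels.

**Motif enrichment.** Motifs (MEME minimal format) are scanned over
accessible intervals with the summed log-odds `log2((p+c)/(bg+c))`
(pseudocount c = 0.001), both strands, scores discretized at 1/1000 bit;
p-values come from the exact dynamic-programming null over the 0-order
background (convolution of per-position score distributions), thresholded
at 1e-5. Positions containing an ambiguous base are skipped. Decoys
shuffle each motif's columns (content intact). Each occurrence gets the
median per-base importance over its span; per motif a right-tailed
Mann-Whitney U test (exact null for group sizes ≤ 25, asymptotic
otherwise) compares real vs decoy occurrences, with Benjamini-Hochberg
control at α = 0.01 across motifs. Motifs with fewer than five
occurrences on either side are reported untested.

**G-quadruplexes.** Greedy non-overlapping regex matches of
`G{3,}N{1,7}G{3,}N{1,7}G{3,}N{1,7}G{3,}` (the C-run mirror on the reverse
strand; both strands by default). Pairs split into contact (score > 0.5)
and no-contact (score ≤ 0.5; exact 0.5 goes to no-contact) groups; G4
counts summed over both windows are compared by a right-tailed U test and
summarized by the AUROC of counts against the grouping.

## Synthetic data generator

The generator emulates the study's data shapes with a known ground truth:

- **Genome.** Six (default) to sixteen 400 kb chromosomes of iid sequence
  at GC 0.41. Each 5 kb window carries motif X with probability 0.25 and
  motif Y independently with probability 0.25; motif windows always get a
  500 bp accessible interval (emitted as a BED peak; motif-free windows
  get one with probability 0.3). Motif windows receive 1 + Poisson(4)
  non-overlapping instances sampled from a strength-0.997 consensus PWM,
  95% of them inside the peak — a clustered-binding profile.
- **Contacts.** Pair contact probability is
  `logistic(-5 + 7.5·co-occurrence)` where co-occurrence means X in one
  window and Y in the other, in either order (stored pairs are
  chromosome-ordered, so the rule must be order-symmetric); an optional GC
  term is off by default. The contact indicator is drawn once per pair and
  shared by all replicates of both donor groups; each of the five
  replicates per group then draws counts Poisson(6) at contacting pairs
  and Poisson(0.3) elsewhere. All randomness derives from the spec seed;
  artifacts are byte-identical across runs.

What this does *not* emulate: cis distance decay, matrix-balancing
artifacts, chromosome territories, repeats, or realistic motif libraries.
Passing the end-to-end recovery therefore shows that the pipeline wiring —
labels, sampler, optimization, evaluation, interpretation — behaves
correctly on data obeying its assumptions; it says nothing about
performance on real Hi-C.

**Problem sizes.** The end-to-end demonstration uses sixteen chromosomes
with a 10/3/3 chromosome split and ~1,400 training batches. Two findings
fixed these sizes: chromosome-disjoint trans evaluation needs at least two
chromosomes per set, and motif-rule learning (as opposed to window
memorization) emerges only with roughly a thousand distinct training
windows and several motif instances per positive window — with a few
hundred windows the network memorizes window identities and generalizes at
chance, which is the expected small-data failure mode of sequence CNNs.
A separate checkerboard simulator emits compartment-structured cis maps
(two interleaved block colorings, 1/(1+d) distance decay, within/between
enrichment 2.0/0.5, GC and ATAC signals elevated in A blocks) for testing
the compartment caller.

## Numerical choices and degenerate inputs

- Ambiguous bases map to zero one-hot rows and are excluded from GC
  denominators; an all-N window has GC 0.
- o/e log normalization uses a pseudocount of one raw count,
  `ln((o+1)/(e+1))`, bounding the transform at zero-observed cells;
  normalization requires a positive expected scalar.
- Empty TSVs load as all-zero maps; negative counts and off-grid
  coordinates are errors; windows may not cross chromosome ends (no
  padding).
- Sweep candidates with an empty class are flagged NaN and skipped; label
  parameters must satisfy i > j ≥ 0 and 1 ≤ m, n ≤ replicate count.
- Batch-norm inference uses running statistics (momentum 0.1); training
  aborts on non-finite loss with diagnostics.
- The reproducibility point requires non-empty denominators; single-class
  metric computations raise rather than return a default.

## Known limitations

- CPU-only NumPy training: practical up to the toy scale; the full-scale
  network is instantiated (for architecture work and parameter counting)
  but not trained here.
- The regression variant is exercised on synthetic targets; no real
  micro-C preprocessing beyond the o/e log pipeline is included.
- Matrix balancing is consumed, never performed; `.hic` binary input is
  not supported (cooler-style HDF5 and a TSV dialect are).
- The compartment caller approximates the external PCA tool it stands in
  for by the standard o/e → correlation → PCA pipeline.
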
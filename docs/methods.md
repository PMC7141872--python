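# Methods

## Problem setting

Phage-display panning iteratively selects antibody Fab fragments that bind
an immobilized target. Sequencing the pool after each round gives per-round
read counts for every CDR-H3 sequence, and the log10 ratio of a sequence's
frequency between consecutive rounds — its *enrichment* — is a quantitative
readout of selection, hence of binding. This package (i) learns a
differentiable model of enrichment from such count tables, (ii) uses
gradients of that model with respect to the sequence encoding to design
improved CDR-H3 sequences, (iii) filters designs predicted to bind
off-targets, and (iv) explains predictions through sufficient input
subsets. A panning simulator with a known ground-truth affinity landscape
makes every stage testable end to end.

## Sequence encoding

CDR-H3 loops of length 10–18 over the 20 canonical residues are encoded as
a fixed 20-position x 20-channel matrix: the sequence occupies the leftmost
positions (one 1 per column), trailing positions are all-zero padding.
There is no dedicated padding channel; padding and masking share the
all-zero column. During design the 0/1 constraint is relaxed: the matrix
takes arbitrary real values between projections, and a discrete sequence is
recovered by per-position argmax (ties broken toward the lowest channel
index, for determinism).

The 20x20 input shape and the padding convention are fixed by arithmetic:
they are the unique simple convention under which the six reference
architecture parameter totals (13 954, 8 402, 18 706, 16 754, 7 122,
13 082) are reproduced exactly, layer by layer. Left- vs right-alignment of
padding is not pinned by that arithmetic; left-justification was chosen
once.

## Enrichment

For a count table with per-round totals `N_r`,
`freq[s][r] = count[s][r] / N_r` and
`enrichment(s, r -> r') = log10(freq[s][r'] / freq[s][r])`. The sign of
enrichment doubles as the classification label; exactly zero counts as
non-positive everywhere. Frequencies are always computed on unfiltered
totals, so filtering never changes a surviving sequence's value, and all
enrichments are invariant under rescaling every round's counts.

The filter policy defaults to: require at least 1 read in the earlier
round; sequences absent from the later round receive a pseudo-count of 1
there (configurable to a different pseudo-count, or to dropping such
sequences). The pseudo-count keeps negatively enriched sequences finite —
both directions of enrichment are modeled — at the cost of a floor effect
for sequences that vanish; under strong selection that floor can distort
the low-affinity tail, which is why the minimum-count threshold is exposed.

## Architectures

Six small networks over the 20x20 input, with reference parameter totals
reproduced exactly:

| name | layers | parameters |
|---|---|---|
| Seq_32_32 | dense 400-32-32, dropout each | 13 954 |
| Seq_32x1_16 | conv w5x32, pool, dense 16 | 8 402 |
| Seq_32x2_16 | conv w5x32, pool, conv w5x64, pool, dense 16 | 18 706 |
| Seq_64x1_16 | conv w5x64, pool, dense 16 | 16 754 |
| Seq_32x1_16_filt3 | conv w3x32, pool, dense 16 | 7 122 |
| Seq_embed_32x1_16 | conv w1x8 (no pool), conv w5x64, pool, dense 16 | 13 082 |

Conventions: convolutions are length-preserving ('same', stride 1);
max-pooling is window 2, stride 2, 'valid'; each hidden dense layer is
followed by ReLU and dropout; the default head has two units — an
enrichment regression output and a sign-classification logit. The
embedding network's width-1 layer is not followed by pooling and its second
convolution has 64 filters; these two choices are required by the 13 082
total. The multi-output variant replaces the head with one regression unit
per target and masks missing targets out of the loss, so a fully missing
target reduces training exactly to the remaining targets.

The networks, backpropagation and the Adam optimizer are implemented
directly on numpy. This is deliberate: the design method *is*
backpropagation to the input layer of a frozen network, so the same
machinery serves training (gradients w.r.t. weights) and design (gradients
w.r.t. the relaxed input).

## Training

Loss = squared error on enrichment + logistic loss on its sign, equally
weighted by default. Adam at learning rate 1e-3, batch size 64, up to 100
epochs, early stopping on a 10% validation split with patience 10, best
weights restored. All randomness (init, subsampling, shuffling, dropout)
derives from integer seeds, making training bit-reproducible. Default
dropout is 0.2: with 16-unit hidden layers and desk-scale training sets,
0.5 underfits the convolutional models severely; the rate is config-exposed.

## Ensemble

The canonical ensemble trains each of the six architectures on each of
three random 80% subsamples of the observations (shared across
architectures, distinct member seeds): 18 members. The ensemble prediction
is the arithmetic mean of member regression scores; uncertainty is the
across-member sample variance (0 for a singleton by convention); the
pessimistic score is `upper95 = mean + 1.96 * sd`. Whether the original
subsets were folds, bootstraps or replicate-derived splits is not derivable
from the parameter arithmetic; random 80% subsampling was chosen once,
with bootstrap as a config alternative. Calibration is reported as the
Spearman correlation between per-example variance and squared error plus a
variance-decile MSE table; identical members are flagged as degenerate
rather than scored.

## Gradient-ascent design (Ens-Grad)

From a seed's one-hot encoding: take `k` plain ascent steps
`x <- x + lambda * grad` on the unconstrained relaxed matrix, project to a
sequence by restricted per-position argmax, score the projection, repeat;
stop when the projected score has not improved the best (strict `>`) for
`patience = 10` consecutive projections, or at a safety cap
(`max_iterations = 1000` by default; hitting it is flagged in the trace).
The best is initialized from the seed itself, so a returned design never
scores below its seed under the optimizing objective.

Residue channels for cysteine and asparagine (sequence liabilities)
receive zero gradient and are excluded from projection, so designs never
introduce them. Positions beyond the seed length are frozen: design is
substitution-only and length-preserving. No simplex renormalization is
applied between projections (a simplex mode exists but is off by default)
— the relaxation is genuinely unconstrained. The objective can be a single
member or the ensemble mean (default).

Library proposal pools the best projection per seed per (lambda, k) grid
point (default grid lambda in {0.1, 0.5, 1.0}, k in {1, 5, 10}),
deduplicates against seeds and within the pool, then applies the two-step
filter: (1) voting — keep candidates scored strictly above their own seed
by at least `vote_rule` members (default: strict majority); (2)
thresholding — keep survivors with ensemble mean >= `score_threshold`
(default 0), sorted by descending mean with lexicographic tie-break,
truncated to the budget. Seeds are sequences with non-negative
round-2-to-round-3 enrichment or final-round frequency strictly above
5e-5.

## Specificity filter

Binder classes follow the four-target sign table: target-specific
(positive focal, non-positive elsewhere), Fc binder (positive on every
Fc-containing target, non-positive on the Fc-free one), non-specific
(positive focal plus some off-target), non-binder otherwise. The filter
rejects a candidate when the multi-output ensemble's `upper95` is positive
for *any* off-target; rejections name the triggering target(s). The rule
is monotone: lowering an off-target bound can only turn a rejection into a
keep.

## Sufficient input subsets

A sufficient input subset (SIS) at threshold `tau` (default 0.4 log10
units) is a set of positions whose residues alone — all others replaced by
the all-zero mask column — keep the prediction at or above `tau`. Backward
selection repeatedly masks the position whose removal hurts the prediction
least; the subset is the shortest suffix of the removal order that
restores `tau`, then pruned so removing any single remaining position
drops below `tau` (greedy minimality, re-verified for every emitted
subset). Disjoint further subsets are extracted by re-running on the
residual masked input; the returned family is ordered by descending masked
prediction. The zero mask matches the encoder's padding semantics; a
training-mean mask column is available as an alternative.

## Panning simulator

The generator supplies the statistical structure the method assumes, with
a known ground truth:

- **Library**: i.i.d. uniform-residue sequences, lengths 10–18 uniform by
  default.
- **Landscape**: additive per-position/per-residue weights (10% nonzero,
  normal scale 0.5) plus two pairwise motif bonuses (+1.0) — realized
  enrichments span roughly -1.5 to +1 log10 under the default selection
  strength, the dynamic range a real campaign shows.
- **Selection**: round `r` counts are multinomial draws of the configured
  depth from probabilities proportional to `counts_{r-1} * exp(beta * score)`.
  Round 1 is by default the unselected starting pool (pure resampling);
  selection acts from round 2 onward. `beta = 0` is the mock-panning null:
  enrichment centered at zero, sampling noise only.
- **Replicates**: the final round is re-drawn under a landscape perturbed
  by independent Gaussian noise of scale `sigma_rep` per sequence;
  `sigma_rep = 0` leaves only sampling noise, and moderate values
  (~0.3) put replicate consistency in the 0.6–0.95 Pearson range
  observed experimentally.

What the simulator does *not* emulate: display/propagation bias,
amplification chimeras, sequencing error, length-changing mutations, and
any real biophysics — the landscape is an arbitrary sparse additive
function. Passing benchmarks therefore demonstrate that the pipeline
recovers and optimizes the signal its own generative assumptions encode,
not that it would achieve any particular accuracy on a real campaign.

## Benchmark problem sizes

The bundled benchmarks use desk-scale conditions chosen once: single-model
prediction, 5 000-sequence library at depth 1e5 and beta 1; ensemble and
calibration benchmarks, 2 000-sequence campaigns (calibration holds out
2 000 sequences from a larger one); design, 200 seeds with a 500-sequence
budget; specificity, a 6 000-sequence pool with 500 planted candidates
(rejection-sampled fresh sequences, never seen in training) labeled by
their noise-free infinite-depth enrichment — above +0.2 log10 on either
off-target for cross-reactive, below -0.5 on both for specific. The
specific margin is wider because the upper-bound rule deliberately
rejects anything within ~2 member standard deviations of zero: a planted
specific candidate must sit decisively outside that band. Optimizer and
SIS oracles use 100 random separable instances each.

## Known limitations

- On the position-additive default landscape the dense architecture
  dominates the convolutional ones (pooling smears position information),
  so the 18-member ensemble mean reliably beats the *average* member (an
  algebraic guarantee) but typically not the single *best* member. With
  real panning data, where members are closer in quality, the mean is
  expected to win across the board.
- The pseudo-count policy assigns enrichment `-log10(c)` to sequences that
  vanish after round `r` with count `c`, compressing the negative tail.
- Gradient ascent with a long projection interval on a near-linear
  objective effectively converges in one projection; on rugged learned
  objectives small `k` with many projections explores more and diverges
  further from seeds, which is the intended use of the (lambda, k) grid.
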
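# Methods

## Binding-matrix encoding

A pair is a miRNA standardized to exactly 20 nt (5′-anchored: longer
sequences are truncated after position 20, shorter ones N-padded at the
3′ end; at least 6 nt are required so a seed region exists) and a 50-nt
target window. Windows are cut from genomic intervals as `[c−25, c+25)`
with `c = ⌊(start+end)/2⌋` in 0-based half-open coordinates,
reverse-complemented for minus-strand intervals and N-padded where a
sequence boundary truncates them. T is mapped to U and case folded
everywhere, since targets typically come from DNA references.

The encoder emits a 20×50 grid of indicators over Watson–Crick pairs
only ({A:U, U:A, G:C, C:G}); G:U wobble is deliberately not marked, and
any position involving N never pairs. Rows index miRNA positions and
columns target positions, both 5′→3′ and neither strand reversed inside
the encoder. The literature writes this grid both as 20×50 and as
50×20; the row/column convention here is a documented package choice
and `encode_pair(..., orientation="target_rows")` yields the transpose.

## Scorers

Two architectures map the (1, 20, 50) matrix to a binding probability
through a single sigmoid unit:

* **CNN** — six blocks of (5×5 convolution → leaky ReLU (α = 0.1) →
  batch normalization → optional 2×2 max pool → dropout), then two
  dense blocks, then the sigmoid head. Full-profile defaults: channels
  (32, 32, 64, 64, 128, 128), dense (128, 64), dropout 0.3, Adam with
  learning rate 0.00152, 10 epochs, batch size 32, binary cross-entropy.
* **Residual network** — the conventional 7×7 stem convolution and stem
  pooling are removed: on a 20×50 input they would shrink the feature
  map below what later blocks need, so the first operation is a 3×3
  residual-stage convolution. Stages of two-convolution residual blocks
  (1×1 projection on channel changes) are separated by 2×2 max pooling,
  with global average pooling before the head.

Both train with Adam on cross-entropy evaluated against possibly *soft*
targets, so hardness-smoothed labels need no separate loss. Inference
is deterministic (dropout off, batch-norm running statistics), scores
are batch-size invariant to 1e-6, and all randomness flows from a
single integer seed.

**Desk profile.** CPU-scale presets (`CNNConfig.desk()`,
`ResNetConfig.desk()`) narrow the channels to (8, 12, 12, 16, 16, 16)
/ dense (32, 16) (~26k parameters), raise the Adam step to 0.01 and
relax dropout to 0.15. Both changes address the same failure mode: at
desk widths and desk sample sizes (hundreds rather than tens of
thousands of positives), the full-profile step size and dropout leave
the optimizer stuck at the constant-prediction plateau — training-loss
ln 2, chance-level ranking — for its whole epoch budget, and whether
it escapes becomes an initialization lottery. The full-profile
hyperparameters are unchanged.

**Balanced minibatches.** `train(..., balance_batches=True)` builds
each batch half from positives (resampled with replacement) and half
from negatives (cycled without replacement), keeping the epoch size at
the dataset size. Whether published 1:k training sets reused each
positive once or oversampled positives is not documented; at desk
scale (hundreds rather than tens of thousands of positives) one-pass
training on a 1:20 set leaves the positive gradient too diluted to
learn at all, so the synthetic workflows enable this option. The
dataset ratio itself — which controls what the model learns about
negatives — is unchanged.

## Negatives and ratio datasets

Negatives re-pair each positive target with k miRNAs drawn uniformly
from the experiment's miRNA pool, excluding (by exact sequence
identity) any pair in the positive set; draws are without replacement
per target until the admissible pool is exhausted, then with
replacement. This keeps target composition identical across classes.
`assemble_ratio` fixes the realized ratio 1:k exactly and shuffles
deterministically; prevalence is 1/(1+k) by construction. Splitting is
by pair, with an off-by-default option to keep identical sequence
pairs within one split. A single RNG seed makes every dataset
byte-reproducible.

## Instance hardness and label smoothing

For a committee of scorers, a sample's instance hardness is the mean
probability the committee assigns to the wrong class (for a negative:
its mean predicted binding probability). The committee is built from
CNNs trained on 1:1 datasets with member-specific negative draws and
initialization seeds (default 5 members; the desk workflows use 3).
Members that saw a sample during training are excluded from its
estimate when training-set membership is provided; committee training
positives are necessarily scored in-fold (warned).

Hard-negative selection keeps all positives and the highest-IH
negatives until a requested ratio (e.g. 1:100 pool → 1:20) or fraction
is met, with deterministic ties (IH desc, pair key asc, index asc).
Smoothing maps each negative's IH through a monotone map
[0,1] → [0,0.5] — linear IH/2 by default, the functional form being a
package choice since only the range is prescribed — so the hardest
negatives approach maximal uncertainty (0.5) and labels never flip.
Positives always keep label 1; the label invariant
(label ∈ [0,0.5] ∪ {1}) rules out positive-class smoothing.

## Baselines

* **Seed heuristic**: binary call — does the reverse complement of the
  miRNA 2–7 hexamer (1-based, 5′-anchored) occur contiguously in the
  target? All match offsets are reported; a seed containing N yields a
  negative call with a warning. The 2–8 heptamer sometimes used in the
  literature is intentionally not the implemented rule.
* **Free-energy adapters**: external minimum-free-energy scores
  (kcal/mol, ≤ 0 favourable) are min-max normalized,
  `score = (max−raw)/(max−min)`, so the most favourable energy maps
  to 1; an all-equal table degenerates to 0.5 with a warning. Pattern-
  discovery tools reporting p-values are converted via `1 − p` before
  normalization. Pairs missing from a tool's output receive the worst
  score (0). The external tools themselves are never reimplemented or
  invoked; only their tabular outputs are adapted.

## Metrics

Predicted-positive rule: `score ≥ threshold` (ties positive; the
convention is stated because it is often left implicit). auPRC is
non-interpolated average precision; auROC is the trapezoidal area —
both via scikit-learn, and both checked in the tests against exhaustive
threshold enumeration. Undefined ratios (zero denominators) are
returned as NaN flags, never raised. Two named operating thresholds
are reported by default: *normal* (0.1) and *strict* (0.5). Soft
labels are thresholded at 0.5 (with a warning) for evaluation;
evaluation sets should carry hard labels.

Structurally, a fixed scorer's auROC is invariant to the
negative:positive ratio (it is a pairwise ranking probability), while
its auPRC decreases monotonically as k grows — the package's
ratio-stratified reports make both visible, and
`precision_from_rates(tpr, fpr, k) = tpr/(tpr + k·fpr)` reproduces
count-based precision exactly whenever the rates realize as integer
counts.

## Synthetic generator

`SynthSpec` plants one binding element per positive in otherwise i.i.d.
flanks (default GC 0.5), at a uniform random offset of a 50-nt target:

* `canonical` (default fraction 0.40) — reverse complement of miRNA
  2–7; the seed heuristic fires by construction at mutation rate 0.
* `three_prime` (0.18) — reverse complement of miRNA 13–20 with *no*
  seed complement anywhere (rejection-resampled; a miRNA whose 3′
  element embeds its own seed complement is replaced).
* `noncanonical` (remainder, 0.42) — reverse complement of miRNA 3–9
  with one forced internal mismatch, also seed-free. Real non-canonical
  duplexes are heterogeneous; this single imperfect-duplex class is a
  deliberately simple stand-in.

The default fractions follow the published estimates that ~60% of
chimeric-read duplexes lack a canonical seed and ~18% bind only at the
miRNA 3′ end. `mutation_rate` adds per-site mismatches to planted
elements (default 0: clean duplexes). Negatives come from the shuffling
construction above with an extra rejection of accidental seed
complements, so the seed heuristic's false-positive rate on synthetic
data is exactly 0. Mechanism labels are stored per pair, making
per-mechanism recall computable for any scorer.

What passing tests on this generator do **not** show: thermodynamic
realism, transcriptome-like background composition, bulges or wobble
duplex geometry, or the difficulty of real CLASH noise. They do show
that every pipeline stage behaves per contract and that the planted
complementarity rules are learnable and learned.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen as the
package's own defaults: learnability uses 4000+4000 all-canonical
training pairs; the training-regimen comparison uses 500 positives with
a 1:40 negative pool selected down to 1:20 (committee of 2, evaluated
on a held-out 1:100 set of 150 positives, majority over 3 seeds); the
ratio-invariance checks use 300 held-out positives. Float32 arithmetic
throughout the engine; Adam β = (0.9, 0.999), ε = 1e-7; batch-norm
momentum 0.9, ε = 1e-5; He-uniform initialization. Seeds derived from
a single user seed via a NumPy generator stay below 2³¹.

## Known limitations

* The numpy engine is single-threaded-CPU oriented; full-profile
  training at published dataset sizes is out of its intended range.
* The non-canonical synthetic class is one fixed motif family, so
  per-mechanism recall on it is an upper bound on what heterogeneous
  real non-canonical sites would yield.
* Hardness estimation quality is bounded by the committee's own
  ranking quality; at desk scale the committee is small and its IH
  estimates are correspondingly noisy.
* `RatioDataset` requires the realized ratio to be exact; datasets
  whose negatives are not a multiple of positives must be truncated by
  the caller.
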
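# Methods

## The augmentation

Self-attention in a fine-tuned Transformer encoder computes, per head, a
row-stochastic score matrix `A ∈ R^{n×n}` (softmax of scaled query–key
products) and contextualises the sequence as `H = A V`.  On small labelled
clinical cohorts, fine-tuning tends to drive these scores toward a
degenerate two-point pattern — after per-head min–max scaling, most mass
sits at 0 or 1 — which locks the model into a rigid set of token
dependencies.

Adaptive noise-augmented attention (ANAA) perturbs `A` during fine-tuning
in two steps, applied to every head of every layer, after the softmax and
before the value product:

1. **Adaptive noise.**  Add i.i.d. Gaussian noise `G ~ N(μ, σ_GN²)` over the
   valid (non-padded) region, where

       μ     = mean of the valid n×n block of A
       σ_GN  = sqrt( Σ (A_ij − μ)² / D )

   computed independently per sample and per head.  For a row-stochastic
   matrix `μ = 1/n` exactly, so the noise level tracks sequence length and
   the head's own score dispersion: a two-point head with "on" mass `α` has
   `μ = α` and per-element variance `α(1−α)` (up to the `m/(m−1)` sample
   correction, `m = n²`), so every Dirac spike is broadened proportionally
   to how binary the head is.

2. **Gaussian smoothing.**  Convolve the noised matrix with a discrete 2D
   Gaussian kernel of width `σ_eh` (the *event horizon*), side length
   `k = round(2π σ_eh)` clamped to ≥ 1.  The kernel acts as a low-pass
   filter: isolated noise spikes are averaged away while coherent score
   structure survives, and each score is interpolated with its neighbours
   in (query, key) offset space.

At inference the random draw is replaced by its expectation `μ`
(recomputed from the current matrix), making predictions deterministic:
`A_eval = smooth(A + μ)`.  RNA ("raw noise injected attention") is step 1
alone, with the same eval-path convention `A + μ`.  Augmented rows are
deliberately **not** renormalised and may leave `[0, 1]`.

### Numerical choices

* **Variance denominator.**  The printed estimator divides the sum of `n²`
  squared deviations by `n−1`, which inflates `σ_GN` by ≈ `√n` and lets the
  noise swamp the attention scores for long sequences.  The default here is
  `D = n²−1` — the standard sample estimator over all matrix elements,
  consistent with the per-element `α(1−α)` variance story above.  The
  `variance_denominator="as_printed"` switch (`D = n−1`) restores the
  literal formula for fidelity experiments.
* **Kernel anchoring.**  The kernel support uses centered integer offsets
  `−⌊k/2⌋ … ⌈k/2⌉−1`; an even kernel is anchored one cell up-left of
  center.  A one-sided support would *translate* the attention map rather
  than smooth it.
* **Normalisation.**  Kernels are normalised to unit mass by default so
  interior smoothing is mass-preserving (a constant block stays constant
  away from boundaries); the raw Gaussian weights are available via
  `kernel_normalized=False`.
* **Boundaries and padding.**  Zero-padded convolution with same-size
  output; entries outside the valid block are re-zeroed afterwards so no
  attention mass leaks into padding.  Kernels wider than twice the valid
  length trigger a warning (heavy smoothing) but proceed.
* **Degenerate inputs.**  `valid_len < 2` leaves the variance undefined:
  the standalone operations raise, the encoder's batched path passes such
  samples through unaugmented.  Constant score blocks short-circuit to
  `σ_GN = 0` exactly.
* **Separable implementation.**  The 2D Gaussian factorises, so the
  convolution is computed as two 1D passes; this is exact (the test suite
  pins it against a nested-sum oracle at 1e−10) and roughly `k/2`× faster.

### Gradients

The encoder is pure NumPy with hand-written backpropagation.  The sampled
noise field (and the eval-path `μ` shift) is treated as a constant in the
backward pass — the augmentation adds a sampled value, it does not
reparameterise a distribution — and the smoothing convolution is linear,
so its backward pass is the adjoint (offset-flipped) convolution restricted
to the valid block.  All gradients are verified against central finite
differences with the noise draw frozen.

## Encoder

A compact BERT-style stack: learned token + absolute position embeddings
(optional visit-ordinal segment embeddings, off by default), post-LN
residual blocks with ReLU feed-forward, masked-language-model head with a
tied decoder, and a sigmoid classification head.  Defaults: 2 layers,
4 heads, `d_model = 64`, feed-forward `4·d_model`, dropout 0 — all
configurable; the reference implementation's exact sizes are not published,
so these are declared desk-scale defaults, not inferences.

**Pooling.**  The classification head reads a pooled sequence
representation: the mean over valid positions by default, or the `[CLS]`
position (`pooling="cls"`).  With a large pre-training corpus `[CLS]`
pooling is standard; at the corpus sizes used here the `[CLS]` state
carries no MLM signal (nothing ever predicts from it during pre-training),
and fine-tuning from ~10² labelled sequences cannot learn the routing from
scratch — mean pooling is markedly more sample-efficient and is therefore
the default.

**MLM corruption** follows the BERT convention (unstated in the original
description): 15 % of non-special tokens, 80/10/10 mask/random/keep.

**Special tokens** are fixed for reproducibility:
`[PAD]=0, [CLS]=1, [SEP]=2, [MASK]=3, [UNK]=4`.

## Tokenization and labelling

Visits are sets of diagnosis (ICD-like) and medication (ATC-like) codes.
Codes are normalised by removing dots and keeping the first 4 characters
("initial 4 digits" is read as *characters* — ICD-10 codes mix letters and
digits, and a digits-only reading would destroy the letter prefix).  Codes
rarer than `min_count` (default 5; no published threshold exists) map to
`[UNK]`.  Sequences are `[CLS] V₁ [SEP] V₂ [SEP] …` with visits in
temporal order and codes sorted within a visit (visits are sets; a
canonical order is needed for reproducibility).  Over-long sequences keep
the most recent whole visits that fit — prediction conditions on recent
history — always retaining `[CLS]`.

Outcome labels use first-occurrence semantics with positive-case
truncation: excluded codes (e.g. treatment medications that would leak
outcome timing) are removed everywhere *first*; then the first visit
containing a target code and all later visits are dropped and the patient
is positive; patients whose first visit already contains the target have
no usable history and are dropped.  The minimum-visit filter is applied
after truncation, i.e. to the history the model actually sees (whether the
original protocol filtered before or after truncation is not stated; the
alternative is a one-line change).

Splitting is patient-level 70/20/10 (pre-train / fine-tune / test), with
the fine-tuning pool partitioned into 5 label-stratified folds
(stratification keeps the small positive counts balanced; the original
protocol states only "5 folds").

## Synthetic cohorts

Real corpora of this kind are access-restricted, so all experiments run on
synthetic cohorts that emulate their shape statistics:

* visit counts: shifted negative binomial (EHR visit counts are
  over-dispersed; only the means are published, so the distribution family
  is a declared choice);
* codes per visit: shifted Poisson;
* code popularity: power law over a seeded shuffle of the vocabulary;
* outcome: logistic in the base rate plus planted *motifs* — ordered code
  pairs `(a, b)` that fire when `b` occurs at least `min_offset` visits
  after `a`, each contributing its log-odds.  Positive patients get the
  target code appended in a final extra visit, so the labelling module's
  truncation reconstructs exactly the generated history (this round trip
  is asserted on 5 000 patients).

Presets: `mimic_like` (≈9 visits/patient, 2195+137 codes, ≈61
codes/patient) and `mdc_like` (≈19 visits/patient, 1558+111 codes, ≈257
codes/patient).  The generator also exposes the Bayes ceiling — the AUC of
its own true logits — which upper-bounds any classifier on that cohort.

What the generator does **not** emulate: disease progression dynamics,
calendar time, code ontologies, realistic co-occurrence structure.
Passing tests therefore show that the pipeline learns planted long-range
co-occurrence signal under realistic shape statistics — not that any
real-data AUC would be reproduced.

## Baselines

* `naive_mask`: pre-softmax masking to −∞ with probability `p` (0.2 in the
  published setting); rows that become entirely masked are restored
  (softmax would be undefined; unstated in the original).
* `drop_attention`: seed masks expanded to an `ω`-length span along the key
  axis (`ω` = kernel size in the published comparison).  Both masking
  baselines keep rows stochastic after the softmax — a discriminating
  contrast with ANAA, which deliberately does not.
* `embed_noise` / `ffn_noise`: uniform noise on `[−1, 1]` scaled by
  `α/√(n·d)` added to embeddings / feed-forward inputs (the cited
  calibration rule; this package records it as external-method fidelity).
  All baselines are identity maps at evaluation.

## Train/eval protocol

MLM pre-training on the 70 % pool; then, per fold, fine-tuning from the
*same* pre-trained checkpoint on 4 folds with early stopping on the fifth
(monitoring validation AUC — the reported metric — not loss), scored on
the untouched 10 % test pool; reports carry per-fold test AUCs and their
mean ± std.  AUC is rank-based with ties counted half.  Optimiser:
adaptive-moment gradient descent (Adam), defaults lr 1e−3 pre-train /
5e−4 fine-tune, batch 32, patience 5; the published training schedule is
not available, so these are declared defaults.  A data-insufficiency sweep
subsamples the fine-tuning pool label-stratified at 50/20/10 % and repeats
the CV protocol per fraction.

## The directional benchmark

`anaa.training.directional_benchmark` is the package's end-to-end smoke
surface: an `mdc_like`-shaped cohort (≈19 visits/patient) scaled down to
desk size — 800 patients, 150+20 codes, 3 codes/visit, one long-offset
motif (`min_offset = 10` visits, log-odds 3.0, plant probability 0.5, base
rate 0.2; Bayes ceiling ≈ 0.79) — with a 48-dimensional 2-layer encoder
(3 heads, dropout 0.1, mean pooling), 40 MLM epochs and up to 24
fine-tuning epochs (patience 5, lr 1e−3, batch 16).  These sizes are the
package's own desk-scale conditions, chosen so one pre-train + two 5-fold
fine-tune cycles complete in a few minutes per seed on one CPU while the
planted signal remains clearly learnable.  The pre-training budget is
deliberately generous relative to the fine-tuning budget: the failure mode
the augmentation addresses — confident, rigid attention inherited from
pre-training and overfit during a small fine-tune — only materialises once
the MLM model is well trained, and in that regime the noise-plus-smoothing
arm also shows visibly lower fold-to-fold variance.  Training batches are
length-bucketed (shuffled pools of four batches, locally sorted by length)
to avoid quadratic-cost padding waste on variable-length histories.  Over
5 seeds the benchmark checks a *direction* — both augmentation modes beat
chance comfortably and ANAA does not fall behind the unaugmented baseline
— never a published effect size.

## Diagnostics

Attention matrices are pooled per (layer, head) across an evaluation
split, min–max scaled to `[0, 1]`, and histogrammed on fixed bins.  The
*polarization index* (fraction of scaled scores within ε = 0.05 of 0 or 1)
is an invented scalar summarising the near-binary pattern; `on_mass_alpha`
(the pooled mean) estimates the "on" mass of a two-point head.  Constant
heads (min = max) are scaled to 0 and flagged degenerate.  Receptive-field
curves bucket scores by query−key offset `i−j` and report the median per
bucket, pooled over heads by default (per-head tables optional; the
published figures do not state their pooling).  Heatmaps are exported one
pixel per cell with the colormap spanning exactly `[min, max]`.

## Known limitations

* The encoder is desk-scale by construction; no GPU path, no sparse or
  rotary attention variants.
* Eval-path `μ` is recomputed from the current sample's attention, as the
  inference formula reads; freezing training-time statistics instead is a
  plausible alternative not implemented.
* The masking baselines draw seeds per element; whether the original drew
  per row or per matrix is unstated.
* No significance testing of AUC differences is provided, and none of the
  published real-data AUC tables can be checked from synthetic cohorts.
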
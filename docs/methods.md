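# Methods

This note documents the models, the synthetic benchmark, and the numerical
and design choices behind `pepfun`, at the level a maintainer or reviewer
needs to judge what the package's results do and do not show.

## Sequence representation

Peptides over the 20 canonical amino acids are mapped to integer codes 1–20
in alphabetical one-letter order (A=1 … Y=20) and right-padded with 0 to a
fixed length of 50, the upper end of the therapeutic-peptide length range
(5–50). Right padding keeps code index *i* equal to sequence position *i*,
which the positional encoding and the per-residue attribution rely on.
Non-canonical symbols (X, B, Z, U, lowercase) are rejected rather than
coerced — silent mapping to the pad code would corrupt attribution
positions; an opt-in `skip_invalid` drops offending records with a logged
count. Over-length sequences error unless truncation to the N-terminal 50
residues is requested explicitly, since both cases are outside the
benchmark distribution.

## Classifier

Four blocks: (i) a learned embedding of codes 0–20 (code 0 is a learned pad
vector) plus the closed-form sinusoidal positional encoding, refined by one
multi-head self-attention layer; (ii) 1-D convolutions with kernel widths
{2,3,4,5} and global max pooling, concatenated; (iii) a residual two-layer
perceptron with layer normalization, `LN(max(0, Yw1+b1)w2 + b2 + Y)`;
(iv) a linear head with sigmoid outputs.

Choices the architecture description leaves open, and what this package
does:

- **Positional information is added** to the semantic embedding, not
  concatenated, following the transformer convention the encoding comes
  from.
- **Padding is masked in self-attention keys** (masked logits get −1e9
  before the softmax, which underflows to exactly zero weight in float
  arithmetic) but **not in the convolutions**: the learned pad vector
  handles pad positions there, and masking convolutions would change the
  pooled feature width. Consequently the full model's logits are *not*
  invariant to the pad embedding; the attention-only backbone is, and the
  tests check each contract where it actually holds.
- **One attention layer**, 8 heads at d=192 (24 per head), 128 filters per
  kernel, dropout 0.1, FFN hidden width 2× the pooled width: conventional
  values, all exposed in `NetworkConfig`.
- Alternative backbones (attention-only, BiLSTM+attention with hidden d/2
  per direction, TextCNN-only, TextCNN+FFN) and ablation flags (positional
  encoding, FFN, TextCNN) are configuration options. Without the TextCNN
  the length dimension is collapsed by mean pooling over non-pad positions;
  max pooling was rejected because it would partially reintroduce
  TextCNN-like behavior into the ablation.
- The network returns probabilities only; the 0.5 decision threshold lives
  in the training/metrics layer. A probability exactly at the threshold is
  called positive, so a maximally uncertain output is surfaced rather than
  dropped.

## The focal dice loss

Foreground and background probabilities are modulated by
`p¹ = min(p+ε1, 1)·p` and `p⁰ = (1 − max(p−ε0, 0))·(1−p)` and entered into
a two-term soft-dice loss balanced by ω (see README for the formulas).
Numerical and boundary decisions:

- **Reduction: mean over samples** (sum retained as an option). The [0,1]
  bound of the loss holds per sample; the mean preserves it and makes batch
  size irrelevant to learning-rate choice.
- **Smoothing δ = 1e-8** in the dice denominators guards the 0/0 case when
  a sample has no background labels (an all-positive row then contributes
  background loss 1). δ is far below every test tolerance.
- **Kinks**: at `p = 1−ε1` and `p = ε0` exactly, the constant branch of the
  piecewise derivative applies (the strict-inequality side carries the
  variable branch). The autodiff ops implement the same convention with
  strict masks, so the analytic gradient and the training gradient agree
  *everywhere*, kinks included; evaluating the analytic gradient exactly at
  a kink emits a warning.
- Defaults ε1 = ε0 = ω = 0.5; the originally tuned values are not public,
  so all three are config-exposed and first-class grid-search dimensions.
- Baselines: binary cross-entropy; focal loss (γ = 2); asymmetric loss
  (γ+ = 0, γ− = 4, probability shift 0.05); plain dice = the focal dice
  loss at ε1 = ε0 = 1. Hyperparameters follow the losses' original
  publications.

The analytic gradient (closed form, including the coupling of every label
through the dice denominators) is implemented independently of the autodiff
tape and serves as the oracle in the test suite; both paths must agree to
1e-6 and to finite differences to 1e-5 relative error.

## Autodiff engine

No deep-learning framework is used: the networks train through a small
reverse-mode tape over numpy (`pepfun/_autodiff.py`) providing exactly the
ops the architectures need. Gradients stay in each parameter's dtype
(float32 by default for training, float64 wherever oracles are compared);
the first gradient contribution to a node is borrowed without copying —
safe because reverse topological order finalizes a child's gradient before
its backward runs — and copy-on-write protects nodes with several
consumers. Every op is finite-difference-tested.

## Metrics and model comparison

The five set-based metrics follow their standard definitions. Two cases the
definitions leave open: an empty predicted set contributes 0 to Precision
(penalizing abstention keeps `Accuracy ≤ Precision`), and Absolute false is
averaged over samples (without 1/N it would not be a rate). The comparison
protocol draws five independent 80% subsets of the test set (a sample may
recur across subsets), evaluates both models on the same subsets, and runs
a **paired** two-sided t-test per metric — paired because the subsets are
shared — at α/k with k = 5 comparisons (0.01 → 0.002). Zero-variance
differences are reported as p = 1 with a degenerate flag rather than an
infinite statistic.

## Synthetic benchmark

The generator emulates the statistical structure of the real
multi-functional therapeutic peptide benchmark so the full pipeline is
testable without downloads: label vectors are independent Bernoulli draws
at configured prevalences, passed through one Gibbs-style sweep applying
pairwise co-occurrence odds (identity = independent), and rejected if all
zero, so marginals after rejection are `prevalence / (1 − P(no label))`.
Background residues are i.i.d. (uniform by default; natural frequencies are
a preset); each positive class plants one of its short motifs (length 2–5)
at a uniform feasible position with probability `plant_probability`,
overwriting in place so sequence length is independent of the labels;
negative sequences carry the motif at a small `decoy_probability`.

The shipped benchmark: n = 2000, M = 6 classes, prevalences
[0.40, 0.30, 0.20, 0.10, 0.05, 0.025] (16:1 imbalance), lengths 10–50, one
length-3 motif per class, plant probability 0.9, decoy probability 0.02,
generator seed 7, split 80/20. What it does **not** emulate: real
physicochemistry, positional motif preferences, length–label dependence,
homology structure between sequences. Passing tests therefore demonstrate
that the algorithms behave as specified under controlled conditions, not
that the reported performance transfers to real peptide data.

Note the rarest class is deliberately hard: ~40 training positives against
a decoy rate (0.02) comparable to its prevalence (0.025), so the Bayes
posterior for a motif carrier is only ≈ 0.6. At the benchmark training
budget the rarest class sits at the edge of learnability, which is exactly
the regime an imbalance-aware loss targets; conclusions about it are
correspondingly noisy (16 test positives ⇒ coverage granularity 1/16).

## Training protocol and problem sizes

Optimization is mini-batch Adam (default lr 1e-3, batch 64), fully seeded:
parameter init, batch order, dropout and fold assignment all derive from
one integer, and runs are bit-reproducible on a fixed platform. Model
selection is grid search scored by 5-fold cross-validation on the mean of
Absolute true (the strictest metric), ties broken toward earlier grid
order; a log-uniform random-search hook over the learning rate stands in
for fancier schedulers. Fold assignment is plain random with equal sizes
(±1); stratification is available as an option for rare labels.

For the fixture-scale studies in the tests and the acceptance script the
architecture keeps all four blocks but shrinks widths (d = 32, 4 heads, 16
filters per kernel, float32, dropout 0) and trains 30 epochs without early
stopping — sizes chosen so the whole suite, which fits more than a dozen
models, runs comfortably on one CPU. The same code paths scale to the
full-size configuration (d = 192, 8 heads, 128 filters).

## Distillation and attribution

The student is an embedding (+ positional encoding) followed by
padding-masked self-attention that preserves the length dimension, then
per-class attention pooling: class m's learned query scores every position,
a softmax over non-pad positions yields that class's attribution profile
(summing to 1 over real residues; pads receive exactly zero), and the
attended context vector is scored by a per-class output vector. "Masked" is
a padding mask, not a causal one — peptides have no autoregressive order
and attribution needs bidirectional context.

Teacher soft labels are the frozen teacher's sigmoid probabilities,
computed once and cached (no distillation temperature is introduced). The
distillation loss is plain cross-entropy from teacher to student
probabilities, reduced as mean over samples and sum over labels so that μ
keeps its meaning across batch sizes; `TL = SL + μ·KDL` with μ = 1 by
default, and μ = 0 reduces bit-exactly to plain student training.

Attribution utilities: fragment framing returns the odd-width window
centered on the arg-max attention position (ties break toward the
N-terminus, windows clip at the ends, a window longer than the sequence
returns the whole sequence flagged); the class-similarity matrix is the
Pearson correlation between the per-class query vectors, with zero-variance
vectors reported as 0.

A caution on reading attention: in the benchmark the most prevalent class
can be predicted largely from its base rate, so its attention is diffuse
even when planted motifs exist; mid-prevalence classes show the sharpest
motif concentration. Aggregate checks therefore pool attribution
measurements across all classes rather than inspecting a single one.

## Known limitations

- The loss hyperparameters (ε1, ε0, ω, μ) and the original training
  schedule were tuned values not available to this implementation; defaults
  are conventional and exposed for search rather than copied.
- The student architecture is a reconstruction from the published block
  diagram; its fidelity to the original cannot be verified.
- The numpy training stack is single-process and CPU-oriented; it is sized
  for the synthetic benchmark and for method study, not for large-scale
  screening runs.
- Checkpoints store raw parameter arrays plus a JSON header; they are
  version-tagged but not portable across incompatible config changes.
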
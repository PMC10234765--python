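# pepfun

Multi-label classification of therapeutic peptide function from sequence
alone, with an imbalance-aware loss and per-residue attribution.

Therapeutic peptides are short amino-acid chains (5–50 residues) that often
carry several activities at once — antibacterial, anticancer,
antihypertensive, and so on. Screening candidate peptides computationally is
a multi-label classification problem with two recurring obstacles: the label
classes are heavily imbalanced (a few common activities, many rare ones),
and the deep models that predict well are opaque about *which residues*
drive each predicted activity. `pepfun` addresses both: a focal dice loss
that couples all labels of a sample and focuses the gradient on hard label
assignments, and a teacher–student distillation scheme whose student exposes
a per-class attention profile over residues.

It is intended for computational biologists building peptide-function
screens and for methods researchers studying multi-label losses under class
imbalance.

## The model

A peptide is encoded as integer codes 1–20 (alphabetical order of the
one-letter residue codes), right-padded with 0 to length 50. The classifier
has four blocks:

1. **Embedding** — learned residue embeddings (dimension *d*, default 192)
   plus the sinusoidal positional encoding
   `p[i,2j] = sin(i / 10000^(2j/d))`, `p[i,2j+1] = cos(i / 10000^(2j/d))`,
   refined by one layer of multi-head self-attention with padding masked
   out of the keys.
2. **TextCNN** — 1-D convolutions with kernel widths 2–5 and global max
   pooling, concatenated (the smallest admissible peptide is 5 residues).
3. **Feed-forward** — `FFN(Y) = LN(max(0, Y·w1 + b1)·w2 + b2 + Y)`.
4. **Classification** — a linear layer to M label scores with sigmoid
   outputs; labels are called at the 0.5 threshold.

Training minimizes the **multi-label focal dice loss (MLFDL)**. With
foreground probability `p` and focal factors `ε1, ε0 ∈ [0,1]`:

```
p¹ = min(p + ε1, 1) · p                 p⁰ = (1 − max(p − ε0, 0)) · (1 − p)
L¹ₙ = 1 − 2 Σₘ p¹y / (Σₘ (p¹)² + Σₘ y²)   L⁰ₙ analogously on (p⁰, 1−y)
MLFDL = meanₙ [ ω·L¹ₙ + (1−ω)·L⁰ₙ ]
```

The dice denominators couple every label of a sample, so the gradient at one
label depends on the probabilities of all others — unlike per-label
cross-entropy variants. The analytic gradient is implemented in closed form
and cross-checked against both finite differences and the automatic
differentiation used in training.

Evaluation uses the five standard set-based multi-label metrics (Precision,
Coverage, Accuracy, Absolute true, Absolute false), and model comparison
uses five random 80% test subsets with a paired Student's t-test at a
Bonferroni-corrected significance level.

Interpretation: the trained classifier (teacher) is distilled into a small
length-preserving attention network (student) trained on
`TL = SL + μ·KDL`, where SL is the focal dice loss on the true labels and
KDL the cross-entropy to the teacher's sigmoid probabilities. Each class
owns a learned query vector; its normalized attention over positions is the
class's per-residue attribution profile.

Because the original benchmark is an external download, the package ships a
synthetic-data module that emulates its structure: lengths 5–50, heavy
prevalence imbalance, label co-occurrence, and short class-specific motifs
planted into positive sequences. Everything in the test suite runs on this
generator.

## Worked example

```python
import numpy as np
from pepfun.simulate import default_fixture_spec, sample_dataset
from pepfun.network import NetworkConfig
from pepfun.training import PeptideClassifier, TrainConfig
from pepfun.distill import Distillation, DistillConfig, StudentConfig

spec = default_fixture_spec()            # 2000 peptides, 6 classes, 16:1 imbalance
records = sample_dataset(spec)
train, test = records[:1600], records[1600:]

net = NetworkConfig(label_dim=6, embed_dim=32, n_heads=4,
                    filters_per_kernel=16, dropout=0.0, dtype="float32")
results = PeptideClassifier(train, spec.label_space, net).fit(
    TrainConfig(epochs=30, batch_size=64, seed=1, early_stop_patience=None))
print(results.summary())
print(results.evaluate(test))
```

prints

```
Peptide function classifier
==========================================
backbone:        etfc
labels (M):      6
embed dim (d):   32   heads: 4
kernels:         [2, 3, 4, 5] x 16 filters
parameters:      29126
loss:            mlfdl
epochs run:      30
final mean loss: 0.1223
seed:            1

      precision: 0.7429
       coverage: 0.7148
       accuracy: 0.6192
  absolute_true: 0.4100
 absolute_false: 0.1500
      n_samples: 400
```

So on held-out data the model recovers the exact label set for 41% of
peptides (a majority-labelset baseline reaches 21%), and on average 71% of
each peptide's true activities are predicted (Coverage). Distilling into the
attention student and framing the most-attended fragment recovers the
planted motif for class C0 (`AGK`):

```python
student = Distillation(results, train, spec.label_space,
                       StudentConfig(label_dim=6, embed_dim=32, n_heads=4),
                       DistillConfig(mu=1.0, epochs=15, seed=1)).fit()
rec = next(r for r in test if r.labels[0] and "AGK" in r.sequence)
frag = student.frame_fragment(rec.sequence, class_index=0, window=3)
print(rec.sequence)
print(frag.fragment, frag.start + 1, frag.end)
```

```
VEGGANMEKLLGIEEQTWIFGDSMWAGKRVSSNDKFMCQPIFAQIM
AGK 26 28
```

A command-line interface covers the same pipeline
(`pepfun simulate | train | cv | gridsearch | predict | evaluate | compare |
distill | explain | classcorr`); every run writes a manifest recording the
seed, config hash and file paths.

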
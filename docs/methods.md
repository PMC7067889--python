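# Methods

`mc4deep` predicts DNA N4-methylcytosine (4mC) sites from fixed-length,
cytosine-centred sequence windows (41 bp by default).  The model family
has four stages, trained strictly under one k-fold protocol so that
every learned feature a later stage consumes is an out-of-fold
prediction:

1. eight preliminary sequence encodings;
2. one small CNN+BLSTM network per encoding, whose sigmoid output is
   that encoding's *advanced probability feature* (8 columns total);
3. an iterative probability-stacking ensemble of six classical
   classifiers that appends one winning out-of-fold probability column
   per round;
4. a small fully connected network on the enriched matrix that emits
   the final 4mC probability.

Performance is reported as sensitivity (SN), specificity (SP), accuracy
(ACC), Matthews correlation coefficient (MCC) and the area under the
ROC curve (AUC).

## Input model and quality filtering

A sample is a window of length L (odd; default 41) over {A, C, G, T}
with the putative 4mC cytosine at the 1-based centre (L+1)/2.  Both
positive and negative windows have a central C — negatives are centred
cytosines not detected as methylated — so the centre base itself is
uninformative and the signal, if any, lives in the flanks.  Lowercase
input and U are normalized; any other residue is an error (degenerate
bases are not part of the model).  The centre-C check is a
warn-or-fail switch, failing by default.

Windows may carry a modQV score (SMRT-kinetics modification quality).
The default filter removes samples with modQV above 30 and keeps the
boundary value; because the literal published rule and the usual
meaning of the 30 threshold ("minimum score for calling a position
modified") point in opposite directions, the inverted rule is available
as `mode="drop_below"`.  Redundancy reduction defaults to
exact-duplicate removal (first occurrence kept), which is deliberately
weaker than similarity clustering; a CD-HIT binary can be configured as
an external hook (`dedup_cdhit`) for 80 %-identity clustering when
available.

Fold assignment is stratified: a seeded shuffle within each class
followed by round-robin assignment, with the round-robin phase carried
across classes so total fold sizes differ by at most one.  A single
master seed fans out (via `numpy.random.SeedSequence`) to the fold
split, every network initialisation and shuffle, the stacking learners
and the final classifier, making the whole protocol reproducible from
the manifest.

## The eight encodings

The published description names the schemes but defers every numeric
detail to earlier predictors, so the formulations below are this
package's pinned, documented choices (all constants overridable through
`EncoderParams`).

| scheme  | definition | length (L=41) |
|---------|------------|---------------|
| BKF     | per-position one-hot (4L) + relative k-mer frequencies, k = 2, 3, 4 | 500 |
| DBPF    | per dinucleotide position: 16-bit identity one-hot + running frequency of that dinucleotide among positions 1..j | 680 |
| KNN     | for fractions f = 0.02, 0.04, …, 0.20: positive fraction among the ⌈f·n⌉ nearest labelled references under per-position identity similarity; ties broken by reference order | 10 |
| PCP     | six standardized B-DNA dinucleotide step-parameter scales (twist, tilt, roll, shift, slide, rise) per position | 240 |
| MMI     | pairwise terms I(x,y) = f(xy)·ln(f(xy)/(f(x)f(y))) over the 10 unordered pairs, plus interaction terms I(x,y,z) = I(x,y) − f(xyz)·ln(f(z)f(xyz)/(f(xz)f(yz))) over the 20 unordered triples; any term touching a zero frequency is 0 | 30 |
| PseDNC  | pseudo dinucleotide composition: 16 normalized dinucleotide frequencies + λ = 3 correlation tiers (weight w = 0.1) using the six PCP scales; components sum to 1 | 19 |
| PseEIIP | per trinucleotide, (sum of its three EIIP values: A 0.1260, C 0.1340, G 0.0806, T 0.1335) × relative frequency | 64 |
| RFHCP   | per position, three chemical bits (ring: A,G; H-bond strength: C,G; amino group: A,C) + cumulative frequency of that nucleotide in the prefix | 164 |

The BKF width of 500 at L=41 is the canonical extractor input size and
fixes the k-mer range at k = 2, 3, 4 (164 + 16 + 64 + 256 = 500).

The PCP property table ships as a package constant: a
reverse-complement-symmetric set of B-DNA step parameters with
physically plausible magnitudes (twist ≈ 29–38°, rise ≈ 3.3 Å, …),
standardized to zero mean and unit variance across the 16 dinucleotides
before use.  Only relative differences between dinucleotides enter the
PCP and PseDNC coordinates, so any standardized six-scale table yields
an equivalent feature space up to rotation of those coordinates.

The KNN encoding is label-derived and therefore a leakage hazard:
dataset encoding requires a fold assignment, and each row's references
are restricted to the other folds.  At prediction time the full
training set serves as the reference pool.

## CNN+BLSTM extractors

Each encoding's feature vector is treated as a length-N, one-channel
signal.  The default extractor is three blocks of
[valid 1-D convolution → ReLU → max-pool 2] with 16/32/64 filters of
length 8, followed by dropout (0.2), a bidirectional LSTM (32 units per
direction, outputs concatenated over the full sequence), a flatten, a
16-unit ReLU layer and a single sigmoid output.  Training uses Adam
(learning rate 10⁻³), batch size 64, binary cross-entropy, and 5 epochs
— the convergence point of the accuracy/loss curves under this
protocol.  Alternate depths (2–7 conv blocks) are available through the
configuration for depth-sweep experiments.

With valid convolutions the default stack needs an input of at least 53
values, which four of the eight encodings (KNN 10, PseDNC 19, MMI 30)
do not reach.  The strict builder (`build_network`) raises with the
minimum length; the pipeline instead uses an adaptive build that clips
each kernel to the current sequence length and skips pooling once the
sequence is shorter than the pool, preserving the three-block
architecture for every scheme.  Shape table for the default
configuration on the 500-wide BKF input: 493×16 → 246×16 → 239×32 →
119×32 → 112×64 → 56×64, then BLSTM → 56×64.  (The layer stack is the
published one; intermediate widths follow from valid padding and are
documented here rather than matched to any printed value.)

Features are z-scored per column with the training split's statistics
before entering the network (std floored at 10⁻⁸); the scaler is part
of the saved model.  The networks are implemented in a compact numpy
core (`mc4deep.nn`) with analytic gradients — convolution via
im2col/matmul, LSTM with the standard four-gate recurrences, Adam — and
the gradients are verified against central finite differences in the
test suite.  Training is exactly reproducible for a fixed seed.

Under k-fold training, fold f's network is trained on the other folds
and predicts fold f, so the n×8 advanced matrix consists entirely of
out-of-fold probabilities; a final network per scheme is refit on all
training rows and used only for new windows.

## Iterative probability stacking

Six learners compete each round on the current matrix under the same
fold assignment: k-nearest neighbours (k=5), logistic regression (L2,
C=1), an RBF SVM (C=1, gamma='scale') with Platt-scaled probabilities,
Gaussian naive Bayes, a decision tree, and a random forest (100 trees);
tree-based learners and the SVM are seeded.  The winner is the learner
with the highest out-of-fold accuracy (exact ties go to the earlier
learner in the fixed order; the selection metric is configurable), and
its out-of-fold class-1 probability column is appended: after t rounds
the matrix has 8 + t columns (13 after 5 rounds).  Iteration stops at
`max_iter` (default 10) or when the winning accuracy changes by less
than `tol` (default 10⁻⁴) between consecutive rounds.  Winner selection
uses cross-validated rather than training accuracy — the published
account does not say which, and CV accuracy is the choice that matches
the out-of-fold construction of the appended columns.

For new windows, each round's winner refit on the full training matrix
is applied in sequence, reproducing the column-growth path without
leakage into training.

## Final classifier

A fully connected network with 2–4 ReLU hidden layers (default 2, with
32 and 16 units) and a sigmoid output, trained with Adam (10⁻³), batch
32, up to 50 epochs with early stopping (patience 5) on a 10 %
validation slice.  Probabilities at or above the threshold (default
0.5) are called positive.  Epochs, widths and threshold are package
defaults — the published description fixes only the 2–4 layer range and
the activations.

## Metrics

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/n,
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)) with MCC := 0
when the denominator vanishes.  AUC uses the Mann–Whitney rank
statistic with average ranks, equivalent to the pairwise estimator with
ties counted one half; it is invariant under strictly monotone score
transforms.  The test suite checks all five against brute-force tallies,
an O(n²) pairwise AUC oracle, and scikit-learn.

## Synthetic benchmark generator

The generator emulates the study's benchmark construction: two classes
of L-bp windows over {A,C,G,T}, both with a forced central C.
Positives carry a planted PWM motif (default width 6, starting one base
right of the centre): at each motif position the consensus base has
probability 0.25 + 0.75·effect and the others are uniform, so effect 0
makes the classes identical and effect 1 plants a deterministic
consensus.  The motif's KL divergence from background is closed-form
and strictly monotone in effect — the calibration knob for every
null/power test.  The consensus string is drawn once per seed.
Synthetic modQV scores are Uniform(0, 30), emulating an already
quality-screened dataset so the default filter leaves the benchmark
intact.  Default background composition is uniform.

What the generator does **not** emulate: genomic base composition and
its positional biases, SMRT-kinetics noise structure, near-duplicate
sequences, or motif families with internal dependencies.  Passing the
calibration and power tests therefore shows that the machinery learns a
planted positional signal without leaking labels — not that it attains
any particular accuracy on real methylomes.

## Problem sizes and runtime choices

The package's study-scale checks use n = 2000 windows (1000 per class,
70/30 train/test split, 3-fold CV) for null calibration (effect 0:
held-out AUC must land in [0.45, 0.55]) and signal recovery (effect
0.8: held-out ACC > 0.9), and n = 600 per effect level for the
monotonicity of held-out AUC over effect ∈ {0, 0.4, 0.8}.  At these
sizes the pipeline runs with the reduced extractor preset
(`compact_network_config`: filters 4/8/16 of length 5, 8 LSTM units) —
the same three-block architecture, narrow enough that a full n = 2000
run takes on the order of a minute and a half on one CPU core.  The
full-size default configuration (16/32/64, kernel 8, 32 LSTM units)
carries the protocol constants and is what the manifest asserts.

## Numerical and design notes

- Pooling drops a trailing remainder window; dropped positions receive
  zero gradient.
- The LSTM forget-gate bias initialises to 1; other weights are
  Glorot-uniform from the seeded generator.
- Sigmoid and binary cross-entropy use log1p/logaddexp forms; scores
  are finite for arbitrary finite logits.
- KNN similarity ties are resolved by reference input order (stable
  sort), making the encoding deterministic.
- MCC, SN and SP return 0 rather than NaN on empty denominators;
  AUC requires both classes and raises otherwise.
- `filter_by_modqv` keeps samples lacking a score, so the filter is a
  no-op on datasets without kinetics metadata.
- Probabilities are never exactly 1.0, so threshold 1.0 calls nothing;
  the ≥ convention makes threshold 0.0 call everything.

## Known limitations

- Exact-duplicate removal does not remove near-duplicates; without an
  external CD-HIT binary, redundancy filtering is weaker than the
  published 80 % clustering and cross-validation estimates may be
  slightly optimistic on redundant data.
- The numpy core is single-threaded and CPU-bound; the full-size
  default networks are practical up to a few thousand windows, not
  genome scale.
- Backend determinism is exact here (pure numpy), but results will not
  be bit-identical to any GPU/framework re-implementation; tests
  therefore use tolerance bands for learned quantities.
- The six stacking learners use pinned default hyperparameters; no
  per-round hyperparameter search is performed.
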
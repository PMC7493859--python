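# Methods

## Sequence representation

Sequences are strings over Σ = {A, C, G, T}; a length-L sequence is one-hot
encoded as a binary (L, 4) matrix with positions along the rows and one
indicator channel per symbol, in fixed alphabetical channel order (A, C, G,
T). A batch is the tensor (N, L, 4). Storing positions × channels (rather
than the transposed channels × positions picture) matches how the first
convolution consumes the data — it scans positions with 4 input channels —
and carries identical information. Classification is invariant to any
consistent channel order.

IUPAC ambiguity codes (including N) are rejected by default (`strict`
policy); a `drop` policy removes offending sequences and logs the count. No
fractional encoding of ambiguous bases is offered. Parsing is
case-insensitive with an uppercase canonical form.

## Architecture

The hybrid network is: Conv1D(50 filters, kernel 5, stride 1, same padding,
ReLU) → MaxPool(2, stride 2) → Dropout(0.5), then two parallel paths on the
73×50 feature map — LSTM(50 units, sequence output) → Dropout → Flatten
(3650) and Conv1D(50 filters, kernel 10, same, ReLU) → MaxPool(2,2) →
Dropout → Flatten (1800) — concatenated to a 5450-vector, then Dense(370,
ReLU) → Dropout(0.5) → Dense(1, sigmoid).

Fixed numerical conventions, each forced by the published shape chain
147 → 147×50 → 73×50 → {73×50, 36×50} → {3650, 1800} → 5450:

* **Same padding.** Both convolutions preserve length. For the even kernel
  (10) the total padding k−1 = 9 splits as 4 left / 5 right, the convention
  of the framework family the architecture was designed in.
* **Pooling.** Pool 2, stride 2, no padding, floor semantics (147 → 73,
  73 → 36; the trailing odd position is dropped).
* **Sequence-output LSTM.** The LSTM emits one hidden vector per position
  (73×50), not only the final state — otherwise the flatten length would be
  50, not 3650.
* **Output activation** is sigmoid (probabilities in [0, 1]); the hidden
  dense layer uses ReLU, consistent with the convolutional non-linearity.

Parameter counts follow the closed forms conv = k·c_in·f + f, LSTM =
4(u·d + u² + u), dense = n_in·n_out + n_out, and are verified in the tests by
enumerating the weight tensors: 1,050 + 20,200 + 25,050 + 2,017,241 =
2,063,541 trainable parameters at the default widths.

The two baselines mirror the hybrid network's corresponding blocks (the
ConvNet is the stem + convolutional path + dense head; the LSTM baseline is
the stem + recurrent path + dense head), so comparisons isolate the
architectural delta; all widths are configurable.

## NumPy implementation

The layers (Conv1D, MaxPool1D, Dropout, LSTM, Dense), backpropagation and
Adam are implemented directly in NumPy. Correctness is established three
ways: the first-layer pre-activations are checked against a direct
windowed-sum oracle; the LSTM hidden-state sequence is checked against a
step-by-step evaluation of the gate equations with explicit per-gate weight
matrices; and the analytic gradients of all three architectures are checked
against central-difference numeric gradients (relative error < 1e-8 in
development runs; the suite asserts 1e-6). The layer scans windows
left-to-right (cross-correlation, as deep-learning frameworks do); the
windowed-sum equation with index k−u is the same operation with the kernel
order reversed, which is immaterial to a learned kernel and handled
explicitly in the oracle tests.

Weights are Glorot-uniform initialized from a seeded generator; the LSTM
forget-gate bias starts at 1. Dropout is inverted (scaling by 1/(1−rate) at
train time, identity at inference). The training loop fuses the sigmoid and
binary cross-entropy gradients (δ = (p − y)/N at the output pre-activation)
for numerical stability.

## Training protocol

Adam (learning rate 3·10⁻⁴, β₁ = 0.9, β₂ = 0.999 — the paper-level recipe
pins only the learning rate; the moment coefficients are the conventional
defaults) minimizes binary cross-entropy plus an L2 penalty λ·Σw² with
λ = 10⁻³ applied to convolutional and dense kernel weights only — not
biases, not LSTM weights — the conventional reading of "L2 regularisation";
a config switch (`l2_on_kernels`) disables it. Maximum 200 epochs; early
stopping halts when the validation loss has not decreased below its best
value for 5 consecutive epochs (strict decrease, tolerance 0). The
validation set is a stratified random 10% of the training portion, seeded.
Weights are not restored to the best epoch by default (offered as
`restore_best_weights`). Batch size defaults to 32 (unspecified in the
recipe; immaterial to the contracts). Everything is reproducible from a
single seed.

Decision threshold: a score exactly at 0.5 is classified positive
(nucleosome). This tie rule is documented explicitly because "above the
threshold" phrasings are ambiguous; ties have probability ~0 for a sigmoid
output anyway.

## Evaluation protocols

**k-fold cross-validation** (default k = 20): stratified by default — class
proportions per fold within one sequence of proportionality — with overall
fold sizes within one of each other (a 4,573-item set yields 13 folds of 229
and 7 of 228). Stratification is this package's choice; non-stratified
folding is available. Per fold: a fresh network is trained on the other k−1
folds and ACC/SENS/SPEC/MCC/AUC are computed on the held-out fold; the
report carries per-fold values and mean ± sd.

**Bootstrap resampling**: n_samples (default 100) draws of sample_size
(default 100) sequences with replacement from a held-out pool; the ROC AUC
is computed per draw and the summary statistic is the mean over draws. A
draw containing a single class (AUC undefined) is redrawn and logged — at
the intended pool sizes this has negligible probability. Train/test
disjointness is asserted via sequence-id overlap.

**Metrics.** ACC = (TP+TN)/total, SENS = TP/(TP+FN), SPEC = TN/(TN+FP),
MCC = (TP·TN − FP·FN)/√((TN+FN)(TN+FP)(TP+FN)(TP+FP)). Specificity is the
universal true-negative rate; a `printed_variant` flag computes the
TN/(TN+FN) form found in some published tables, for compatibility. MCC with
a zero denominator factor returns 0 with a warning. The ROC curve is swept
over all distinct thresholds with trapezoidal integration; the tests verify
exact agreement with the pairwise-concordance definition
P(s⁺ > s⁻) + ½P(tie). Curve sweeping is delegated to scikit-learn's
`roc_curve`; the concordance oracle in the tests is independent of it.

## Synthetic data generator

The generator emulates the two signal classes the two paths are built for:

* **Periodic signal**: positions j = 0, p, 2p, … (p = 10 bp by default, the
  helical repeat scale of rotational nucleosome positioning) of a positive
  sequence are forced to a WW dinucleotide (W ∈ {A, T}, each base uniform)
  independently with probability `periodic_strength`.
* **Localized signal**: a fixed 6-mer (default GGGCCC) planted at one
  uniform random offset with probability `motif_prob`; planting happens
  after the periodic forcing, so a planted motif is always intact.
* Optional GC-content offset of the positive class (`gc_bias`; background
  P(G) = P(C) = 0.25 + gc_bias/2).

Negatives are i.i.d. uniform over ACGT. Defaults (500 per class, length
147, period 10, strength 0.8, motif probability 0.8, gc_bias 0) were chosen
once as a realistic-but-learnable setting: strength 0.8 leaves genuine
stochasticity in the periodic signal, and a 6-mer at 80% penetrance mimics
a strong but not universal motif preference. Setting every strength to 0
gives a label-permutation null in which both classes are identically
distributed.

What the simulator does **not** emulate: real genome base composition and
k-mer statistics, MNase digestion bias, read-level artifacts, boundary
effects of nucleosome calling, or correlated signal between the periodic
and motif components. Passing the synthetic recovery tests therefore shows
that the pipeline can learn the kinds of features it targets — not that it
attains any particular accuracy on real chromatin data, which requires the
external benchmark datasets and full-scale training.

`periodicity_diagnostic` verifies the generator plants what it claims: the
per-class fraction of WW dinucleotide starts at each offset modulo the
period is flat (≈ 0.25 under uniform composition) for negatives and null
data, and saturates at the planted phase for strength-1 positives.

## Problem sizes in the test-suite

The suite exercises the full-width architecture only for construction,
shape and parameter accounting (seconds). Learning checks use a scaled-down
variant — 16 conv filters, 16 LSTM units, 64 dense units — trained on 1,000
sequences (500 held out) for at most 30 epochs, which recovers the planted
signal to held-out AUC ≈ 0.99 and stays in [0.4, 0.6] on null data, with
AUC non-decreasing in the periodic strength across {0, 0.5, 1.0}. These
sizes are the package's scaled-down study conditions for CPU execution.

## Known limitations

* CPU-only NumPy execution: full-width training on benchmark-scale datasets
  (thousands of 147-bp sequences, 20 folds) is supported but slow compared
  to a GPU framework; the architecture and protocol are identical at any
  scale.
* Binary classification only; no calibration metrics.
* BED-to-sequence extraction for genome-derived datasets is an external
  step (any genome browser / `bedtools getfasta` workflow produces the
  two-FASTA input this package consumes).
* The resample protocol redraws degenerate single-class samples rather than
  scoring them; with heavily imbalanced pools and small sample sizes the
  redraw rate can be substantial (it is logged).
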
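# corenup

Nucleosome vs linker classification from DNA sequence with a hybrid
convolutional + recurrent neural network.

## The problem

Roughly 147 bp of eukaryotic DNA wraps around a histone octamer to form a
nucleosome; stretches between nucleosomes are linker DNA. Sequence itself
carries part of the positioning signal: nucleosomal DNA shows quasi-periodic
(~10 bp) dinucleotide patterns that favour bending, alongside localized motif
preferences. Given a FASTA file of fixed-length sequences, the task is binary
classification: nucleosome (positive) or linker (negative).

## The model

The CORENup architecture feeds a shared convolutional feature extractor into
two parallel paths whose flattened outputs are concatenated and classified by
dense layers:

```
input (L=147, 4 one-hot channels)
  └─ Conv1D(50 filters, kernel 5, same padding, ReLU) → MaxPool(2,2) → Dropout(0.5)
       ├─ LSTM(50 units, sequence output) → Dropout → Flatten   (periodic features,  3650 dims)
       └─ Conv1D(50, kernel 10, same, ReLU) → MaxPool(2,2)
            → Dropout → Flatten                                 (localized features, 1800 dims)
  └─ Concatenate (5450) → Dense(370, ReLU) → Dropout(0.5) → Dense(1, sigmoid)
```

The convolutional path captures static, non-periodic patterns
(`y_k^i = φ(Σ_u w_u^i x_{k−u})`, φ = ReLU); the sequence-output LSTM — with
forget/input/output gates `f_t, i_t, o_t = σ(W x_t + U h_{t−1} + b)`, cell
state `s_t = f_t ⊙ s_{t−1} + i_t ⊙ tanh(·)` and output `h_t = o_t ⊙ tanh(s_t)`
— captures periodic structure. With the default widths the network has
2,063,541 trainable parameters (1,050 feature-extraction + 20,200 LSTM path +
25,050 conv path + 2,017,241 dense path).

Training: Adam (learning rate 3·10⁻⁴) on binary cross-entropy with L2 weight
decay (λ = 10⁻³ on conv/dense kernels), at most 200 epochs, early stopping
when the validation loss (on a stratified 10% split) fails to decrease for 5
consecutive epochs; class-1 probabilities are thresholded at 0.5. Evaluation:
stratified 20-fold cross-validation reporting ACC, SENS, SPEC, MCC and ROC
AUC per fold (mean ± sd), or bootstrap resampling (100 samples of 100
sequences, with replacement) reporting mean AUC.

Everything — layers, backpropagation, Adam — is implemented in NumPy; no deep
learning framework is required. Two reference baselines (a pure two-block
ConvNet and a conv-stem + LSTM network) are included for architecture
comparisons, plus a synthetic-data generator that plants a tunable periodic
WW-dinucleotide signal and a localized motif so both paths can be exercised
without any external data.

## Worked example

```python
from corenup import (CORENup, ModelConfig, TrainConfig,
                     SimulationConfig, simulate_dataset)

# 1500 sequences of 147 bp; positives carry a period-10 WW signal at
# strength 0.8 and a GGGCCC motif in 80% of sequences
ds = simulate_dataset(SimulationConfig(n_per_class=750, seed=11))

import numpy as np
idx = np.random.default_rng(1).permutation(len(ds))
train_ds, test_ds = ds.subset(idx[:1000]), ds.subset(idx[1000:])

scaled = ModelConfig(conv1_filters=16, lstm_units=16, conv2_filters=16,
                     dense_units=64)          # CPU-friendly variant
model = CORENup(train_ds, scaled)
res = model.fit(TrainConfig(seed=5, max_epochs=30))
print({k: round(v, 3) for k, v in res.evaluate(test_ds).items()})
```

prints

```
{'ACC': 0.944, 'SENS': 0.964, 'SPEC': 0.923, 'MCC': 0.889, 'AUC': 0.989}
```

i.e. the scaled-down network recovers the planted signal almost perfectly on
held-out sequences (AUC 0.989), while the same run on signal-free data stays
at chance (AUC ≈ 0.47). The full-width architecture table is printed by
`model.summary()` or `corenup summary --model corenup`.

## Command line

```bash
corenup simulate --out data/ --seed 7 --n-per-class 500
corenup train data/nucleosomes.fasta data/linkers.fasta --out run/ --seed 0
corenup crossval data/nucleosomes.fasta data/linkers.fasta --k 20 --out cv/
corenup predict run/weights.npz new_sequences.fasta --out preds.tsv
corenup summary --model corenup
```

Every run writes a `manifest.json` with the config snapshot, seeds and input
digests, so results are reproducible byte for byte.

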
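# botnet-rna

Sequence-based prediction of long non-coding RNA (lncRNA) interactions with
miRNAs or proteins, using a lightweight "bag of tricks" recurrent classifier
(BoT-Net) and, at its core, a systematic treatment of the *fixed-length
problem*: lncRNAs range from a couple of hundred to tens of thousands of
nucleotides, and how a variable-length sequence is squeezed into the
fixed-length input a neural classifier needs largely decides how well the
classifier works.

The package is aimed at computational biologists who want to train and
evaluate interaction predictors from nothing but FASTA files and a table of
known interacting pairs, and at methodologists who want to probe *which
region* of a long transcript carries the discriminative signal.

## The method

**Fixed-length generation.** Six strategies map a corpus of variable-length
sequences to one common length: the three traditional baselines — pad all to
the corpus maximum, truncate all to the minimum, pad/truncate to the average
— and three positional sub-sequence settings that keep only the first *X*
residues, the last *Y* residues, or the first-*X* plus last-*Y* residues.
Padding and truncation act on the sequence end. The sub-sequence settings
are the interesting ones: a 20,000-nt lncRNA reduced to its first 50 nt
often retains almost all of the signal, while max-length copy padding drowns
the corpus in padding symbols.

**Classifier.** Each fixed-length (lncRNA, partner) pair is fused into one
instance, tokenized into overlapping k-mers (window *k*, stride 1 by
default; vocabulary = all 4^k RNA k-mers plus PAD/UNK), and classified by:

- a learned embedding table E ∈ R^(vocab × 120), initialized from a standard
  normal, regularized by dropping whole token vectors (p = 0.004) and
  individual weights (p = 0.005);
- a single-layer LSTM (hidden size H = 120) with the standard gate
  equations i_t = σ(W^i x_t + U^i h_{t-1}), f_t, o_t alike,
  cin_t = tanh(W^c x_t + U^c h_{t-1}), c_t = f_t ⊙ c_{t-1} + i_t ⊙ cin_t,
  h_t = o_t ⊙ tanh(c_t), regularized by DropConnect on the hidden-to-hidden
  matrices U (one mask per forward/backward pass, p = 0.004);
- triple pooling over time — [max; mean; last] — giving a 3H = 360-d vector;
- batch normalization → dropout (0.1) → dense 360→50 (sigmoid) → batch
  normalization → dropout → dense 50→2 → softmax, trained with categorical
  cross-entropy and AdamW (decoupled weight decay: lr 0.01, λ 0.02, batch
  64, per-epoch learning-rate decay).

Everything — forward pass, backpropagation through time, batch-norm
backward, AdamW — is implemented in NumPy and validated against central
finite differences and hand-evaluated updates in the test suite.

**Evaluation.** Stratified 5-fold cross-validation with a 10% validation
split for early stopping; metrics ACC, specificity, sensitivity, precision,
F1, Matthews correlation coefficient and AUROC (Mann–Whitney rank statistic
with midranks).

**Synthetic corpora.** Because the public interaction benchmarks are not
redistributable as accessioned files, `botnet.synthetic` generates
seed-reproducible corpora with the same statistical shape: variable-length
lncRNAs, short partners, random-pairing negatives disjoint from positives,
and a binding-site-like motif planted at a configurable region of
interacting lncRNAs — making "which region is informative" a question with
a known answer.

## Worked example

```python
from botnet import SyntheticConfig, generate_corpus
from botnet.length_policy import LengthPolicy, Strategy
from botnet.train_eval import PipelineConfig, TrainConfig, cross_validate

corpus = generate_corpus(SyntheticConfig(n_pos=500, n_neg=500,
                                         lnc_len_range=(200, 2000), seed=1))
pipe = PipelineConfig(lnc_policy=LengthPolicy(Strategy.START, X=20),
                      partner_policy=LengthPolicy(Strategy.MAX_PAD), lnc_k=5)
result = cross_validate(corpus, pipe, {"n_embedding": 32, "hidden": 32},
                        TrainConfig(max_epochs=6, patience=2, seed=1),
                        n_folds=5, seed=1)
print({m: round(v, 4) for m, v in result.mean.items()})
```

prints

```
{'ACC': 1.0, 'SPE': 1.0, 'SEN': 1.0, 'PRE': 1.0, 'F1': 1.0, 'MCC': 1.0, 'AUROC': 1.0}
```

— the start-region setting reads the planted 10-nt motif in the first 20
residues of each positive lncRNA, so held-out prediction is essentially
perfect. Swapping the policy to `LengthPolicy(Strategy.END, Y=20)` (the last
20 residues, which contain no signal) collapses mean accuracy to ≈ 0.5.
The scripts under `examples/` walk through the corpus generator, the
fixed-length settings, training/evaluation, and the region sweep.

A shell interface wraps the same pipeline:

```
botnet simulate --seed 1 --out corpus/
botnet train  --lnc-fasta corpus/lncrna.fasta --partner-fasta corpus/partner.fasta \
              --pairs corpus/pairs.tsv --task lnc_mirna --out run/
botnet evaluate --checkpoint run/checkpoint.npz --lnc-fasta corpus/lncrna.fasta \
              --partner-fasta corpus/partner.fasta --pairs corpus/pairs.tsv --out eval/
```

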
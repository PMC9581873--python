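# Methods

## Problem and model

The package classifies (lncRNA, partner) sequence pairs as interactive or
non-interactive using only the raw residue strings. The partner is a miRNA
(RNA alphabet) or a protein (20-letter alphabet). A pair is one instance: the
two sides are each mapped to a fixed length, fused in order (lncRNA first),
tokenized into k-mers, and fed to a single-head recurrent classifier.

The classifier is deliberately small — one LSTM layer plus a two-layer dense
head — and relies on a collection of regularization and optimization tricks
rather than depth: embedding-level dropout at two granularities, DropConnect
on the recurrent weight matrices, triple pooling (max/mean/last over time),
two batch-normalization layers, standard dropout, decoupled weight decay
(AdamW) and per-epoch learning-rate decay. The entire network and its
backward pass are written in NumPy in double precision; gradient correctness
is enforced by finite-difference checks in the test suite rather than taken
on faith from an autodiff framework.

Modeling assumptions worth making explicit:

- **Independence of pairs.** Hidden state is reset (h_0 = c_0 = 0) for every
  instance. Carrying state across shuffled batches of independent pairs has
  no statistical meaning; a `stateful` training variant is deliberately not
  offered.
- **Positional, content-blind region selection.** The sub-sequence settings
  keep the first X and/or last Y residues regardless of content or secondary
  structure. The claim they embody is that discriminative residue
  distributions are *location-concentrated*, not that the model knows where
  binding sites are.
- **Junction hygiene.** Tokenization is per segment; no k-mer spans the
  lncRNA/partner junction, since such chimeric tokens are artifacts of
  concatenation rather than biology.

## Fixed-length strategies

Six strategies, all emitting one common length per corpus side:

| strategy | target length | short sequences | long sequences |
|---|---|---|---|
| max_pad | corpus max (training split) | end-padded | — (truncated if a held-out sequence exceeds the training max) |
| min_trunc | corpus min | — | end-truncated |
| avg_hybrid | corpus mean, rounded half-up | end-padded | end-truncated |
| start | X | end-padded | first X kept |
| end | Y | end-padded | last Y kept |
| start_end | X + Y | end-padded | first X + last Y |

Padding and truncation act on the sequence end, the dominant convention.
Corpus statistics (min/max/mean) are computed on the training split only, so
target lengths never leak information from held-out pairs; a held-out
sequence longer than the training maximum is truncated to preserve the
fixed-length contract. If X + Y exceeds a sequence's length under
`start_end`, the two windows overlap and a warning is logged; the result is
still emitted and padded to X + Y. Coordinates in documentation and logs are
1-based inclusive; internal slicing is half-open.

## Tokenization

The vocabulary enumerates all |alphabet|^k k-mers lexicographically
(4^k for RNA), so indices are corpus-independent and stable across
save/load. Two indices are reserved: PAD = 0 for any k-mer containing the
padding symbol (PAD wins when a window contains both padding and ambiguity
symbols, since padding is structural), and UNK = 1 for k-mers containing an
ambiguity residue (N/X). Defaults: k = 5, stride 1 (overlapping) for
RNA–RNA; k = 1 for RNA–protein, where 20^5 would dwarf any training corpus.
Mixed-alphabet pairs use one vocabulary per segment, offset into a single
contiguous index space so a single embedding table serves both sides, with
PAD/UNK shared.

## Network parameters and defaults

| parameter | default | note |
|---|---|---|
| embedding dim | 120 | grid-search optimum for both tasks |
| hidden size H | 120 | pooled vector is 3H = 360; see below |
| dense hidden | 50 | compact representation before the softmax |
| embedding vector dropout | 0.004 | whole token vector zeroed |
| embedding weight dropout | 0.005 | individual entries zeroed |
| DropConnect | 0.004 | recurrent matrices U, one mask per pass |
| standard dropout | 0.1 (RNA–RNA), 0.4 (RNA–protein) | after each batch norm |
| learning rate | 0.01 (RNA–RNA), 0.05 (RNA–protein) | AdamW |
| weight decay λ | 0.02 (RNA–RNA), 0.01 (RNA–protein) | decoupled |
| batch size | 64 | |
| lr decay | ×0.95 per epoch | multiplicative; the schedule is a package choice |
| max epochs / patience | 100 / 5 | early stopping on validation loss |
| batch-norm momentum / ε | 0.1 / 1e-5 | package choice |

The hidden size deserves a comment: the 360 → 50 dense head fixes the
default at H = 120 (three pooled views of an H-vector), but H is fully
configurable, and the package's own scaled-down experiments use H = 32.

Further design choices that were genuinely open:

- **Cell update.** The standard LSTM update
  c_t = f_t ⊙ c_{t-1} + i_t ⊙ cin_t is used.
- **Gate biases** are included (standard practice) and can be disabled with
  `lstm_bias=False` for a literal-gate-equation variant.
- **PAD handling.** PAD embeddings are zero-initialized but trainable, and
  PAD positions participate in pooling. This is faithful to the padding-bias
  framing the sub-sequence settings are designed to expose: masking padding
  away would partially solve the problem the method studies.
- **Dropout convention.** Inverted dropout (scale by 1/(1-p) at train time)
  is the default so evaluation is the identity; the mathematically
  equivalent test-time (1-p) scaling is available via
  `inverted_dropout=False`. DropConnect follows the same convention, and
  p = 0 reproduces the unregularized LSTM bit-for-bit.
- **AdamW.** Moments accumulate the raw gradient only; the decay term
  -lr·λ·w uses the *pre-update* weight. With λ = 0 the update is plain Adam.
  Non-finite gradients raise, naming the offending tensor.
- **Initialization.** Embeddings ~ N(0, 1) with the PAD row zeroed; LSTM and
  dense weights uniform on ±1/√fan-in; all draws from a seeded generator.
- **Determinism.** Every stochastic operation (init, dropout masks, batch
  shuffling, fold splits, corpus generation) consumes an explicit seed;
  two runs with the same seed produce bitwise-identical weights and logs.

## Evaluation

Confusion-matrix metrics use the standard textbook definitions; the test
suite cross-checks every metric against brute-force confusion arithmetic and
scikit-learn. AUROC is computed from the Mann–Whitney rank statistic with
midranks, which handles tied scores exactly. Ratios with zero denominators
are reported as 0 and flagged `undefined` rather than raised, so sweeps
survive degenerate folds. Cross-validation reports per-fold metrics, their
unweighted mean (the headline numbers), and a pooled report over
concatenated held-out predictions. Grid-search ties are broken by smaller
parameter count, then lexicographic configuration order.

## Negative sampling

Negative pairs are generated by random pairing: both id lists are shuffled
(Knuth–Durstenfeld algorithm, ten passes by default, written out explicitly
and chi-square-tested for permutation uniformity), then random combinations
are drawn, rejecting any pair present in the positive set *or already drawn
as a negative* — duplicate negatives would make label counts ill-defined.
Rejection sampling is capped at 100·n attempts.

## Synthetic corpora: what they emulate, and what they do not

`generate_corpus` reproduces the statistical shape of the sequence-based
interaction benchmarks: lncRNA lengths uniform (optionally log-uniform, for
the heavy right tail of real length distributions) over a configurable
range; miRNA-like partners of 17–25 nt (or protein partners); partners
reused across many pairs as in real corpora; negatives by random pairing,
disjoint from positives. The discriminative signal is a planted
binding-site-like motif (default: a 10-nt let-7-seed-like string) at a
configurable region of *interacting* lncRNAs, with optional positional
jitter and per-residue mutation.

Two deliberate departures from naive realism:

- **lncRNAs are not reused across pairs.** Motif-bearing lncRNAs occur only
  in positives, so sharing one lncRNA between a training and a held-out pair
  would let a classifier read the label off sequence *identity* (e.g. a
  memorized tail) instead of the planted region, corrupting the
  region-recovery ground truth. One fresh lncRNA per pair keeps the planted
  region the only recoverable signal. Partners are reused — they occur in
  both classes, so their identity carries almost no label information.
- **The null calibration uses fresh partners.** Even "almost no" is not
  none: with a small reused partner pool, chance per-partner class imbalance
  is a corpus property shared by training and held-out folds, and a
  classifier can exploit it (measurably, AUROC ≈ 0.55–0.6 on otherwise
  signal-free corpora). The null experiment therefore draws one fresh
  partner per pair, making positives and negatives fully exchangeable —
  which is precisely what a null should be.

What passing tests on these corpora show: that the pipeline recovers a
region-localized signal when present, at the planted location, and finds
nothing when none exists. What they do not show: performance on real
benchmarks, where the signal is weaker, distributed, partner-dependent
(actual hybridization), and confounded with composition biases. The
generator makes no attempt to simulate binding energetics, secondary
structure, or expression.

## Scaled study conditions

The packaged region-recovery experiment uses 2000 pairs (lncRNA lengths
200–2000 nt), a 10-nt start-planted motif, k = 5, a 32/32 embedding/hidden
model, 5-fold cross-validation, and three corpus seeds; the null calibration
uses 1000 pairs and 2-fold splits. These sizes are the package's desk-scale
choice: the planted signal is strong enough that the start-region setting
saturates (mean ACC ≈ 1.0) while the end-region setting stays at chance
(≈ 0.5), so larger corpora or models would not change the qualitative
conclusion.

## Known limitations

- The NumPy LSTM is single-threaded BLAS-bound; training is practical to a
  few tens of thousands of pairs, not millions.
- Max-length copy padding with real lncRNA maxima (>20,000 nt) produces
  extremely long token sequences; it is implemented and tested, but the
  sub-sequence settings are the intended operating mode at that scale.
- Mixed-alphabet support offsets vocabularies rather than learning separate
  embedding tables; very large protein k would inflate the table
  (20^k rows), hence the k = 1 default for the protein task.
- Sequences shorter than k cannot be tokenized; the fixed-length policies
  make this unreachable in normal use (budgets ≥ k, padding to the budget).
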
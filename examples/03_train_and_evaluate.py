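"""Train the classifier on a synthetic corpus and evaluate it by
cross-validation.

Uses the start-region setting (first 20 lncRNA residues) against a corpus
whose interacting lncRNAs carry a start-planted motif, so held-out
performance should be near-perfect; the printed metrics are 5-fold means.
"""

from botnet import SyntheticConfig, generate_corpus
from botnet.length_policy import LengthPolicy, Strategy
from botnet.train_eval import PipelineConfig, TrainConfig, cross_validate

corpus = generate_corpus(
    SyntheticConfig(n_pos=500, n_neg=500, lnc_len_range=(200, 2000), seed=1)
)
pipe = PipelineConfig(
    lnc_policy=LengthPolicy(Strategy.START, X=20),     # first 20 nt of the lncRNA
    partner_policy=LengthPolicy(Strategy.MAX_PAD),     # miRNAs padded to corpus max (25)
    lnc_k=5,                                           # overlapping 5-mers, stride 1
)
result = cross_validate(
    corpus, pipe,
    model_kwargs={"n_embedding": 32, "hidden": 32},    # scaled-down model
    train_config=TrainConfig(max_epochs=6, patience=2, seed=1),
    n_folds=5, seed=1,
)
print("per-fold ACC:", [round(r.ACC, 4) for r in result.fold_reports])
print("5-fold means:", {m: round(v, 4) for m, v in result.mean.items()})
# ACC/AUROC at or near 1.0: the motif sits inside the first 20 residues, so
# the start-region setting sees the full label signal on held-out pairs.
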
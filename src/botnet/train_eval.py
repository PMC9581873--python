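"""Training with decoupled weight decay, cross-validation, grid search, the
region sweep, and the seven evaluation metrics.

The optimizer is AdamW: Adam moment estimates are computed on the raw
gradient only, and the weight-decay term -lr * lambda * w is applied directly
in the parameter update, so the penalty is never rescaled by the adaptive
moments (unlike L2 regularization folded into the loss).  The learning rate
is multiplied by a decay factor after every epoch, and early stopping
monitors validation loss.

Metrics: accuracy, specificity TN/(TN+FP), sensitivity TP/(TP+FN), precision
TP/(TP+FP), F1, Matthews correlation coefficient
(TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), and AUROC computed from
the Mann–Whitney rank statistic with midranks for ties.  Ratios with a zero
denominator are reported as 0 and flagged, so sweeps keep running on
degenerate folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from botnet.length_policy import (
    LengthPolicy,
    CorpusLengthStats,
    Strategy,
    apply_policy,
    fuse_pair,
)
from botnet.model import BotNet, ModelConfig
from botnet.sequence_io import InteractionPair, PairedCorpus, split_folds
from botnet.tokenizer import KmerVocabulary, PairEncoder, TokenizedPair, build_vocab

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SPE", "SEN", "PRE", "F1", "MCC", "AUROC")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the lncRNA–miRNA optima
    (lr 0.01, weight decay 0.02, batch size 64)."""

    learning_rate: float = 0.01
    weight_decay: float = 0.02
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 5
    lr_decay_factor: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch normalization)")


class AdamW:
    """Adam with decoupled weight decay.

    ``m`` and ``v`` accumulate the raw gradient; the decay term is added only
    in the update step:  w <- w - lr * (m_hat / (sqrt(v_hat) + eps) + lambda*w).
    With ``weight_decay=0`` this is exactly plain Adam.
    """

    def __init__(self, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for name, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for tensor {name!r}")
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            w = params[name]
            step = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            # decay term uses the pre-update weight, decoupled from the moments
            w -= self.lr * (step + self.weight_decay * w)


def adamw_step(params, grads, optimizer: AdamW) -> dict[str, np.ndarray]:
    """One decoupled-decay update; mutates and returns ``params``."""
    optimizer.step(params, grads)
    return params


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class TokenizedDataset:
    """A stack of equal-shape tokenized pairs."""

    token_ids: np.ndarray  # (N, T) int64
    labels: np.ndarray     # (N,) int64
    segment_lengths: tuple[int, int]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "TokenizedDataset":
        return TokenizedDataset(self.token_ids[idx], self.labels[idx], self.segment_lengths)


def stack_pairs(pairs: Sequence[TokenizedPair]) -> TokenizedDataset:
    """Stack tokenized pairs into matrices; all must share segment lengths."""
    if not pairs:
        raise ValueError("no pairs to stack")
    seg = pairs[0].segment_lengths
    for p in pairs:
        if p.segment_lengths != seg:
            raise ValueError(f"heterogeneous segment lengths: {p.segment_lengths} vs {seg}")
    ids = np.stack([p.token_ids for p in pairs])
    labels = np.array([p.label for p in pairs], dtype=np.int64)
    return TokenizedDataset(ids, labels, seg)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _dataset_loss(model: BotNet, ds: TokenizedDataset, batch_size: int = 256) -> float:
    total = 0.0
    for i in range(0, len(ds), batch_size):
        ids = ds.token_ids[i : i + batch_size]
        probs = model.forward(ids, training=False)
        p = np.clip(probs[np.arange(len(ids)), ds.labels[i : i + batch_size]], 1e-300, None)
        total += float(-np.log(p).sum())
    return total / len(ds)


def train(
    model: BotNet,
    train_ds: TokenizedDataset,
    val_ds: TokenizedDataset | None = None,
    config: TrainConfig = TrainConfig(),
) -> tuple[BotNet, list[dict]]:
    """Minimize cross-entropy over shuffled mini-batches.

    Per epoch: shuffle, step AdamW per batch, decay the learning rate, then
    score the validation set in eval mode.  Early-stops when validation loss
    has not improved for ``patience`` epochs and restores the best
    checkpoint.  Fully reproducible given ``config.seed``.
    """
    if len(np.unique(train_ds.labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(config.learning_rate, config.weight_decay)
    log: list[dict] = []
    best_val = np.inf
    best_state = model.get_state()
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_ds))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            loss, grads, _ = model.loss_and_grads(
                train_ds.token_ids[idx], train_ds.labels[idx], training=True, rng=rng
            )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        opt.lr *= config.lr_decay_factor
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": epoch_loss / max(n_batches, 1),
        }
        if val_ds is not None and len(val_ds):
            val_loss = _dataset_loss(model, val_ds)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = model.get_state()
                since_best = 0
            else:
                since_best += 1
        log.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if val_ds is not None and since_best >= config.patience:
            break
    if val_ds is not None and len(val_ds) and np.isfinite(best_val):
        model.set_state(best_state)
    return model, log


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the seven evaluation values.

    Any metric whose denominator is zero is reported as 0 and listed in
    ``undefined``.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SPE: float
    SEN: float
    PRE: float
    F1: float
    MCC: float
    AUROC: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        vals = " ".join(f"{m}={getattr(self, m):.4f}" for m in METRIC_NAMES)
        return f"TP={self.TP} TN={self.TN} FP={self.FP} FN={self.FN} {vals}"


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann–Whitney rank statistic; midranks handle ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Score binary predictions.

    ``probabilities`` is either the positive-class probability per instance
    (shape (N,)) or the full softmax output (shape (N, 2)).
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim == 2:
        probs = probs[:, 1]
    if len(labels) != len(probs):
        raise ValueError(f"{len(labels)} labels but {len(probs)} probabilities")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (probs >= threshold).astype(int)
    TP = int(np.sum((labels == 1) & (pred == 1)))
    TN = int(np.sum((labels == 0) & (pred == 0)))
    FP = int(np.sum((labels == 0) & (pred == 1)))
    FN = int(np.sum((labels == 1) & (pred == 0)))
    undefined: list[str] = []
    acc = _safe_div(TP + TN, TP + TN + FP + FN, "ACC", undefined)
    spe = _safe_div(TN, TN + FP, "SPE", undefined)
    sen = _safe_div(TP, TP + FN, "SEN", undefined)
    pre = _safe_div(TP, TP + FP, "PRE", undefined)
    f1 = _safe_div(2 * pre * sen, pre + sen, "F1", undefined)
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = _safe_div(float(TP) * TN - float(FP) * FN, mcc_den, "MCC", undefined)
    if labels.min() == labels.max():
        undefined.append("AUROC")
        auroc = 0.0
    else:
        auroc = auroc_score(labels, probs)
    return MetricsReport(TP, TN, FP, FN, acc, spe, sen, pre, f1, mcc, auroc, tuple(undefined))


def mean_metrics(reports: Sequence[MetricsReport]) -> dict[str, float]:
    """Unweighted arithmetic mean of the seven metrics over folds."""
    return {m: float(np.mean([getattr(r, m) for r in reports])) for m in METRIC_NAMES}


# ---------------------------------------------------------------------------
# corpus -> tokenized dataset pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing settings shared by cross-validation and sweeps."""

    lnc_policy: LengthPolicy
    partner_policy: LengthPolicy
    lnc_k: int = 5
    partner_k: int | None = None  # defaults to lnc_k for same-alphabet tasks
    stride: int = 1


def build_encoder(corpus: PairedCorpus, pipe: PipelineConfig) -> PairEncoder:
    lnc_alpha = next(iter(corpus.lnc_records.values())).alphabet
    partner_alpha = next(iter(corpus.partner_records.values())).alphabet
    partner_k = pipe.partner_k if pipe.partner_k is not None else pipe.lnc_k
    lnc_vocab = build_vocab(lnc_alpha, pipe.lnc_k, pipe.stride)
    if partner_alpha == lnc_alpha and partner_k == pipe.lnc_k:
        return PairEncoder(lnc_vocab)
    return PairEncoder(lnc_vocab, build_vocab(partner_alpha, partner_k, pipe.stride))


def tokenize_pairs(
    corpus: PairedCorpus,
    pairs: Sequence[InteractionPair],
    pipe: PipelineConfig,
    encoder: PairEncoder,
    train_pairs: Sequence[InteractionPair] | None = None,
) -> TokenizedDataset:
    """Fixed-length + fuse + tokenize a pair list into a dataset.

    Corpus length statistics for the data-dependent strategies are computed
    from the records referenced by ``train_pairs`` (default: ``pairs``), so a
    held-out split never defines the target lengths.
    """
    ref = train_pairs if train_pairs is not None else pairs
    lnc_ids = sorted({p.a_id for p in ref} | {p.a_id for p in pairs})
    partner_ids = sorted({p.b_id for p in ref} | {p.b_id for p in pairs})
    lnc_stats = CorpusLengthStats.from_lengths(
        [corpus.lnc_records[i].length for i in sorted({p.a_id for p in ref})]
    )
    partner_stats = CorpusLengthStats.from_lengths(
        [corpus.partner_records[i].length for i in sorted({p.b_id for p in ref})]
    )
    lnc_fixed = dict(zip(lnc_ids, apply_policy(
        [corpus.lnc_records[i].residues for i in lnc_ids], pipe.lnc_policy, lnc_stats)))
    partner_fixed = dict(zip(partner_ids, apply_policy(
        [corpus.partner_records[i].residues for i in partner_ids], pipe.partner_policy, partner_stats)))
    tokenized = [
        encoder.encode(fuse_pair(lnc_fixed[p.a_id], partner_fixed[p.b_id]), p.label)
        for p in pairs
    ]
    return stack_pairs(tokenized)


# ---------------------------------------------------------------------------
# cross-validation, grid search, region sweep
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    pooled: MetricsReport
    logs: list[list[dict]] = field(default_factory=list)


def cross_validate(
    corpus: PairedCorpus,
    pipe: PipelineConfig,
    model_kwargs: dict,
    train_config: TrainConfig,
    n_folds: int = 5,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> CrossValResult:
    """Stratified k-fold cross-validation of the full pipeline.

    One model is trained per fold on the training split (with its stratified
    validation subset for early stopping) and scored on the held-out fold.
    Reports per-fold metrics, their unweighted mean, and a pooled report over
    the concatenated held-out predictions.
    """
    pairs = list(corpus.pairs)
    folds = split_folds(pairs, n_folds=n_folds, val_fraction=val_fraction, seed=seed)
    encoder = build_encoder(corpus, pipe)
    reports = []
    logs = []
    all_labels: list[np.ndarray] = []
    all_probs: list[np.ndarray] = []
    for f, fold in enumerate(folds):
        train_pairs = [pairs[i] for i in fold.train_idx]
        val_pairs = [pairs[i] for i in fold.val_idx]
        test_pairs = [pairs[i] for i in fold.test_idx]
        train_ds = tokenize_pairs(corpus, train_pairs, pipe, encoder)
        val_ds = tokenize_pairs(corpus, val_pairs, pipe, encoder, train_pairs) if val_pairs else None
        test_ds = tokenize_pairs(corpus, test_pairs, pipe, encoder, train_pairs)
        model = BotNet(
            ModelConfig(vocab_size=encoder.vocab_size, **model_kwargs),
            seed=train_config.seed + f,
        )
        fold_cfg = TrainConfig(**{**asdict(train_config), "seed": train_config.seed + f})
        model, log = train(model, train_ds, val_ds, fold_cfg)
        probs = model.predict_proba(test_ds.token_ids)
        reports.append(compute_metrics(test_ds.labels, probs))
        logs.append(log)
        all_labels.append(test_ds.labels)
        all_probs.append(probs[:, 1])
        logger.info("fold %d: %s", f, reports[-1].summary())
    pooled = compute_metrics(np.concatenate(all_labels), np.concatenate(all_probs))
    return CrossValResult(reports, mean_metrics(reports), pooled, logs)


@dataclass
class GridSpec:
    """Candidate lists per hyperparameter plus the selection metric.

    Keys in ``model_grid`` are ModelConfig fields (plus ``k``/``stride`` for
    the tokenizer); keys in ``train_grid`` are TrainConfig fields.
    """

    model_grid: dict[str, list] = field(default_factory=dict)
    train_grid: dict[str, list] = field(default_factory=dict)
    selection_metric: str = "ACC"


def grid_search(
    corpus: PairedCorpus,
    base_pipe: PipelineConfig,
    grid: GridSpec,
    train_config: TrainConfig = TrainConfig(),
    model_kwargs: dict | None = None,
    val_fraction: float = 0.1,
    seed: int = 0,
    budget: int | None = None,
):
    """Exhaustive grid search scored on a stratified validation split.

    Returns (best combination, leaderboard sorted by the selection metric).
    Ties are broken by smaller trainable-parameter count, then by the
    lexicographic order of the configuration items.
    """
    keys = sorted(grid.model_grid) + sorted(grid.train_grid)
    if not keys:
        raise ValueError("empty grid")
    values = [grid.model_grid[k] for k in sorted(grid.model_grid)]
    values += [grid.train_grid[k] for k in sorted(grid.train_grid)]
    combos = list(itertools.product(*values))
    if budget is not None:
        combos = combos[:budget]
    pairs = list(corpus.pairs)
    folds = split_folds(pairs, n_folds=2, val_fraction=val_fraction, seed=seed)
    train_pairs = [pairs[i] for i in folds[0].train_idx]
    val_pairs = [pairs[i] for i in folds[0].val_idx]
    leaderboard = []
    for combo in combos:
        conf = dict(zip(keys, combo))
        pipe = PipelineConfig(
            lnc_policy=base_pipe.lnc_policy,
            partner_policy=base_pipe.partner_policy,
            lnc_k=conf.pop("k", base_pipe.lnc_k),
            partner_k=base_pipe.partner_k,
            stride=conf.pop("stride", base_pipe.stride),
        )
        mkw = dict(model_kwargs or {})
        tkw = {}
        for key, val in conf.items():
            (tkw if key in TrainConfig.__dataclass_fields__ else mkw)[key] = val
        encoder = build_encoder(corpus, pipe)
        train_ds = tokenize_pairs(corpus, train_pairs, pipe, encoder)
        val_ds = tokenize_pairs(corpus, val_pairs, pipe, encoder, train_pairs)
        model = BotNet(ModelConfig(vocab_size=encoder.vocab_size, **mkw), seed=seed)
        tc = TrainConfig(**{**asdict(train_config), **tkw, "seed": seed})
        model, _ = train(model, train_ds, val_ds, tc)
        report = compute_metrics(val_ds.labels, model.predict_proba(val_ds.token_ids))
        leaderboard.append({
            "config": dict(zip(keys, combo)),
            "score": getattr(report, grid.selection_metric),
            "n_parameters": model.count_parameters(),
            "report": report,
        })
    leaderboard.sort(
        key=lambda e: (-e["score"], e["n_parameters"], sorted(e["config"].items()).__repr__())
    )
    return leaderboard[0], leaderboard


def region_sweep(
    corpus: PairedCorpus,
    partner_policy: LengthPolicy,
    budgets: Sequence[int] = tuple(range(5, 55, 5)),
    settings: Sequence[Strategy] = (Strategy.START, Strategy.END, Strategy.START_END),
    model_kwargs: dict | None = None,
    train_config: TrainConfig = TrainConfig(),
    n_folds: int = 5,
    lnc_k: int = 5,
    stride: int = 1,
    seed: int = 0,
) -> list[dict]:
    """Cross-validate every (sub-sequence setting, residue budget) cell.

    Budgets default to 5..50 in steps of 5.  For the START_END setting the
    budget is used for both sides (X = Y = budget).  Returns one row per cell
    with the mean metrics, mirroring the region-informativeness experiment.
    """
    rows = []
    for setting in settings:
        for budget in budgets:
            if setting is Strategy.START:
                policy = LengthPolicy(setting, X=budget)
            elif setting is Strategy.END:
                policy = LengthPolicy(setting, Y=budget)
            else:
                policy = LengthPolicy(setting, X=budget, Y=budget)
            pipe = PipelineConfig(policy, partner_policy, lnc_k=lnc_k, stride=stride)
            result = cross_validate(
                corpus, pipe, model_kwargs or {}, train_config, n_folds=n_folds, seed=seed
            )
            row = {"setting": setting.value, "budget": budget, **result.mean}
            rows.append(row)
            logger.info("sweep %s budget=%d: %s", setting.value, budget, result.mean)
    return rows
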
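"""Optimizer exactness, metric definitions, the training loop, and
cross-validation plumbing."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from botnet import BotNet, ModelConfig, SyntheticConfig, generate_corpus
from botnet.length_policy import LengthPolicy, Strategy
from botnet.train_eval import (
    AdamW,
    GridSpec,
    PipelineConfig,
    TrainConfig,
    TokenizedDataset,
    adamw_step,
    auroc_score,
    build_encoder,
    compute_metrics,
    cross_validate,
    grid_search,
    mean_metrics,
    region_sweep,
    stack_pairs,
    tokenize_pairs,
    train,
)


class TestAdamW:
    def test_single_scalar_step_matches_hand_update(self):
        """One decoupled step from fresh moments, evaluated by hand."""
        lr, lam, b1, b2, eps = 0.1, 0.02, 0.9, 0.999, 1e-8
        w0, g = 1.5, 0.4
        params = {"w": np.array([w0])}
        opt = AdamW(lr, lam, b1, b2, eps)
        adamw_step(params, {"w": np.array([g])}, opt)
        m = (1 - b1) * g
        v = (1 - b2) * g * g
        m_hat = m / (1 - b1)
        v_hat = v / (1 - b2)
        expected = w0 - lr * m_hat / (np.sqrt(v_hat) + eps) - lr * lam * w0
        assert params["w"][0] == pytest.approx(expected, abs=1e-15)

    def test_zero_decay_is_plain_adam_bitwise(self, rng):
        """lambda = 0 reproduces a reference Adam trajectory exactly."""
        shapes = {"a": (3, 2), "b": (4,)}
        lr, b1, b2, eps = 0.05, 0.9, 0.999, 1e-8
        params = {k: rng.normal(size=s) for k, s in shapes.items()}
        ref = {k: v.copy() for k, v in params.items()}
        opt = AdamW(lr=lr, weight_decay=0.0)
        m = {k: np.zeros(s) for k, s in shapes.items()}
        v = {k: np.zeros(s) for k, s in shapes.items()}
        for t in range(1, 6):
            grads = {k: rng.normal(size=s) for k, s in shapes.items()}
            opt.step(params, grads)
            for k in shapes:  # textbook Adam
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                ref[k] -= lr * ((m[k] / (1 - b1**t)) / (np.sqrt(v[k] / (1 - b2**t)) + eps))
        for k in shapes:
            assert np.array_equal(params[k], ref[k])

    def test_decoupled_differs_from_l2_folded(self):
        """Folding the decay into the gradient rescales it by the adaptive
        moments; with unequal second moments the two updates must differ."""
        w = np.array([1.0, 1.0])
        g = np.array([10.0, 0.01])  # very different curvature estimates
        lr, lam = 0.1, 0.1
        decoupled = {"w": w.copy()}
        AdamW(lr, lam).step(decoupled, {"w": g.copy()})
        folded = {"w": w.copy()}
        AdamW(lr, 0.0).step(folded, {"w": g + lam * w})  # L2 as gradient term
        diff = np.abs(decoupled["w"] - folded["w"])
        assert diff.max() > 1e-4
        assert not np.allclose(decoupled["w"], folded["w"])

    def test_non_finite_gradient_names_tensor(self):
        opt = AdamW(0.1)
        with pytest.raises(FloatingPointError, match="bad"):
            opt.step({"bad": np.array([1.0])}, {"bad": np.array([np.nan])})


class TestComputeMetrics:
    def test_perfect_predictions(self):
        labels = np.array([1, 1, 0, 0])
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        r = compute_metrics(labels, probs)
        for m in ("ACC", "SPE", "SEN", "PRE", "F1", "MCC", "AUROC"):
            assert getattr(r, m) == 1.0
        assert r.undefined == ()

    def test_known_confusion_matrix(self):
        """TP=40 TN=30 FP=10 FN=20: values from confusion arithmetic."""
        labels = np.array([1] * 60 + [0] * 40)
        probs = np.array([0.9] * 40 + [0.1] * 20 + [0.9] * 10 + [0.1] * 30)
        r = compute_metrics(labels, probs)
        assert (r.TP, r.TN, r.FP, r.FN) == (40, 30, 10, 20)
        assert r.ACC == pytest.approx(0.70)
        assert r.SEN == pytest.approx(2 / 3, abs=1e-4)
        assert r.SPE == pytest.approx(0.75)
        assert r.PRE == pytest.approx(0.80)
        assert r.F1 == pytest.approx(0.7273, abs=1e-4)
        assert r.MCC == pytest.approx(0.4082, abs=1e-4)

    def test_auroc_perfect_separation(self):
        r = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.1])
        assert r.AUROC == 1.0

    def test_auroc_matches_pairwise_comparison_with_ties(self, rng):
        """Rank-statistic AUROC equals brute-force pair counting (ties = 1/2)."""
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ])
            assert auroc_score(labels, scores) == pytest.approx(brute, abs=1e-12)
            assert auroc_score(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_accuracy_identity_over_confusion_counts(self, rng):
        """ACC = (SEN*P + SPE*N) / (P + N) for any report."""
        for _ in range(20):
            labels = rng.integers(0, 2, size=50)
            probs = rng.random(50)
            if labels.min() == labels.max():
                continue
            r = compute_metrics(labels, probs)
            P, N = r.TP + r.FN, r.TN + r.FP
            assert r.ACC == pytest.approx((r.SEN * P + r.SPE * N) / (P + N))

    def test_mcc_label_swap_invariance(self, rng):
        """Complementing labels and scores together leaves MCC unchanged."""
        labels = rng.integers(0, 2, size=80)
        probs = rng.random(80)
        a = compute_metrics(labels, probs).MCC
        b = compute_metrics(1 - labels, 1 - probs).MCC
        assert a == pytest.approx(b, abs=1e-12)

    def test_undefined_ratios_flagged_not_raised(self):
        r = compute_metrics([1, 1, 1, 0], [0.1, 0.2, 0.1, 0.05])  # nothing predicted positive
        assert r.PRE == 0.0
        assert "PRE" in r.undefined

    def test_single_class_flags_auroc(self):
        r = compute_metrics([1, 1], [0.9, 0.8])
        assert "AUROC" in r.undefined

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [0.5])


def _toy_dataset(corpus, pipe, pairs=None):
    enc = build_encoder(corpus, pipe)
    return tokenize_pairs(corpus, pairs or corpus.pairs, pipe, enc), enc


class TestTrain:
    def test_loss_decreases_on_planted_motif(self, small_corpus, small_pipe):
        ds, enc = _toy_dataset(small_corpus, small_pipe)
        model = BotNet(ModelConfig(vocab_size=enc.vocab_size, n_embedding=16, hidden=16), seed=0)
        model, log = train(model, ds, None, TrainConfig(max_epochs=3, batch_size=32, seed=0))
        losses = [e["train_loss"] for e in log]
        assert losses[1] < losses[0] and losses[2] < losses[1]

    def test_zero_epochs_leaves_model_unchanged(self, small_corpus, small_pipe):
        ds, enc = _toy_dataset(small_corpus, small_pipe)
        model = BotNet(ModelConfig(vocab_size=enc.vocab_size, n_embedding=8, hidden=8), seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        model, log = train(model, ds, None, TrainConfig(max_epochs=0, seed=0))
        assert log == []
        for k in before:
            assert np.array_equal(model.params[k], before[k])

    def test_same_seed_identical_runs(self, small_corpus, small_pipe):
        ds, enc = _toy_dataset(small_corpus, small_pipe)
        results = []
        for _ in range(2):
            model = BotNet(ModelConfig(vocab_size=enc.vocab_size, n_embedding=8, hidden=8), seed=3)
            model, log = train(model, ds, None, TrainConfig(max_epochs=2, batch_size=32, seed=3))
            results.append((log, {k: v.copy() for k, v in model.params.items()}))
        assert results[0][0] == results[1][0]
        for k in results[0][1]:
            assert np.array_equal(results[0][1][k], results[1][1][k])

    def test_single_class_dataset_rejected(self):
        ds = TokenizedDataset(np.zeros((10, 4), dtype=np.int64), np.ones(10, dtype=np.int64), (2, 2))
        model = BotNet(ModelConfig(vocab_size=5, n_embedding=4, hidden=3), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, ds, None, TrainConfig(max_epochs=1))

    def test_heterogeneous_segment_lengths_rejected(self, small_corpus):
        from botnet.length_policy import fuse_pair
        from botnet.tokenizer import PairEncoder, build_vocab
        enc = PairEncoder(build_vocab("RNA", 2))
        a = enc.encode(fuse_pair("ACGU", "ACGU"), 1)
        b = enc.encode(fuse_pair("ACGUA", "ACG"), 0)
        with pytest.raises(ValueError, match="heterogeneous"):
            stack_pairs([a, b])


@pytest.fixture(scope="module")
def result(small_corpus, small_pipe):
    return cross_validate(
        small_corpus, small_pipe, {"n_embedding": 16, "hidden": 16},
        TrainConfig(max_epochs=3, patience=2, batch_size=32, seed=0),
        n_folds=3, seed=0,
    )


class TestCrossValidate:

    def test_mean_is_arithmetic_mean_of_folds(self, result):
        assert result.mean["ACC"] == pytest.approx(
            np.mean([r.ACC for r in result.fold_reports])
        )
        assert result.mean == mean_metrics(result.fold_reports)

    def test_separable_corpus_scores_high(self, result):
        assert result.mean["AUROC"] > 0.95

    def test_one_report_and_log_per_fold(self, result):
        assert len(result.fold_reports) == 3
        assert len(result.logs) == 3


class TestGridSearch:
    def test_singleton_grid_returns_that_combination(self, small_corpus, small_pipe):
        grid = GridSpec(model_grid={"hidden": [8]}, train_grid={})
        best, board = grid_search(
            small_corpus, small_pipe, grid,
            TrainConfig(max_epochs=1, batch_size=32, seed=0),
            model_kwargs={"n_embedding": 8}, seed=0,
        )
        assert best["config"] == {"hidden": 8}
        assert len(board) == 1

    def test_leaderboard_covers_grid_and_is_sorted(self, small_corpus, small_pipe):
        grid = GridSpec(model_grid={"hidden": [8, 12]}, train_grid={"learning_rate": [0.01]})
        best, board = grid_search(
            small_corpus, small_pipe, grid,
            TrainConfig(max_epochs=1, batch_size=32, seed=0),
            model_kwargs={"n_embedding": 8}, seed=0,
        )
        assert len(board) == 2
        scores = [e["score"] for e in board]
        assert scores == sorted(scores, reverse=True)
        assert best["score"] == scores[0]

    def test_empty_grid_rejected(self, small_corpus, small_pipe):
        with pytest.raises(ValueError):
            grid_search(small_corpus, small_pipe, GridSpec(), TrainConfig())


class TestRegionSweep:
    def test_row_per_setting_budget_cell(self, small_corpus):
        rows = region_sweep(
            small_corpus,
            partner_policy=LengthPolicy(Strategy.MAX_PAD),
            budgets=[10, 20],
            settings=[Strategy.START],
            model_kwargs={"n_embedding": 8, "hidden": 8},
            train_config=TrainConfig(max_epochs=1, batch_size=32, seed=0),
            n_folds=2,
            seed=0,
        )
        assert len(rows) == 2
        assert {r["budget"] for r in rows} == {10, 20}
        assert all(r["setting"] == "start" for r in rows)
        assert all("ACC" in r and "AUROC" in r for r in rows)
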
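"""The bag-of-tricks classifier, implemented in NumPy with analytic gradients.

Architecture, for a batch of equal-length token-id rows:

1. learned k-mer embedding lookup (table initialized from a standard normal,
   PAD row zero-initialized) regularized by two dropout schemes — whole token
   vectors dropped with probability ``p_vector_drop`` and individual weight
   units with ``p_weight_drop``;
2. a single-layer LSTM whose hidden-to-hidden matrices are regularized by
   DropConnect: one Bernoulli mask per forward/backward pass zeroes individual
   recurrent weights for the whole pass;
3. triple pooling over time — elementwise max, elementwise mean, and the last
   hidden state — concatenated to a 3H-dimensional vector (360 at the default
   H = 120);
4. batch normalization, standard dropout, a dense layer 3H -> 50 with sigmoid
   activation, a second batch normalization, dropout again, a dense layer
   50 -> 2, and softmax.

The training objective is categorical cross-entropy.  Every layer has a
hand-derived backward pass; gradients are validated against central finite
differences in the test suite.  All stochastic masks are drawn from an
explicit ``numpy.random.Generator`` so training is bit-reproducible; passing
``rng=None`` in training mode disables every stochastic layer (used for
gradient checks) while keeping batch-statistics normalization.

Standard dropout uses the inverted convention by default (scaling by
1/(1-p) at train time so evaluation is the identity); the mathematically
equivalent test-time (1-p) scaling is available via ``inverted_dropout=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from botnet.tokenizer import PAD_INDEX


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults are the grid-search optima for the lncRNA–miRNA task: 120-d
    embeddings, H = 120 (so the pooled vector is 360-d), a 50-unit dense
    layer, embedding vector/weight dropout 0.004/0.005, DropConnect 0.004,
    standard dropout 0.1.
    """

    vocab_size: int
    n_embedding: int = 120
    hidden: int = 120
    n_dense: int = 50
    n_classes: int = 2
    p_vector_drop: float = 0.004
    p_weight_drop: float = 0.005
    p_dropconnect: float = 0.004
    p_dense_drop: float = 0.1
    lstm_bias: bool = True
    inverted_dropout: bool = True
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5


# ---------------------------------------------------------------------------
# layer primitives (forward + backward), shared by the model and the tests
# ---------------------------------------------------------------------------

def lstm_forward(X: np.ndarray, W: np.ndarray, U_eff: np.ndarray, b: np.ndarray):
    """Run the LSTM over X (B, T, d); returns hidden states (B, T, H) + cache.

    Gate order in the concatenated 4H axis is [input, forget, cell, output]:
        i_t = sigma(W^i x_t + U^i h_{t-1} + b^i)
        f_t = sigma(W^f x_t + U^f h_{t-1} + b^f)
        cin_t = tanh(W^c x_t + U^c h_{t-1} + b^c)
        o_t = sigma(W^o x_t + U^o h_{t-1} + b^o)
        c_t = f_t * c_{t-1} + i_t * cin_t
        h_t = o_t * tanh(c_t)
    with h_0 = c_0 = 0 per instance.  ``U_eff`` is the recurrent matrix after
    any DropConnect masking.
    """
    B, T, d = X.shape
    H = U_eff.shape[0]
    if W.shape != (d, 4 * H):
        raise ValueError(f"W shape {W.shape} incompatible with d={d}, H={H}")
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    steps = []
    for t in range(T):
        z = X[:, t] @ W + h @ U_eff + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev_store = h
        h = o * tc
        Hs[:, t] = h
        steps.append((i, f, g, o, c_prev, tc, h_prev_store))
    return Hs, steps


def lstm_backward(dHs: np.ndarray, X: np.ndarray, W: np.ndarray, U_eff: np.ndarray, steps):
    """Backprop through time.  ``dHs`` holds dL/dh_t for every step.

    Returns (dX, dW, dU_eff, db).
    """
    B, T, d = X.shape
    H = U_eff.shape[0]
    dX = np.zeros_like(X)
    dW = np.zeros_like(W)
    dU = np.zeros_like(U_eff)
    db = np.zeros(4 * H)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = steps[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        dX[:, t] = dz @ W.T
        dW += X[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ U_eff.T
    return dX, dW, dU, db


def pool(hidden_states: np.ndarray):
    """Concatenate [max over time, mean over time, last state] -> (B, 3H)."""
    if hidden_states.ndim != 3 or hidden_states.shape[1] < 1:
        raise ValueError("expected (B, T, H) with T >= 1")
    mx = hidden_states.max(axis=1)
    argmx = hidden_states.argmax(axis=1)
    mn = hidden_states.mean(axis=1)
    last = hidden_states[:, -1]
    return np.concatenate([mx, mn, last], axis=1), argmx


def pool_backward(dout: np.ndarray, shape: tuple, argmx: np.ndarray) -> np.ndarray:
    B, T, H = shape
    dmx, dmn, dlast = dout[:, :H], dout[:, H : 2 * H], dout[:, 2 * H :]
    dHs = np.zeros(shape)
    bi = np.arange(B)[:, None]
    hi = np.arange(H)[None, :]
    np.add.at(dHs, (bi, argmx, hi), dmx)
    dHs += (dmn / T)[:, None, :]
    dHs[:, -1] += dlast
    return dHs


def batch_norm_forward(x, gamma, beta, running_mean, running_var, eps, momentum, training):
    """Batch normalization over the batch axis.

    Training mode normalizes by batch mean/variance (batch size >= 2
    required) and updates the running statistics by exponential moving
    average; eval mode normalizes by the running statistics.
    """
    if training:
        if x.shape[0] < 2:
            raise ValueError("batch normalization in training mode requires batch size >= 2")
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * x.shape[0] / max(x.shape[0] - 1, 1)
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    return gamma * xhat + beta, (xhat, inv_std, training)


def batch_norm_backward(dy, gamma, cache):
    xhat, inv_std, training = cache
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma
    if training:
        dx = inv_std * (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0))
    else:
        dx = dxhat * inv_std
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class BotNet:
    """The full classifier; parameters live in ``self.params`` (name -> array)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        V, d, H = config.vocab_size, config.n_embedding, config.hidden
        nd, nc = config.n_dense, config.n_classes
        s = 1.0 / np.sqrt(H)
        E = rng.normal(0.0, 1.0, size=(V, d))
        E[PAD_INDEX] = 0.0
        self.params: dict[str, np.ndarray] = {
            "E": E,
            "W": rng.uniform(-s, s, size=(d, 4 * H)),
            "U": rng.uniform(-s, s, size=(H, 4 * H)),
            "bn1_gamma": np.ones(3 * H),
            "bn1_beta": np.zeros(3 * H),
            "fc1_W": rng.uniform(-1 / np.sqrt(3 * H), 1 / np.sqrt(3 * H), size=(3 * H, nd)),
            "fc1_b": np.zeros(nd),
            "bn2_gamma": np.ones(nd),
            "bn2_beta": np.zeros(nd),
            "fc2_W": rng.uniform(-1 / np.sqrt(nd), 1 / np.sqrt(nd), size=(nd, nc)),
            "fc2_b": np.zeros(nc),
        }
        if config.lstm_bias:
            self.params["b"] = rng.uniform(-s, s, size=4 * H)
        self.buffers: dict[str, np.ndarray] = {
            "bn1_mean": np.zeros(3 * H),
            "bn1_var": np.ones(3 * H),
            "bn2_mean": np.zeros(nd),
            "bn2_var": np.ones(nd),
        }

    # -- helpers -----------------------------------------------------------

    def _lstm_b(self) -> np.ndarray:
        return self.params.get("b", np.zeros(4 * self.config.hidden))

    def _dropout_mask(self, shape, p, rng, training):
        """Bernoulli keep-mask, already scaled per the dropout convention.

        Returns (train_multiplier, eval_multiplier): in training the input is
        multiplied by the mask; in eval either by 1 (inverted dropout) or by
        the keep probability (classic convention).
        """
        cfg = self.config
        if not training:
            return None, (1.0 if cfg.inverted_dropout else 1.0 - p)
        if p <= 0 or rng is None:
            return np.float64(1.0), 1.0
        keep = (rng.random(shape) >= p).astype(np.float64)
        if cfg.inverted_dropout:
            keep /= 1.0 - p
        return keep, 1.0

    def embed(self, token_ids: np.ndarray, training: bool = False, rng=None):
        """Embedding lookup with vector- and weight-level dropout."""
        E = self.params["E"]
        ids = np.asarray(token_ids)
        if ids.min() < 0 or ids.max() >= E.shape[0]:
            raise IndexError(f"token id out of range [0, {E.shape[0]})")
        X = E[ids]
        B, T, d = X.shape
        mvec, evec = self._dropout_mask((B, T, 1), self.config.p_vector_drop, rng, training)
        mwt, ewt = self._dropout_mask((B, T, d), self.config.p_weight_drop, rng, training)
        if training:
            mult = mvec * mwt
        else:
            mult = evec * ewt
        return X * mult, mult

    # -- forward / backward ------------------------------------------------

    def forward(self, token_ids: np.ndarray, training: bool = False, rng=None):
        """Class probabilities (B, 2) for a batch of equal-length id rows."""
        probs, _ = self._forward_cached(token_ids, training, rng)
        return probs

    def _forward_cached(self, token_ids, training, rng):
        cfg = self.config
        ids = np.atleast_2d(np.asarray(token_ids))
        X, emb_mult = self.embed(ids, training, rng)
        U = self.params["U"]
        mU, eU = self._dropout_mask(U.shape, cfg.p_dropconnect, rng, training)
        U_eff = U * (mU if training else eU)
        Hs, steps = lstm_forward(X, self.params["W"], U_eff, self._lstm_b())
        pooled, argmx = pool(Hs)
        y1, bn1_cache = batch_norm_forward(
            pooled, self.params["bn1_gamma"], self.params["bn1_beta"],
            self.buffers["bn1_mean"], self.buffers["bn1_var"],
            cfg.bn_eps, cfg.bn_momentum, training,
        )
        m1, e1 = self._dropout_mask(y1.shape, cfg.p_dense_drop, rng, training)
        y1d = y1 * (m1 if training else e1)
        a1pre = y1d @ self.params["fc1_W"] + self.params["fc1_b"]
        a1 = sigmoid(a1pre)
        y2, bn2_cache = batch_norm_forward(
            a1, self.params["bn2_gamma"], self.params["bn2_beta"],
            self.buffers["bn2_mean"], self.buffers["bn2_var"],
            cfg.bn_eps, cfg.bn_momentum, training,
        )
        m2, e2 = self._dropout_mask(y2.shape, cfg.p_dense_drop, rng, training)
        y2d = y2 * (m2 if training else e2)
        logits = y2d @ self.params["fc2_W"] + self.params["fc2_b"]
        probs = softmax(logits)
        cache = dict(
            ids=ids, X=X, emb_mult=emb_mult, U_eff=U_eff, mU=mU, eU=eU,
            Hs=Hs, steps=steps, argmx=argmx, bn1_cache=bn1_cache,
            m1=m1, e1=e1, y1=y1, y1d=y1d, a1=a1, bn2_cache=bn2_cache,
            m2=m2, e2=e2, y2=y2, y2d=y2d, probs=probs, training=training,
        )
        return probs, cache

    @staticmethod
    def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
        """Mean categorical cross-entropy, -sum_i t_i log f(s_i)."""
        p = np.clip(probs[np.arange(len(labels)), labels], 1e-300, None)
        return float(-np.mean(np.log(p)))

    def loss_and_grads(self, token_ids, labels, training: bool = True, rng=None):
        """Forward + full backward pass; returns (loss, grads dict, probs)."""
        probs, cache = self._forward_cached(token_ids, training, rng)
        labels = np.asarray(labels)
        B = len(labels)
        loss = self.cross_entropy(probs, labels)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B

        grads["fc2_W"] = cache["y2d"].T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        dy2d = dlogits @ self.params["fc2_W"].T
        dy2 = dy2d * (cache["m2"] if training else cache["e2"])
        da1, grads["bn2_gamma"], grads["bn2_beta"] = batch_norm_backward(
            dy2, self.params["bn2_gamma"], cache["bn2_cache"]
        )
        da1pre = da1 * cache["a1"] * (1 - cache["a1"])
        grads["fc1_W"] = cache["y1d"].T @ da1pre
        grads["fc1_b"] = da1pre.sum(axis=0)
        dy1d = da1pre @ self.params["fc1_W"].T
        dy1 = dy1d * (cache["m1"] if training else cache["e1"])
        dpooled, grads["bn1_gamma"], grads["bn1_beta"] = batch_norm_backward(
            dy1, self.params["bn1_gamma"], cache["bn1_cache"]
        )
        dHs = pool_backward(dpooled, cache["Hs"].shape, cache["argmx"])
        dX, dW, dU_eff, db = lstm_backward(
            dHs, cache["X"], self.params["W"], cache["U_eff"], cache["steps"]
        )
        grads["W"] = dW
        grads["U"] = dU_eff * (cache["mU"] if training else cache["eU"])
        if "b" in self.params:
            grads["b"] = db
        dE_rows = dX * cache["emb_mult"]
        np.add.at(grads["E"], cache["ids"], dE_rows)
        return loss, grads, probs

    def predict_proba(self, token_ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
        ids = np.atleast_2d(np.asarray(token_ids))
        return np.concatenate(
            [self.forward(ids[i : i + batch_size]) for i in range(0, len(ids), batch_size)]
        )

    # -- bookkeeping -------------------------------------------------------

    def count_parameters(self) -> int:
        """Exact number of trainable scalars."""
        return int(sum(v.size for v in self.params.values()))

    def get_state(self):
        return (
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.buffers.items()},
        )

    def set_state(self, state) -> None:
        params, buffers = state
        for k in self.params:
            self.params[k][...] = params[k]
        for k in self.buffers:
            self.buffers[k][...] = buffers[k]

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Checkpoint: one .npz with all arrays plus a JSON config header."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload.update({f"buffer_{k}": v for k, v in self.buffers.items()})
        header = {"config": asdict(self.config), "meta": meta or {}}
        payload["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> tuple["BotNet", dict]:
        with np.load(path) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode())
            model = cls(ModelConfig(**header["config"]))
            for k in model.params:
                model.params[k][...] = data[f"param_{k}"]
            for k in model.buffers:
                model.buffers[k][...] = data[f"buffer_{k}"]
        return model, header["meta"]
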
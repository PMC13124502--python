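"""LSTM sequence classifier implemented in numpy.

A single LSTM layer (default 96 hidden units) runs over the per-trial
feature-sequence (PCA scores per window); the final hidden state feeds
three fully connected ReLU layers (128–64–32) with dropout (0.4–0.3–0.2)
and a 3-way softmax. The recurrence follows the standard gate equations

    f_t = σ(W_f·[h_{t−1}, x_t] + b_f)
    i_t = σ(W_i·[h_{t−1}, x_t] + b_i)
    c̃_t = tanh(W_c·[h_{t−1}, x_t] + b_c)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t
    o_t = σ(W_o·[h_{t−1}, x_t] + b_o)
    h_t = o_t ⊙ tanh(c_t)

Training uses backpropagation through time with Adam (lr 0.001),
mini-batches of 32, reduce-on-plateau learning-rate decay (factor 0.5,
patience 5) and early stopping (patience 10) on validation loss with
best-weight restoration. Everything is deterministic given the seed:
the RNG drives weight initialization, batch shuffling and dropout masks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy.special import expit

__all__ = ["TrainConfig", "LSTMWeights", "lstm_forward", "PCALSTMClassifier"]


@dataclass(frozen=True)
class TrainConfig:
    hidden: int = 96
    fc_sizes: tuple[int, ...] = (128, 64, 32)
    dropout: tuple[float, ...] = (0.4, 0.3, 0.2)
    n_classes: int = 3
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-5
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fc_sizes) != len(self.dropout):
            raise ValueError("one dropout rate per fully connected hidden layer")
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.hidden) <= 0:
            raise ValueError("training hyperparameters must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


@dataclass
class LSTMWeights:
    """All learnable parameters. Gate matrices act on [h_{t−1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    fc_W: list[np.ndarray] = field(default_factory=list)
    fc_b: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def init(cls, input_dim: int, cfg: TrainConfig, rng) -> "LSTMWeights":
        """Uniform(±1/√H) gate init with forget bias 1; He init for the FC stack."""
        h = cfg.hidden
        bound = 1.0 / np.sqrt(h)

        def gate():
            return rng.uniform(-bound, bound, size=(h, h + input_dim))

        w = cls(
            W_f=gate(), W_i=gate(), W_c=gate(), W_o=gate(),
            b_f=np.ones(h), b_i=np.zeros(h), b_c=np.zeros(h), b_o=np.zeros(h),
        )
        sizes = [h, *cfg.fc_sizes, cfg.n_classes]
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            w.fc_W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)))
            w.fc_b.append(np.zeros(d_out))
        return w

    def params(self) -> list[np.ndarray]:
        return [
            self.W_f, self.W_i, self.W_c, self.W_o,
            self.b_f, self.b_i, self.b_c, self.b_o,
            *self.fc_W, *self.fc_b,
        ]


def lstm_forward(
    sequence: np.ndarray,
    weights: LSTMWeights,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the recurrence and the FC head in inference mode (no dropout).

    ``sequence`` is (T, k) for one trial or (B, T, k) for a batch. Returns
    ``(h_T, class_scores)`` where class_scores are softmax probabilities,
    shaped to match the input's batching.
    """
    single = sequence.ndim == 2
    X = sequence[None] if single else sequence
    out = _forward_pass(X, weights, h0=h0, c0=c0, dropout=None)
    h_T, probs = out["h_T"], out["probs"]
    return (h_T[0], probs[0]) if single else (h_T, probs)


def _forward_pass(X, w: LSTMWeights, h0=None, c0=None, dropout=None):
    """Batched forward pass; caches intermediates when training."""
    B, T, _ = X.shape
    H = w.b_f.size
    h = np.zeros((B, H)) if h0 is None else np.broadcast_to(h0, (B, H)).copy()
    c = np.zeros((B, H)) if c0 is None else np.broadcast_to(c0, (B, H)).copy()
    steps = []
    for t in range(T):
        z = np.concatenate([h, X[:, t, :]], axis=1)
        f = _sigmoid(z @ w.W_f.T + w.b_f)
        i = _sigmoid(z @ w.W_i.T + w.b_i)
        g = np.tanh(z @ w.W_c.T + w.b_c)
        o = _sigmoid(z @ w.W_o.T + w.b_o)
        c_new = f * c + i * g
        h = o * np.tanh(c_new)
        steps.append({"z": z, "f": f, "i": i, "g": g, "o": o,
                      "c_prev": c, "c": c_new})
        c = c_new
    h_T = h

    acts = [h_T]
    masks = []
    a = h_T
    n_hidden = len(w.fc_W) - 1
    for li in range(n_hidden):
        a = np.maximum(a @ w.fc_W[li].T + w.fc_b[li], 0.0)
        if dropout is not None:
            p = dropout["rates"][li]
            mask = (dropout["rng"].random(a.shape) >= p) / (1.0 - p)
            a = a * mask
            masks.append(mask)
        acts.append(a)
    logits = a @ w.fc_W[-1].T + w.fc_b[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return {"steps": steps, "h_T": h_T, "acts": acts, "masks": masks,
            "probs": probs, "X": X}


def _backward_pass(cache, w: LSTMWeights, y: np.ndarray) -> list[np.ndarray]:
    """Gradients of mean cross-entropy w.r.t. every parameter (params() order)."""
    X, steps, acts, masks, probs = (
        cache["X"], cache["steps"], cache["acts"], cache["masks"], cache["probs"],
    )
    B = X.shape[0]
    H = w.b_f.size

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    g_fc_W = [np.zeros_like(m) for m in w.fc_W]
    g_fc_b = [np.zeros_like(b) for b in w.fc_b]
    delta = dlogits
    g_fc_W[-1] = delta.T @ acts[-1]
    g_fc_b[-1] = delta.sum(axis=0)
    da = delta @ w.fc_W[-1]
    for li in range(len(w.fc_W) - 2, -1, -1):
        if masks:
            da = da * masks[li]
        pre_relu = acts[li + 1] > 0  # post-dropout zeros coincide with mask
        da = da * pre_relu
        g_fc_W[li] = da.T @ acts[li]
        g_fc_b[li] = da.sum(axis=0)
        da = da @ w.fc_W[li]

    dW = {k: np.zeros_like(getattr(w, k)) for k in ("W_f", "W_i", "W_c", "W_o")}
    db = {k: np.zeros_like(getattr(w, k)) for k in ("b_f", "b_i", "b_c", "b_o")}
    dh = da
    dc = np.zeros((B, H))
    for t in range(len(steps) - 1, -1, -1):
        s = steps[t]
        tc = np.tanh(s["c"])
        do = dh * tc
        dc = dc + dh * s["o"] * (1.0 - tc**2)
        df = dc * s["c_prev"]
        di = dc * s["g"]
        dg = dc * s["i"]
        dc = dc * s["f"]
        da_f = df * s["f"] * (1.0 - s["f"])
        da_i = di * s["i"] * (1.0 - s["i"])
        da_o = do * s["o"] * (1.0 - s["o"])
        da_g = dg * (1.0 - s["g"] ** 2)
        z = s["z"]
        dW["W_f"] += da_f.T @ z
        dW["W_i"] += da_i.T @ z
        dW["W_c"] += da_g.T @ z
        dW["W_o"] += da_o.T @ z
        db["b_f"] += da_f.sum(axis=0)
        db["b_i"] += da_i.sum(axis=0)
        db["b_c"] += da_g.sum(axis=0)
        db["b_o"] += da_o.sum(axis=0)
        dz = da_f @ w.W_f + da_i @ w.W_i + da_g @ w.W_c + da_o @ w.W_o
        dh = dz[:, :H]
    return [
        dW["W_f"], dW["W_i"], dW["W_c"], dW["W_o"],
        db["b_f"], db["b_i"], db["b_c"], db["b_o"],
        *g_fc_W, *g_fc_b,
    ]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class PCALSTMClassifier:
    """Sequence classifier over PCA-score windows.

    ``fit`` expects train/validation arrays of shape (n, T, k) with integer
    labels 0/1/2. History records per-epoch training loss, validation loss
    and validation accuracy. Two fits with the same config and data are
    bit-identical.
    """

    def __init__(self, input_dim: int, cfg: TrainConfig = TrainConfig()):
        self.cfg = cfg
        self.input_dim = input_dim
        self._rng = default_rng(cfg.seed)
        self.weights = LSTMWeights.init(input_dim, cfg, self._rng)
        self.history: dict[str, list[float]] = {
            "train_loss": [], "val_loss": [], "val_accuracy": [], "lr": [],
        }

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _forward_pass(np.asarray(X, float), self.weights, dropout=None)["probs"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    @staticmethod
    def _ce(probs: np.ndarray, y: np.ndarray) -> float:
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
    ) -> "PCALSTMClassifier":
        cfg = self.cfg
        X_train = np.asarray(X_train, float)
        y_train = np.asarray(y_train, int)
        X_val = np.asarray(X_val, float)
        y_val = np.asarray(y_val, int)
        if len(np.unique(y_val)) < cfg.n_classes:
            import warnings

            warnings.warn("validation split is missing a class", stacklevel=2)

        opt = _Adam(self.weights.params(), cfg.learning_rate)
        dropout = {"rates": cfg.dropout, "rng": self._rng}
        best_loss = np.inf
        best_weights = copy.deepcopy(self.weights)
        stall_stop = stall_lr = 0
        n = len(y_train)

        for _epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                cache = _forward_pass(X_train[idx], self.weights, dropout=dropout)
                epoch_loss += self._ce(cache["probs"], y_train[idx]) * len(idx)
                grads = _backward_pass(cache, self.weights, y_train[idx])
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                if norm > cfg.grad_clip:
                    grads = [g * (cfg.grad_clip / norm) for g in grads]
                opt.step(self.weights.params(), grads)

            val_probs = self.predict_proba(X_val)
            val_loss = self._ce(val_probs, y_val)
            val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
            self.history["train_loss"].append(epoch_loss / n)
            self.history["val_loss"].append(val_loss)
            self.history["val_accuracy"].append(val_acc)
            self.history["lr"].append(opt.lr)

            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = copy.deepcopy(self.weights)
                stall_stop = stall_lr = 0
            else:
                stall_stop += 1
                stall_lr += 1
                if stall_lr >= cfg.lr_patience and opt.lr > cfg.min_lr:
                    opt.lr = max(opt.lr * cfg.lr_factor, cfg.min_lr)
                    stall_lr = 0
                if stall_stop >= cfg.early_stopping_patience:
                    break

        self.weights = best_weights
        return self
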
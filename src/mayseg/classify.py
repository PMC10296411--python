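"""BiLSTM classifier over fused feature vectors, with training and metrics.

Architecture (in order): the flat fused vector is zero-padded and reshaped
into a ``seq_len x input_per_step`` sequence; a forward LSTM and a backward
LSTM run over it and their per-step hidden states are concatenated; max
pooling over time collapses the sequence; a fully-connected ReLU layer
(50 units) with dropout feeds a softmax output over the classes.  The
output layer is a softmax rather than independent sigmoids because the
three tumor classes are mutually exclusive, so the class probabilities
must sum to one.

Training is plain mini-batch SGD with the Adam update rule on the
cross-entropy loss (defaults: learning rate 0.001, batch size 32), with
seeded shuffling and dropout masks so runs are bit-reproducible.  The
network and its backward pass are implemented directly in numpy.

Evaluation reports the confusion matrix, macro-averaged one-vs-rest
precision / recall / F1, accuracy, and the mean one-vs-rest ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiLSTMSpec",
    "TrainConfig",
    "EvalReport",
    "BiLSTM",
    "build_model",
    "train",
    "evaluate",
    "roc_auc_ovr",
]


@dataclass(frozen=True)
class BiLSTMSpec:
    input_dim: int = 1126  # flat fused-vector length
    seq_len: int = 100
    hidden_units: int = 100  # per direction
    fc_units: int = 50
    dropout_rate: float = 0.5
    n_classes: int = 3
    seed: int = 0

    @property
    def input_per_step(self) -> int:
        return -(-self.input_dim // self.seq_len)  # ceil; final step zero-padded


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001  # Adam
    batch_size: int = 32
    epochs: int = 60
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0


@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray  # (n_classes, n_classes), rows = truth
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTM:
    """Single-direction LSTM with cached forward pass and exact BPTT."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        h = hidden
        s_in = 1.0 / np.sqrt(input_dim)
        s_h = 1.0 / np.sqrt(h)
        self.Wx = rng.uniform(-s_in, s_in, size=(input_dim, 4 * h))
        self.Wh = rng.uniform(-s_h, s_h, size=(h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.hidden = h

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray):
        """X: (B, T, I) -> per-step hidden states (B, T, H) plus cache."""
        B, T, _ = X.shape
        h = self.hidden
        hs = np.zeros((B, T, h))
        cache = []
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        for t in range(T):
            z = X[:, t] @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            hs[:, t] = h_t
            cache.append((X[:, t], h_prev, c_prev, i, f, g, o, c_t, tc))
        return hs, cache

    def backward(self, dhs: np.ndarray, cache):
        """dhs: (B, T, H) gradient on every per-step hidden state."""
        B, T, h = dhs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_t, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ self.Wh.T
        return [dWx, dWh, db]


class BiLSTM:
    """The full classifier: BiLSTM -> max-pool over time -> FC ReLU ->
    dropout -> softmax."""

    def __init__(self, spec: BiLSTMSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ips, h = spec.input_per_step, spec.hidden_units
        self.fwd = _LSTM(ips, h, rng)
        self.bwd = _LSTM(ips, h, rng)
        s1 = np.sqrt(2.0 / (2 * h))
        self.W1 = rng.normal(0.0, s1, size=(2 * h, spec.fc_units))
        self.b1 = np.zeros(spec.fc_units)
        s2 = np.sqrt(2.0 / spec.fc_units)
        self.W2 = rng.normal(0.0, s2, size=(spec.fc_units, spec.n_classes))
        self.b2 = np.zeros(spec.n_classes)

    # ---- parameter plumbing ----
    def params(self):
        return self.fwd.params() + self.bwd.params() + [self.W1, self.b1, self.W2, self.b2]

    def _reshape(self, X: np.ndarray) -> np.ndarray:
        spec = self.spec
        B = X.shape[0]
        full = spec.seq_len * spec.input_per_step
        pad = np.zeros((B, full))
        pad[:, : X.shape[1]] = X
        return pad.reshape(B, spec.seq_len, spec.input_per_step)

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Returns class probabilities (B, n_classes) and a cache for
        backward.  Dropout is active only when ``dropout_rng`` is given."""
        seq = self._reshape(np.asarray(X, dtype=float))
        hs_f, cache_f = self.fwd.forward(seq)
        hs_b_rev, cache_b = self.bwd.forward(seq[:, ::-1])
        hs_b = hs_b_rev[:, ::-1]
        H = np.concatenate([hs_f, hs_b], axis=2)  # (B, T, 2h)
        pool_idx = H.argmax(axis=1)  # (B, 2h)
        pooled = H.max(axis=1)
        a1 = pooled @ self.W1 + self.b1
        r1 = np.maximum(a1, 0.0)
        if dropout_rng is not None and self.spec.dropout_rate > 0:
            keep = 1.0 - self.spec.dropout_rate
            mask = (dropout_rng.random(r1.shape) < keep) / keep
        else:
            mask = np.ones_like(r1)
        d1 = r1 * mask
        logits = d1 @ self.W2 + self.b2
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (seq, cache_f, cache_b, H, pool_idx, pooled, a1, r1, mask, d1, probs)
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(X, dropout_rng=None)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, dropout_rng=None):
        """Mean cross-entropy and gradients for every parameter."""
        B = X.shape[0]
        probs, cache = self.forward(X, dropout_rng)
        seq, cache_f, cache_b, H, pool_idx, pooled, a1, r1, mask, d1, _ = cache
        loss = float(-np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean())

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dW2 = d1.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dd1 = dlogits @ self.W2.T
        dr1 = dd1 * mask
        da1 = dr1 * (a1 > 0)
        dW1 = pooled.T @ da1
        db1 = da1.sum(axis=0)
        dpooled = da1 @ self.W1.T
        # max-pool routes gradient to the arg-max time step
        dH = np.zeros_like(H)
        b_idx = np.repeat(np.arange(B), H.shape[2])
        f_idx = np.tile(np.arange(H.shape[2]), B)
        dH[b_idx, pool_idx.ravel(), f_idx] = dpooled.ravel()
        h = self.spec.hidden_units
        g_f = self.fwd.backward(dH[:, :, :h], cache_f)
        g_b = self.bwd.backward(dH[:, :, h:][:, ::-1], cache_b)
        return loss, g_f + g_b + [dW1, db1, dW2, db2]


def build_model(spec: BiLSTMSpec) -> BiLSTM:
    return BiLSTM(spec)


def train(model: BiLSTM, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None):
    """Adam training on (features, labels); returns the model and the
    per-epoch mean-loss trace.  Deterministic for fixed seeds."""
    if config is None:
        config = TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least two classes")
    rng = np.random.default_rng(config.seed)
    params = model.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    step = 0
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(X[idx], y[idx], dropout_rng=rng)
            losses.append(loss)
            step += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= config.beta1
                mi += (1 - config.beta1) * g
                vi *= config.beta2
                vi += (1 - config.beta2) * g**2
                mhat = mi / (1 - config.beta1**step)
                vhat = vi / (1 - config.beta2**step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + config.adam_eps)
        trace.append(float(np.mean(losses)))
    return model, np.asarray(trace)


def roc_auc_ovr(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mean one-vs-rest ROC AUC via the rank (Mann-Whitney) statistic.

    ``scores`` is (n_samples, n_classes); classes absent from ``y_true``
    are skipped.
    """
    from scipy.stats import rankdata

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    aucs = []
    for cls in range(scores.shape[1]):
        pos = y_true == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(scores[:, cls])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("AUC undefined: need both positives and negatives")
    return float(np.mean(aucs))


def evaluate(model: BiLSTM, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Confusion matrix, macro one-vs-rest metrics and mean ROC AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    k = model.spec.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y, pred), 1)

    precisions, recalls, f1s = [], [], []
    for cls in range(k):
        tp = confusion[cls, cls]
        fp = confusion[:, cls].sum() - tp
        fn = confusion[cls, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return EvalReport(
        confusion=confusion,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        accuracy=float(np.trace(confusion) / confusion.sum()),
        f1=float(np.mean(f1s)),
        auc=roc_auc_ovr(y, probs),
    )
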
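"""Recurrent per-event classifier over raw waveform vectors.

Architecture: a single LSTM layer reads the baseline-normalised event
waveform one sample at a time; its hidden states are mean-pooled over
time; the two scalar features (relative blockade, log10 dwell) are
appended to the pooled representation; four fully connected ReLU layers
follow; a linear softmax output produces class probabilities.  Training
is mini-batch Adam on the cross-entropy, with early stopping on
validation accuracy and restoration of the best weights.

The network is implemented directly in numpy (forward pass and
backpropagation through time), which keeps the package dependency-light
and the arithmetic fully seedable: a fixed seed fixes initialisation
and batch order, so reported accuracies reproduce to within a point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "SequenceClassifierConfig",
    "SequenceClassifier",
    "train_sequence_classifier",
]


@dataclass(frozen=True)
class SequenceClassifierConfig:
    lstm_hidden: int = 64
    pooling: str = "mean-over-time"
    fc_widths: tuple[int, int, int, int] = (64, 32, 16, 8)
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 10
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fc_widths) != 4:
            raise ValidationError("exactly four fully connected layers required")
        if self.pooling != "mean-over-time":
            raise ValidationError(f"unsupported pooling: {self.pooling!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class SequenceClassifier:
    """LSTM + mean pooling + 4 FC layers + softmax, sklearn-style API.

    ``fit(X, y, X_val, y_val)`` expects ``X`` of shape (n, L + 2): the
    first L columns are the waveform vector, the last two the scalar
    features (relative blockade, log10 dwell).  Fitted attributes:
    ``classes_``, ``params_``, ``history_``, ``n_waveform_``.
    """

    def __init__(self, config: SequenceClassifierConfig | None = None, **overrides):
        if config is None:
            config = SequenceClassifierConfig(**overrides)
        elif overrides:
            config = SequenceClassifierConfig(**{**config.__dict__, **overrides})
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return dict(self.config.__dict__)

    def set_params(self, **params) -> "SequenceClassifier":
        self.config = SequenceClassifierConfig(**{**self.config.__dict__, **params})
        return self

    # ---- parameters ----------------------------------------------------
    def _init_weights(self, n_classes: int, rng: np.random.Generator) -> dict:
        H = self.config.lstm_hidden

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        params = {
            "Wx": glorot((4 * H, 1)),
            "Wh": glorot((4 * H, H)),
            "b": np.zeros(4 * H),
        }
        params["b"][H: 2 * H] = 1.0  # forget-gate bias: remember by default
        widths = [H + 2, *self.config.fc_widths, n_classes]
        for k, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            params[f"W{k}"] = glorot((a, b))
            params[f"c{k}"] = np.zeros(b)
        return params

    # ---- forward -------------------------------------------------------
    def _forward(self, Wv: np.ndarray, S: np.ndarray, params: dict,
                 want_cache: bool = False):
        H = self.config.lstm_hidden
        B, L = Wv.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs_sum = np.zeros((B, H))
        steps = []
        Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
        for t in range(L):
            z = Wv[:, t: t + 1] @ Wx.T + h @ Wh.T + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H: 2 * H])
            g = np.tanh(z[:, 2 * H: 3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs_sum = hs_sum + h
            if want_cache:
                steps.append((i, f, g, o, c_prev, h_prev, tc))
        a = np.concatenate([hs_sum / L, S], axis=1)
        inputs = [a]  # input of each dense layer
        n_fc = len(self.config.fc_widths)
        for k in range(n_fc + 1):
            a = a @ params[f"W{k}"] + params[f"c{k}"]
            if k < n_fc:
                a = np.maximum(a, 0.0)
            inputs.append(a)
        logits = inputs[-1]
        shifted = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(shifted)
        p /= p.sum(axis=1, keepdims=True)
        if want_cache:
            return p, (steps, inputs)
        return p

    # ---- backward ------------------------------------------------------
    def _backward(self, Wv, S, Y, params, p, cache) -> dict:
        H = self.config.lstm_hidden
        B, L = Wv.shape
        steps, inputs = cache
        n_fc = len(self.config.fc_widths)
        grads = {}

        delta = (p - Y) / B  # d loss / d logits
        for k in range(n_fc, -1, -1):
            grads[f"W{k}"] = inputs[k].T @ delta
            grads[f"c{k}"] = delta.sum(axis=0)
            delta = delta @ params[f"W{k}"].T
            if k > 0:
                delta = delta * (inputs[k] > 0)  # ReLU gate
        dh_each = delta[:, :H] / L  # pooled mean spreads evenly over time

        Wx, Wh = params["Wx"], params["Wh"]
        gWx = np.zeros_like(Wx)
        gWh = np.zeros_like(Wh)
        gb = np.zeros_like(params["b"])
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = steps[t]
            dh = dh_each + dh_next
            do = dh * tc * o * (1 - o)
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g**2)
            dz = np.concatenate([di, df, dg, do], axis=1)  # (B, 4H)
            gWx += dz.T @ Wv[:, t: t + 1]
            gWh += dz.T @ h_prev
            gb += dz.sum(axis=0)
            dh_next = dz @ Wh
            dc_next = dc * f
        grads["Wx"], grads["Wh"], grads["b"] = gWx, gWh, gb
        return grads

    # ---- training ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "SequenceClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValidationError("X must be (n, L + 2) with L >= 1")
        self.classes_ = np.array(sorted(set(y.tolist()), key=str), dtype=object)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 classes")
        class_index = {c: k for k, c in enumerate(self.classes_)}
        self.n_waveform_ = X.shape[1] - 2
        Wv, S = X[:, : self.n_waveform_], X[:, self.n_waveform_:]
        yi = np.array([class_index[v] for v in y])
        Y = np.eye(len(self.classes_))[yi]

        rng = np.random.default_rng(cfg.seed)
        params = self._init_weights(len(self.classes_), rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(val) for k, val in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=object)
            unseen = set(y_val.tolist()) - set(self.classes_.tolist())
            if unseen:
                raise ValidationError(f"validation labels unseen in training: {unseen}")

        best = (-1.0, None)
        since_best = 0
        history = []
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                sel = order[lo: lo + cfg.batch_size]
                p, cache = self._forward(Wv[sel], S[sel], params, want_cache=True)
                loss = -np.mean(np.log(p[np.arange(len(sel)), yi[sel]] + 1e-12))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss!r}; "
                        "lower the learning rate or check the encoding"
                    )
                losses.append(loss)
                grads = self._backward(Wv[sel], S[sel], Y[sel], params, p, cache)
                gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
                scale = min(1.0, cfg.grad_clip / (gnorm + 1e-12))
                step += 1
                for k in params:
                    g = grads[k] * scale
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

            self.params_ = params
            if X_val is not None and len(y_val):
                val_acc = float(np.mean(self._predict_with(X_val, params) == y_val))
            else:
                val_acc = float(np.mean(self._predict_with(X, params) == y))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                            "val_accuracy": val_acc})
            if val_acc > best[0]:
                best = (val_acc, {k: p.copy() for k, p in params.items()})
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

        self.params_ = best[1] if best[1] is not None else params
        self.history_ = history
        self.best_val_accuracy_ = best[0]
        return self

    # ---- inference -----------------------------------------------------
    def _predict_with(self, X, params, chunk: int = 512) -> np.ndarray:
        proba = self._proba_with(X, params, chunk)
        return self.classes_[np.argmax(proba, axis=1)]

    def _proba_with(self, X, params, chunk: int = 512) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.zeros((0, len(self.classes_)))
        if X.shape[1] != self.n_waveform_ + 2:
            raise ValidationError(
                f"encoding length mismatch: expected {self.n_waveform_ + 2} "
                f"columns, got {X.shape[1]}"
            )
        out = []
        for lo in range(0, X.shape[0], chunk):
            Wv = X[lo: lo + chunk, : self.n_waveform_]
            S = X[lo: lo + chunk, self.n_waveform_:]
            out.append(self._forward(Wv, S, params))
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        return self._proba_with(X, self.params_)

    def predict(self, X) -> np.ndarray:
        return self._predict_with(X, self.params_)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))


def train_sequence_classifier(
    train, validation, config: SequenceClassifierConfig | None = None, L: int | None = None
) -> SequenceClassifier:
    """Train the sequence model on encoded events (see
    :func:`porecall.classify.encode_events`)."""
    from .classify import encode_frame

    Wt, St, yt = encode_frame(train)
    Xt = np.hstack([Wt, St])
    if validation:
        Wv, Sv, yv = encode_frame(validation)
        Xv = np.hstack([Wv, Sv])
    else:
        Xv, yv = None, None
    model = SequenceClassifier(config)
    return model.fit(Xt, yt, Xv, yv)
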
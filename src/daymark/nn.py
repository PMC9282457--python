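"""A small LSTM binary sequence classifier in pure numpy.

Implements exactly what the forecasting stage needs and nothing more: one
LSTM layer over left-padded variable-length windows (a boolean mask freezes
the hidden and cell state on padded steps), dropout on the final hidden
state, a sigmoid head, weighted binary cross-entropy, Adam, and early
stopping on validation loss. Gradients are computed by backpropagation
through time and are verified against finite differences in the test suite.

Shapes: ``X`` is (batch, T, F), ``mask`` is (batch, T) with 1 on valid
steps; padding sits at the old (left) end so the final step is always valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LSTMConfig", "LSTMClassifier"]


@dataclass
class LSTMConfig:
    """Hyperparameters, shared across feature sets and never tuned per set."""

    n_features: int
    hidden: int = 32
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    class_weighting: bool = True
    seed: int = 0
    dtype: str = "float32"  # activation dtype; gradient-check tests use float64


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-free: sigmoid(x) = (tanh(x/2) + 1) / 2
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class LSTMClassifier:
    """Masked-sequence LSTM with a sigmoid head, trained by Adam + BPTT."""

    #: parameter names, fixed order for the Adam state
    _PARAMS = ("Wx", "Wh", "b", "w_out", "b_out")

    def __init__(self, config: LSTMConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        F, H = config.n_features, config.hidden
        # Glorot-scaled gate weights; forget-gate bias starts at 1
        sx = np.sqrt(6.0 / (F + 4 * H))
        sh = np.sqrt(6.0 / (H + 4 * H))
        self.Wx = rng.uniform(-sx, sx, size=(F, 4 * H)).astype(self.dtype)
        self.Wh = rng.uniform(-sh, sh, size=(H, 4 * H)).astype(self.dtype)
        self.b = np.zeros(4 * H, dtype=self.dtype)
        self.b[H : 2 * H] = 1.0
        so = np.sqrt(6.0 / (H + 1))
        self.w_out = rng.uniform(-so, so, size=H).astype(self.dtype)
        self.b_out = 0.0
        self._rng = rng
        self._adam_m = {k: np.zeros_like(np.asarray(getattr(self, k), dtype=float))
                        for k in self._PARAMS}
        self._adam_v = {k: np.zeros_like(np.asarray(getattr(self, k), dtype=float))
                        for k in self._PARAMS}
        self._adam_t = 0
        self.history: list[dict] = []

    # ---- forward -----------------------------------------------------

    def _forward_lstm(self, X: np.ndarray, mask: np.ndarray, keep_cache: bool = True):
        B, T, F = X.shape
        H = self.config.hidden
        X = np.ascontiguousarray(X, dtype=self.dtype)
        mask = np.ascontiguousarray(mask, dtype=self.dtype)
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        Zx = X.reshape(B * T, F) @ self.Wx
        Zx = Zx.reshape(B, T, 4 * H) + self.b
        cache = [] if keep_cache else None
        for t in range(T):
            m = mask[:, t][:, None]
            z = Zx[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if keep_cache:
                cache.append((h, c, i, f, g, o, tc, m))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        return h, cache

    def forward(
        self, X: np.ndarray, mask: np.ndarray, dropout_mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, tuple]:
        """Probabilities for a batch; returns (p, cache) for backprop."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        mask = np.ascontiguousarray(mask, dtype=self.dtype)
        if dropout_mask is not None:
            dropout_mask = dropout_mask.astype(self.dtype, copy=False)
        hT, cache = self._forward_lstm(X, mask)
        hd = hT * dropout_mask if dropout_mask is not None else hT
        logit = hd @ self.w_out + self.b_out
        p = _sigmoid(logit)
        return p, (X, mask, cache, hT, hd, dropout_mask, p)

    def predict_proba(
        self, X: np.ndarray, mask: np.ndarray, chunk: int = 1024
    ) -> np.ndarray:
        """Cache-free chunked forward pass; safe for large evaluation sets."""
        if X.shape[2] != self.config.n_features:
            raise ValueError(
                f"model expects {self.config.n_features} features, got {X.shape[2]}"
            )
        if len(X) == 0:
            return np.zeros(0)
        out = np.empty(len(X))
        for lo in range(0, len(X), chunk):
            hT, _ = self._forward_lstm(
                X[lo : lo + chunk], mask[lo : lo + chunk], keep_cache=False
            )
            out[lo : lo + chunk] = _sigmoid(hT @ self.w_out + self.b_out)
        return out

    # ---- backward ----------------------------------------------------

    def backward(self, cache: tuple, y: np.ndarray, sample_weight: np.ndarray):
        """Gradients of the mean weighted BCE for the cached batch."""
        X, mask, lstm_cache, hT, hd, dmask, p = cache
        B = len(y)
        H = self.config.hidden
        grads = {k: np.zeros_like(np.asarray(getattr(self, k), dtype=float))
                 for k in self._PARAMS}

        dlogit = (sample_weight * (p - y) / B).astype(self.dtype)
        grads["w_out"] = hd.T @ dlogit
        grads["b_out"] = dlogit.sum()
        dhd = dlogit[:, None] * self.w_out[None, :]
        dh = dhd * dmask if dmask is not None else dhd
        dc = np.zeros((B, H), dtype=self.dtype)
        T = X.shape[1]
        DZ = np.empty((B, T, 4 * H), dtype=self.dtype)

        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = lstm_cache[t]
            dh_new = dh * m
            dh_pass = dh * (1.0 - m)
            dc_new = dc * m
            dc_pass = dc * (1.0 - m)

            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc**2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_new * f + dc_pass

            dz = DZ[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g**2)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            grads["Wh"] += h_prev.T @ dz
            dh = dz @ self.Wh.T + dh_pass
            dc = dc_prev

        F = X.shape[2]
        grads["Wx"] = X.reshape(B * T, F).T @ DZ.reshape(B * T, 4 * H)
        grads["b"] = DZ.sum(axis=(0, 1))
        return grads

    @staticmethod
    def loss(
        p: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> float:
        eps = 1e-12
        ll = -(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
        if sample_weight is not None:
            ll = ll * sample_weight
        return float(ll.mean())

    # ---- optimization ------------------------------------------------

    def _adam_step(self, grads: dict) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        for k in self._PARAMS:
            g = grads[k]
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            update = lr * mhat / (np.sqrt(vhat) + eps)
            if k in ("b_out",):
                setattr(self, k, getattr(self, k) - float(update))
            else:
                setattr(self, k, getattr(self, k) - update)

    def _class_weights(self, y: np.ndarray) -> np.ndarray:
        if not self.config.class_weighting:
            return np.ones_like(y, dtype=float)
        n, n_pos = len(y), y.sum()
        w_pos = n / (2.0 * n_pos)
        w_neg = n / (2.0 * (n - n_pos))
        return np.where(y > 0.5, w_pos, w_neg)

    def fit(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        mask_val: np.ndarray,
        y_val: np.ndarray,
    ) -> "LSTMClassifier":
        """Train with early stopping on validation loss; restores the best
        epoch's weights. Requires both classes in the training labels."""
        y = np.asarray(y, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if y.min() == y.max():
            raise ValueError("training labels contain a single class")
        X = X.astype(self.dtype, copy=False)
        mask = mask.astype(self.dtype, copy=False)
        X_val = X_val.astype(self.dtype, copy=False)
        mask_val = mask_val.astype(self.dtype, copy=False)
        cfg = self.config
        weights = self._class_weights(y)
        n = len(y)
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if cfg.dropout > 0:
                    keep = (
                        self._rng.random((len(idx), cfg.hidden)) >= cfg.dropout
                    ) / (1.0 - cfg.dropout)
                else:
                    keep = None
                p, cache = self.forward(X[idx], mask[idx], keep)
                grads = self.backward(cache, y[idx], weights[idx])
                self._adam_step(grads)

            val_p = self.predict_proba(X_val, mask_val)
            val_loss = self.loss(val_p, y_val)
            self.history.append({"epoch": epoch, "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: np.copy(getattr(self, k)) for k in self._PARAMS}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        if best_state is not None:
            for k, v in best_state.items():
                setattr(self, k, v if np.ndim(v) else float(v))
        return self
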
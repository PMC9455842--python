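"""Compact convolutional classifier for trials × channels × time input.

One convolution layer with a (1, 3) kernel shared across channels,
batch normalization, ELU, dropout (p = 0.25) and a fully connected
layer to two logits, trained with Adam (lr 0.005, batch 25) on the
cross-entropy loss.  Forward and backward passes are explicit numpy;
all randomness (init, shuffling, dropout, validation split) comes from
one seeded generator, so identical seed + data give identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CNNConfig", "CompactCNN"]


@dataclass(frozen=True)
class CNNConfig:
    n_filters: int = 8
    kernel: tuple[int, int] = (1, 3)
    dropout_p: float = 0.25
    lr: float = 0.005
    batch_size: int = 25
    epochs: int = 100
    seed: int = 0
    early_stopping: bool = True
    val_fraction: float = 0.1
    patience: int = 10
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.kernel != (1, 3):
            raise ValueError("this architecture uses a (1, 3) kernel")


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CompactCNN:
    """conv(1×3) → batch-norm → ELU → dropout → flatten → FC → 2 logits."""

    def __init__(self, config: CNNConfig = CNNConfig()):
        self.cfg = config
        self.params: dict | None = None
        self.running_mean: np.ndarray | None = None
        self.running_var: np.ndarray | None = None
        self._in_scale: float = 1.0

    # -- forward pieces ----------------------------------------------------

    def _conv(self, X: np.ndarray) -> np.ndarray:
        """(N, C, T) -> (N, F, C, T-2) via the shared (1,3) kernel."""
        Xw = np.lib.stride_tricks.sliding_window_view(X, 3, axis=2)  # (N,C,T-2,3)
        return np.einsum("ncts,fs->nfct", Xw, self.params["W1"]) + self.params["b1"][None, :, None, None]

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator) -> dict:
        cfg = self.cfg
        conv = self._conv(X)
        axes = (0, 2, 3)
        mu = conv.mean(axis=axes)
        var = conv.var(axis=axes)
        self.running_mean = (1 - cfg.bn_momentum) * self.running_mean + cfg.bn_momentum * mu
        self.running_var = (1 - cfg.bn_momentum) * self.running_var + cfg.bn_momentum * var
        inv_std = 1.0 / np.sqrt(var + cfg.bn_eps)
        xhat = (conv - mu[None, :, None, None]) * inv_std[None, :, None, None]
        bn = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        act = _elu(bn)
        mask = (rng.random(act.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
        drop = act * mask
        flat = drop.reshape(X.shape[0], -1)
        logits = flat @ self.params["W2"] + self.params["b2"]
        return {
            "X": X, "conv": conv, "xhat": xhat, "inv_std": inv_std,
            "bn": bn, "act": act, "mask": mask, "flat": flat, "logits": logits,
        }

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        conv = self._conv(X)
        inv_std = 1.0 / np.sqrt(self.running_var + cfg.bn_eps)
        xhat = (conv - self.running_mean[None, :, None, None]) * inv_std[None, :, None, None]
        bn = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        flat = _elu(bn).reshape(X.shape[0], -1)
        return flat @ self.params["W2"] + self.params["b2"]

    # -- backward ----------------------------------------------------------

    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        N = len(y)
        probs = _softmax(cache["logits"])
        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        grads = {
            "W2": cache["flat"].T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dflat = dlogits @ self.params["W2"].T
        ddrop = dflat.reshape(cache["act"].shape) * cache["mask"]
        dbn = ddrop * np.where(cache["bn"] > 0, 1.0, _elu(cache["bn"]) + 1.0)
        grads["gamma"] = np.einsum("nfct,nfct->f", dbn, cache["xhat"])
        grads["beta"] = dbn.sum(axis=(0, 2, 3))
        dxhat = dbn * self.params["gamma"][None, :, None, None]
        M = dbn.shape[0] * dbn.shape[2] * dbn.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = np.einsum("nfct,nfct->f", dxhat, cache["xhat"])
        dconv = (cache["inv_std"][None, :, None, None] / M) * (
            M * dxhat
            - s1[None, :, None, None]
            - cache["xhat"] * s2[None, :, None, None]
        )
        Xw = np.lib.stride_tricks.sliding_window_view(cache["X"], 3, axis=2)
        grads["W1"] = np.einsum("nfct,ncts->fs", dconv, Xw)
        grads["b1"] = dconv.sum(axis=(0, 2, 3))
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CompactCNN":
        """Train on (n_trials, channels, time) input with labels in {0, 1}."""
        cfg = self.cfg
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 3 or X.shape[2] < 3:
            raise ValueError("input must be trials × channels × time, time >= 3")
        rng = np.random.default_rng(cfg.seed)
        scale = X.std()
        self._in_scale = scale if scale > 0 else 1.0
        X = X / self._in_scale
        F = cfg.n_filters
        C, T = X.shape[1], X.shape[2]
        D = F * C * (T - 2)
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / 3.0), (F, 3)),
            "b1": np.zeros(F),
            "gamma": np.ones(F),
            "beta": np.zeros(F),
            "W2": rng.normal(0.0, np.sqrt(2.0 / D), (D, 2)),
            "b2": np.zeros(2),
        }
        self.running_mean = np.zeros(F)
        self.running_var = np.ones(F)
        opt = _Adam(self.params, cfg.lr)

        n = len(y)
        idx = rng.permutation(n)
        n_val = int(round(cfg.val_fraction * n)) if cfg.early_stopping else 0
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        best_loss, best_state, since_best = np.inf, None, 0
        for ep in range(cfg.epochs):
            order = rng.permutation(len(train_idx))
            for start in range(0, len(order), cfg.batch_size):
                bi = train_idx[order[start : start + cfg.batch_size]]
                if len(bi) < 2:
                    continue  # batch norm needs at least two samples
                cache = self._forward_train(X[bi], rng)
                grads = self._backward(cache, y[bi])
                if not all(np.all(np.isfinite(g)) for g in grads.values()):
                    raise FloatingPointError(
                        f"non-finite gradient at epoch {ep}; inputs may be degenerate"
                    )
                opt.step(self.params, grads)
            if n_val >= 2:
                logits = self._forward_eval(X[val_idx])
                p = _softmax(logits)
                val_loss = -np.mean(np.log(p[np.arange(n_val), y[val_idx]] + 1e-12))
                if val_loss < best_loss - 1e-6:
                    best_loss, since_best = val_loss, 0
                    best_state = (
                        {k: v.copy() for k, v in self.params.items()},
                        self.running_mean.copy(),
                        self.running_var.copy(),
                    )
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_state is not None:
            self.params, self.running_mean, self.running_var = best_state
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("fit before predict")
        X = np.asarray(X, float) / self._in_scale
        return _softmax(self._forward_eval(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (remembered) class."""
        return self.predict_proba(X)[:, 1]

    def weights_hash(self) -> str:
        """Stable digest of all learned parameters (reproducibility checks)."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        h.update(self.running_mean.tobytes())
        h.update(self.running_var.tobytes())
        return h.hexdigest()
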
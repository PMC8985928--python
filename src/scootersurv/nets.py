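"""Minimal numpy neural networks used as ensemble members.

Two member families: a feedforward network over TF-IDF vectors and a 1-D
convolutional network over word-embedding sequences (frozen embeddings,
valid convolutions, global max pooling, sigmoid head). Both train with
binary cross-entropy and Adam. Sizes here are deliberately small — the
ensemble's robustness comes from averaging randomly configured members, not
from the capacity of any single one — so everything is plain, deterministic
numpy: no GPU, no framework, bitwise-reproducible under a seed.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .records import StateError


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


class DenseNet:
    """Feedforward binary scorer: ReLU hidden layers, sigmoid output."""

    def __init__(self, input_dim: int, hidden: list[int], dropout: float = 0.0,
                 lr: float = 1e-3, epochs: int = 8, batch_size: int = 64,
                 seed: int = 0):
        self.input_dim = input_dim
        self.hidden = list(hidden)
        self.dropout = dropout
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed
        self.params: list[np.ndarray] | None = None

    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        prev = self.input_dim
        for width in self.hidden:
            params.append(_he_init(rng, prev, (prev, width)))
            params.append(np.zeros(width))
            prev = width
        params.append(_he_init(rng, prev, (prev, 1)))
        params.append(np.zeros(1))
        return params

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        acts = [X]
        masks = []
        a = X
        n_hidden = len(self.hidden)
        for layer in range(n_hidden):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            a = np.maximum(a @ W + b, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        W, b = self.params[-2], self.params[-1]
        logit = (a @ W + b).ravel()
        return logit, acts, masks

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DenseNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.seed)
        self.params = self._init_params(rng)
        optimizer = _Adam(self.params, lr=self.lr)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                logit, acts, masks = self._forward(xb, rng)
                p = expit(logit)
                dlogit = ((p - yb) / len(idx))[:, None]
                grads: list[np.ndarray] = [None] * len(self.params)
                grads[-2] = acts[-1].T @ dlogit
                grads[-1] = dlogit.sum(axis=0)
                da = dlogit @ self.params[-2].T
                for layer in range(len(self.hidden) - 1, -1, -1):
                    if masks[layer] is not None:
                        da = da * masks[layer]
                    dz = da * (acts[layer + 1] > 0)
                    grads[2 * layer] = acts[layer].T @ dz
                    grads[2 * layer + 1] = dz.sum(axis=0)
                    if layer > 0:
                        da = dz @ self.params[2 * layer].T
                optimizer.step(self.params, grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise StateError("network is not trained")
        logit, _, _ = self._forward(np.asarray(X, dtype=np.float64), rng=None)
        return expit(logit)


class ConvNet:
    """1-D convolutional binary scorer over frozen embedding sequences.

    Stacked valid convolutions with ReLU, global max pooling, then a sigmoid
    dense head. Input is a matrix of token row-indices into the embedding
    table (0 = padding/unknown); the embedding table itself is not updated.
    """

    def __init__(self, embedding_matrix: np.ndarray,
                 conv_layers: list[tuple[int, int]], dropout: float = 0.0,
                 lr: float = 1e-3, epochs: int = 8, batch_size: int = 64,
                 seed: int = 0):
        self.embedding = np.asarray(embedding_matrix, dtype=np.float64)
        self.conv_layers = [(int(f), int(k)) for f, k in conv_layers]
        self.dropout = dropout
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed
        self.params: list[np.ndarray] | None = None

    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        channels = self.embedding.shape[1]
        for filters, kernel in self.conv_layers:
            params.append(_he_init(rng, kernel * channels, (kernel * channels, filters)))
            params.append(np.zeros(filters))
            channels = filters
        params.append(_he_init(rng, channels, (channels, 1)))
        params.append(np.zeros(1))
        return params

    @staticmethod
    def _conv_forward(a: np.ndarray, W: np.ndarray, b: np.ndarray, kernel: int):
        # a: (B, L, C) -> patches (B, P, kernel*C) -> relu(patches @ W + b)
        windows = sliding_window_view(a, kernel, axis=1)  # (B, P, C, kernel)
        patches = np.swapaxes(windows, 2, 3).reshape(
            a.shape[0], a.shape[1] - kernel + 1, -1
        )
        z = patches @ W + b
        return np.maximum(z, 0.0), patches, z

    def _forward(self, idx: np.ndarray, rng: np.random.Generator | None):
        a = self.embedding[idx]  # (B, L, D)
        caches = []
        for layer, (filters, kernel) in enumerate(self.conv_layers):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            out, patches, z = self._conv_forward(a, W, b, kernel)
            caches.append((patches, z, a.shape))
            a = out
        pooled_arg = a.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(a, pooled_arg[:, None, :], axis=1)[:, 0, :]
        mask = None
        if rng is not None and self.dropout > 0:
            mask = (rng.random(pooled.shape) >= self.dropout) / (1 - self.dropout)
            pooled_d = pooled * mask
        else:
            pooled_d = pooled
        W, b = self.params[-2], self.params[-1]
        logit = (pooled_d @ W + b).ravel()
        return logit, caches, pooled_arg, pooled_d, mask

    def fit(self, idx: np.ndarray, y: np.ndarray) -> "ConvNet":
        idx = np.asarray(idx, dtype=np.int32)
        y = np.asarray(y, dtype=np.float64)
        min_len = sum(k for _, k in self.conv_layers) - len(self.conv_layers) + 1
        if idx.shape[1] < min_len:
            raise ValueError("sequence length shorter than stacked kernels")
        rng = np.random.default_rng(self.seed)
        self.params = self._init_params(rng)
        optimizer = _Adam(self.params, lr=self.lr)
        n = idx.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = idx[batch], y[batch]
                logit, caches, pooled_arg, pooled_d, mask = self._forward(xb, rng)
                p = expit(logit)
                dlogit = ((p - yb) / len(batch))[:, None]
                grads: list[np.ndarray] = [None] * len(self.params)
                grads[-2] = pooled_d.T @ dlogit
                grads[-1] = dlogit.sum(axis=0)
                dpooled = dlogit @ self.params[-2].T
                if mask is not None:
                    dpooled = dpooled * mask
                # scatter pooled gradient back to argmax positions
                patches_last, z_last, _ = caches[-1]
                da = np.zeros_like(z_last)
                np.put_along_axis(da, pooled_arg[:, None, :], dpooled[:, None, :], axis=1)
                for layer in range(len(self.conv_layers) - 1, -1, -1):
                    patches, z, in_shape = caches[layer]
                    _, kernel = self.conv_layers[layer]
                    dz = da * (z > 0)
                    B, P, F = dz.shape
                    grads[2 * layer] = patches.reshape(-1, patches.shape[-1]).T @ dz.reshape(-1, F)
                    grads[2 * layer + 1] = dz.reshape(-1, F).sum(axis=0)
                    if layer > 0:
                        W = self.params[2 * layer]
                        dpatches = dz @ W.T  # (B, P, kernel*C)
                        C = in_shape[2]
                        dpatches = dpatches.reshape(B, P, kernel, C)
                        da_prev = np.zeros(in_shape)
                        for j in range(kernel):
                            da_prev[:, j:j + P, :] += dpatches[:, :, j, :]
                        da = da_prev
                optimizer.step(self.params, grads)
        return self

    def predict_proba(self, idx: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise StateError("network is not trained")
        idx = np.asarray(idx, dtype=np.int32)
        out = np.empty(idx.shape[0])
        # bounded memory on long inputs
        for start in range(0, idx.shape[0], 2048):
            logit, *_ = self._forward(idx[start:start + 2048], rng=None)
            out[start:start + 2048] = expit(logit)
        return out
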
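"""Environment feature networks (linear map or small MLP), numpy-native.

Forward/backward passes are hand-written; ``rowwise_forward`` computes
the same predictor with feature-wise accumulation so that results are
bit-identical regardless of how input rows are batched (needed for the
chunked-raster-prediction invariance guarantee).
"""

from __future__ import annotations

import numpy as np

__all__ = ["LinearNet", "MLPNet", "make_network"]


def _rowwise_matmul(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    # Accumulate over input features one at a time: per-row float ops do
    # not depend on the batch size, unlike BLAS gemm blocking.
    out = np.zeros((X.shape[0], W.shape[1]))
    for k in range(X.shape[1]):
        out += X[:, k : k + 1] * W[k : k + 1, :]
    return out


class LinearNet:
    """eta = X W + b."""

    kind = "linear"

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=float)
        self.b = np.asarray(b, dtype=float)

    @classmethod
    def init(cls, n_features: int, n_species: int, rng: np.random.Generator,
             bias: np.ndarray | None = None) -> "LinearNet":
        W = 0.1 * rng.standard_normal((n_features, n_species))
        b = np.zeros(n_species) if bias is None else np.asarray(bias, dtype=float).copy()
        return cls(W, b)

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return ()

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        return X @ self.W + self.b

    def rowwise_forward(self, X: np.ndarray) -> np.ndarray:
        return _rowwise_matmul(X, self.W) + self.b

    def backward(self, d_eta: np.ndarray) -> dict[str, np.ndarray]:
        return {"W": self._X.T @ d_eta, "b": d_eta.sum(axis=0)}

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def weight_keys(self) -> list[str]:
        # biases are never penalized
        return ["W"]


class MLPNet:
    """Small tanh MLP: X -> hidden layers -> per-species linear predictor."""

    kind = "mlp"

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]

    @classmethod
    def init(cls, n_features: int, n_species: int, hidden: tuple[int, ...],
             rng: np.random.Generator, bias: np.ndarray | None = None) -> "MLPNet":
        sizes = [n_features, *hidden, n_species]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            weights.append(scale * rng.standard_normal((fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        if bias is not None:
            biases[-1] = np.asarray(bias, dtype=float).copy()
        return cls(weights, biases)

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.weights[:-1])

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + b)
            self._acts.append(h)
        return h @ self.weights[-1] + self.biases[-1]

    def rowwise_forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(_rowwise_matmul(h, W) + b)
        return _rowwise_matmul(h, self.weights[-1]) + self.biases[-1]

    def backward(self, d_eta: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        delta = d_eta
        n_layers = len(self.weights)
        for layer in range(n_layers - 1, -1, -1):
            a_in = self._acts[layer]
            grads[f"W{layer}"] = a_in.T @ delta
            grads[f"b{layer}"] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (1.0 - a_in**2)
        return grads

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def weight_keys(self) -> list[str]:
        return [f"W{i}" for i in range(len(self.weights))]


def make_network(
    n_features: int,
    n_species: int,
    hidden: tuple[int, ...],
    rng: np.random.Generator,
    bias: np.ndarray | None = None,
):
    if hidden:
        return MLPNet.init(n_features, n_species, tuple(hidden), rng, bias=bias)
    return LinearNet.init(n_features, n_species, rng, bias=bias)
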
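"""The coordinate-regression MLP g_θ.

A plain fully connected network mapping a voxel descriptor to one predicted
clean intensity: ``depth`` hidden layers of ``hidden_dim`` units with ReLU
activations, followed by a linear scalar head.  ReLU is used because the
positional encoding already supplies the sinusoidal basis; the network itself
only needs to combine features.  Weights and biases use uniform fan-in
initialisation, U(−1/√fan_in, 1/√fan_in), drawn from a seeded generator so that
construction is fully deterministic.

Implemented directly in NumPy with an explicit backward pass; at the scales
used for per-volume training (hidden ≤ 1024, a few dozen thousand voxels) this
runs comfortably on a CPU.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["MLPModel", "init_model", "predict"]


class MLPModel:
    """Fully connected scalar-output regressor.

    Parameters
    ----------
    input_dim : int
        Descriptor length.
    hidden_dim : int
        Width of each hidden layer (default 1024).
    depth : int
        Number of hidden layers (default 4); a linear scalar head follows.
    seed : int
        Seed for parameter initialisation.
    dtype : numpy dtype
        Parameter/compute dtype; float32 is used for training speed,
        float64 for numerical checks.
    """

    def __init__(self, input_dim: int, hidden_dim: int = 1024, depth: int = 4,
                 seed: int = 0, dtype=np.float32):
        if input_dim < 1 or hidden_dim < 1 or depth < 1:
            raise ValueError("input_dim, hidden_dim and depth must be positive")
        self.input_dim = int(input_dim)
        self.hidden_dim = int(hidden_dim)
        self.depth = int(depth)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        dims = [self.input_dim] + [self.hidden_dim] * self.depth + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(
                rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(self.dtype)
            )
            self.biases.append(rng.uniform(-bound, bound, size=fan_out).astype(self.dtype))

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predictions for a batch, shape (n,). Input shape (n, input_dim)."""
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"descriptor batch has shape {X.shape}, expected (n, {self.input_dim})"
            )
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        out = a @ self.weights[-1] + self.biases[-1]
        return out[:, 0]

    def forward_backward(self, X: np.ndarray, y: np.ndarray):
        """MSE loss over the batch and its gradients w.r.t. all parameters.

        Returns (loss, grads_W, grads_b) where the gradient lists parallel
        ``self.weights``/``self.biases``.
        """
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype)
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty batch")
        acts = [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        pred = (a @ self.weights[-1] + self.biases[-1])[:, 0]
        resid = pred - y
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        # d loss / d pred
        delta = (2.0 / n) * resid.astype(self.dtype)
        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        d = delta[:, None]  # (n, 1)
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_W[layer] = acts[layer].T @ d
            grads_b[layer] = d.sum(axis=0)
            if layer > 0:
                d = (d @ self.weights[layer].T) * (acts[layer] > 0)
        return loss, grads_W, grads_b

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def parameters(self):
        """Flat list of parameter arrays (weights then bias per layer)."""
        out = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist parameters plus architecture metadata to one ``.npz`` file."""
        meta = dict(input_dim=self.input_dim, hidden_dim=self.hidden_dim,
                    depth=self.depth, seed=self.seed, dtype=self.dtype.name)
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path: str) -> "MLPModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            model = cls(meta["input_dim"], meta["hidden_dim"], meta["depth"],
                        meta["seed"], dtype=meta["dtype"])
            model.weights = [f[f"W{i}"] for i in range(len(model.weights))]
            model.biases = [f[f"b{i}"] for i in range(len(model.biases))]
        return model


def init_model(input_dim: int, hidden_dim: int = 1024, depth: int = 4,
               seed: int = 0, dtype=np.float32) -> MLPModel:
    """Construct a seeded :class:`MLPModel` (functional alias)."""
    return MLPModel(input_dim, hidden_dim, depth, seed, dtype)


def predict(model: MLPModel, descriptor: np.ndarray):
    """Scalar prediction for one descriptor, or an (n,) array for a batch."""
    d = np.asarray(descriptor)
    if d.ndim == 1:
        if d.shape[0] != model.input_dim:
            raise ValueError(
                f"descriptor length {d.shape[0]} != model input_dim {model.input_dim}"
            )
        return float(model.forward(d[None, :])[0])
    return model.forward(d)
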
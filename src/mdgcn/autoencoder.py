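"""Dual autoencoder feature compression.

miRNA and disease feature matrices are compressed independently by two
autoencoders that share an architecture but never share parameters. The
encoder maps ``input_dim -> hidden_dims... -> code_dim`` with a sigmoid
at every layer; the decoder mirrors it back to ``input_dim``. Training
minimises the summed squared reconstruction error with full-batch Adam;
the low-dimensional encoder output (the code) is what downstream stages
consume as the node embedding.

Default widths target the reference-scale data (feature dimension 878):
one hidden layer of 512 and a 128-dimensional code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam, glorot_uniform, sigmoid

__all__ = ["AutoencoderSpec", "Autoencoder", "train_autoencoder"]


class DivergenceError(RuntimeError):
    """Training loss became non-finite (learning rate likely too high)."""


@dataclass
class AutoencoderSpec:
    """Architecture and training hyper-parameters for one autoencoder."""

    code_dim: int = 128
    hidden_dims: tuple[int, ...] = (512,)
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self, input_dim: int) -> None:
        dims = (input_dim, *self.hidden_dims, self.code_dim)
        if any(d2 >= d1 for d1, d2 in zip(dims, dims[1:])):
            raise ValueError(
                f"encoder widths must strictly decrease from input to code, got {dims}"
            )
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate positive")


class Autoencoder:
    """Symmetric sigmoid autoencoder trained by reconstruction loss."""

    def __init__(self, input_dim: int, spec: AutoencoderSpec | None = None):
        self.spec = spec or AutoencoderSpec()
        self.spec.validate(input_dim)
        self.input_dim = input_dim
        dims = [input_dim, *self.spec.hidden_dims, self.spec.code_dim]
        dims = dims + dims[-2::-1]  # mirror decoder
        self.dims = dims
        rng = np.random.default_rng(self.spec.seed)
        self.weights = [
            glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.n_encoder_layers = len(self.spec.hidden_dims) + 1
        self.loss_history: list[float] = []
        self.trained = False

    # -- forward passes -------------------------------------------------

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        """All layer activations, input first, reconstruction last."""
        acts = [np.asarray(x, dtype=float)]
        for w, b in zip(self.weights, self.biases):
            acts.append(sigmoid(acts[-1] @ w + b))
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Code matrix (rows x code_dim); requires a trained model."""
        if not self.trained:
            raise RuntimeError("autoencoder is untrained; call fit() first")
        return self._encode_raw(x)

    def _encode_raw(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=float)
        if a.shape[1] != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {a.shape[1]}")
        for w, b in zip(
            self.weights[: self.n_encoder_layers], self.biases[: self.n_encoder_layers]
        ):
            a = sigmoid(a @ w + b)
        return a

    def decode(self, y: np.ndarray) -> np.ndarray:
        """Reconstruction (rows x input_dim) from codes."""
        if not self.trained:
            raise RuntimeError("autoencoder is untrained; call fit() first")
        a = np.asarray(y, dtype=float)
        if a.shape[1] != self.spec.code_dim:
            raise ValueError(f"expected code dim {self.spec.code_dim}, got {a.shape[1]}")
        for w, b in zip(
            self.weights[self.n_encoder_layers :], self.biases[self.n_encoder_layers :]
        ):
            a = sigmoid(a @ w + b)
        return a

    def reconstruction_loss(self, x: np.ndarray) -> float:
        acts = self._forward(x)
        return float(((acts[0] - acts[-1]) ** 2).sum())

    # -- training --------------------------------------------------------

    def fit(self, x: np.ndarray) -> "Autoencoder":
        x = np.asarray(x, dtype=float)
        if x.shape[0] < 2:
            raise ValueError("need at least 2 samples to train")
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {x.shape[1]}")
        opt = Adam(self.weights + self.biases, lr=self.spec.learning_rate)
        for _ in range(self.spec.epochs):
            acts = self._forward(x)
            loss = float(((acts[0] - acts[-1]) ** 2).sum())
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite reconstruction loss at epoch {len(self.loss_history)}; "
                    f"try a smaller learning rate than {self.spec.learning_rate}"
                )
            self.loss_history.append(loss)
            # backprop through the sigmoid stack
            delta = 2.0 * (acts[-1] - acts[0]) * acts[-1] * (1.0 - acts[-1])
            w_grads: list[np.ndarray] = [None] * len(self.weights)
            b_grads: list[np.ndarray] = [None] * len(self.biases)
            for layer in range(len(self.weights) - 1, -1, -1):
                w_grads[layer] = acts[layer].T @ delta
                b_grads[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ self.weights[layer].T) * acts[layer] * (
                        1.0 - acts[layer]
                    )
            opt.step(w_grads + b_grads)
        self.trained = True
        return self


def train_autoencoder(
    features: np.ndarray, spec: AutoencoderSpec | None = None
) -> tuple[Autoencoder, np.ndarray]:
    """Train one autoencoder and return it with the code matrix."""
    features = np.asarray(features, dtype=float)
    model = Autoencoder(features.shape[1], spec).fit(features)
    return model, model.encode(features)
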
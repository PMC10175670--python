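"""Graph-convolutional link predictor on the unified bipartite graph.

The miRNA and disease node sets are spliced into one graph whose
adjacency is the block matrix ``[[0, A], [A^T, 0]]`` (miRNAs first, then
diseases). Node embeddings from the dual autoencoders are propagated
through two graph-convolution layers

    H_{i+1} = act( D^{-1/2} (A + I) D^{-1/2} H_i W_i )

with ReLU after the first layer and identity before the decoder. A pair
(m, d) is scored by the inner-product decoder ``sigmoid(<h_m, h_d>)``
and the weights are trained by binary cross-entropy on a balanced set of
positive and sampled negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import Adam, glorot_uniform, sigmoid
from .types import AssociationMatrix

__all__ = [
    "UnifiedGraph",
    "GCNSpec",
    "GCNLinkPredictor",
    "build_unified_adjacency",
    "extract_association_block",
    "normalize_adjacency",
]


@dataclass
class UnifiedGraph:
    """Unified (n_m + n_d)-node graph; node order is miRNAs then diseases."""

    n_m: int
    n_d: int
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.n_m + self.n_d


def build_unified_adjacency(a: AssociationMatrix) -> UnifiedGraph:
    """Block adjacency ``[[0, A], [A^T, 0]]`` over miRNA + disease nodes."""
    n_m, n_d = a.n_m, a.n_d
    adj = np.zeros((n_m + n_d, n_m + n_d), dtype=float)
    adj[:n_m, n_m:] = a.values
    adj[n_m:, :n_m] = a.values.T
    return UnifiedGraph(n_m=n_m, n_d=n_d, adjacency=adj)


def extract_association_block(g: UnifiedGraph) -> np.ndarray:
    """Inverse of :func:`build_unified_adjacency` (the miRNA-disease block)."""
    return g.adjacency[: g.n_m, g.n_m :].copy()


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalisation with self-loops: D^{-1/2}(A+I)D^{-1/2}."""
    adjacency = np.asarray(adjacency, dtype=float)
    a_hat = adjacency + np.eye(adjacency.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))  # self-loops keep degrees > 0
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class GCNSpec:
    """Two propagation layers; ``layer_dims`` is (input, hidden, output)."""

    layer_dims: tuple[int, int, int] = (128, 64, 32)
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0

    def validate(self, input_dim: int) -> None:
        if len(self.layer_dims) != 3:
            raise ValueError("layer_dims must have exactly 3 entries (2 GCN layers)")
        if self.layer_dims[0] != input_dim:
            raise ValueError(
                f"GCN input width {self.layer_dims[0]} != embedding width {input_dim}"
            )


class GCNLinkPredictor:
    """2-layer GCN with an inner-product decoder, trained by BCE."""

    def __init__(self, spec: GCNSpec | None = None):
        self.spec = spec or GCNSpec()
        self.weights: list[np.ndarray] | None = None
        self.loss_history: list[float] = []
        self._s: np.ndarray | None = None  # normalised adjacency used at fit
        self._h0: np.ndarray | None = None
        self.n_m: int | None = None

    # -- forward ---------------------------------------------------------

    def _forward(self, s: np.ndarray, h0: np.ndarray):
        sh0 = s @ h0
        z1 = sh0 @ self.weights[0]
        h1 = np.maximum(z1, 0.0)  # ReLU
        sh1 = s @ h1
        h2 = sh1 @ self.weights[1]  # identity activation before the decoder
        return sh0, z1, h1, sh1, h2

    def embeddings(self) -> np.ndarray:
        """Final node embeddings on the training graph (miRNAs then diseases)."""
        self._require_trained()
        return self._forward(self._s, self._h0)[-1]

    def _require_trained(self) -> None:
        if self.weights is None or self._s is None:
            raise RuntimeError("link predictor is untrained; call fit() first")

    # -- training ---------------------------------------------------------

    def fit(
        self,
        graph: UnifiedGraph,
        h0: np.ndarray,
        pos_pairs: np.ndarray,
        neg_pairs: np.ndarray,
    ) -> "GCNLinkPredictor":
        """Train on balanced (m, d) index pairs.

        ``pos_pairs`` must be edges of ``graph``; ``neg_pairs`` must be
        absent from it (no label leakage through the propagation graph).
        """
        h0 = np.asarray(h0, dtype=float)
        if h0.shape[0] != graph.n_nodes:
            raise ValueError("embedding row count does not match graph size")
        self.spec.validate(h0.shape[1])
        pos_pairs = np.asarray(pos_pairs, dtype=np.int64).reshape(-1, 2)
        neg_pairs = np.asarray(neg_pairs, dtype=np.int64).reshape(-1, 2)
        if len(pos_pairs) == 0:
            raise ValueError("empty positive pair set")
        block = graph.adjacency[: graph.n_m, graph.n_m :]
        if neg_pairs.size and block[neg_pairs[:, 0], neg_pairs[:, 1]].any():
            raise ValueError("negative pair present as an edge in the training graph")

        rng = np.random.default_rng(self.spec.seed)
        d0, d1, d2 = self.spec.layer_dims
        self.weights = [glorot_uniform(rng, d0, d1), glorot_uniform(rng, d1, d2)]
        self._s = normalize_adjacency(graph.adjacency)
        self._h0 = h0
        self.n_m = graph.n_m

        pairs = np.vstack([pos_pairs, neg_pairs])
        m_idx = pairs[:, 0]
        d_idx = pairs[:, 1] + graph.n_m
        y = np.concatenate([np.ones(len(pos_pairs)), np.zeros(len(neg_pairs))])
        n_pairs = len(y)

        opt = Adam(self.weights, lr=self.spec.learning_rate)
        for _ in range(self.spec.epochs):
            sh0, z1, h1, sh1, h2 = self._forward(self._s, h0)
            logits = (h2[m_idx] * h2[d_idx]).sum(axis=1)
            p = sigmoid(logits)
            eps = 1e-12
            loss = -float(
                np.mean(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
            )
            self.loss_history.append(loss)
            # gradient of mean BCE wrt logits, then through the decoder
            dlogit = (p - y) / n_pairs
            dh2 = np.zeros_like(h2)
            np.add.at(dh2, m_idx, dlogit[:, None] * h2[d_idx])
            np.add.at(dh2, d_idx, dlogit[:, None] * h2[m_idx])
            dw1 = sh1.T @ dh2
            dh1 = (self._s.T @ dh2) @ self.weights[1].T
            dz1 = dh1 * (z1 > 0)
            dw0 = sh0.T @ dz1
            opt.step([dw0, dw1])
        return self

    # -- scoring -----------------------------------------------------------

    def score_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Scores in (0, 1) for (miRNA index, disease index) pairs."""
        self._require_trained()
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        h = self.embeddings()
        logits = (h[pairs[:, 0]] * h[pairs[:, 1] + self.n_m]).sum(axis=1)
        return sigmoid(logits)

    def score_matrix(self) -> np.ndarray:
        """Full n_m x n_d score matrix in one pass."""
        self._require_trained()
        h = self.embeddings()
        return sigmoid(h[: self.n_m] @ h[self.n_m :].T)
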
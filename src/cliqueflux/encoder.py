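"""Two-layer mean-pooling graph encoder with a sigmoid classification head.

Each mean-pooling (MP) layer computes ReLU(D_hat^-1 A_hat H Theta), where
A_hat = A + I augments the weighted adjacency with unit self-loops and
D_hat is the corresponding degree matrix. Row i of D_hat^-1 A_hat is a
convex combination over i's closed neighbourhood, so clique weights act
directly as aggregation weights. Two stacked MP layers produce F' = 16
dimensional embeddings; a single linear layer plus sigmoid maps an
embedding to an outcome probability, trained with binary cross-entropy.

Implemented in NumPy with hand-derived analytic gradients (verified against
central finite differences in the test suite), which keeps the model fully
deterministic and dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

EMBED_DIM = 16
SCORE_EPS = 1e-7


@dataclass
class EncoderModel:
    """Trainable parameters: two MP transformation matrices and a linear head."""

    theta1: np.ndarray
    theta2: np.ndarray
    head_weights: np.ndarray
    head_bias: float
    init_seed: int = 0

    @classmethod
    def init(cls, n_features: int, embed_dim: int = EMBED_DIM, seed: int = 0) -> "EncoderModel":
        """Glorot-uniform initialisation, seeded for reproducibility."""
        rng = np.random.default_rng(seed)

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        return cls(
            theta1=glorot(n_features, embed_dim),
            theta2=glorot(embed_dim, embed_dim),
            head_weights=glorot(embed_dim, 1).ravel(),
            head_bias=0.0,
            init_seed=seed,
        )

    def params(self) -> list[np.ndarray]:
        return [self.theta1, self.theta2, self.head_weights, np.atleast_1d(np.float64(self.head_bias))]

    def copy(self) -> "EncoderModel":
        return EncoderModel(
            theta1=self.theta1.copy(),
            theta2=self.theta2.copy(),
            head_weights=self.head_weights.copy(),
            head_bias=float(self.head_bias),
            init_seed=self.init_seed,
        )

    def assert_finite(self) -> None:
        for p in (self.theta1, self.theta2, self.head_weights, np.array([self.head_bias])):
            if not np.isfinite(p).all():
                raise FloatingPointError("non-finite model parameters")


def normalized_propagation(a: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Row-stochastic propagation operator P = D_hat^-1 (A + I).

    Self-loops always carry weight 1 (clique weights do not apply to them),
    which guarantees every row degree is positive.
    """
    a = sp.csr_matrix(a, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got {a.shape}")
    a_hat = a + sp.identity(a.shape[0], format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    inv_d = sp.diags(1.0 / deg)
    return (inv_d @ a_hat).tocsr()


def mean_pool_layer(h: np.ndarray, a: sp.spmatrix | np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One MP layer: ReLU(P H Theta) with P = D_hat^-1 (A + I)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if h.shape[1] != theta.shape[0]:
        raise ValueError(f"feature dim {h.shape[1]} does not match theta rows {theta.shape[0]}")
    p = normalized_propagation(a)
    return np.maximum(p @ h @ theta, 0.0)


def encode(x: np.ndarray, a: sp.spmatrix | np.ndarray, m: EncoderModel) -> np.ndarray:
    """Two stacked MP layers: embeddings = MP2(MP1(X, A), A)."""
    h1 = mean_pool_layer(x, a, m.theta1)
    return mean_pool_layer(h1, a, m.theta2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Prediction:
    """Outcome scores in (0, 1) plus the embeddings they were read from."""

    scores: np.ndarray
    embeddings: np.ndarray = field(default_factory=lambda: np.empty((0, EMBED_DIM)))


def predict(embeddings: np.ndarray, m: EncoderModel) -> Prediction:
    """Sigmoid head on the embeddings; scores clamped away from exact 0/1."""
    z = embeddings @ m.head_weights + m.head_bias
    scores = np.clip(_sigmoid(z), SCORE_EPS, 1.0 - SCORE_EPS)
    return Prediction(scores=scores, embeddings=embeddings)


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy -(1/N) sum[y log yhat + (1-y) log(1-yhat)]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ in length")
    s = np.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


def forward_loss(
    x: np.ndarray,
    p: sp.csr_matrix,
    m: EncoderModel,
    labels: np.ndarray,
    batch: np.ndarray,
) -> tuple[float, dict]:
    """Full-graph forward pass; BCE evaluated on ``batch`` nodes only.

    Returns the loss and a cache of intermediates for the backward pass.
    ``p`` is the precomputed row-stochastic propagation operator.
    """
    px = p @ x
    z1 = px @ m.theta1
    h1 = np.maximum(z1, 0.0)
    ph1 = p @ h1
    z2 = ph1 @ m.theta2
    h2 = np.maximum(z2, 0.0)
    logits = h2 @ m.head_weights + m.head_bias
    scores = np.clip(_sigmoid(logits), SCORE_EPS, 1.0 - SCORE_EPS)
    yb = labels[batch].astype(float)
    sb = scores[batch]
    loss = float(-np.mean(yb * np.log(sb) + (1.0 - yb) * np.log(1.0 - sb)))
    cache = dict(px=px, z1=z1, h1=h1, ph1=ph1, z2=z2, h2=h2, scores=scores, batch=batch, labels=labels)
    return loss, cache


def backward(p: sp.csr_matrix, m: EncoderModel, cache: dict) -> dict:
    """Analytic gradients of the batched BCE w.r.t. all parameters.

    d loss / d logit_i = (sigmoid(logit_i) - y_i) / |batch| on batch nodes,
    zero elsewhere; the rest is the chain rule through the two MP layers,
    using P^T to push gradients back through the propagation.
    """
    batch = cache["batch"]
    n = cache["h2"].shape[0]
    dlogits = np.zeros(n)
    dlogits[batch] = (cache["scores"][batch] - cache["labels"][batch].astype(float)) / batch.size

    g_head_w = cache["h2"].T @ dlogits
    g_head_b = float(dlogits.sum())

    dh2 = np.outer(dlogits, m.head_weights)
    dz2 = dh2 * (cache["z2"] > 0.0)
    g_theta2 = cache["ph1"].T @ dz2
    dh1 = p.T @ (dz2 @ m.theta2.T)
    dz1 = dh1 * (cache["z1"] > 0.0)
    g_theta1 = cache["px"].T @ dz1
    return dict(theta1=g_theta1, theta2=g_theta2, head_weights=g_head_w, head_bias=g_head_b)


class Adam:
    """Adam optimiser with the standard decay constants, no weight decay."""

    def __init__(self, model: EncoderModel, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=float) for k, v in self._param_dict(model).items()}
        self.v = {k: np.zeros_like(v, dtype=float) for k, v in self._param_dict(model).items()}

    @staticmethod
    def _param_dict(model: EncoderModel) -> dict:
        return dict(
            theta1=model.theta1,
            theta2=model.theta2,
            head_weights=model.head_weights,
            head_bias=np.atleast_1d(np.float64(model.head_bias)),
        )

    def step(self, model: EncoderModel, grads: dict) -> None:
        self.t += 1
        params = self._param_dict(model)
        for k, p in params.items():
            g = np.atleast_1d(np.asarray(grads[k], dtype=float))
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / (1.0 - self.beta1**self.t)
            v_hat = self.v[k] / (1.0 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        model.head_bias = float(params["head_bias"][0])
        model.assert_finite()
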
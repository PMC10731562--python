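"""Neural building blocks: focal-flooding loss, FCNN head, small bidirectional
transformer encoder, AdamW, and a seeded early-stopping training loop.

The flooding regularizer keeps the batch training loss from descending below a
floor ``b`` (|L - b| + b applied to the batch mean), and the focal term
down-weights easy samples and re-weights classes, so that minority
satisfaction classes keep contributing gradient on imbalanced review corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor, embedding_lookup

__all__ = [
    "FFLossParams",
    "focal_loss_per_sample",
    "ff_batch_loss",
    "softmax_probabilities",
    "ff_loss_from_logits",
    "cross_entropy_from_logits",
    "Linear",
    "MLPNet",
    "TransformerNet",
    "AdamW",
    "TrainingResult",
    "train_network",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FFLossParams:
    """Hyperparameters of the focal-flooding (FF) loss.

    alpha
        Per-class positive weights; class 1 is the one usually re-weighted.
    gamma
        Focusing exponent >= 0; 0 recovers weighted cross-entropy.
    flood_b
        Flood level >= 0; 0 recovers the plain focal loss.
    """

    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: float = 1.0
    flood_b: float = 0.125

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"alpha weights must be positive, got {self.alpha}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.flood_b < 0:
            raise ValueError("flood_b must be >= 0")


def _check_labels(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes}), got {labels}")
    return labels.astype(np.int64)


def focal_loss_per_sample(
    probabilities: np.ndarray, labels: np.ndarray, params: FFLossParams
) -> np.ndarray:
    """Per-sample focal loss  -alpha_y (1 - p_y)^gamma ln p_y.

    ``probabilities`` is (n, 3) on the simplex; values are clipped to
    [1e-12, 1] before the log.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    labels = _check_labels(np.atleast_1d(labels), probs.shape[1])
    p_y = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    alpha_y = np.asarray(params.alpha)[labels]
    return -alpha_y * (1.0 - p_y) ** params.gamma * np.log(p_y)


def ff_batch_loss(
    probabilities: np.ndarray, labels: np.ndarray, params: FFLossParams
) -> float:
    """Focal-flooding batch loss  |mean(focal) - b| + b  (>= b always)."""
    labels = np.atleast_1d(labels)
    if labels.size == 0:
        raise ValueError("ff_batch_loss requires a non-empty batch")
    focal = focal_loss_per_sample(probabilities, labels, params)
    b = params.flood_b
    return float(abs(focal.mean() - b) + b)


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ff_loss_from_logits(logits: Tensor, labels: np.ndarray, params: FFLossParams) -> Tensor:
    """Differentiable FF loss on raw logits (autodiff path)."""
    labels = _check_labels(labels, logits.shape[-1])
    probs = logits.softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    # squeeze p into [1e-9, 1-1e-9] so (1-p)^gamma and log p stay finite for
    # every gamma >= 0, including the perfect-fit limit
    p_y = (probs * onehot).sum(axis=-1) * (1.0 - 2e-9) + 1e-9
    alpha_y = np.asarray(params.alpha)[labels]
    focal = (p_y.log() * ((1.0 - p_y) ** params.gamma)) * (-alpha_y)
    mean_focal = focal.mean()
    return (mean_focal - params.flood_b).abs() + params.flood_b


def cross_entropy_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Plain mean cross-entropy (the baseline the FF loss is compared with)."""
    labels = _check_labels(labels, logits.shape[-1])
    probs = logits.softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    p_y = (probs * onehot).sum(axis=-1) + _EPS
    return -(p_y.log().mean())


# --- layers ------------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.g + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.g, self.b]


class MLPNet:
    """Fully connected classifier head: input -> hidden layers -> 3 logits."""

    def __init__(
        self,
        n_features: int,
        hidden_width: int = 64,
        n_hidden_layers: int = 2,
        n_classes: int = 3,
        seed: int = 0,
    ):
        if n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        rng = np.random.default_rng(seed)
        dims = [n_features] + [hidden_width] * n_hidden_layers + [n_classes]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        return self.layers[-1](h)

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class _AttentionBlock:
    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)) + attn_bias
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = self.ln1(x + self.wo(ctx))
        ff = self.ff2(self.ff1(x).relu())
        return self.ln2(x + ff)

    @property
    def params(self) -> list[Tensor]:
        mods = [self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff2,
                self.ln1, self.ln2]
        return [p for m in mods for p in m.params]


class TransformerNet:
    """Small bidirectional (unmasked) transformer encoder with mean pooling.

    Token + learned positional embeddings, ``n_layers`` post-norm blocks of
    multi-head self-attention and position-wise feed-forward with residuals.
    Padding positions are excluded from both attention and pooling.
    """

    def __init__(
        self,
        vocab_size: int,
        d_model: int = 128,
        n_heads: int = 4,
        n_layers: int = 4,
        d_ff: int = 256,
        max_len: int = 128,
        seed: int = 0,
    ):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if max_len < 8:
            raise ValueError("max_sequence_length must be >= 8")
        rng = np.random.default_rng(seed)
        self.max_len = max_len
        self.d_model = d_model
        self.tok_emb = Tensor(rng.normal(0, 0.02, (vocab_size, d_model)), requires_grad=True)
        self.pos_emb = Tensor(rng.normal(0, 0.02, (max_len, d_model)), requires_grad=True)
        self.blocks = [_AttentionBlock(d_model, n_heads, d_ff, rng) for _ in range(n_layers)]

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Pooled document vectors for (B, T) token ids and a 0/1 pad mask."""
        B, T = ids.shape
        pos = embedding_lookup(self.pos_emb, np.arange(T))
        x = embedding_lookup(self.tok_emb, ids) + pos
        attn_bias = (1.0 - mask[:, None, None, :]) * -1e9  # (B,1,1,T)
        for block in self.blocks:
            x = block(x, attn_bias)
        m = mask[:, :, None]
        pooled = (x * m).sum(axis=1) / mask.sum(axis=1, keepdims=True)
        return pooled

    @property
    def params(self) -> list[Tensor]:
        return [self.tok_emb, self.pos_emb] + [p for b in self.blocks for p in b.params]


# --- optimizer & training loop -----------------------------------------------


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


@dataclass
class TrainingResult:
    """Per-epoch loss curves and the epoch whose parameters were kept."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def train_network(
    params: Sequence[Tensor],
    forward_loss: Callable[[np.ndarray], Tensor],
    n_train: int,
    val_loss: Callable[[], float] | None,
    *,
    lr: float = 1e-3,
    weight_decay: float = 0.01,
    batch_size: int = 32,
    max_epochs: int = 100,
    patience: int = 10,
    seed: int = 0,
) -> TrainingResult:
    """Minibatch AdamW training with early stopping on validation loss.

    ``forward_loss(idx)`` must return the scalar loss Tensor for the training
    subset ``idx``; ``val_loss`` the current validation loss. The parameters
    of the best validation epoch are restored before returning. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    opt = AdamW(params, lr=lr, weight_decay=weight_decay)
    result = TrainingResult()
    best = np.inf
    best_params: list[np.ndarray] | None = None
    since_best = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            loss = forward_loss(idx)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss {loss.data} at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        result.train_losses.append(float(np.mean(epoch_losses)))
        if val_loss is None:
            result.best_epoch = epoch
            continue
        vl = float(val_loss())
        result.val_losses.append(vl)
        if vl < best - 1e-12:
            best = vl
            best_params = [p.data.copy() for p in params]
            result.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                result.stopped_early = True
                break
    if best_params is not None:
        for p, d in zip(params, best_params):
            p.data = d
    return result
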
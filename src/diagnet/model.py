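"""Tied-weight autoencoder jointly trained with a single-layer perceptron.

The network encodes a masked-correlation feature vector x into a
bottleneck h = tanh(W x + b_enc), reconstructs it linearly with the
*transposed* encoder weight, x' = W^T h + b_dec (tied weights: the decoder
has no weight matrix of its own), and classifies from the bottleneck with
a single sigmoid unit, f(x) = sigma(w_slp . h + b_slp).

Training minimizes the sum of the reconstruction MSE and the binary
cross-entropy of the classifier ("joint" phase), so the bottleneck is
shaped simultaneously for reconstruction and for class discrimination;
afterwards only the perceptron is fine-tuned on the cross-entropy for a
few extra epochs with the encoder frozen.

The model is small enough (at most tens of thousands of parameters at
desk scale) that it is implemented directly in numpy with analytic
gradients and an Adam optimizer; gradient correctness is pinned by a
finite-difference test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: probability clip inside the cross-entropy, avoids log(0)
EPS = 1e-7


@dataclass
class HybridModelParams:
    """All trainable parameters. The decoder weight is never materialized:
    decoding always uses the transpose of ``W_enc``, so the tied-weight
    constraint holds by construction."""

    W_enc: np.ndarray  # (bottleneck_dim, input_dim)
    b_enc: np.ndarray  # (bottleneck_dim,)
    b_dec: np.ndarray  # (input_dim,)
    W_slp: np.ndarray  # (bottleneck_dim,)
    b_slp: float

    @property
    def input_dim(self) -> int:
        return int(self.W_enc.shape[1])

    @property
    def bottleneck_dim(self) -> int:
        return int(self.W_enc.shape[0])

    def copy(self) -> "HybridModelParams":
        return HybridModelParams(
            W_enc=self.W_enc.copy(),
            b_enc=self.b_enc.copy(),
            b_dec=self.b_dec.copy(),
            W_slp=self.W_slp.copy(),
            b_slp=float(self.b_slp),
        )

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            W_enc=self.W_enc,
            b_enc=self.b_enc,
            b_dec=self.b_dec,
            W_slp=self.W_slp,
            b_slp=np.array(self.b_slp),
        )

    @classmethod
    def load(cls, path: str | Path) -> "HybridModelParams":
        with np.load(path) as data:
            return cls(
                W_enc=data["W_enc"],
                b_enc=data["b_enc"],
                b_dec=data["b_dec"],
                W_slp=data["W_slp"],
                b_slp=float(data["b_slp"]),
            )


@dataclass
class TrainConfig:
    """Hyperparameters for joint training and SLP fine-tuning.

    bottleneck_dim : hidden width; None means floor(input_dim / 2),
        continuing the halving pattern of the feature pipeline.
    joint_epochs / finetune_epochs : epochs for the two phases.
    learning_rate : Adam step size.
    batch_size : minibatch size; None means full batch.
    loss_weights : (mse_weight, ce_weight), both applied additively.
    """

    bottleneck_dim: int | None = None
    joint_epochs: int = 25
    finetune_epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int | None = 8
    loss_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    finetune_freezes_encoder: bool = True

    def __post_init__(self) -> None:
        if self.joint_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None for full batch")


def init_model(
    input_dim: int, bottleneck_dim: int | None = None, seed: int = 0
) -> HybridModelParams:
    """Fan-in-scaled symmetric random weights, zero biases, seeded."""
    if bottleneck_dim is None:
        bottleneck_dim = input_dim // 2
    if not 1 <= bottleneck_dim <= input_dim:
        raise ValueError(
            f"need 1 <= bottleneck_dim <= input_dim, got "
            f"bottleneck_dim={bottleneck_dim}, input_dim={input_dim}"
        )
    rng = np.random.default_rng(seed)
    scale_enc = 1.0 / np.sqrt(input_dim)
    scale_slp = 1.0 / np.sqrt(bottleneck_dim)
    return HybridModelParams(
        W_enc=rng.uniform(-scale_enc, scale_enc, size=(bottleneck_dim, input_dim)),
        b_enc=np.zeros(bottleneck_dim),
        b_dec=np.zeros(input_dim),
        W_slp=rng.uniform(-scale_slp, scale_slp, size=bottleneck_dim),
        b_slp=0.0,
    )


def encode(params: HybridModelParams, x: np.ndarray) -> np.ndarray:
    """Bottleneck activation tanh(W_enc x + b_enc); components in (-1, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.input_dim:
        raise ValueError(
            f"input has {x.shape[-1]} features, model expects {params.input_dim}"
        )
    return np.tanh(x @ params.W_enc.T + params.b_enc)


def decode(params: HybridModelParams, h: np.ndarray) -> np.ndarray:
    """Linear reconstruction W_enc^T h + b_dec (tied weights)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.bottleneck_dim:
        raise ValueError(
            f"bottleneck has {h.shape[-1]} units, model expects "
            f"{params.bottleneck_dim}"
        )
    return h @ params.W_enc + params.b_dec


def classify_prob(params: HybridModelParams, x: np.ndarray) -> np.ndarray | float:
    """Patient-class probability sigma(W_slp . encode(x) + b_slp)."""
    h = encode(params, x)
    logit = h @ params.W_slp + params.b_slp
    prob = 1.0 / (1.0 + np.exp(-logit))
    return float(prob) if np.isscalar(logit) or logit.ndim == 0 else prob


def predict_label(params: HybridModelParams, x: np.ndarray) -> np.ndarray | int:
    """Threshold the probability at 0.5; the boundary maps to the patient
    class (label 1)."""
    prob = classify_prob(params, x)
    if np.isscalar(prob):
        return int(prob >= 0.5)
    return (np.asarray(prob) >= 0.5).astype(int)


def _forward(params: HybridModelParams, X: np.ndarray):
    H = np.tanh(X @ params.W_enc.T + params.b_enc)
    Xp = H @ params.W_enc + params.b_dec
    logits = H @ params.W_slp + params.b_slp
    P = 1.0 / (1.0 + np.exp(-logits))
    return H, Xp, P


def joint_loss(
    params: HybridModelParams,
    X: np.ndarray,
    y: np.ndarray,
    loss_weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """mse_weight * mean squared reconstruction error
    + ce_weight * mean binary cross-entropy (probabilities clipped)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    mse_w, ce_w = loss_weights
    _H, Xp, P = _forward(params, X)
    mse = float(np.mean((Xp - X) ** 2))
    Pc = np.clip(P, EPS, 1.0 - EPS)
    ce = float(np.mean(-(y * np.log(Pc) + (1.0 - y) * np.log(1.0 - Pc))))
    return mse_w * mse + ce_w * ce


def _gradients(
    params: HybridModelParams,
    X: np.ndarray,
    y: np.ndarray,
    loss_weights: tuple[float, float],
    slp_only: bool = False,
):
    """Analytic gradients of `joint_loss` (or its CE term when slp_only)."""
    mse_w, ce_w = loss_weights
    B, d = X.shape
    H, Xp, P = _forward(params, X)

    # cross-entropy path; the clip has zero derivative where it is active
    Pc = np.clip(P, EPS, 1.0 - EPS)
    dCE_dPc = (-(y / Pc) + (1.0 - y) / (1.0 - Pc)) / B
    inside = (P > EPS) & (P < 1.0 - EPS)
    dCE_dlogit = ce_w * dCE_dPc * np.where(inside, P * (1.0 - P), 0.0)

    g_Wslp = H.T @ dCE_dlogit
    g_bslp = float(dCE_dlogit.sum())
    if slp_only:
        return {"W_slp": g_Wslp, "b_slp": g_bslp}

    G_H = np.outer(dCE_dlogit, params.W_slp)

    # reconstruction path (tied weights: W_enc appears in encode and decode)
    G_Xp = mse_w * 2.0 * (Xp - X) / (B * d)
    g_bdec = G_Xp.sum(axis=0)
    g_W = H.T @ G_Xp  # decode usage: Xp = H W + b_dec
    G_H = G_H + G_Xp @ params.W_enc.T

    G_pre = G_H * (1.0 - H**2)  # through tanh
    g_W = g_W + G_pre.T @ X  # encode usage
    g_benc = G_pre.sum(axis=0)

    return {
        "W_enc": g_W,
        "b_enc": g_benc,
        "b_dec": g_bdec,
        "W_slp": g_Wslp,
        "b_slp": g_bslp,
    }


class _Adam:
    """Minimal Adam (adaptive-moment gradient descent) over a param dict."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray | float] = {}
        self.v: dict[str, np.ndarray | float] = {}
        self.t = 0

    def step(self, values: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for key, g in grads.items():
            m = self.m.get(key, np.zeros_like(g))
            v = self.v.get(key, np.zeros_like(g))
            m = self.beta1 * m + (1 - self.beta1) * np.asarray(g)
            v = self.beta2 * v + (1 - self.beta2) * np.asarray(g) ** 2
            self.m[key], self.v[key] = m, v
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            out[key] = values[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out


def _param_dict(params: HybridModelParams) -> dict:
    return {
        "W_enc": params.W_enc,
        "b_enc": params.b_enc,
        "b_dec": params.b_dec,
        "W_slp": params.W_slp,
        "b_slp": params.b_slp,
    }


def _apply(params: HybridModelParams, values: dict) -> HybridModelParams:
    updates = {k: (float(v) if k == "b_slp" else v) for k, v in values.items()}
    return replace(params, **updates)


def _epoch_batches(n: int, batch_size: int | None, rng: np.random.Generator):
    order = rng.permutation(n)
    if batch_size is None:
        yield order
        return
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_joint(
    params: HybridModelParams,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> tuple[HybridModelParams, list[float]]:
    """Joint training phase: Adam on MSE + cross-entropy.

    Returns the trained parameters and the full-batch loss after each
    epoch (entry 0 is the pre-training loss). The tied-weight constraint
    holds throughout since the decoder weight is derived, never stored.

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite, naming the epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must align")
    params = params.copy()
    rng = np.random.default_rng(config.seed)
    optimizer = _Adam(config.learning_rate)
    trajectory = [joint_loss(params, X, y, config.loss_weights)]
    for epoch in range(config.joint_epochs):
        for batch in _epoch_batches(X.shape[0], config.batch_size, rng):
            grads = _gradients(params, X[batch], y[batch], config.loss_weights)
            params = _apply(params, optimizer.step(_param_dict(params), grads))
        loss = joint_loss(params, X, y, config.loss_weights)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch + 1}")
        trajectory.append(loss)
    return params, trajectory


def fine_tune_slp(
    params: HybridModelParams,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> HybridModelParams:
    """Fine-tune the perceptron on the cross-entropy alone.

    With the default ``finetune_freezes_encoder`` only ``W_slp``/``b_slp``
    move; encoder and decoder parameters are returned bit-identical.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    params = params.copy()
    rng = np.random.default_rng(config.seed + 1)
    optimizer = _Adam(config.learning_rate)
    ce_only = (0.0, config.loss_weights[1])
    slp_only = config.finetune_freezes_encoder
    for epoch in range(config.finetune_epochs):
        for batch in _epoch_batches(X.shape[0], config.batch_size, rng):
            grads = _gradients(params, X[batch], y[batch], ce_only, slp_only=slp_only)
            params = _apply(params, optimizer.step(_param_dict(params), grads))
        loss = joint_loss(params, X, y, ce_only)
        if not np.isfinite(loss):
            raise FloatingPointError(f"fine-tuning diverged at epoch {epoch + 1}")
    return params
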
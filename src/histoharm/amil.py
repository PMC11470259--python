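"""Attention-based multiple-instance-learning classifier over patch bags.

Architecture: per patch, an affine D->embed_dim map with ReLU gives h_k; a
two-layer attention module scores a_k = softmax_k(w^T tanh(V h_k)); the bag
embedding is h_sum = sum_k a_k h_k.  Bags in a mini-batch are pooled
independently; the batch of h_sum vectors passes through batch normalization,
dropout, and an affine map to class probabilities.  Training minimizes
cross-entropy weighted inversely to class frequency, with a one-cycle cosine
learning-rate schedule, Adam updates, and early stopping on validation loss.

Implemented directly on NumPy with hand-derived gradients so the package has
no deep-learning framework dependency; all randomness flows from one seeded
generator, so training is bit-reproducible on one machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bags import Cohort, PatchBag

__all__ = ["AMILConfig", "AMILModel", "attention_scores", "pool", "forward",
           "train_amil", "predict_proba"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class AMILConfig:
    input_dim: int
    n_classes: int = 2
    embed_dim: int = 256
    attn_dim: int = 128
    dropout: float = 0.5
    k_patches: int = 512        # max patches sampled per bag per epoch
    batch_size: int = 64        # bags per mini-batch
    max_epochs: int = 64
    patience: int = 16
    max_lr: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.embed_dim, self.attn_dim, self.k_patches,
               self.batch_size, self.max_epochs) < 1 or self.n_classes < 2:
            raise ValueError("all dimensions must be >= 1 and n_classes >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class AMILModel:
    config: AMILConfig
    classes: list[str]
    params: dict[str, np.ndarray]
    bn_mean: np.ndarray
    bn_var: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def _init_params(cfg: AMILConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Fan-based (Kaiming-uniform style) initialization, seeded."""
    def affine(fan_in, fan_out):
        bound = 1.0 / math.sqrt(fan_in)
        return (rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                rng.uniform(-bound, bound, size=fan_out))

    W1, b1 = affine(cfg.input_dim, cfg.embed_dim)
    V, _ = affine(cfg.embed_dim, cfg.attn_dim)
    w = rng.uniform(-1.0 / math.sqrt(cfg.attn_dim), 1.0 / math.sqrt(cfg.attn_dim),
                    size=cfg.attn_dim)
    W2, b2 = affine(cfg.embed_dim, cfg.n_classes)
    return {
        "W1": W1, "b1": b1,
        "V": V.T,            # stored attn_dim x embed_dim, as in the math
        "w": w,
        "bn_gamma": np.ones(cfg.embed_dim),
        "bn_beta": np.zeros(cfg.embed_dim),
        "W2": W2, "b2": b2,
    }


def attention_scores(H: np.ndarray, V: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Softmax attention a_k over patches, computed with log-sum-exp stability."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a K x embed_dim matrix with K >= 1")
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite patch embeddings")
    s = np.tanh(H @ V.T) @ w
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def pool(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of patch embeddings: h_sum = sum_k a_k h_k."""
    H = np.asarray(H, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).ravel()
    if a.shape[0] != H.shape[0]:
        raise ValueError("attention vector length must match patch count")
    if abs(a.sum() - 1.0) > 1e-8:
        raise ValueError("attention weights must sum to 1")
    return a @ H


def _bag_embed(X: np.ndarray, params: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward through embed + attention; returns (H, T, a, h_sum)."""
    H = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    T = np.tanh(H @ params["V"].T)
    s = T @ params["w"]
    s = s - s.max()
    e = np.exp(s)
    a = e / e.sum()
    return H, T, a, a @ H


def _head(S: np.ndarray, params: dict, bn_mean: np.ndarray, bn_var: np.ndarray) -> np.ndarray:
    """Eval-mode head: batchnorm with running stats, no dropout, softmax."""
    Sn = (S - bn_mean) / np.sqrt(bn_var + _BN_EPS)
    logits = (params["bn_gamma"] * Sn + params["bn_beta"]) @ params["W2"] + params["b2"]
    logits = logits - logits.max(axis=1, keepdims=True)
    E = np.exp(logits)
    return E / E.sum(axis=1, keepdims=True)


def forward(
    bag: PatchBag | np.ndarray,
    model: AMILModel,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities for one bag.

    Train mode subsamples min(P, K) patches without replacement from ``rng``;
    eval mode uses every patch, running normalization statistics, and no
    dropout, so it is deterministic and permutation invariant.
    """
    X = bag.features if isinstance(bag, PatchBag) else np.asarray(bag, dtype=np.float64)
    if X.shape[0] < 1:
        raise ValueError("empty bag")
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"bag has {X.shape[1]} features, model expects {model.config.input_dim}"
        )
    if mode == "train":
        if rng is None:
            raise ValueError("train mode needs an rng for patch subsampling")
        K = model.config.k_patches
        if X.shape[0] > K:
            X = X[rng.choice(X.shape[0], size=K, replace=False)]
    _, _, _, h = _bag_embed(X, model.params)
    return _head(h[None, :], model.params, model.bn_mean, model.bn_var)[0]


def predict_proba(model: AMILModel, cohort: Cohort) -> np.ndarray:
    """Eval-mode probabilities, one row per bag; rows sum to 1."""
    S = np.vstack([_bag_embed(b.features, model.params)[3] for b in cohort.bags])
    return _head(S, model.params, model.bn_mean, model.bn_var)


def _class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(y, minlength=n_classes).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("a class is absent from the training split")
    return counts.sum() / (n_classes * counts)


def _one_cycle_lr(step: int, total: int, max_lr: float,
                  pct_start: float = 0.3, div: float = 25.0,
                  final_div: float = 1e4) -> float:
    """One-cycle schedule: cosine ramp to max_lr, cosine anneal to ~0."""
    lo = max_lr / div
    end = max_lr / final_div
    up = max(1, int(total * pct_start))
    if step < up:
        t = step / up
        return lo + (max_lr - lo) * 0.5 * (1.0 - math.cos(math.pi * t))
    t = (step - up) / max(1, total - up)
    return end + (max_lr - end) * 0.5 * (1.0 + math.cos(math.pi * t))


def _weighted_ce(probs: np.ndarray, y: np.ndarray, wgt: np.ndarray) -> float:
    sw = wgt[y]
    nll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-300, None))
    return float((sw * nll).sum() / sw.sum())


def _eval_loss(model: AMILModel, bags: list[PatchBag], y: np.ndarray,
               wgt: np.ndarray) -> float:
    S = np.vstack([_bag_embed(b.features, model.params)[3] for b in bags])
    probs = _head(S, model.params, model.bn_mean, model.bn_var)
    return _weighted_ce(probs, y, wgt)


def train_amil(
    cohort: Cohort,
    target: str,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: AMILConfig,
) -> AMILModel:
    """Fit an A-MIL classifier on the given split.

    Early stopping monitors validation loss with the configured patience and
    the returned parameters are those of the best-validation-loss epoch.
    """
    labels = cohort.labels(target)
    classes = sorted({str(v) for v in labels[np.asarray(train_idx)]})
    if len(classes) < 2:
        raise ValueError("training split must contain >= 2 classes")
    cls_index = {c: k for k, c in enumerate(classes)}
    if config.n_classes != len(classes):
        config = AMILConfig(**{**config.__dict__, "n_classes": len(classes)})

    def encode(idx):
        out = []
        for i in idx:
            c = str(labels[i])
            if c not in cls_index:
                raise ValueError(f"label {c!r} absent from training split")
            out.append(cls_index[c])
        return np.array(out, dtype=np.int64)

    train_idx = np.asarray(train_idx, dtype=np.int64)
    val_idx = np.asarray(val_idx, dtype=np.int64)
    y_tr = encode(train_idx)
    y_va = encode(val_idx)
    bags_tr = [cohort.bags[i] for i in train_idx]
    bags_va = [cohort.bags[i] for i in val_idx]
    wgt = _class_weights(y_tr, len(classes))

    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    model = AMILModel(
        config=config, classes=classes, params=params,
        bn_mean=np.zeros(config.embed_dim), bn_var=np.ones(config.embed_dim),
        history={"train_loss": [], "val_loss": [], "lr": []},
    )
    mom1 = {k: np.zeros_like(v) for k, v in params.items()}
    mom2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    adam_t = 0

    n_tr = len(bags_tr)
    steps_per_epoch = math.ceil(n_tr / config.batch_size)
    total_steps = steps_per_epoch * config.max_epochs

    best_loss = np.inf
    best_params = model.copy_params()
    best_stats = (model.bn_mean.copy(), model.bn_var.copy())
    best_epoch = -1
    stall = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for s0 in range(0, n_tr, config.batch_size):
            mb = order[s0:s0 + config.batch_size]
            step = epoch * steps_per_epoch + s0 // config.batch_size
            lr = _one_cycle_lr(step, total_steps, config.max_lr)
            grads, loss = _step(model, [bags_tr[i] for i in mb], y_tr[mb], wgt, rng)
            epoch_loss += loss * len(mb)
            adam_t += 1
            for k, g in grads.items():
                mom1[k] = beta1 * mom1[k] + (1 - beta1) * g
                mom2[k] = beta2 * mom2[k] + (1 - beta2) * g * g
                mh = mom1[k] / (1 - beta1 ** adam_t)
                vh = mom2[k] / (1 - beta2 ** adam_t)
                params[k] -= lr * mh / (np.sqrt(vh) + adam_eps)
            model.history["lr"].append(lr)
        model.history["train_loss"].append(epoch_loss / n_tr)

        val_loss = _eval_loss(model, bags_va, y_va, wgt)
        model.history["val_loss"].append(val_loss)
        if not math.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = model.copy_params()
            best_stats = (model.bn_mean.copy(), model.bn_var.copy())
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    model.params = best_params
    model.bn_mean, model.bn_var = best_stats
    model.best_epoch = best_epoch
    return model


def _step(model: AMILModel, bags: list[PatchBag], y: np.ndarray,
          wgt: np.ndarray, rng: np.random.Generator) -> tuple[dict, float]:
    """One forward/backward pass over a mini-batch of bags."""
    cfg = model.config
    p = model.params
    caches = []
    S = np.empty((len(bags), cfg.embed_dim))
    for b_i, bag in enumerate(bags):
        X = bag.features
        if X.shape[0] > cfg.k_patches:
            X = X[rng.choice(X.shape[0], size=cfg.k_patches, replace=False)]
        H, T, a, h = _bag_embed(X, p)
        caches.append((X, H, T, a))
        S[b_i] = h

    B = len(bags)
    mu = S.mean(axis=0)
    var = S.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    Sn = (S - mu) * inv_std
    model.bn_mean = (1 - _BN_MOMENTUM) * model.bn_mean + _BN_MOMENTUM * mu
    unbiased = var * B / max(B - 1, 1)
    model.bn_var = (1 - _BN_MOMENTUM) * model.bn_var + _BN_MOMENTUM * unbiased

    out = p["bn_gamma"] * Sn + p["bn_beta"]
    if cfg.dropout > 0.0:
        M = (rng.random(out.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
    else:
        M = np.ones_like(out)
    out_d = out * M
    logits = out_d @ p["W2"] + p["b2"]
    logits -= logits.max(axis=1, keepdims=True)
    E = np.exp(logits)
    probs = E / E.sum(axis=1, keepdims=True)
    loss = _weighted_ce(probs, y, wgt)

    sw = wgt[y] / wgt[y].sum()
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= sw[:, None]

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    grads["W2"] = out_d.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dout_d = dlogits @ p["W2"].T
    dout = dout_d * M
    grads["bn_gamma"] = (dout * Sn).sum(axis=0)
    grads["bn_beta"] = dout.sum(axis=0)
    dSn = dout * p["bn_gamma"]
    dS = (inv_std / B) * (B * dSn - dSn.sum(axis=0) - Sn * (dSn * Sn).sum(axis=0))

    for b_i, (X, H, T, a) in enumerate(caches):
        dh = dS[b_i]
        dH = np.outer(a, dh)
        da = H @ dh
        ds = a * (da - float(a @ da))
        grads["w"] += T.T @ ds
        dT = np.outer(ds, p["w"])
        dZ = dT * (1.0 - T * T)
        grads["V"] += dZ.T @ H
        dH += dZ @ p["V"]
        dpre = dH * (H > 0.0)
        grads["W1"] += X.T @ dpre
        grads["b1"] += dpre.sum(axis=0)
    return grads, loss
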
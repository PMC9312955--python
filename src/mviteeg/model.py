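"""Multi-channel vision transformer (MViT) for scalogram classification.

One transformer-encoder branch per EEG channel: each channel's scalogram
image is split into non-overlapping patches, linearly projected to the latent
dimension, given learned position embeddings, and passed through a stack of
pre-norm encoder blocks

    u   = tokens + MSA(LN(tokens))
    out = u + MLP(LN(u)),        MLP = linear -> GELU -> linear.

Each branch's output tokens are mean-pooled into a single feature vector; the
N branch features are concatenated in channel order and an MLP head with a
softmax produces the preictal/interictal probability pair.  There is no class
token.

The forward and backward passes are written directly in NumPy (float64), so
gradients are exact and checkable against finite differences.  Dropout (when
training) is inverted dropout applied to the attention and MLP residual
contributions and to the head's hidden activation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .errors import ConfigError, DataError

# ---------------------------------------------------------------------------
# configuration & parameters

_LN_EPS = 1e-5


@dataclass(frozen=True)
class MViTConfig:
    """Architecture hyperparameters for the N-branch transformer."""

    n_branches: int
    image_hw: tuple[int, int] = (64, 256)
    patch_hw: tuple[int, int] = (8, 8)
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_hidden: int = 128
    dropout: float = 0.1
    n_classes: int = 2
    share_branch_weights: bool = False
    pool: str = "mean"

    def __post_init__(self) -> None:
        h, w = self.image_hw
        ph, pw = self.patch_hw
        if self.n_branches < 1:
            raise ConfigError("n_branches must be >= 1")
        if h % ph != 0 or w % pw != 0:
            raise ConfigError(
                f"patch {ph}x{pw} must divide image {h}x{w} exactly"
            )
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.n_tokens < 1:
            raise ConfigError("config yields zero tokens")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0,1), got {self.dropout}")
        if self.pool != "mean":
            raise ConfigError(f"unsupported pooling {self.pool!r}")

    @property
    def n_tokens(self) -> int:
        """L = H*W / (P_h*P_w), tokens per branch."""
        h, w = self.image_hw
        ph, pw = self.patch_hw
        return (h * w) // (ph * pw)

    @property
    def patch_dim(self) -> int:
        return self.patch_hw[0] * self.patch_hw[1]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MViTConfig":
        d = json.loads(s)
        d["image_hw"] = tuple(d["image_hw"])
        d["patch_hw"] = tuple(d["patch_hw"])
        return cls(**d)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at 2 std by resampling."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while np.any(bad):
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def _branch_prefixes(cfg: MViTConfig) -> list[str]:
    if cfg.share_branch_weights:
        return ["b0"] * cfg.n_branches
    return [f"b{b}" for b in range(cfg.n_branches)]


def init_params(cfg: MViTConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded parameter initialisation: truncated-normal (sigma 0.02)
    projections and position embeddings, zero biases/LN offsets, unit LN
    gains."""
    rng = np.random.default_rng(seed)
    D, L, P = cfg.embed_dim, cfg.n_tokens, cfg.patch_dim
    params: dict[str, np.ndarray] = {}
    for pre in dict.fromkeys(_branch_prefixes(cfg)):
        params[f"{pre}.patch_W"] = _trunc_normal(rng, (P, D))
        params[f"{pre}.patch_b"] = np.zeros(D)
        params[f"{pre}.pos"] = _trunc_normal(rng, (L, D))
        for l in range(cfg.depth):
            lp = f"{pre}.l{l}"
            params[f"{lp}.ln1_g"] = np.ones(D)
            params[f"{lp}.ln1_b"] = np.zeros(D)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                params[f"{lp}.{name}"] = _trunc_normal(rng, (D, D))
            for name in ("bq", "bk", "bv", "bo"):
                params[f"{lp}.{name}"] = np.zeros(D)
            params[f"{lp}.ln2_g"] = np.ones(D)
            params[f"{lp}.ln2_b"] = np.zeros(D)
            params[f"{lp}.W1"] = _trunc_normal(rng, (D, cfg.mlp_hidden))
            params[f"{lp}.b1"] = np.zeros(cfg.mlp_hidden)
            params[f"{lp}.W2"] = _trunc_normal(rng, (cfg.mlp_hidden, D))
            params[f"{lp}.b2"] = np.zeros(D)
    params["head.W1"] = _trunc_normal(rng, (cfg.n_branches * D, cfg.mlp_hidden))
    params["head.b1"] = np.zeros(cfg.mlp_hidden)
    params["head.W2"] = _trunc_normal(rng, (cfg.mlp_hidden, cfg.n_classes))
    params["head.b2"] = np.zeros(cfg.n_classes)
    return params


# ---------------------------------------------------------------------------
# primitives (forward + backward)


def patchify(image: np.ndarray, patch_hw: tuple[int, int]) -> np.ndarray:
    """Split an H x W image into L x (P_h*P_w) flattened patches.

    Patches are enumerated row-major over the patch grid; each patch is
    flattened row-major.  Lossless: :func:`unpatchify` inverts it."""
    H, W = image.shape[-2:]
    ph, pw = patch_hw
    if H % ph != 0 or W % pw != 0:
        raise ConfigError(f"patch {ph}x{pw} does not divide image {H}x{W}")
    lead = image.shape[:-2]
    x = image.reshape(*lead, H // ph, ph, W // pw, pw)
    x = np.moveaxis(x, -3, -2)  # (..., H/ph, W/pw, ph, pw)
    return x.reshape(*lead, (H // ph) * (W // pw), ph * pw)


def unpatchify(patches: np.ndarray, image_hw: tuple[int, int], patch_hw: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    H, W = image_hw
    ph, pw = patch_hw
    lead = patches.shape[:-2]
    x = patches.reshape(*lead, H // ph, W // pw, ph, pw)
    x = np.moveaxis(x, -3, -2)
    return x.reshape(*lead, H, W)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return cdf + x * pdf


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _ln_fwd(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    B, L, D = x.shape
    return x.reshape(B, L, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, h, L, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)


def _as_batched(tokens: np.ndarray) -> np.ndarray:
    tokens = np.asarray(tokens, dtype=np.float64)
    return tokens[None] if tokens.ndim == 2 else tokens


def msa(tokens: np.ndarray, p: dict[str, np.ndarray], prefix: str, n_heads: int) -> np.ndarray:
    """Multi-head scaled dot-product self-attention (inference path)."""
    out, _ = _msa_fwd(_as_batched(tokens), p, prefix, n_heads)
    return out if np.asarray(tokens).ndim == 3 else out[0]


def attention_weights(tokens: np.ndarray, p: dict[str, np.ndarray], prefix: str, n_heads: int) -> np.ndarray:
    """Attention probability tensor (B, heads, L, L); rows sum to one."""
    A = _as_batched(tokens)
    q = _split_heads(A @ p[f"{prefix}.Wq"] + p[f"{prefix}.bq"], n_heads)
    k = _split_heads(A @ p[f"{prefix}.Wk"] + p[f"{prefix}.bk"], n_heads)
    scale = 1.0 / math.sqrt(q.shape[-1])
    return _softmax(scale * (q @ k.transpose(0, 1, 3, 2)))


def _msa_fwd(A: np.ndarray, p: dict, prefix: str, n_heads: int):
    q = _split_heads(A @ p[f"{prefix}.Wq"] + p[f"{prefix}.bq"], n_heads)
    k = _split_heads(A @ p[f"{prefix}.Wk"] + p[f"{prefix}.bk"], n_heads)
    v = _split_heads(A @ p[f"{prefix}.Wv"] + p[f"{prefix}.bv"], n_heads)
    scale = 1.0 / math.sqrt(q.shape[-1])
    S = scale * (q @ k.transpose(0, 1, 3, 2))
    P = _softmax(S)
    O = _merge_heads(P @ v)
    out = O @ p[f"{prefix}.Wo"] + p[f"{prefix}.bo"]
    if not np.all(np.isfinite(out)):
        raise DataError("non-finite values in attention output")
    return out, (A, q, k, v, P, O, scale, prefix, n_heads)


def _msa_bwd(dout: np.ndarray, p: dict, cache, grads: dict):
    A, q, k, v, P, O, scale, prefix, n_heads = cache
    B, L, D = A.shape
    _acc(grads, f"{prefix}.Wo", _mm2(O, dout))
    _acc(grads, f"{prefix}.bo", dout.sum(axis=(0, 1)))
    dO = _split_heads(dout @ p[f"{prefix}.Wo"].T, n_heads)
    dP = dO @ v.transpose(0, 1, 3, 2)
    dv = P.transpose(0, 1, 3, 2) @ dO
    dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
    dq = scale * (dS @ k)
    dk = scale * (dS.transpose(0, 1, 3, 2) @ q)
    dq, dk, dv = _merge_heads(dq), _merge_heads(dk), _merge_heads(dv)
    _acc(grads, f"{prefix}.Wq", _mm2(A, dq))
    _acc(grads, f"{prefix}.bq", dq.sum(axis=(0, 1)))
    _acc(grads, f"{prefix}.Wk", _mm2(A, dk))
    _acc(grads, f"{prefix}.bk", dk.sum(axis=(0, 1)))
    _acc(grads, f"{prefix}.Wv", _mm2(A, dv))
    _acc(grads, f"{prefix}.bv", dv.sum(axis=(0, 1)))
    return dq @ p[f"{prefix}.Wq"].T + dk @ p[f"{prefix}.Wk"].T + dv @ p[f"{prefix}.Wv"].T


def _mm2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(B,L,M)^T x (B,L,N) contracted over batch and tokens -> (M,N)."""
    return np.tensordot(a, b, axes=([0, 1], [0, 1]))


def _acc(grads: dict, key: str, val: np.ndarray) -> None:
    if key in grads:
        grads[key] = grads[key] + val
    else:
        grads[key] = val


def _dropout_mask(rng, shape, rate: float):
    if rng is None or rate <= 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _apply(x, mask):
    return x if mask is None else x * mask


def encoder_block(
    tokens: np.ndarray, p: dict[str, np.ndarray], prefix: str, n_heads: int
) -> np.ndarray:
    """Pre-norm encoder block (inference): residual MSA then residual MLP."""
    out, _ = _block_fwd(_as_batched(tokens), p, prefix, n_heads, None, 0.0)
    return out if np.asarray(tokens).ndim == 3 else out[0]


def _block_fwd(T: np.ndarray, p: dict, prefix: str, n_heads: int, rng, rate: float):
    A, ln1c = _ln_fwd(T, p[f"{prefix}.ln1_g"], p[f"{prefix}.ln1_b"])
    M, msac = _msa_fwd(A, p, prefix, n_heads)
    m_mask = _dropout_mask(rng, M.shape, rate)
    U = T + _apply(M, m_mask)
    A2, ln2c = _ln_fwd(U, p[f"{prefix}.ln2_g"], p[f"{prefix}.ln2_b"])
    Z1 = A2 @ p[f"{prefix}.W1"] + p[f"{prefix}.b1"]
    G = _gelu(Z1)
    F = G @ p[f"{prefix}.W2"] + p[f"{prefix}.b2"]
    f_mask = _dropout_mask(rng, F.shape, rate)
    out = U + _apply(F, f_mask)
    return out, (prefix, ln1c, msac, m_mask, A2, ln2c, Z1, G, f_mask)


def _block_bwd(dout: np.ndarray, p: dict, cache, grads: dict):
    prefix, ln1c, msac, m_mask, A2, ln2c, Z1, G, f_mask = cache
    dU = dout.copy()
    dF = _apply(dout, f_mask)
    _acc(grads, f"{prefix}.W2", _mm2(G, dF))
    _acc(grads, f"{prefix}.b2", dF.sum(axis=(0, 1)))
    dG = dF @ p[f"{prefix}.W2"].T
    dZ1 = dG * _gelu_grad(Z1)
    _acc(grads, f"{prefix}.W1", _mm2(A2, dZ1))
    _acc(grads, f"{prefix}.b1", dZ1.sum(axis=(0, 1)))
    dA2 = dZ1 @ p[f"{prefix}.W1"].T
    dU2, dg2, db2 = _ln_bwd(dA2, ln2c)
    _acc(grads, f"{prefix}.ln2_g", dg2)
    _acc(grads, f"{prefix}.ln2_b", db2)
    dU = dU + dU2
    dT = dU.copy()
    dM = _apply(dU, m_mask)
    dA = _msa_bwd(dM, p, msac, grads)
    dT1, dg1, db1 = _ln_bwd(dA, ln1c)
    _acc(grads, f"{prefix}.ln1_g", dg1)
    _acc(grads, f"{prefix}.ln1_b", db1)
    return dT + dT1


def embed_patches(
    patches: np.ndarray, p: dict[str, np.ndarray], cfg: MViTConfig, branch: int
) -> np.ndarray:
    """Linear patch projection plus the branch's position embeddings."""
    pre = _branch_prefixes(cfg)[branch]
    return patches @ p[f"{pre}.patch_W"] + p[f"{pre}.patch_b"] + p[f"{pre}.pos"]


# ---------------------------------------------------------------------------
# full model


def _check_images(images: np.ndarray, cfg: MViTConfig) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4:
        raise DataError(f"expected (batch, channels, H, W) images, got shape {images.shape}")
    B, N, H, W = images.shape
    if N != cfg.n_branches:
        raise DataError(f"{N} channel images for a {cfg.n_branches}-branch model")
    if (H, W) != cfg.image_hw:
        raise DataError(f"image shape {(H, W)} != configured {cfg.image_hw}")
    return images


def _forward_full(images: np.ndarray, p: dict, cfg: MViTConfig, rng, rate: float):
    """Shared forward pass; returns probs and every cache needed for backward."""
    B, N = images.shape[:2]
    L = cfg.n_tokens
    prefixes = _branch_prefixes(cfg)
    feats = []
    branch_caches = []
    for b in range(N):
        pre = prefixes[b]
        X = patchify(images[:, b], cfg.patch_hw)  # (B, L, P)
        T = X @ p[f"{pre}.patch_W"] + p[f"{pre}.patch_b"] + p[f"{pre}.pos"]
        blocks = []
        for l in range(cfg.depth):
            T, cache = _block_fwd(T, p, f"{pre}.l{l}", cfg.n_heads, rng, rate)
            blocks.append(cache)
        feats.append(T.mean(axis=1))  # (B, D)
        branch_caches.append((pre, X, blocks))
    Z = np.concatenate(feats, axis=1)  # (B, N*D)
    H1 = Z @ p["head.W1"] + p["head.b1"]
    G = _gelu(H1)
    g_mask = _dropout_mask(rng, G.shape, rate)
    Gd = _apply(G, g_mask)
    logits = Gd @ p["head.W2"] + p["head.b2"]
    probs = _softmax(logits)
    return probs, (branch_caches, Z, H1, G, g_mask, Gd)


def forward(
    images: np.ndarray, params: dict[str, np.ndarray], cfg: MViTConfig
) -> np.ndarray:
    """Class probabilities for a batch of scalogram stacks (eval mode).

    images: (batch, N, H, W) or a single (N, H, W) stack.  Returns (batch,
    n_classes) softmax probabilities (or a single pair for a single stack)."""
    single = np.asarray(images).ndim == 3
    x = _check_images(images, cfg)
    probs, _ = _forward_full(x, params, cfg, None, 0.0)
    return probs[0] if single else probs


def branch_features(
    images: np.ndarray, params: dict[str, np.ndarray], cfg: MViTConfig
) -> np.ndarray:
    """Per-branch pooled features before aggregation, shape (batch, N, D)."""
    x = _check_images(images, cfg)
    prefixes = _branch_prefixes(cfg)
    feats = []
    for b in range(cfg.n_branches):
        pre = prefixes[b]
        X = patchify(x[:, b], cfg.patch_hw)
        T = X @ params[f"{pre}.patch_W"] + params[f"{pre}.patch_b"] + params[f"{pre}.pos"]
        for l in range(cfg.depth):
            T, _ = _block_fwd(T, params, f"{pre}.l{l}", cfg.n_heads, None, 0.0)
        feats.append(T.mean(axis=1))
    return np.stack(feats, axis=1)


def loss_and_grads(
    images: np.ndarray,
    labels: np.ndarray,
    params: dict[str, np.ndarray],
    cfg: MViTConfig,
    class_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Class-weighted cross-entropy and exact gradients for one batch.

    labels: (batch,) integer classes.  Passing an rng enables dropout
    (training mode); omit it for deterministic eval-mode gradients.
    Returns (loss, grads keyed like params, probs)."""
    x = _check_images(images, cfg)
    labels = np.asarray(labels, dtype=int)
    B = x.shape[0]
    w = np.ones(cfg.n_classes) if class_weights is None else np.asarray(class_weights, float)
    rate = cfg.dropout if rng is not None else 0.0
    probs, cache = _forward_full(x, params, cfg, rng, rate)
    branch_caches, Z, H1, G, g_mask, Gd = cache
    wi = w[labels]
    wsum = wi.sum()
    # log-softmax recomputed from probs is ill-conditioned when saturated;
    # use log(p) guarded only by the float floor so grad = (p - onehot) exactly
    logp = np.log(np.maximum(probs[np.arange(B), labels], np.finfo(float).tiny))
    loss = float(-(wi * logp).sum() / wsum)
    if not np.isfinite(loss):
        raise DataError("non-finite training loss")

    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    dlogits = (wi[:, None] * (probs - onehot)) / wsum

    grads: dict[str, np.ndarray] = {}
    grads["head.W2"] = Gd.T @ dlogits
    grads["head.b2"] = dlogits.sum(axis=0)
    dGd = dlogits @ params["head.W2"].T
    dG = _apply(dGd, g_mask)
    dH1 = dG * _gelu_grad(H1)
    grads["head.W1"] = Z.T @ dH1
    grads["head.b1"] = dH1.sum(axis=0)
    dZ = dH1 @ params["head.W1"].T

    D = cfg.embed_dim
    L = cfg.n_tokens
    for b, (pre, X, blocks) in enumerate(branch_caches):
        dfeat = dZ[:, b * D : (b + 1) * D]
        dT = np.repeat(dfeat[:, None, :], L, axis=1) / L
        for block_cache in reversed(blocks):
            dT = _block_bwd(dT, params, block_cache, grads)
        _acc(grads, f"{pre}.pos", dT.sum(axis=0))
        _acc(grads, f"{pre}.patch_W", _mm2(X, dT))
        _acc(grads, f"{pre}.patch_b", dT.sum(axis=(0, 1)))
    # parameters untouched by this batch (shouldn't happen) get zero grads
    for k, v in params.items():
        if k not in grads:
            grads[k] = np.zeros_like(v)
    return loss, grads, probs


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, params: dict[str, np.ndarray], cfg: MViTConfig) -> Path:
    """Array archive of the parameters with the config embedded as JSON."""
    path = Path(path)
    arrays = {k.replace(".", "__"): v for k, v in params.items()}
    arrays["__config_json__"] = np.frombuffer(cfg.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], MViTConfig]:
    path = Path(path)
    with np.load(path) as npz:
        cfg = MViTConfig.from_json(bytes(npz["__config_json__"]).decode())
        params = {
            k.replace("__", "."): npz[k] for k in npz.files if k != "__config_json__"
        }
    return params, cfg
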
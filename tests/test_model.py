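"""Transformer correctness: patching, attention, encoder blocks, the full
forward pass, and exact gradients — each against an independent brute-force
oracle where one exists."""

import math

import numpy as np
import pytest

from mviteeg.errors import ConfigError, DataError
from mviteeg.model import (
    MViTConfig,
    attention_weights,
    branch_features,
    embed_patches,
    encoder_block,
    forward,
    init_params,
    load_checkpoint,
    loss_and_grads,
    msa,
    patchify,
    save_checkpoint,
    unpatchify,
)

RNG = np.random.default_rng(1234)


def _layer_params(D, hidden, prefix="b0.l0", scale=1.0, seed=0):
    rng = np.random.default_rng(seed)
    p = {
        f"{prefix}.ln1_g": np.ones(D),
        f"{prefix}.ln1_b": np.zeros(D),
        f"{prefix}.ln2_g": np.ones(D),
        f"{prefix}.ln2_b": np.zeros(D),
    }
    for n in ("Wq", "Wk", "Wv", "Wo"):
        p[f"{prefix}.{n}"] = rng.normal(scale=scale, size=(D, D))
    for n in ("bq", "bk", "bv", "bo"):
        p[f"{prefix}.{n}"] = rng.normal(scale=scale, size=D)
    p[f"{prefix}.W1"] = rng.normal(scale=scale, size=(D, hidden))
    p[f"{prefix}.b1"] = rng.normal(scale=scale, size=hidden)
    p[f"{prefix}.W2"] = rng.normal(scale=scale, size=(hidden, D))
    p[f"{prefix}.b2"] = rng.normal(scale=scale, size=D)
    return p


# ---------------------------------------------------------------------------
# patchify


def test_patchify_full_image_single_patch():
    img = RNG.normal(size=(3, 4))
    out = patchify(img, (3, 4))
    assert out.shape == (1, 12)
    assert np.array_equal(out[0], img.ravel())


def test_patchify_matches_bruteforce_windows():
    img = RNG.normal(size=(6, 4))
    out = patchify(img, (2, 2))
    assert out.shape == (6, 4)
    k = 0
    for bi in range(3):
        for bj in range(2):
            window = img[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
            assert np.array_equal(out[k], window.ravel())
            k += 1


def test_patchify_roundtrip_and_divisibility():
    img = RNG.normal(size=(8, 12))
    assert np.array_equal(unpatchify(patchify(img, (4, 3)), (8, 12), (4, 3)), img)
    with pytest.raises(ConfigError):
        patchify(img, (3, 3))


# ---------------------------------------------------------------------------
# embedding


def test_embed_zero_projection_returns_position_embeddings():
    cfg = MViTConfig(n_branches=1, image_hw=(4, 4), patch_hw=(2, 2), embed_dim=6,
                     depth=1, n_heads=2, mlp_hidden=8)
    p = init_params(cfg, seed=0)
    p["b0.patch_W"][:] = 0.0
    p["b0.patch_b"][:] = 0.0
    patches = RNG.normal(size=(cfg.n_tokens, cfg.patch_dim))
    tokens = embed_patches(patches, p, cfg, branch=0)
    assert np.array_equal(tokens, p["b0.pos"])


def test_embed_permutation_equivariant_without_positions():
    cfg = MViTConfig(n_branches=1, image_hw=(4, 4), patch_hw=(2, 2), embed_dim=6,
                     depth=1, n_heads=2, mlp_hidden=8)
    p = init_params(cfg, seed=0)
    p["b0.pos"][:] = 0.0
    patches = RNG.normal(size=(cfg.n_tokens, cfg.patch_dim))
    perm = np.array([2, 0, 3, 1])
    t = embed_patches(patches, p, cfg, branch=0)
    tp = embed_patches(patches[perm], p, cfg, branch=0)
    assert np.allclose(tp, t[perm])


def test_embed_identity_projection():
    cfg = MViTConfig(n_branches=1, image_hw=(1, 2), patch_hw=(1, 2), embed_dim=2,
                     depth=1, n_heads=1, mlp_hidden=4)
    p = init_params(cfg, seed=0)
    p["b0.patch_W"] = np.eye(2)
    p["b0.patch_b"][:] = 0.0
    p["b0.pos"][:] = 0.0
    tokens = embed_patches(np.array([[1.0, 2.0]]), p, cfg, branch=0)
    assert np.array_equal(tokens, [[1.0, 2.0]])


# ---------------------------------------------------------------------------
# attention


def test_msa_single_token_is_projection_of_value():
    D = 4
    p = _layer_params(D, 8, scale=0.7, seed=2)
    tok = RNG.normal(size=(1, D))
    out = msa(tok, p, "b0.l0", n_heads=2)
    v = tok @ p["b0.l0.Wv"] + p["b0.l0.bv"]
    expected = v @ p["b0.l0.Wo"] + p["b0.l0.bo"]
    assert np.allclose(out, expected, atol=1e-12)


def test_attention_rows_sum_to_one():
    D, L = 6, 5
    p = _layer_params(D, 8, scale=1.3, seed=3)
    tok = RNG.normal(size=(2, L, D))
    w = attention_weights(tok, p, "b0.l0", n_heads=3)
    assert w.shape == (2, 3, L, L)
    assert np.allclose(w.sum(axis=-1), 1.0)


def test_msa_matches_loop_level_oracle():
    """Explicit loops over queries/keys/heads reproduce the vectorised MSA."""
    L, D, heads = 3, 2, 1
    p = _layer_params(D, 4, scale=1.0, seed=4)
    for n in ("bq", "bk", "bv", "bo"):  # keep the oracle simple but non-trivial
        p[f"b0.l0.{n}"] = np.array([0.5, -0.25])
    tok = np.array([[1.0, 2.0], [-1.0, 0.5], [0.0, 1.0]])
    out = msa(tok, p, "b0.l0", n_heads=heads)

    q = tok @ p["b0.l0.Wq"] + p["b0.l0.bq"]
    k = tok @ p["b0.l0.Wk"] + p["b0.l0.bk"]
    v = tok @ p["b0.l0.Wv"] + p["b0.l0.bv"]
    dh = D // heads
    oracle = np.zeros((L, D))
    for i in range(L):
        scores = np.array([np.dot(q[i], k[j]) / math.sqrt(dh) for j in range(L)])
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        ctx = sum(a[j] * v[j] for j in range(L))
        oracle[i] = ctx @ p["b0.l0.Wo"] + p["b0.l0.bo"]
    assert np.allclose(out, oracle, atol=1e-6)


# ---------------------------------------------------------------------------
# encoder block


def test_block_zero_weights_is_identity():
    D = 4
    p = _layer_params(D, 8, scale=0.9, seed=5)
    p["b0.l0.Wo"][:] = 0.0
    p["b0.l0.bo"][:] = 0.0
    p["b0.l0.W2"][:] = 0.0
    p["b0.l0.b2"][:] = 0.0
    tok = RNG.normal(size=(5, D))
    out = encoder_block(tok, p, "b0.l0", n_heads=2)
    assert np.array_equal(out, tok)


def test_block_preserves_shape():
    D = 6
    p = _layer_params(D, 10, scale=0.5, seed=6)
    tok = RNG.normal(size=(4, 7, D))
    assert encoder_block(tok, p, "b0.l0", n_heads=2).shape == (4, 7, D)


def test_block_matches_stepwise_oracle():
    """LN -> attention -> residual -> LN -> MLP -> residual, computed by hand."""
    L, D = 2, 2
    p = _layer_params(D, 3, scale=1.0, seed=7)
    tok = np.array([[0.5, -1.0], [2.0, 0.25]])
    out = encoder_block(tok, p, "b0.l0", n_heads=1)

    def ln(x, g, b):
        mu, var = x.mean(-1, keepdims=True), x.var(-1, keepdims=True)
        return g * (x - mu) / np.sqrt(var + 1e-5) + b

    def gelu(x):
        from scipy.special import erf

        return 0.5 * x * (1 + erf(x / math.sqrt(2)))

    A = ln(tok, p["b0.l0.ln1_g"], p["b0.l0.ln1_b"])
    q = A @ p["b0.l0.Wq"] + p["b0.l0.bq"]
    k = A @ p["b0.l0.Wk"] + p["b0.l0.bk"]
    v = A @ p["b0.l0.Wv"] + p["b0.l0.bv"]
    att = np.zeros_like(A)
    for i in range(L):
        s = np.array([q[i] @ k[j] / math.sqrt(D) for j in range(L)])
        e = np.exp(s - s.max())
        att[i] = (e / e.sum()) @ v
    u = tok + (att @ p["b0.l0.Wo"] + p["b0.l0.bo"])
    A2 = ln(u, p["b0.l0.ln2_g"], p["b0.l0.ln2_b"])
    f = gelu(A2 @ p["b0.l0.W1"] + p["b0.l0.b1"]) @ p["b0.l0.W2"] + p["b0.l0.b2"]
    oracle = u + f
    assert np.allclose(out, oracle, atol=1e-6)


# ---------------------------------------------------------------------------
# full model


def _tiny_cfg(n_branches=2, share=False):
    return MViTConfig(n_branches=n_branches, image_hw=(4, 4), patch_hw=(2, 2),
                      embed_dim=8, depth=2, n_heads=2, mlp_hidden=12,
                      dropout=0.0, share_branch_weights=share)


def test_forward_probabilities_sum_to_one():
    cfg = _tiny_cfg()
    p = init_params(cfg, seed=8)
    X = RNG.normal(size=(5, 2, 4, 4))
    probs = forward(X, p, cfg)
    assert probs.shape == (5, 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_branch_independence_pre_aggregation():
    cfg = _tiny_cfg()
    p = init_params(cfg, seed=9)
    X = RNG.normal(size=(3, 2, 4, 4))
    f0 = branch_features(X, p, cfg)
    X2 = X.copy()
    X2[:, 1] += RNG.normal(size=(3, 4, 4))
    f1 = branch_features(X2, p, cfg)
    assert np.array_equal(f0[:, 0], f1[:, 0])  # untouched branch bit-identical
    assert not np.allclose(f0[:, 1], f1[:, 1])


def test_single_branch_forward_matches_manual_composition():
    cfg = _tiny_cfg(n_branches=1)
    p = init_params(cfg, seed=10)
    img = RNG.normal(size=(1, 4, 4))
    probs = forward(img, p, cfg)

    T = embed_patches(patchify(img[0], cfg.patch_hw), p, cfg, branch=0)
    for l in range(cfg.depth):
        T = encoder_block(T, p, f"b0.l{l}", cfg.n_heads)
    feat = T.mean(axis=0)
    from scipy.special import erf

    h1 = feat @ p["head.W1"] + p["head.b1"]
    g = 0.5 * h1 * (1 + erf(h1 / math.sqrt(2)))
    logits = g @ p["head.W2"] + p["head.b2"]
    e = np.exp(logits - logits.max())
    assert np.allclose(probs, e / e.sum(), atol=1e-10)


def test_forward_deterministic_and_validates_shapes():
    cfg = _tiny_cfg()
    p = init_params(cfg, seed=11)
    X = RNG.normal(size=(2, 2, 4, 4))
    assert np.array_equal(forward(X, p, cfg), forward(X, p, cfg))
    with pytest.raises(DataError):
        forward(RNG.normal(size=(2, 3, 4, 4)), p, cfg)  # wrong channel count
    with pytest.raises(DataError):
        forward(RNG.normal(size=(2, 2, 8, 4)), p, cfg)  # wrong image shape


def test_token_count_law():
    cfg = MViTConfig(n_branches=1, image_hw=(64, 256), patch_hw=(8, 8),
                     embed_dim=8, depth=1, n_heads=1, mlp_hidden=8)
    assert cfg.n_tokens == 64 * 256 // 64 == 256
    with pytest.raises(ConfigError):
        MViTConfig(n_branches=1, image_hw=(10, 10), patch_hw=(3, 3),
                   embed_dim=8, depth=1, n_heads=1, mlp_hidden=8)


def test_shared_branch_weights_single_parameter_set():
    cfg = _tiny_cfg(share=True)
    p = init_params(cfg, seed=12)
    assert not any(k.startswith("b1.") for k in p)
    X = RNG.normal(size=(2, 2, 4, 4))
    # swapping the two (identically processed) channel images must not change
    # the per-branch features beyond reordering
    f = branch_features(X, p, cfg)
    fswap = branch_features(X[:, ::-1], p, cfg)
    assert np.allclose(f[:, ::-1], fswap)


def test_gradients_match_finite_differences():
    """Backprop agrees with central finite differences to 1e-4 relative on a
    tiny config (L=4, D_e=8)."""
    cfg = _tiny_cfg()
    p = init_params(cfg, seed=13)
    rng = np.random.default_rng(14)
    for k in p:  # O(1) weights so gradients are well-scaled
        p[k] = p[k] + rng.normal(scale=0.4, size=p[k].shape)
    X = rng.normal(size=(3, 2, 4, 4))
    y = np.array([0, 1, 1])
    w = np.array([1.0, 1.5])
    _, grads, _ = loss_and_grads(X, y, p, cfg, w)
    check_rng = np.random.default_rng(15)
    for k in sorted(p):
        flat = p[k].ravel()
        idxs = check_rng.choice(flat.size, size=min(3, flat.size), replace=False)
        for i in idxs:
            eps = 1e-5
            old = flat[i]
            flat[i] = old + eps
            lp, _, _ = loss_and_grads(X, y, p, cfg, w)
            flat[i] = old - eps
            lm, _, _ = loss_and_grads(X, y, p, cfg, w)
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            ga = grads[k].ravel()[i]
            assert abs(fd - ga) / max(1.0, abs(fd) + abs(ga)) < 1e-4, k


def test_checkpoint_roundtrip(tmp_path):
    cfg = _tiny_cfg()
    p = init_params(cfg, seed=16)
    path = save_checkpoint(tmp_path / "ckpt.npz", p, cfg)
    p2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    assert set(p2) == set(p)
    for k in p:
        assert np.array_equal(p2[k], p[k])
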
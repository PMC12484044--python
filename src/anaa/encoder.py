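"""A compact Transformer encoder with an attention-augmentation hook.

The encoder is a textbook multi-head self-attention stack (scaled-dot-product
attention, post-layer-norm residual blocks, ReLU feed-forward), sized for
desk-scale experiments, with two heads on top:

* a masked-language-model head (tied decoder) for self-supervised
  pre-training on code sequences, and
* a pooled sigmoid head for binary outcome fine-tuning (mean over valid
  positions by default, or the ``[CLS]`` position).

Attention augmentation (none / RNA / ANAA, or one of the baseline
augmentations) is applied to every head of every layer, after the softmax
and before the value product; it changes nothing else about the
computational graph, so the parameter count is identical across modes.

Everything runs in NumPy float64 with hand-written backpropagation (the
model is small enough that this is fast, and it keeps the whole pipeline
dependency-light and bit-reproducible).  The sampled attention noise is
treated as a constant in the backward pass; the smoothing convolution is
linear, so its gradient is the adjoint (offset-flipped) convolution.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .augmentation import (
    AttentionMatrix, AugmentationConfig, build_kernel, smooth_block,
)
from .baselines import BaselineConfig, apply_logit_mask_batch, noise_scale
from .tokenization import PAD, SEP

__all__ = ["EncoderConfig", "TransformerEncoder", "self_attention_head",
           "mlm_corrupt"]

_NEG = -1e30  # effective -inf for masked attention logits


def _es(*args, **kw):
    return np.einsum(*args, optimize=True, **kw)


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    d_model: int = 64
    n_heads: int = 4
    d_k: int = 16
    d_v: int = 16
    n_layers: int = 2
    d_ff: int = 256
    max_len: int = 256
    dropout: float = 0.0
    use_segment_embedding: bool = False
    max_visits: int = 512
    pooling: str = "mean"  # "mean" over valid positions, or "cls"

    def __post_init__(self) -> None:
        if self.d_model != self.n_heads * self.d_v:
            raise ValueError("d_model must equal n_heads * d_v")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pooling not in ("cls", "mean"):
            raise ValueError("pooling must be 'cls' or 'mean'")


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-6):
    mean = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = dxhat.mean(-1, keepdims=True)
    mx = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


class TransformerEncoder:
    """Multi-head self-attention encoder over token-index sequences.

    Parameters live in a flat name -> float64 array dict; ``save``/``load``
    round-trip them bit-exactly together with the configuration.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params(
            np.random.default_rng(seed))

    # ------------------------------------------------------------------ init
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c = self.config

        def nrm(*shape):
            return rng.normal(0.0, 0.02, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": nrm(c.vocab_size, c.d_model),
            "pos_emb": nrm(c.max_len, c.d_model),
        }
        if c.use_segment_embedding:
            p["seg_emb"] = nrm(c.max_visits, c.d_model)
        for l in range(c.n_layers):
            p[f"l{l}.Wq"] = nrm(c.n_heads, c.d_model, c.d_k)
            p[f"l{l}.Wk"] = nrm(c.n_heads, c.d_model, c.d_k)
            p[f"l{l}.Wv"] = nrm(c.n_heads, c.d_model, c.d_v)
            p[f"l{l}.Wo"] = nrm(c.n_heads * c.d_v, c.d_model)
            p[f"l{l}.bo"] = np.zeros(c.d_model)
            p[f"l{l}.ln1.g"] = np.ones(c.d_model)
            p[f"l{l}.ln1.b"] = np.zeros(c.d_model)
            p[f"l{l}.W1"] = nrm(c.d_model, c.d_ff)
            p[f"l{l}.b1"] = np.zeros(c.d_ff)
            p[f"l{l}.W2"] = nrm(c.d_ff, c.d_model)
            p[f"l{l}.b2"] = np.zeros(c.d_model)
            p[f"l{l}.ln2.g"] = np.ones(c.d_model)
            p[f"l{l}.ln2.b"] = np.zeros(c.d_model)
        p["mlm_bias"] = np.zeros(c.vocab_size)
        p["cls_w"] = nrm(c.d_model)
        p["cls_b"] = np.zeros(())
        return p

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -------------------------------------------------------------- plumbing
    @staticmethod
    def _draw_noise(rng: np.random.Generator, mu: np.ndarray,
                    sigma: np.ndarray, shape: tuple) -> np.ndarray:
        """Sample the adaptive attention noise: (B, h) per-sample-per-head
        mu/sigma broadcast over the (B, h, T, T) score tensor.  Isolated so
        tests can freeze the draw."""
        eps = rng.standard_normal(shape)
        return mu[:, :, None, None] + sigma[:, :, None, None] * eps

    def _dropout_mask(self, shape, training, rng):
        rate = self.config.dropout
        if not training or rate == 0.0 or rng is None:
            return None
        return (rng.random(shape) >= rate) / (1.0 - rate)

    def _segments(self, tokens: np.ndarray) -> np.ndarray:
        is_sep = tokens == SEP
        seg = np.cumsum(is_sep, axis=1) - is_sep
        return np.clip(seg, 0, self.config.max_visits - 1)

    # --------------------------------------------------------------- forward
    def forward(self, tokens: np.ndarray,
                aug: AugmentationConfig | None = None,
                baseline: BaselineConfig | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None,
                collect_attention: bool = False):
        """Run the encoder; returns (H, attention, cache).

        ``tokens`` is an int (B, T) array with trailing [PAD]; ``attention``
        (when collected) is a list over layers of the (B, h, T, T) matrices
        actually multiplied with V (i.e. post-augmentation).  ``cache``
        feeds :meth:`backward`.
        """
        if aug is not None and baseline is not None and aug.mode != "none":
            raise ValueError("attention augmentation and baseline are mutually exclusive")
        c, p = self.config, self.params
        tokens = np.asarray(tokens)
        B, T = tokens.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        valid = tokens != PAD
        valid_len = valid.sum(axis=1).astype(int)

        X = p["tok_emb"][tokens] + p["pos_emb"][:T][None]
        seg_ids = None
        if c.use_segment_embedding:
            seg_ids = self._segments(tokens)
            X = X + p["seg_emb"][seg_ids]
        X = X * valid[..., None]

        embed_shift = None
        if (baseline is not None and baseline.kind == "embed_noise" and training):
            embed_shift = self._uniform_shift(X.shape, valid_len, baseline, rng)
            X = X + embed_shift * valid[..., None]

        kern = None
        if aug is not None and aug.mode == "ANAA":
            kern = build_kernel(aug.sigma_eh, aug.kernel_normalized)

        caches = []
        attn_out: list[np.ndarray] = []
        H = X
        for l in range(c.n_layers):
            H, cache = self._layer_forward(l, H, valid, valid_len, aug, kern,
                                           baseline, training, rng)
            caches.append(cache)
            if collect_attention:
                attn_out.append(cache["A_aug"].copy())
        full_cache = {
            "tokens": tokens, "valid": valid, "valid_len": valid_len,
            "seg_ids": seg_ids, "layers": caches, "aug": aug, "kern": kern,
            "H": H,
        }
        return H, attn_out, full_cache

    def _uniform_shift(self, shape, valid_len, baseline, rng):
        B, T, d = shape
        shift = np.zeros(shape)
        for b in range(B):
            L = max(int(valid_len[b]), 1)
            scale = noise_scale(baseline.alpha_scale, L, d)
            shift[b] = rng.uniform(-1.0, 1.0, size=(T, d)) * scale
        return shift

    def _layer_forward(self, l, X, valid, valid_len, aug, kern, baseline,
                       training, rng):
        c, p = self.config, self.params
        B, T, _ = X.shape
        Q = _es("btd,hdk->bhtk", X, p[f"l{l}.Wq"])
        K = _es("btd,hdk->bhtk", X, p[f"l{l}.Wk"])
        V = _es("btd,hdv->bhtv", X, p[f"l{l}.Wv"])
        S = _es("bhik,bhjk->bhij", Q, K) / math.sqrt(c.d_k)
        S = np.where(valid[:, None, None, :], S, _NEG)
        if (baseline is not None and training
                and baseline.kind in ("naive_mask", "drop_attention")):
            S = apply_logit_mask_batch(S, valid_len, baseline, rng)

        S_shift = S - S.max(axis=-1, keepdims=True)
        E = np.exp(S_shift)
        A = E / E.sum(axis=-1, keepdims=True)
        A = A * valid[:, None, :, None]        # zero padded query rows
        A = A * valid[:, None, None, :]        # exact zeros on padded keys

        A_aug = self._augment_batch(A, valid, valid_len, aug, kern, training,
                                    rng)

        Hh = _es("bhij,bhjv->bhiv", A_aug, V)
        concat = Hh.transpose(0, 2, 1, 3).reshape(B, T, c.n_heads * c.d_v)
        attn_proj = concat @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
        drop1 = self._dropout_mask(attn_proj.shape, training, rng)
        if drop1 is not None:
            attn_proj = attn_proj * drop1
        res1 = X + attn_proj
        X1, ln1_cache = _layernorm(res1, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])

        ffn_in = X1
        if baseline is not None and baseline.kind == "ffn_noise" and training:
            ffn_in = X1 + self._uniform_shift(X1.shape, valid_len, baseline, rng)
        h_pre = ffn_in @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
        h_act = np.maximum(h_pre, 0.0)
        ffn_out = h_act @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
        drop2 = self._dropout_mask(ffn_out.shape, training, rng)
        if drop2 is not None:
            ffn_out = ffn_out * drop2
        res2 = X1 + ffn_out
        X2, ln2_cache = _layernorm(res2, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])

        cache = dict(X=X, Q=Q, K=K, V=V, A=A, A_aug=A_aug, concat=concat,
                     ln1=ln1_cache, ln2=ln2_cache, X1=X1, h_pre=h_pre,
                     h_act=h_act, drop1=drop1, drop2=drop2)
        return X2, cache

    def _augment_batch(self, A, valid, valid_len, aug, kern, training, rng):
        """Apply the configured augmentation to every (sample, head) block.

        Fully vectorized over (batch, head): padded entries are exactly zero,
        so masked moment sums and a single full-tensor convolution reproduce
        the per-block computation.  Samples too short to define the noise
        variance (valid_len < 2) pass through unaugmented.
        """
        if aug is None or aug.mode == "none":
            return A
        pair = valid[:, None, :, None] & valid[:, None, None, :]  # (B,1,T,T)
        m = valid_len.astype(float) ** 2
        ok = valid_len >= 2
        mu = A.sum(axis=(2, 3)) / np.maximum(m, 1.0)[:, None]      # (B,h)
        if training:
            ss = (A**2).sum(axis=(2, 3)) - m[:, None] * mu**2
            if aug.variance_denominator == "elements_minus_one":
                d = np.maximum(m - 1.0, 1.0)
            else:
                d = np.maximum(valid_len.astype(float) - 1.0, 1.0)
            sigma = np.sqrt(np.maximum(ss, 0.0) / d[:, None])
            noise = self._draw_noise(rng, mu, sigma, A.shape)
            A_aug = A + noise * pair
        else:
            A_aug = A + mu[:, :, None, None] * pair
        if aug.mode == "ANAA":
            A_aug = np.where(pair, smooth_block(A_aug, kern), 0.0)
        if not ok.all():
            A_aug[~ok] = A[~ok]
        return A_aug

    # -------------------------------------------------------------- backward
    def backward(self, dH: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Backpropagate a gradient w.r.t. the final hidden states through
        the whole stack; returns per-parameter gradients."""
        c, p = self.config, self.params
        grads = self.zero_grads()
        aug, kern = cache["aug"], cache["kern"]
        valid, valid_len = cache["valid"], cache["valid_len"]
        dX = dH
        for l in range(c.n_layers - 1, -1, -1):
            dX = self._layer_backward(l, dX, cache["layers"][l], grads, aug,
                                      kern, valid, valid_len)
        dX = dX * valid[..., None]
        tokens = cache["tokens"]
        np.add.at(grads["tok_emb"], tokens, dX)
        grads["pos_emb"][:tokens.shape[1]] += dX.sum(axis=0)
        if c.use_segment_embedding:
            np.add.at(grads["seg_emb"], cache["seg_ids"], dX)
        return grads

    def _layer_backward(self, l, dX2, cache, grads, aug, kern, valid, valid_len):
        c, p = self.config, self.params
        B, T, _ = dX2.shape
        dres2, dg, db = _layernorm_backward(dX2, cache["ln2"], p[f"l{l}.ln2.g"])
        grads[f"l{l}.ln2.g"] += dg
        grads[f"l{l}.ln2.b"] += db
        dX1 = dres2.copy()
        dffn = dres2 if cache["drop2"] is None else dres2 * cache["drop2"]
        grads[f"l{l}.W2"] += _es("btf,btd->fd", cache["h_act"], dffn)
        grads[f"l{l}.b2"] += dffn.sum(axis=(0, 1))
        dh = (dffn @ p[f"l{l}.W2"].T) * (cache["h_pre"] > 0)
        grads[f"l{l}.W1"] += _es("btd,btf->df", cache["X1"], dh)
        grads[f"l{l}.b1"] += dh.sum(axis=(0, 1))
        dX1 += dh @ p[f"l{l}.W1"].T  # ffn noise shift is an additive constant

        dres1, dg, db = _layernorm_backward(dX1, cache["ln1"], p[f"l{l}.ln1.g"])
        grads[f"l{l}.ln1.g"] += dg
        grads[f"l{l}.ln1.b"] += db
        dXres = dres1.copy()
        dproj = dres1 if cache["drop1"] is None else dres1 * cache["drop1"]
        grads[f"l{l}.Wo"] += _es("btc,btd->cd", cache["concat"], dproj)
        grads[f"l{l}.bo"] += dproj.sum(axis=(0, 1))
        dconcat = dproj @ p[f"l{l}.Wo"].T
        dHh = dconcat.reshape(B, T, c.n_heads, c.d_v).transpose(0, 2, 1, 3)

        A_aug, A, V = cache["A_aug"], cache["A"], cache["V"]
        dA_aug = _es("bhiv,bhjv->bhij", dHh, V)
        dV = _es("bhij,bhiv->bhjv", A_aug, dHh)

        # augmentation backward: noise/mu are stop-gradients; smoothing is
        # linear, its gradient is the adjoint convolution on the valid block
        if aug is not None and aug.mode == "ANAA":
            pair_mask = (valid[:, None, :, None] & valid[:, None, None, :])
            adj = smooth_block(dA_aug * pair_mask, kern, adjoint=True)
            dA = dA_aug.copy()
            for b in range(B):
                L = int(valid_len[b])
                if L < 2:
                    continue
                dA[b, :, :L, :L] = adj[b, :, :L, :L]
        else:
            dA = dA_aug

        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True)) / math.sqrt(c.d_k)
        dQ = _es("bhij,bhjk->bhik", dS, cache["K"])
        dK = _es("bhij,bhik->bhjk", dS, cache["Q"])

        X = cache["X"]
        grads[f"l{l}.Wq"] += _es("btd,bhtk->hdk", X, dQ)
        grads[f"l{l}.Wk"] += _es("btd,bhtk->hdk", X, dK)
        grads[f"l{l}.Wv"] += _es("btd,bhtv->hdv", X, dV)
        dXres += _es("bhtk,hdk->btd", dQ, p[f"l{l}.Wq"])
        dXres += _es("bhtk,hdk->btd", dK, p[f"l{l}.Wk"])
        dXres += _es("bhtv,hdv->btd", dV, p[f"l{l}.Wv"])
        return dXres

    # ------------------------------------------------------------- MLM head
    def mlm_forward(self, corrupted: np.ndarray, targets: np.ndarray,
                    mask_rows: np.ndarray, mask_cols: np.ndarray,
                    training: bool = False,
                    rng: np.random.Generator | None = None,
                    aug: AugmentationConfig | None = None,
                    baseline: BaselineConfig | None = None,
                    with_grads: bool = False):
        """Masked-language-model loss (cross-entropy over masked positions).

        ``corrupted`` is the already-corrupted batch; ``targets`` holds the
        original token ids at the masked positions given by the
        (``mask_rows``, ``mask_cols``) index arrays.  Returns
        (loss, log_scores[, grads]).
        """
        p = self.params
        H, _, cache = self.forward(corrupted, aug=aug, baseline=baseline,
                                   training=training, rng=rng)
        M = len(mask_rows)
        if M == 0:
            warnings.warn("no masked positions; MLM loss is 0 by convention",
                          RuntimeWarning, stacklevel=2)
            out = (0.0, np.zeros((0, self.config.vocab_size)))
            return out + (self.zero_grads(),) if with_grads else out
        Hm = H[mask_rows, mask_cols]
        logits = Hm @ p["tok_emb"].T + p["mlm_bias"]
        logZ = np.log(np.exp(logits - logits.max(1, keepdims=True))
                      .sum(1, keepdims=True)) + logits.max(1, keepdims=True)
        log_probs = logits - logZ
        loss = float(-log_probs[np.arange(M), targets].mean())
        if not with_grads:
            return loss, log_probs
        dlogits = np.exp(log_probs)
        dlogits[np.arange(M), targets] -= 1.0
        dlogits /= M
        dH = np.zeros_like(H)
        np.add.at(dH, (mask_rows, mask_cols), dlogits @ p["tok_emb"])
        grads = self.backward(dH, cache)
        grads["tok_emb"] += dlogits.T @ Hm
        grads["mlm_bias"] += dlogits.sum(axis=0)
        return loss, log_probs, grads

    # ---------------------------------------------------- classification head
    def classify_forward(self, tokens: np.ndarray,
                         aug: AugmentationConfig | None = None,
                         baseline: BaselineConfig | None = None,
                         training: bool = False,
                         rng: np.random.Generator | None = None):
        """Positive-outcome probability from the pooled sequence
        representation (the [CLS] position, or the mean over valid
        positions — the latter is far more sample-efficient when the
        pre-training corpus is small and [CLS] carries no MLM signal)."""
        H, _, cache = self.forward(tokens, aug=aug, baseline=baseline,
                                   training=training, rng=rng)
        pooled = self._pool(H, cache)
        z = pooled @ self.params["cls_w"] + self.params["cls_b"]
        return 1.0 / (1.0 + np.exp(-z)), (cache, z, pooled)

    def _pool(self, H: np.ndarray, cache: dict) -> np.ndarray:
        if self.config.pooling == "cls":
            return H[:, 0, :]
        valid = cache["valid"]
        return (H * valid[..., None]).sum(1) / valid.sum(1)[:, None]

    def classify_loss(self, tokens: np.ndarray, labels: np.ndarray,
                      aug: AugmentationConfig | None = None,
                      baseline: BaselineConfig | None = None,
                      training: bool = False,
                      rng: np.random.Generator | None = None,
                      with_grads: bool = False):
        """Binary cross-entropy of the [CLS] head (numerically stable)."""
        probs, (cache, z, pooled) = self.classify_forward(
            tokens, aug=aug, baseline=baseline, training=training, rng=rng)
        y = np.asarray(labels, dtype=float)
        loss = float(np.mean(np.maximum(z, 0) - z * y
                             + np.log1p(np.exp(-np.abs(z)))))
        if not with_grads:
            return loss, probs
        B = len(y)
        dz = (probs - y) / B
        H = cache["H"]
        dpooled = np.outer(dz, self.params["cls_w"])
        dH = np.zeros_like(H)
        if self.config.pooling == "cls":
            dH[:, 0, :] = dpooled
        else:
            valid = cache["valid"]
            dH += (dpooled[:, None, :] / valid.sum(1)[:, None, None]
                   ) * valid[..., None]
        grads = self.backward(dH, cache)
        grads["cls_w"] += pooled.T @ dz
        grads["cls_b"] += dz.sum()
        return loss, probs, grads

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        meta = json.dumps({"config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "TransformerEncoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return cls(EncoderConfig(**meta["config"]), params=params)


def self_attention_head(X: np.ndarray, Wq: np.ndarray, Wk: np.ndarray,
                        Wv: np.ndarray, valid_len: int,
                        aug: AugmentationConfig | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[np.ndarray, AttentionMatrix]:
    """One attention head on a single (n, d_model) sequence.

    Returns the head output computed with the augmented matrix and the
    *pre-augmentation* AttentionMatrix (row-stochastic on the valid block).
    """
    from .augmentation import augment_train, augment_eval
    n = X.shape[0]
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    S = (Q @ K.T) / math.sqrt(Wq.shape[1])
    col_valid = np.arange(n) < valid_len
    S = np.where(col_valid[None, :], S, _NEG)
    E = np.exp(S - S.max(axis=1, keepdims=True))
    A = E / E.sum(axis=1, keepdims=True)
    A = A * col_valid[:, None] * col_valid[None, :]
    attn = AttentionMatrix(scores=A, valid_len=valid_len)
    if aug is None or aug.mode == "none":
        A_used = A
    elif aug.training:
        A_used = augment_train(attn, aug, rng)
    else:
        A_used = augment_eval(attn, aug)
    return A_used @ V, attn


def mlm_corrupt(tokens: np.ndarray, vocab_size: int,
                rng: np.random.Generator, mask_prob: float = 0.15):
    """BERT-style MLM corruption: select ``mask_prob`` of the non-special
    tokens, then 80% -> [MASK], 10% -> random in-vocabulary code, 10% kept.

    Returns (corrupted, targets, mask_rows, mask_cols).
    """
    from .tokenization import MASK, SPECIAL_TOKENS
    n_special = len(SPECIAL_TOKENS)
    eligible = tokens >= n_special
    sel = eligible & (rng.random(tokens.shape) < mask_prob)
    rows, cols = np.nonzero(sel)
    targets = tokens[rows, cols].copy()
    corrupted = tokens.copy()
    u = rng.random(len(rows))
    mask_it = u < 0.8
    rand_it = (u >= 0.8) & (u < 0.9)
    corrupted[rows[mask_it], cols[mask_it]] = MASK
    if rand_it.any() and vocab_size > n_special:
        corrupted[rows[rand_it], cols[rand_it]] = rng.integers(
            n_special, vocab_size, size=int(rand_it.sum()))
    return corrupted, targets, rows, cols
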
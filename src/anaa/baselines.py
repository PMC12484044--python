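"""Comparison augmentations: naive attention masking, DropAttention, and
uniform noise on embeddings / feed-forward inputs.

Unlike ANAA, the masking baselines act on the *pre-softmax* logits — masked
entries are set to -inf, so the surviving entries renormalise and the rows
stay stochastic.  The noise baselines add calibrated uniform noise
(magnitude ``alpha / sqrt(n * d)`` for an n-token, d-dimensional input) to
internal representations.  All baselines are training-only: at evaluation
they are identity maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BaselineConfig", "naive_mask", "drop_attention", "embed_noise",
           "ffn_noise", "noise_scale", "apply_logit_mask_batch"]

_NEG = -1e30

KINDS = ("naive_mask", "drop_attention", "embed_noise", "ffn_noise")


@dataclass(frozen=True)
class BaselineConfig:
    kind: str
    p: float = 0.2          # mask probability (masking baselines)
    omega: int = 1          # span length along the key axis (DropAttention)
    alpha_scale: float = 5.0  # uniform-noise magnitude (noise baselines)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if self.alpha_scale < 0:
            raise ValueError("alpha_scale must be >= 0")


def noise_scale(alpha_scale: float, n: int, d: int) -> float:
    """Calibrated uniform-noise magnitude ``alpha / sqrt(n * d)``."""
    return alpha_scale / math.sqrt(n * d)


def _restore_dead_rows(out: np.ndarray, logits: np.ndarray, L: int) -> None:
    # a row whose valid entries are all masked has no softmax; restore it
    dead = np.all(out[:L, :L] <= _NEG / 2, axis=1)
    if dead.any():
        out[:L][dead] = logits[:L][dead]


def naive_mask(logits: np.ndarray, p: float, rng: np.random.Generator,
               valid_len: int) -> np.ndarray:
    """Set each valid pre-softmax entry to -inf independently with
    probability ``p``; rows that become entirely masked are restored."""
    L = valid_len
    out = logits.copy()
    mask = rng.random((L, L)) < p
    out[:L, :L] = np.where(mask, _NEG, out[:L, :L])
    _restore_dead_rows(out, logits, L)
    return out


def drop_attention(logits: np.ndarray, p: float, omega: int,
                   rng: np.random.Generator, valid_len: int) -> np.ndarray:
    """DropAttention: Bernoulli(p) seed positions, each expanded to an
    ``omega``-length run along the key axis within the valid block."""
    L = valid_len
    out = logits.copy()
    seeds = rng.random((L, L)) < p
    mask = np.zeros_like(seeds)
    for s in range(omega):
        mask[:, s:] |= seeds[:, :L - s]
    out[:L, :L] = np.where(mask, _NEG, out[:L, :L])
    _restore_dead_rows(out, logits, L)
    return out


def apply_logit_mask_batch(S: np.ndarray, valid_len: np.ndarray,
                           cfg: BaselineConfig, rng: np.random.Generator
                           ) -> np.ndarray:
    """Apply naive_mask / drop_attention per (sample, head) to a batched
    (B, h, T, T) logit tensor (used by the encoder's training path)."""
    out = S.copy()
    for b in range(S.shape[0]):
        L = int(valid_len[b])
        if L < 1:
            continue
        for h in range(S.shape[1]):
            if cfg.kind == "naive_mask":
                out[b, h] = naive_mask(S[b, h], cfg.p, rng, L)
            else:
                out[b, h] = drop_attention(S[b, h], cfg.p, cfg.omega, rng, L)
    return out


def embed_noise(E: np.ndarray, alpha_scale: float,
                rng: np.random.Generator, training: bool = True) -> np.ndarray:
    """Uniform noise on an (n, d) embedded sequence, scaled by
    ``alpha / sqrt(n*d)``; identity at evaluation."""
    if not training or alpha_scale == 0.0:
        return E.copy()
    n, d = E.shape
    return E + rng.uniform(-1.0, 1.0, size=E.shape) * noise_scale(alpha_scale, n, d)


def ffn_noise(H: np.ndarray, alpha_scale: float,
              rng: np.random.Generator, training: bool = True) -> np.ndarray:
    """Same calibration applied to (n, d) feed-forward inputs."""
    return embed_noise(H, alpha_scale, rng, training)
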
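"""Adaptive noise-augmented attention (ANAA): the augmentation core.

ANAA perturbs a post-softmax attention score matrix ``A`` in two steps:

1. add i.i.d. Gaussian noise ``N(mu, sigma_gn^2)`` whose parameters are
   computed *adaptively* from ``A`` itself — ``mu`` is the mean attention
   score and ``sigma_gn`` the sample standard deviation over the valid
   (non-padded) region of the matrix, per sample and per head;
2. convolve the noised matrix with a discrete 2D Gaussian smoothing kernel
   whose width is controlled by the *event horizon* ``sigma_eh`` through the
   size rule ``k = round(2*pi*sigma_eh)``.

At inference the random draw is replaced by its expectation ``mu`` so the
model stays deterministic.  RNA ("raw noise injected attention") is the
noise step alone, without smoothing.  Augmented rows are deliberately *not*
renormalised: the perturbed scores multiply the value vectors directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionMatrix",
    "NoiseParams",
    "SmoothingKernel",
    "AugmentationConfig",
    "DegenerateInputError",
    "kernel_size",
    "build_kernel",
    "compute_noise_params",
    "smooth",
    "augment_train",
    "augment_eval",
]

MODES = ("none", "RNA", "ANAA")
VARIANCE_DENOMINATORS = ("elements_minus_one", "as_printed")


class DegenerateInputError(ValueError):
    """Raised when adaptive noise statistics are undefined (valid_len < 2)."""


@dataclass(frozen=True)
class AttentionMatrix:
    """One head's n-by-n post-softmax attention scores for one sample.

    Only the leading ``valid_len`` rows/columns are real positions; the rest
    is padding and must be exactly zero.
    """

    scores: np.ndarray
    valid_len: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError(f"scores must be square, got shape {s.shape}")
        if not 0 <= self.valid_len <= s.shape[0]:
            raise ValueError("valid_len must lie in [0, n]")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def validate(self, atol: float = 1e-6) -> None:
        """Check the pre-augmentation invariants (row-stochastic valid block,
        entries in [0, 1], zero padding)."""
        L, n = self.valid_len, self.n
        block = self.scores[:L, :L]
        if L and not np.allclose(block.sum(axis=1), 1.0, atol=atol):
            raise ValueError("valid rows do not sum to 1")
        if block.size and (block.min() < -atol or block.max() > 1 + atol):
            raise ValueError("pre-augmentation entries must lie in [0, 1]")
        pad = self.scores.copy()
        pad[:L, :L] = 0.0
        if np.any(pad != 0.0):
            raise ValueError("padded rows/columns must be exactly 0")


@dataclass(frozen=True)
class NoiseParams:
    """Adaptive Gaussian noise parameters for one (sample, head) matrix."""

    mu: float
    sigma_gn: float
    scope: str = ""


@dataclass(frozen=True)
class SmoothingKernel:
    """Discrete k-by-k 2D Gaussian with event-horizon width ``sigma_eh``.

    The support uses centered integer offsets ``-floor(k/2) .. ceil(k/2)-1``;
    for even ``k`` the kernel is anchored one cell up-left of center (a
    one-sided support would translate the attention map instead of smoothing
    it).
    """

    sigma_eh: float
    size_k: int
    weights: np.ndarray
    normalized: bool

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.size_k) - self.size_k // 2

    def to_text(self, path) -> None:
        """Write the weight matrix as plain text for inspection."""
        header = (f"sigma_eh={self.sigma_eh} size_k={self.size_k} "
                  f"normalized={self.normalized}")
        np.savetxt(path, self.weights, header=header)


@dataclass(frozen=True)
class AugmentationConfig:
    """How (and whether) to augment attention scores.

    mode
        ``"none"`` (identity), ``"RNA"`` (adaptive noise only) or ``"ANAA"``
        (noise plus Gaussian-kernel smoothing).
    sigma_eh
        Event-horizon width of the smoothing kernel; kernel side length is
        ``round(2*pi*sigma_eh)`` clamped to at least 1.
    variance_denominator
        ``"elements_minus_one"`` divides the sum of squared deviations over
        the n*n valid entries by n^2-1 (the sample estimator over all matrix
        elements, the default); ``"as_printed"`` divides by n-1.
    """

    mode: str = "none"
    sigma_eh: float = 1.0
    kernel_normalized: bool = True
    variance_denominator: str = "elements_minus_one"
    training: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.variance_denominator not in VARIANCE_DENOMINATORS:
            raise ValueError(
                f"variance_denominator must be one of {VARIANCE_DENOMINATORS}"
            )


def kernel_size(sigma_eh: float) -> int:
    """Kernel side length: ``k = 2*pi*sigma`` rounded to the nearest integer,
    clamped to >= 1 (sigma 1.0 -> 6, sigma 0.33 -> 2)."""
    if sigma_eh <= 0:
        raise ValueError(f"sigma_eh must be > 0, got {sigma_eh}")
    return max(1, round(2.0 * math.pi * sigma_eh))


def build_kernel(sigma_eh: float, normalized: bool = True) -> SmoothingKernel:
    """Construct the discrete 2D Gaussian smoothing kernel for ``sigma_eh``.

    Weights are ``(1/(2 pi sigma^2)) exp(-(u^2+v^2)/(2 sigma^2))`` at the
    centered integer offsets; when ``normalized`` they are rescaled to sum
    to 1 so interior smoothing preserves total attention mass.
    """
    k = kernel_size(sigma_eh)
    offs = np.arange(k) - k // 2
    u, v = np.meshgrid(offs, offs, indexing="ij")
    w = np.exp(-0.5 * (u**2 + v**2) / sigma_eh**2) / (2.0 * math.pi * sigma_eh**2)
    if normalized:
        w = w / w.sum()
    return SmoothingKernel(sigma_eh=float(sigma_eh), size_k=k, weights=w,
                           normalized=normalized)


def compute_noise_params(A: AttentionMatrix, cfg: AugmentationConfig) -> NoiseParams:
    """Adaptive noise statistics over the valid region of ``A``.

    ``mu`` is the arithmetic mean of the valid_len x valid_len block (for a
    row-stochastic matrix this is exactly 1/valid_len); ``sigma_gn`` is
    ``sqrt(SS / D)`` where SS is the sum of squared deviations and D is
    selected by ``cfg.variance_denominator``.
    """
    L = A.valid_len
    if L < 2:
        raise DegenerateInputError(
            f"valid_len must be >= 2 to define noise variance, got {L}"
        )
    block = A.scores[:L, :L]
    if np.all(block == block.flat[0]):  # constant block: sigma is exactly 0
        return NoiseParams(mu=float(block.flat[0]), sigma_gn=0.0,
                           scope=f"n={L}")
    mu = float(block.mean())
    ss = float(((block - mu) ** 2).sum())
    d = L * L - 1 if cfg.variance_denominator == "elements_minus_one" else L - 1
    return NoiseParams(mu=mu, sigma_gn=math.sqrt(ss / d), scope=f"n={L}")


def smooth_block(block: np.ndarray, kern: SmoothingKernel,
                 adjoint: bool = False) -> np.ndarray:
    """Convolve the trailing two axes of ``block`` with ``kern`` under zero
    padding: out[i, j] = sum_{u,v} w[u, v] * block[i-u, j-v] over the
    centered offsets.  ``adjoint`` applies the transpose operator (used by
    backpropagation through the smoothing step)."""
    k = kern.size_k
    Lr, Lc = block.shape[-2], block.shape[-1]
    offs = kern.offsets
    sgn = -1 if adjoint else 1
    # the 2D Gaussian is separable: weights[a, b] = c * e[a] * e[b], so two
    # 1D passes replace the k^2 double loop
    e = np.exp(-0.5 * offs.astype(float) ** 2 / kern.sigma_eh**2)
    c = kern.weights.sum() / (e.sum() ** 2)
    pad_r = [(0, 0)] * (block.ndim - 2) + [(k, k), (0, 0)]
    padded = np.pad(block, pad_r)
    tmp = np.zeros_like(block)
    for a, du in enumerate(offs):
        r0 = k - sgn * du
        tmp += e[a] * padded[..., r0:r0 + Lr, :]
    pad_c = [(0, 0)] * (block.ndim - 2) + [(0, 0), (k, k)]
    padded = np.pad(tmp, pad_c)
    acc = np.zeros_like(block)
    for b, dv in enumerate(offs):
        c0 = k - sgn * dv
        acc += (c * e[b]) * padded[..., :, c0:c0 + Lc]
    return acc


def smooth(M: np.ndarray, kern: SmoothingKernel, valid_len: int) -> np.ndarray:
    """Smooth the ``valid_len`` x ``valid_len`` sub-block of ``M`` with the
    kernel; zero-padded boundary, same-size output, padding stays zero."""
    M = np.asarray(M, dtype=float)
    L = valid_len
    if L > M.shape[0]:
        raise ValueError("valid_len exceeds matrix size")
    if kern.size_k > 2 * L:
        warnings.warn(
            f"kernel size {kern.size_k} exceeds twice the valid length {L}; "
            "smoothing will be heavy", RuntimeWarning, stacklevel=2)
    out = np.zeros_like(M)
    out[:L, :L] = smooth_block(M[:L, :L], kern)
    return out


def _resolve_kernel(cfg: AugmentationConfig) -> SmoothingKernel:
    return build_kernel(cfg.sigma_eh, cfg.kernel_normalized)


def augment_train(A: AttentionMatrix, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Stochastic training-path augmentation.

    ANAA: ``smooth(A + G)`` with ``G ~ N(mu, sigma_gn^2)`` i.i.d. over the
    valid region, drawn fresh on every call; RNA: ``A + G`` without
    smoothing; none: identity.  Rows are not renormalised afterwards.
    """
    if cfg.mode == "none":
        return A.scores.copy()
    p = compute_noise_params(A, cfg)
    L = A.valid_len
    out = A.scores.copy()
    out[:L, :L] += rng.normal(p.mu, p.sigma_gn, size=(L, L))
    if cfg.mode == "ANAA":
        out = smooth(out, _resolve_kernel(cfg), L)
    return out


def augment_eval(A: AttentionMatrix, cfg: AugmentationConfig) -> np.ndarray:
    """Deterministic inference-path augmentation: the noise draw is replaced
    by its expected value ``mu`` (recomputed from the current ``A``).

    ANAA: ``smooth(A + mu)``; RNA: ``A + mu``; none: identity.
    """
    if cfg.mode == "none":
        return A.scores.copy()
    p = compute_noise_params(A, cfg)
    L = A.valid_len
    out = A.scores.copy()
    out[:L, :L] += p.mu
    if cfg.mode == "ANAA":
        out = smooth(out, _resolve_kernel(cfg), L)
    return out
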
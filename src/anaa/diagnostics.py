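"""Attention-behavior diagnostics.

Fine-tuned Transformers often drive attention toward a near-binary pattern:
after per-head min-max scaling, scores pile up at 0 and 1.  This module
quantifies that pattern and how augmentation changes it:

* per-head histograms of [0, 1]-scaled scores pooled over sequences;
* a *polarization index* per head — the fraction of scaled scores within
  ``eps`` of 0 or 1 (an invented scalar summarising the near-binary shape);
* an estimate of the "on" mass alpha of the two-point pattern (the mean of
  the scaled pool, which equals alpha when scores are exactly two-valued);
* receptive-field curves — the median attention score as a function of the
  query-key offset ``i - j``, over previous (positive offsets) and
  subsequent (negative offsets) events;
* min-max scaled heatmap export for individual matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AttentionSample", "DiagnosticsReport", "collect_attention",
           "scaled_histogram", "receptive_field", "export_heatmap"]


@dataclass
class AttentionSample:
    """Attention matrices for a set of evaluation sequences.

    ``matrices[s]`` has shape (n_layers, n_heads, T_s, T_s) for sequence
    ``s``; ``valid_lens[s]`` marks its non-padding length.  ``augmented``
    records whether the eval-path augmentation was applied when collecting.
    """

    matrices: list[np.ndarray]
    valid_lens: list[int]
    augmented: bool = False

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("empty attention sample")
        shape = self.matrices[0].shape[:2]
        if any(m.shape[:2] != shape for m in self.matrices):
            raise ValueError("inconsistent layer/head counts across sequences")

    @property
    def n_layers(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def n_heads(self) -> int:
        return self.matrices[0].shape[1]

    def head_pool(self, layer: int, head: int) -> np.ndarray:
        """All valid-region scores of one head, pooled across sequences."""
        vals = [m[layer, head, :L, :L].ravel()
                for m, L in zip(self.matrices, self.valid_lens)]
        return np.concatenate(vals)


def collect_attention(model, sequences, aug=None, batch_size: int = 32
                      ) -> AttentionSample:
    """Run the encoder's eval path over tokenized sequences and collect the
    attention matrices it actually used (augmented when ``aug`` says so)."""
    from .training import pad_batch
    matrices: list[np.ndarray] = []
    valid_lens: list[int] = []
    for i in range(0, len(sequences), batch_size):
        chunk = sequences[i:i + batch_size]
        batch = pad_batch([s.tokens for s in chunk])
        _, attn, cache = model.forward(batch, aug=aug, training=False,
                                       collect_attention=True)
        stacked = np.stack(attn, axis=0)  # (layers, B, h, T, T)
        for b, s in enumerate(chunk):
            L = int(cache["valid_len"][b])
            matrices.append(stacked[:, b])
            valid_lens.append(L)
    return AttentionSample(matrices=matrices, valid_lens=valid_lens,
                           augmented=aug is not None and aug.mode != "none")


@dataclass
class DiagnosticsReport:
    """Histogram, polarization and receptive-field summaries."""

    bin_edges: np.ndarray
    histograms: dict[str, np.ndarray]       # head key -> normalized masses
    polarization: dict[str, float]
    degenerate: dict[str, bool]
    on_mass_alpha: dict[str, float]
    receptive_field: dict[int, float] = field(default_factory=dict)
    receptive_field_per_head: dict[str, dict[int, float]] = field(default_factory=dict)

    def occupied_bins(self, head: str) -> int:
        return int((self.histograms[head] > 0).sum())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "bin_edges": self.bin_edges.tolist(),
            "histograms": {k: v.tolist() for k, v in self.histograms.items()},
            "polarization": self.polarization,
            "degenerate": self.degenerate,
            "on_mass_alpha": self.on_mass_alpha,
            "receptive_field": {str(k): v for k, v in self.receptive_field.items()},
        }, indent=1))

    def receptive_field_csv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.receptive_field.items()),
                     columns=["offset", "median_score"]).to_csv(path, index=False)


def _scale01(pool: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = pool.min(), pool.max()
    if hi == lo:  # constant-score head: defined as 0, flagged degenerate
        return np.zeros_like(pool), True
    return (pool - lo) / (hi - lo), False


def scaled_histogram(sample: AttentionSample, bins: int = 50,
                     eps: float = 0.05) -> DiagnosticsReport:
    """Per-head histograms of min-max scaled scores plus polarization.

    Scores are pooled per (layer, head) across all sequences' valid regions,
    scaled to [0, 1] over the pool, then binned on fixed edges.  The
    polarization index is the fraction of scaled scores within ``eps`` of
    0 or 1; ``on_mass_alpha`` is the pooled mean (the "on" fraction when
    the head is exactly two-valued).
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    histograms, polarization, degenerate, alpha = {}, {}, {}, {}
    for layer in range(sample.n_layers):
        for head in range(sample.n_heads):
            key = f"L{layer}H{head}"
            pool = sample.head_pool(layer, head)
            scaled, flag = _scale01(pool)
            counts, _ = np.histogram(scaled, bins=edges)
            histograms[key] = counts / counts.sum()
            polarization[key] = float(((scaled <= eps) | (scaled >= 1 - eps)).mean())
            degenerate[key] = flag
            alpha[key] = float(scaled.mean())
    report = DiagnosticsReport(bin_edges=edges, histograms=histograms,
                               polarization=polarization, degenerate=degenerate,
                               on_mass_alpha=alpha)
    report.receptive_field = receptive_field(sample)
    return report


def receptive_field(sample: AttentionSample, per_head: bool = False):
    """Median attention score per query-key offset ``i - j``.

    Positive offsets look at previous events, negative at subsequent ones.
    By default scores pool over all layers and heads; ``per_head`` returns
    one table per (layer, head) instead.
    """
    def tables(select):
        buckets: dict[int, list[np.ndarray]] = {}
        for m, L in zip(sample.matrices, sample.valid_lens):
            block = select(m)[..., :L, :L]
            i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
            off = i - j
            for o in range(-(L - 1), L):
                sel = block[..., off == o]
                buckets.setdefault(o, []).append(sel.ravel())
        return {o: float(np.median(np.concatenate(v)))
                for o, v in sorted(buckets.items())}

    if not per_head:
        return tables(lambda m: m)
    out = {}
    for layer in range(sample.n_layers):
        for head in range(sample.n_heads):
            out[f"L{layer}H{head}"] = tables(lambda m: m[layer, head])
    return out


def export_heatmap(sample: AttentionSample, sequence: int, layer: int,
                   head: int, path: str | Path) -> None:
    """Write one head's matrix as a min-max scaled raster heatmap.

    One pixel per matrix cell, so the image dimensions equal the valid
    matrix dimensions; the colormap spans exactly [min, max] of the matrix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    L = sample.valid_lens[sequence]
    M = sample.matrices[sequence][layer, head, :L, :L]
    lo, hi = float(M.min()), float(M.max())
    scaled = np.zeros_like(M) if hi == lo else (M - lo) / (hi - lo)
    plt.imsave(path, scaled, vmin=0.0, vmax=1.0, cmap="viridis")
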
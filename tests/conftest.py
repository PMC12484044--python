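"""Shared fixtures: tiny deterministic models, matrices and cohorts."""

import numpy as np
import pytest

from anaa.augmentation import AttentionMatrix
from anaa.encoder import EncoderConfig, TransformerEncoder
from anaa.tokenization import PatientTrajectory


def random_row_stochastic(n: int, rng: np.random.Generator,
                          valid_len: int | None = None) -> AttentionMatrix:
    """A random softmax-like matrix: nonnegative rows summing to 1 on the
    valid block, exact zeros in the padding."""
    L = valid_len if valid_len is not None else n
    raw = rng.random((L, L)) + 1e-3
    block = raw / raw.sum(axis=1, keepdims=True)
    scores = np.zeros((n, n))
    scores[:L, :L] = block
    return AttentionMatrix(scores=scores, valid_len=L)


def two_point_matrix(n: int, alpha: float, rng: np.random.Generator) -> AttentionMatrix:
    """A degenerate on/off matrix: exactly alpha*n^2 entries equal 1."""
    m = n * n
    k = round(alpha * m)
    assert abs(k - alpha * m) < 1e-9, "alpha*n^2 must be an integer"
    flat = np.zeros(m)
    flat[rng.choice(m, size=k, replace=False)] = 1.0
    return AttentionMatrix(scores=flat.reshape(n, n), valid_len=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_model():
    cfg = EncoderConfig(vocab_size=16, d_model=8, n_heads=2, d_k=4, d_v=4,
                        n_layers=2, d_ff=16, max_len=12)
    return TransformerEncoder(cfg, seed=7)


@pytest.fixture
def tiny_batch():
    # two sequences with trailing padding
    return np.array([[1, 6, 7, 2, 8, 9, 2, 0, 0, 0],
                     [1, 10, 2, 5, 2, 0, 0, 0, 0, 0]])


@pytest.fixture
def toy_cohort():
    """Five patients with visit counts 3, 9, 10, 12, 40."""
    def patient(pid, n_visits):
        return PatientTrajectory(pid, [{f"A{i:03d}", "B001"}
                                       for i in range(n_visits)])
    return [patient(f"P{i}", n) for i, n in enumerate([3, 9, 10, 12, 40])]
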
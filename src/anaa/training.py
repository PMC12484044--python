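"""Pre-training, fine-tuning, cross-validated evaluation and benchmarks.

The protocol: the cohort is split patient-level 70/20/10 into pre-training,
fine-tuning and test pools.  The encoder is pre-trained with masked language
modelling on the pre-training pool, then, for each of 5 label-stratified
folds, fine-tuned from the *same* pre-trained checkpoint on the other 4
folds with early stopping on the held-out fold (monitoring validation AUC,
the reported metric), and scored on the untouched test pool.  Reports carry
the per-fold test AUCs and their mean +/- std.

Attention augmentation (none / RNA / ANAA / a baseline) is active only
during fine-tuning; evaluation always uses the deterministic eval path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .augmentation import AugmentationConfig
from .baselines import BaselineConfig
from .cohort import CohortSpec, Motif, generate_cohort, preset, bayes_auc
from .encoder import EncoderConfig, TransformerEncoder, mlm_corrupt
from .tokenization import (LabeledSequence, PAD, SplitSpec, split_cohort,
                           tokenize_cohort)

__all__ = ["TrainConfig", "EvalReport", "Adam", "auc", "pad_batch",
           "pretrain", "finetune", "finetune_cv", "subsample_experiment",
           "directional_benchmark"]


@dataclass
class TrainConfig:
    lr_pretrain: float = 1e-3
    lr_finetune: float = 5e-4
    batch_size: int = 32
    max_epochs_pretrain: int = 10
    max_epochs_finetune: int = 30
    patience: int = 5
    mask_prob: float = 0.15
    subsample_fractions: tuple[float, ...] = (0.5, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if any(not 0.0 < f <= 1.0 for f in self.subsample_fractions):
            raise ValueError("subsample fractions must lie in (0, 1]")


@dataclass
class EvalReport:
    """Per-fold held-out-test AUCs for one (augmentation, fraction) setting."""

    fold_aucs: list[float]
    mode: str
    subsample_fraction: float = 1.0
    val_curves: list[list[float]] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_aucs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean"] = self.mean
        d["std"] = self.std
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


class Adam:
    """Adaptive-moment gradient descent over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def auc(labels, scores) -> float:
    """Rank-based area under the ROC curve; ties counted half.

    Equals the probability that a random positive outscores a random
    negative, with ties contributing 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pad_batch(token_lists: list[np.ndarray]) -> np.ndarray:
    """Right-pad variable-length token sequences with [PAD] into a matrix."""
    T = max(len(t) for t in token_lists)
    out = np.full((len(token_lists), T), PAD, dtype=np.int64)
    for i, t in enumerate(token_lists):
        out[i, :len(t)] = t
    return out


def _batches(n: int, batch_size: int, rng: np.random.Generator,
             lengths: np.ndarray | None = None):
    """Shuffled mini-batch index stream.

    When ``lengths`` is given, indices are locally sorted by length inside
    shuffled pools of a few batches (standard length bucketing): batches
    stay approximately i.i.d. while padding waste — and hence the quadratic
    attention cost — drops sharply for variable-length corpora.
    """
    order = rng.permutation(n)
    if lengths is None:
        for i in range(0, n, batch_size):
            yield order[i:i + batch_size]
        return
    pool = batch_size * 4
    batches = []
    for i in range(0, n, pool):
        chunk = order[i:i + pool]
        chunk = chunk[np.argsort(lengths[chunk], kind="stable")]
        for j in range(0, len(chunk), batch_size):
            batches.append(chunk[j:j + batch_size])
    for i in rng.permutation(len(batches)):
        yield batches[i]


def pretrain(model: TransformerEncoder, sequences: list[LabeledSequence],
             cfg: TrainConfig, rng: np.random.Generator) -> list[float]:
    """Masked-language-model pre-training; returns per-epoch mean losses."""
    opt = Adam(model.params, lr=cfg.lr_pretrain)
    toks = [s.tokens for s in sequences]
    lengths = np.asarray([len(t) for t in toks])
    history = []
    for _ in range(cfg.max_epochs_pretrain):
        losses = []
        for idx in _batches(len(toks), cfg.batch_size, rng, lengths):
            batch = pad_batch([toks[i] for i in idx])
            corrupted, targets, rows, cols = mlm_corrupt(
                batch, model.config.vocab_size, rng, cfg.mask_prob)
            if len(rows) == 0:
                continue
            loss, _, grads = model.mlm_forward(
                corrupted, targets, rows, cols, training=True, rng=rng,
                with_grads=True)
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)) if losses else float("nan"))
    return history


def _score(model: TransformerEncoder, sequences: list[LabeledSequence],
           aug: AugmentationConfig | None, batch_size: int = 64) -> np.ndarray:
    """Deterministic eval-path scores for a sequence list (length-sorted
    internally to avoid padding waste, returned in input order)."""
    order = np.argsort([len(s.tokens) for s in sequences], kind="stable")
    scores = np.empty(len(sequences))
    for i in range(0, len(sequences), batch_size):
        idx = order[i:i + batch_size]
        batch = pad_batch([sequences[j].tokens for j in idx])
        p, _ = model.classify_forward(batch, aug=aug, training=False)
        scores[idx] = p
    return scores


def finetune(model: TransformerEncoder, train_seqs: list[LabeledSequence],
             val_seqs: list[LabeledSequence],
             aug: AugmentationConfig | None, cfg: TrainConfig,
             rng: np.random.Generator,
             baseline: BaselineConfig | None = None
             ) -> tuple[TransformerEncoder, list[float]]:
    """Fine-tune with early stopping on validation AUC; the best-epoch
    parameters are restored before returning."""
    opt = Adam(model.params, lr=cfg.lr_finetune)
    y_val = np.asarray([s.label for s in val_seqs])
    lengths = np.asarray([len(s.tokens) for s in train_seqs])
    best_auc, best_params, since_best = -np.inf, None, 0
    curve: list[float] = []
    for _ in range(cfg.max_epochs_finetune):
        for idx in _batches(len(train_seqs), cfg.batch_size, rng, lengths):
            batch = pad_batch([train_seqs[i].tokens for i in idx])
            labels = np.asarray([train_seqs[i].label for i in idx])
            _, _, grads = model.classify_loss(
                batch, labels, aug=aug, baseline=baseline, training=True,
                rng=rng, with_grads=True)
            opt.step(model.params, grads)
        try:
            val_auc = auc(y_val, _score(model, val_seqs, aug))
        except ValueError:
            warnings.warn("single-class validation fold; stopping on loss "
                          "is unavailable, keeping last epoch", RuntimeWarning)
            val_auc = 0.5
        curve.append(val_auc)
        if val_auc > best_auc:
            best_auc, since_best = val_auc, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model, curve


def finetune_cv(pretrained: TransformerEncoder,
                folds: list[list[LabeledSequence]],
                test_seqs: list[LabeledSequence],
                aug: AugmentationConfig | None, cfg: TrainConfig,
                baseline: BaselineConfig | None = None,
                subsample_fraction: float = 1.0) -> EvalReport:
    """Repeated fine-tuning: each fold in turn is the early-stopping
    validation set, the rest are training data; every run starts from the
    same pre-trained parameters and is scored on the untouched test set."""
    y_test = np.asarray([s.label for s in test_seqs])
    fold_aucs, curves = [], []
    for i in range(len(folds)):
        train = [s for j, f in enumerate(folds) if j != i for s in f]
        model = TransformerEncoder(
            pretrained.config,
            params={k: v.copy() for k, v in pretrained.params.items()})
        rng = np.random.default_rng([cfg.seed, i])
        model, curve = finetune(model, train, folds[i], aug, cfg, rng,
                                baseline=baseline)
        fold_aucs.append(auc(y_test, _score(model, test_seqs, aug)))
        curves.append(curve)
    mode = baseline.kind if baseline is not None else (
        aug.mode if aug is not None else "none")
    return EvalReport(fold_aucs=fold_aucs, mode=mode,
                      subsample_fraction=subsample_fraction, val_curves=curves)


def _stratified_folds(sequences: list[LabeledSequence], k: int,
                      seed: int) -> list[list[LabeledSequence]]:
    y = np.asarray([s.label for s in sequences])
    if len(np.unique(y)) < 2 or len(sequences) < k:
        parts = np.array_split(np.arange(len(sequences)), k)
        return [[sequences[i] for i in part] for part in parts]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [[sequences[i] for i in val]
            for _, val in skf.split(np.zeros(len(y)), y)]


def subsample_experiment(pretrained: TransformerEncoder,
                         folds: list[list[LabeledSequence]],
                         test_seqs: list[LabeledSequence],
                         aug: AugmentationConfig | None,
                         fractions: tuple[float, ...], cfg: TrainConfig,
                         baseline: BaselineConfig | None = None
                         ) -> list[EvalReport]:
    """Data-insufficiency sweep: label-stratified subsample of the
    fine-tuning pool at each fraction, then the full CV protocol."""
    reports = []
    for frac in fractions:
        if frac == 1.0:
            sub_folds = folds
        else:
            pool = [s for f in folds for s in f]
            rng = np.random.default_rng([cfg.seed, int(round(frac * 1000))])
            keep: list[LabeledSequence] = []
            for label in (0, 1):
                grp = [s for s in pool if s.label == label]
                n_keep = round(frac * len(grp))
                sel = rng.choice(len(grp), size=n_keep, replace=False)
                keep.extend(grp[i] for i in sorted(sel))
            sub_folds = _stratified_folds(keep, len(folds), cfg.seed)
        reports.append(finetune_cv(pretrained, sub_folds, test_seqs, aug, cfg,
                                   baseline=baseline, subsample_fraction=frac))
    return reports


# --------------------------------------------------------------------------
# desk-scale directional benchmark
# --------------------------------------------------------------------------

def benchmark_cohort_spec(seed: int) -> CohortSpec:
    """Reduced-scale long-sequence cohort for the directional benchmark.

    Keeps the defining shape of the long-history cohort (about 19 visits
    per patient) but shrinks patient count, vocabulary and codes/visit so a
    full pre-train + 5-fold fine-tune cycle runs in minutes on one CPU.
    One long-offset motif (minimum 10 visits between its two codes) plants
    signal that requires distant-token interaction.
    """
    spec = preset("mdc_like", n_patients=800, seed=seed)
    spec.n_diag = 150
    spec.n_med = 20
    spec.mean_codes_per_visit = 3.0
    spec.base_rate = 0.2
    spec.motifs = [Motif("A120", "A240", min_offset=10, log_odds=3.0,
                         plant_prob=0.5)]
    return spec


def benchmark_encoder_config(vocab_size: int) -> EncoderConfig:
    return EncoderConfig(vocab_size=vocab_size, d_model=48, n_heads=3,
                         d_k=16, d_v=16, n_layers=2, d_ff=96, max_len=160,
                         dropout=0.1, pooling="mean")


def directional_benchmark(seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                          sigma_eh: float = 1.0,
                          train_cfg: TrainConfig | None = None) -> dict:
    """Mean held-out-test AUC of the fine-tuned encoder with and without
    ANAA on the reduced long-sequence cohort, over several seeds.

    Returns per-seed mean AUCs per mode plus the generator's Bayes ceiling.
    A stochastic smoke surface: it checks the *direction* of the effect at
    desk scale, not any full-scale performance number.
    """
    cfg = train_cfg or TrainConfig(batch_size=16, max_epochs_pretrain=40,
                                   max_epochs_finetune=24, patience=5,
                                   lr_finetune=1e-3)
    results: dict[str, list[float]] = {"none": [], "ANAA": []}
    ceilings = []
    for seed in seeds:
        spec = benchmark_cohort_spec(seed)
        cohort = generate_cohort(spec)
        ceilings.append(bayes_auc(cohort))
        sequences, vocab = tokenize_cohort(
            cohort.trajectories, target_codes=[spec.target_code],
            min_count=5, max_len=160)
        by_id = {s.patient_id: s for s in sequences}
        labels = {s.patient_id: s.label for s in sequences}
        pre_ids, fold_ids, test_ids = split_cohort(
            list(by_id), [labels[p] for p in by_id],
            SplitSpec(seed=seed))
        pre = [by_id[p] for p in pre_ids]
        folds = [[by_id[p] for p in f] for f in fold_ids]
        test = [by_id[p] for p in test_ids]

        model = TransformerEncoder(benchmark_encoder_config(len(vocab)),
                                   seed=seed)
        run_cfg = TrainConfig(**{**asdict(cfg), "seed": seed})
        pretrain(model, pre, run_cfg, np.random.default_rng([seed, 99]))
        for mode in ("none", "ANAA"):
            aug = AugmentationConfig(mode=mode, sigma_eh=sigma_eh,
                                     training=True, rng_seed=seed)
            report = finetune_cv(model, folds, test, aug, run_cfg)
            results[mode].append(report.mean)
    return {
        "mean_auc": {m: float(np.mean(v)) for m, v in results.items()},
        "per_seed": results,
        "bayes_auc": float(np.mean(ceilings)),
        "seeds": list(seeds),
    }
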
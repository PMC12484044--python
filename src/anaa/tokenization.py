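"""Trajectory tokenization for longitudinal medical-code sequences.

A patient trajectory is an ordered list of visits, each a set of diagnosis
(ICD-like) and medication (ATC-like) code strings.  The pipeline here turns
trajectories into BERT-style token sequences:

* codes are normalised (dots stripped, truncated to 4 characters) and rare
  codes are mapped to ``[UNK]``;
* each sequence starts with ``[CLS]`` and every visit is terminated by
  ``[SEP]``;
* outcome labels follow first-occurrence semantics with positive-case
  truncation: the first visit containing a target code and everything after
  it are removed, so the model only ever sees pre-outcome history;
* cohorts are split patient-level into pre-training / fine-tuning / test
  pools, with the fine-tuning pool partitioned into label-stratified folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "SPECIAL_TOKENS", "PAD", "CLS", "SEP", "MASK", "UNK",
    "PatientTrajectory", "Vocabulary", "LabeledSequence", "SplitSpec",
    "normalize_code", "build_vocabulary", "build_sequence", "make_label",
    "filter_min_visits", "split_cohort", "tokenize_cohort",
    "read_jsonl", "write_jsonl",
]

# Fixed special-token ordering for reproducibility.
SPECIAL_TOKENS = ("[PAD]", "[CLS]", "[SEP]", "[MASK]", "[UNK]")
PAD, CLS, SEP, MASK, UNK = range(5)


@dataclass
class PatientTrajectory:
    """Ordered visits of medical codes for one patient.

    Each visit is the set of diagnosis and medication codes recorded at that
    encounter; visit order is temporal.
    """

    patient_id: str
    visits: list[set[str]]

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class Vocabulary:
    """Code-to-index map with the 5 special tokens at reserved low indices."""

    code_to_index: dict[str, int]
    frequencies: dict[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.code_to_index) + len(SPECIAL_TOKENS)

    def index(self, code: str) -> int:
        return self.code_to_index.get(code, UNK)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "special_tokens": list(SPECIAL_TOKENS),
            "code_to_index": self.code_to_index,
            "frequencies": self.frequencies,
            "min_count": self.min_count,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        d = json.loads(Path(path).read_text())
        return cls(code_to_index=d["code_to_index"],
                   frequencies=d["frequencies"], min_count=d["min_count"])


@dataclass
class LabeledSequence:
    """Tokenized trajectory: [CLS] V1 [SEP] V2 [SEP] ... with a binary label."""

    patient_id: str
    tokens: np.ndarray          # int64, length <= max_len
    label: int
    n_visits_used: int


@dataclass
class SplitSpec:
    """Patient-level split fractions plus the fold count for fine-tuning CV."""

    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def normalize_code(code: str) -> str:
    """Strip dots and keep the first 4 characters ("I50.1" -> "I501",
    "C09AA05" -> "C09A"); shorter codes pass through unchanged."""
    if not code:
        raise ValueError("empty code string")
    return code.replace(".", "")[:4]


def build_vocabulary(cohort: Iterable[PatientTrajectory], min_count: int = 5) -> Vocabulary:
    """Count normalised codes over the cohort and index those with frequency
    >= min_count; everything rarer maps to [UNK].  Index assignment is
    deterministic: frequency descending, then code ascending."""
    freqs: dict[str, int] = {}
    for traj in cohort:
        for visit in traj.visits:
            for code in visit:
                c = normalize_code(code)
                freqs[c] = freqs.get(c, 0) + 1
    kept = sorted((c for c, f in freqs.items() if f >= min_count),
                  key=lambda c: (-freqs[c], c))
    code_to_index = {c: i + len(SPECIAL_TOKENS) for i, c in enumerate(kept)}
    return Vocabulary(code_to_index=code_to_index, frequencies=freqs,
                      min_count=min_count)


def build_sequence(traj: PatientTrajectory, vocab: Vocabulary,
                   max_len: int = 512) -> np.ndarray:
    """[CLS], then each visit's normalised codes in lexicographic order
    followed by [SEP].  Over-length sequences keep the most recent visits
    that fit (the [CLS] token is always retained); a single visit longer
    than the budget is tail-truncated to fit."""
    per_visit: list[list[int]] = []
    for visit in traj.visits:
        codes = sorted({normalize_code(c) for c in visit})
        per_visit.append([vocab.index(c) for c in codes] + [SEP])
    # walk backwards, keeping whole recent visits that fit after [CLS]
    budget = max_len - 1
    kept: list[list[int]] = []
    used = 0
    for visit_tokens in reversed(per_visit):
        if used + len(visit_tokens) > budget:
            if not kept:  # single over-long visit: keep its tail, then [SEP]
                kept.append(visit_tokens[-budget:])
                used = budget
            break
        kept.append(visit_tokens)
        used += len(visit_tokens)
    kept.reverse()
    tokens = [CLS] + [t for visit_tokens in kept for t in visit_tokens]
    return np.asarray(tokens, dtype=np.int64)


def make_label(traj: PatientTrajectory, target_codes: Sequence[str],
               excluded_codes: Sequence[str] = ()) -> tuple[PatientTrajectory, int] | None:
    """First-occurrence outcome labelling with positive-case truncation.

    ``excluded_codes`` (e.g. treatment medications that would leak outcome
    timing) are removed from every visit *before* target detection.  If any
    remaining visit contains a target code the patient is positive and the
    trajectory is cut strictly before that visit; otherwise negative with
    the full trajectory.  A positive whose target occurs in visit 1 has no
    usable history and is dropped (returns None).
    """
    if not target_codes:
        raise ValueError("target_codes must be non-empty")
    targets = {normalize_code(c) for c in target_codes}
    excluded = {normalize_code(c) for c in excluded_codes}
    cleaned = [{normalize_code(c) for c in visit} - excluded
               for visit in traj.visits]
    for i, visit in enumerate(cleaned):
        if visit & targets:
            if i == 0:
                logger.info("dropping %s: target in first visit", traj.patient_id)
                return None
            return PatientTrajectory(traj.patient_id, cleaned[:i]), 1
    return PatientTrajectory(traj.patient_id, cleaned), 0


def filter_min_visits(cohort: Sequence[PatientTrajectory], threshold: int
                      ) -> list[PatientTrajectory]:
    """Keep patients with at least ``threshold`` visits (inclusive bound:
    'fewer than threshold' are excluded)."""
    return [t for t in cohort if t.n_visits >= threshold]


def split_cohort(patient_ids: Sequence[str], labels: Sequence[int] | None,
                 spec: SplitSpec) -> tuple[list[str], list[list[str]], list[str]]:
    """Seeded patient-level split into (pretrain, fine-tune folds, test).

    The fine-tuning pool is partitioned into ``k_folds`` label-stratified
    folds when labels are supplied (stratification keeps the small positive
    counts balanced across folds).
    """
    ids = list(patient_ids)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    n_pre = round(spec.fractions[0] * len(ids))
    n_ft = round(spec.fractions[1] * len(ids))
    pre = [ids[i] for i in order[:n_pre]]
    ft = [ids[i] for i in order[n_pre:n_pre + n_ft]]
    test = [ids[i] for i in order[n_pre + n_ft:]]

    if labels is not None:
        lab = dict(zip(ids, labels))
        y = np.asarray([lab[p] for p in ft])
        if len(np.unique(y)) > 1 and len(ft) >= spec.k_folds:
            skf = StratifiedKFold(n_splits=spec.k_folds, shuffle=True,
                                  random_state=spec.seed)
            folds = [[ft[i] for i in val_idx]
                     for _, val_idx in skf.split(np.zeros(len(ft)), y)]
        else:
            folds = [list(f) for f in np.array_split(ft, spec.k_folds)]
    else:
        folds = [list(f) for f in np.array_split(ft, spec.k_folds)]
    return pre, folds, test


def tokenize_cohort(cohort: Sequence[PatientTrajectory],
                    target_codes: Sequence[str],
                    excluded_codes: Sequence[str] = (),
                    vocab: Vocabulary | None = None,
                    min_count: int = 5,
                    max_len: int = 512,
                    min_visits: int | None = None) -> tuple[list[LabeledSequence], Vocabulary]:
    """Label, filter and tokenize a cohort end to end.

    The minimum-visit filter is applied to the label-truncated trajectory —
    i.e. to the history the model will actually see.  The vocabulary, unless
    supplied, is built from the surviving truncated trajectories.
    """
    labelled: list[tuple[PatientTrajectory, int]] = []
    for traj in cohort:
        out = make_label(traj, target_codes, excluded_codes)
        if out is None:
            continue
        truncated, label = out
        if min_visits is not None and truncated.n_visits < min_visits:
            continue
        labelled.append((truncated, label))
    if vocab is None:
        vocab = build_vocabulary((t for t, _ in labelled), min_count=min_count)
    sequences = [
        LabeledSequence(patient_id=t.patient_id,
                        tokens=build_sequence(t, vocab, max_len),
                        label=y, n_visits_used=t.n_visits)
        for t, y in labelled
    ]
    return sequences, vocab


def write_jsonl(cohort: Iterable[PatientTrajectory], path: str | Path,
                labels: dict[str, int] | None = None) -> None:
    """One patient per line: {"patient_id", "visits": [{"codes": [...]}, ...]}."""
    with open(path, "w") as fh:
        for traj in cohort:
            rec = {"patient_id": traj.patient_id,
                   "visits": [{"codes": sorted(v)} for v in traj.visits]}
            if labels is not None and traj.patient_id in labels:
                rec["label"] = int(labels[traj.patient_id])
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path: str | Path) -> tuple[list[PatientTrajectory], dict[str, int]]:
    """Read the line-delimited patient format; returns trajectories plus any
    pre-assigned labels found on the records."""
    cohort, labels = [], {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            cohort.append(PatientTrajectory(
                patient_id=str(rec["patient_id"]),
                visits=[set(v["codes"]) for v in rec["visits"]]))
            if "label" in rec:
                labels[str(rec["patient_id"])] = int(rec["label"])
    return cohort, labels
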
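"""Seeded synthetic cohorts of longitudinal coded trajectories.

Real EHR corpora of this shape (hospital admission streams, long
population-cohort histories) are access-restricted, so every other module
is exercised on synthetic cohorts that emulate their shape statistics:
per-patient visit counts from a negative-binomial-shaped distribution
(EHR visit counts are over-dispersed), codes per visit from a shifted
Poisson, and code popularity from a power law (a few chronic-disease and
common-medication codes dominate).

Outcome signal is planted through *motifs*: a motif is an ordered code pair
(a, b) with a minimum visit offset; it "fires" for a patient when code a
occurs in some visit and code b occurs at least ``min_offset`` visits
later.  The outcome is drawn from a logistic model whose logit is the
base-rate logit plus the log-odds of every fired motif, so the generator
knows the Bayes-optimal score for each patient.  Positive patients receive
the target code in a final appended visit, so the labelling module's
positive-case truncation reconstructs exactly the generated history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tokenization import PatientTrajectory

__all__ = ["Motif", "CohortSpec", "GeneratedCohort", "generate_cohort",
           "preset", "bayes_auc"]


@dataclass(frozen=True)
class Motif:
    """Ordered code pair with a minimum visit offset and a log-odds effect.

    ``plant_prob`` is the probability the pair is explicitly planted into a
    patient's history (code_a early, code_b at least ``min_offset`` visits
    later, visit count permitting); the pair can also fire by chance.
    """

    code_a: str
    code_b: str
    min_offset: int = 0
    log_odds: float = 0.0
    plant_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.min_offset < 0:
            raise ValueError("min_offset must be >= 0")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort."""

    n_patients: int = 1000
    n_diag: int = 300
    n_med: int = 40
    mean_visits: float = 9.0
    visit_dispersion: float = 3.0     # negative-binomial shape; smaller = burstier
    mean_codes_per_visit: float = 5.0
    popularity_exponent: float = 1.0  # power-law exponent of code popularity
    motifs: list[Motif] = field(default_factory=list)
    base_rate: float = 0.2
    target_code: str = "I500"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must lie in (0, 1)")
        if self.mean_codes_per_visit > self.n_diag + self.n_med:
            raise ValueError("codes per visit exceeds vocabulary size")
        if self.mean_visits < 1 or self.n_patients < 1:
            raise ValueError("mean_visits and n_patients must be >= 1")

    def code_universe(self) -> list[str]:
        return diag_codes(self.n_diag) + med_codes(self.n_med)


def diag_codes(n: int) -> list[str]:
    """ICD-like 4-character codes: letter + 3 digits ("A001", "B042", ...)."""
    if n > 26_000:
        raise ValueError("at most 26000 diagnosis codes supported")
    return [f"{chr(65 + i // 1000)}{i % 1000:03d}" for i in range(n)]


def med_codes(n: int) -> list[str]:
    """ATC-like short codes, lowercase-led so they never collide with the
    diagnosis codes ("a00", "a01", ...)."""
    if n > 2_600:
        raise ValueError("at most 2600 medication codes supported")
    return [f"{chr(97 + i // 100)}{i % 100:02d}" for i in range(n)]


@dataclass
class GeneratedCohort:
    """A generated cohort plus its ground truth.

    ``true_logits`` are the generator's own outcome logits (base rate plus
    fired-motif effects) — the Bayes-optimal score any classifier could at
    best recover.  ``log`` records the realised shape statistics.
    """

    trajectories: list[PatientTrajectory]
    labels: dict[str, int]
    true_logits: dict[str, float]
    spec: CohortSpec
    log: dict

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.log, indent=1))


def _sample_visit_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # shifted negative binomial with mean `mean` and >= 1 visit
    m = max(mean - 1.0, 1e-9)
    p = dispersion / (dispersion + m)
    return 1 + int(rng.negative_binomial(dispersion, p))


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw a cohort from ``spec`` (fully reproducible from its seed)."""
    rng = np.random.default_rng(spec.seed)
    universe = np.asarray(spec.code_universe())
    ranks = np.arange(1, len(universe) + 1, dtype=float)
    pop = ranks ** (-spec.popularity_exponent)
    pop /= pop.sum()
    # popularity is assigned to a seeded shuffle of the universe so motif
    # codes are not automatically the most popular ones
    shuffled = rng.permutation(len(universe))
    code_probs = np.empty(len(universe))
    code_probs[shuffled] = pop

    base_logit = float(np.log(spec.base_rate / (1.0 - spec.base_rate)))
    trajectories: list[PatientTrajectory] = []
    labels: dict[str, int] = {}
    true_logits: dict[str, float] = {}
    n_pos = 0
    tot_visits = 0
    tot_codes = 0

    for idx in range(spec.n_patients):
        pid = f"P{idx:06d}"
        n_visits = _sample_visit_count(rng, spec.mean_visits, spec.visit_dispersion)
        visits: list[set[str]] = []
        for _ in range(n_visits):
            n_codes = 1 + rng.poisson(max(spec.mean_codes_per_visit - 1.0, 0.0))
            n_codes = min(n_codes, len(universe))
            chosen = rng.choice(len(universe), size=n_codes, replace=False,
                                p=code_probs)
            visits.append(set(universe[chosen]))

        # plant motif occurrences
        for motif in spec.motifs:
            if n_visits > motif.min_offset and rng.random() < motif.plant_prob:
                ia = int(rng.integers(0, n_visits - motif.min_offset))
                ib = int(rng.integers(ia + motif.min_offset, n_visits))
                visits[ia].add(motif.code_a)
                visits[ib].add(motif.code_b)

        logit = base_logit
        for motif in spec.motifs:
            if _motif_fires(visits, motif):
                logit += motif.log_odds
        p_outcome = float(np.clip(1.0 / (1.0 + np.exp(-logit)), 1e-6, 1 - 1e-6))
        label = int(rng.random() < p_outcome)
        if label:
            visits = visits + [{spec.target_code}]
            n_pos += 1

        trajectories.append(PatientTrajectory(pid, visits))
        labels[pid] = label
        true_logits[pid] = logit
        tot_visits += n_visits
        tot_codes += sum(len(v) for v in visits[:n_visits])

    log = {
        "n_patients": spec.n_patients,
        "positive_fraction": n_pos / spec.n_patients,
        "realized_mean_visits": tot_visits / spec.n_patients,
        "realized_mean_codes_per_visit": tot_codes / max(tot_visits, 1),
        "seed": spec.seed,
    }
    return GeneratedCohort(trajectories=trajectories, labels=labels,
                           true_logits=true_logits, spec=spec, log=log)


def _motif_fires(visits: list[set[str]], motif: Motif) -> bool:
    first_a = None
    for i, v in enumerate(visits):
        if motif.code_a in v:
            first_a = i
            break
    if first_a is None:
        return False
    return any(motif.code_b in visits[j]
               for j in range(first_a + motif.min_offset, len(visits)))


def preset(name: str, n_patients: int = 2000, seed: int = 0) -> CohortSpec:
    """Named cohort shapes.

    ``mimic_like``: hospital-admission shape — about 9 visits/patient,
    2195 diagnosis + 137 medication codes, about 61 codes/patient.
    ``mdc_like``: long population-cohort shape — about 19 visits/patient,
    1558 diagnosis + 111 medication codes, about 257 codes/patient.
    """
    if name == "mimic_like":
        return CohortSpec(n_patients=n_patients, n_diag=2195, n_med=137,
                          mean_visits=9.0, visit_dispersion=3.0,
                          mean_codes_per_visit=61 / 9, seed=seed)
    if name == "mdc_like":
        return CohortSpec(n_patients=n_patients, n_diag=1558, n_med=111,
                          mean_visits=19.0, visit_dispersion=4.0,
                          mean_codes_per_visit=257 / 19, seed=seed)
    raise ValueError(f"unknown preset {name!r}")


def bayes_auc(cohort: GeneratedCohort) -> float:
    """AUC of the generator's true logits against the drawn labels — the
    ceiling any classifier can reach on this cohort."""
    from .training import auc
    pids = [t.patient_id for t in cohort.trajectories]
    y = np.asarray([cohort.labels[p] for p in pids])
    s = np.asarray([cohort.true_logits[p] for p in pids])
    return auc(y, s)
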
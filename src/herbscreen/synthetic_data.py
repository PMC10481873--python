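"""Synthetic prescription cohorts with a planted effective core.

The original 745-case clinical cohort behind the method is not publicly
deposited, so this module generates cohorts with the same statistical
shape — 745 binary prescriptions over a 334-herb vocabulary, formula sizes
around 8-16 herbs, local herb co-occurrence, and an effective/ineffective
class balance of roughly 617:128 — plus a known ground truth: a planted
"effective core" combination whose presence raises the probability that a
prescription is labelled effective.

Labels follow a logistic model: a record containing k of the core herbs is
effective with probability sigmoid(intercept + core_effect * k), then the
label is flipped with a small noise probability.  The intercept is
calibrated once by root finding so that the expected ineffective fraction
matches the target class balance; the calibrated value is echoed in the
truth block.  Core herbs occupy a contiguous vocabulary block by default,
which exercises the locality the convolutional classifier is built around;
a scattered layout is available for robustness checks.

Because the core is known, an end-to-end run (train classifier, search
with the genetic algorithm) can be scored by the Jaccard overlap between
the returned combination and the planted core (:func:`recovery_score`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from herbscreen.ga import Individual
from herbscreen.prescriptions import (
    EncodedCohort,
    HerbVocabulary,
    Outcome,
    PrescriptionRecord,
)

__all__ = [
    "SyntheticSpec",
    "GeneratedCohort",
    "scattered_core",
    "calibrate_intercept",
    "generate_cohort",
    "recovery_score",
    "write_truth",
]

#: Ineffective fraction of the published cohort: 128 progressive of 745.
DEFAULT_INEFFECTIVE_FRACTION = 128.0 / 745.0

#: Relative frequencies of the three effective outcome categories
#: (complete remission : partial remission : stable = 9 : 95 : 513).
_EFFECTIVE_OUTCOME_PROBS = np.array([9.0, 95.0, 513.0]) / 617.0
_EFFECTIVE_OUTCOMES = (
    Outcome.COMPLETE_REMISSION,
    Outcome.PARTIAL_REMISSION,
    Outcome.STABLE,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a planted-core prescription cohort.

    ``core_herbs`` is the planted combination as vocabulary indices; when
    ``None`` it defaults to a contiguous block of ``core_size`` herbs in
    the middle of the vocabulary.  ``core_effect`` is the log-odds boost
    per core herb present; ``intercept`` is the baseline log-odds of an
    effective label and is calibrated automatically when ``None``.
    ``core_inclusion_rate`` is the per-herb probability that a record's
    formula includes each core herb, which spreads the per-record core
    count over an informative range.
    """

    n_records: int = 745
    vocab_size: int = 334
    core_herbs: tuple[int, ...] | None = None
    core_size: int = 12
    core_effect: float = 2.0
    intercept: float | None = None
    target_ineffective: float = DEFAULT_INEFFECTIVE_FRACTION
    formula_size_range: tuple[int, int] = (8, 16)
    block_size: int = 4
    label_noise: float = 0.05
    core_inclusion_rate: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.vocab_size < 1:
            raise ValueError("n_records and vocab_size must be positive")
        lo, hi = self.formula_size_range
        if not 1 <= lo <= hi:
            raise ValueError("formula_size_range must satisfy 1 <= min <= max")
        if hi > self.vocab_size:
            raise ValueError(
                f"max formula size {hi} exceeds vocabulary size {self.vocab_size}"
            )
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        if not 0.0 <= self.core_inclusion_rate <= 1.0:
            raise ValueError("core_inclusion_rate must lie in [0, 1]")
        if not 0.0 < self.target_ineffective < 1.0:
            raise ValueError("target_ineffective must lie in (0, 1)")
        if self.core_herbs is None:
            start = (self.vocab_size - self.core_size) // 2
            if start < 0:
                raise ValueError("core_size exceeds vocabulary size")
            core = tuple(range(start, start + self.core_size))
        else:
            core = tuple(int(i) for i in self.core_herbs)
        if any(i < 0 or i >= self.vocab_size for i in core):
            raise ValueError("core herb indices must lie in [0, vocab_size)")
        if len(set(core)) != len(core):
            raise ValueError("core herb indices must be unique")
        object.__setattr__(self, "core_herbs", core)
        object.__setattr__(self, "core_size", len(core))
        object.__setattr__(
            self, "formula_size_range", (int(lo), int(hi))
        )


def scattered_core(vocab_size: int, size: int, seed: int = 0) -> tuple[int, ...]:
    """A non-contiguous planted core: ``size`` indices sampled without replacement."""
    rng = np.random.default_rng(seed)
    return tuple(sorted(int(i) for i in rng.choice(vocab_size, size=size, replace=False)))


def _herb_names(vocab_size: int) -> tuple[str, ...]:
    width = len(str(vocab_size))
    return tuple(f"herb{str(i + 1).zfill(width)}" for i in range(vocab_size))


def _sample_formula(spec: SyntheticSpec, rng: np.random.Generator) -> set[int]:
    """Herb index set of one record: core subset, co-occurrence blocks, singletons."""
    core = np.asarray(spec.core_herbs)
    herbs: set[int] = set(core[rng.random(core.size) < spec.core_inclusion_rate].tolist())
    lo, hi = spec.formula_size_range
    size = int(rng.integers(lo, hi + 1))
    while len(herbs) < size:
        if size - len(herbs) >= spec.block_size and rng.random() < 0.7:
            start = int(rng.integers(0, spec.vocab_size - spec.block_size + 1))
            for idx in range(start, start + spec.block_size):
                if len(herbs) < size:
                    herbs.add(idx)
        else:
            herbs.add(int(rng.integers(spec.vocab_size)))
    return herbs


def _simulate_core_counts(spec: SyntheticSpec, n_sim: int, seed: tuple) -> np.ndarray:
    rng = np.random.default_rng(seed)
    core = set(spec.core_herbs)
    return np.array(
        [len(_sample_formula(spec, rng) & core) for _ in range(n_sim)], dtype=np.int64
    )


def calibrate_intercept(spec: SyntheticSpec, n_sim: int = 4000) -> float:
    """Root-find the intercept matching the target ineffective fraction.

    Simulates the per-record core-count distribution under the spec's own
    formula sampler and solves for the intercept at which the expected
    observed effective fraction (including label noise) equals
    ``1 - target_ineffective``.  Deterministic given the spec.
    """
    counts = _simulate_core_counts(spec, n_sim, (spec.seed, 0x5EED))
    target = 1.0 - spec.target_ineffective

    def gap(c: float) -> float:
        p_eff = expit(c + spec.core_effect * counts).mean()
        observed = p_eff * (1.0 - 2.0 * spec.label_noise) + spec.label_noise
        return observed - target

    if gap(-80.0) > 0 or gap(80.0) < 0:
        raise ValueError("target class balance is unreachable (label noise too high?)")
    return float(brentq(gap, -80.0, 80.0, xtol=1e-10))


@dataclass(frozen=True)
class GeneratedCohort:
    """A synthetic cohort plus its generative ground truth."""

    cohort: EncodedCohort
    vocab: HerbVocabulary
    records: tuple[PrescriptionRecord, ...]
    spec: SyntheticSpec  # echo, with the calibrated intercept filled in
    probabilities: np.ndarray  # (n_records,) pre-noise effective probability

    @property
    def core_indices(self) -> tuple[int, ...]:
        return self.spec.core_herbs

    def truth(self) -> dict:
        return {
            "core_indices": list(self.spec.core_herbs),
            "core_herbs": [self.vocab.names[i] for i in self.spec.core_herbs],
            "intercept": self.spec.intercept,
            "core_effect": self.spec.core_effect,
            "label_noise": self.spec.label_noise,
            "core_inclusion_rate": self.spec.core_inclusion_rate,
            "target_ineffective": self.spec.target_ineffective,
            "n_records": self.spec.n_records,
            "vocab_size": self.spec.vocab_size,
            "seed": self.spec.seed,
        }


def generate_cohort(spec: SyntheticSpec) -> GeneratedCohort:
    """Draw a full cohort under the spec; fully determined by ``spec.seed``."""
    intercept = spec.intercept
    if intercept is None:
        intercept = calibrate_intercept(spec)
    resolved = dataclasses.replace(spec, intercept=intercept)

    rng = np.random.default_rng((spec.seed, 0xC0A0))
    names = _herb_names(spec.vocab_size)
    vocab = HerbVocabulary(names)
    core = set(spec.core_herbs)

    matrix = np.zeros((spec.n_records, spec.vocab_size), dtype=np.uint8)
    labels = np.zeros(spec.n_records, dtype=np.uint8)
    probs = np.zeros(spec.n_records)
    records: list[PrescriptionRecord] = []
    width = len(str(spec.n_records))
    for i in range(spec.n_records):
        herbs = _sample_formula(spec, rng)
        matrix[i, list(herbs)] = 1
        k = len(herbs & core)
        p_eff = float(expit(intercept + spec.core_effect * k))
        probs[i] = p_eff
        label = int(rng.random() < p_eff)
        if rng.random() < spec.label_noise:
            label = 1 - label
        labels[i] = label
        if label:
            outcome = _EFFECTIVE_OUTCOMES[rng.choice(3, p=_EFFECTIVE_OUTCOME_PROBS)]
        else:
            outcome = Outcome.PROGRESSIVE
        records.append(
            PrescriptionRecord(
                case_id=f"case{str(i + 1).zfill(width)}",
                herbs=frozenset(names[j] for j in herbs),
                outcome=outcome,
            )
        )

    cohort = EncodedCohort(matrix, labels, tuple(r.case_id for r in records))
    return GeneratedCohort(cohort, vocab, tuple(records), resolved, probs)


def recovery_score(best: Individual | np.ndarray, spec: SyntheticSpec) -> float:
    """Jaccard overlap |found ∩ core| / |found ∪ core| with the planted core."""
    genes = best.genes if isinstance(best, Individual) else np.asarray(best)
    found = set(np.flatnonzero(genes).tolist())
    core = set(spec.core_herbs)
    union = found | core
    if not union:
        return 1.0
    return len(found & core) / len(union)


def write_truth(generated: GeneratedCohort, path: str | Path) -> None:
    """Persist the generative ground truth as JSON."""
    Path(path).write_text(json.dumps(generated.truth(), indent=2) + "\n")
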
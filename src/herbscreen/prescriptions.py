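"""Prescription records, herb vocabularies and bag-of-words encoding.

A prescription is a set of herb names administered together, annotated with
a four-level clinical outcome (complete remission / partial remission /
stable / progressive).  The first three outcomes are recoded as *effective*
(label 1) and progression as *ineffective* (label 0).  Each prescription is
encoded as a binary presence/absence vector over a fixed, ordered herb
vocabulary; the dense record x herb matrix plus the binary label vector is
the contract surface consumed by the classifier.

Herb names are matched exactly after whitespace trimming and case folding;
synonym resolution against a pharmacopoeia standard is the caller's job.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "PrescriptionRecord",
    "HerbVocabulary",
    "EncodedCohort",
    "SplitSpec",
    "build_vocabulary",
    "encode",
    "decode",
    "encode_cohort",
    "recode_outcome",
    "split",
    "read_prescriptions",
    "write_prescriptions",
    "read_vocabulary",
    "write_vocabulary",
    "export_cohort_csv",
]


class Outcome(str, enum.Enum):
    """Four-level clinical outcome of one treatment course."""

    COMPLETE_REMISSION = "complete_remission"
    PARTIAL_REMISSION = "partial_remission"
    STABLE = "stable"
    PROGRESSIVE = "progressive"


#: Outcomes recoded to the binary label 1 ("effective").
EFFECTIVE_OUTCOMES = frozenset(
    {Outcome.COMPLETE_REMISSION, Outcome.PARTIAL_REMISSION, Outcome.STABLE}
)


def _normalize_name(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class PrescriptionRecord:
    """One case: an id, a non-empty herb set, and its clinical outcome."""

    case_id: str
    herbs: frozenset[str]
    outcome: Outcome

    def __post_init__(self) -> None:
        normalized = frozenset(_normalize_name(h) for h in self.herbs if h.strip())
        if not normalized:
            raise ValueError(f"record {self.case_id!r} has an empty herb set")
        object.__setattr__(self, "herbs", normalized)
        object.__setattr__(self, "outcome", Outcome(self.outcome))


@dataclass(frozen=True)
class HerbVocabulary:
    """Ordered list of unique herb names; position defines vector index.

    The ordering is meaningful: the classifier's convolutions read local
    neighbourhoods of the vector, so two runs must agree on it.  The
    vocabulary can be persisted to / restored from a TSV for that reason.
    """

    names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("vocabulary must contain at least one herb")
        if len(set(self.names)) != len(self.names):
            raise ValueError("vocabulary names must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self._index[_normalize_name(name)]
        except KeyError:
            raise KeyError(f"herb {name!r} is not in the vocabulary") from None

    def __contains__(self, name: str) -> bool:
        return _normalize_name(name) in self._index

    def __len__(self) -> int:
        return len(self.names)


def build_vocabulary(records: Sequence[PrescriptionRecord]) -> HerbVocabulary:
    """Collect every herb name in first-occurrence order.

    Iterates records in order and, within a record, herb names in sorted
    order (sets carry no order of their own), appending each unseen name.
    """
    if len(records) == 0:
        raise ValueError("cannot build a vocabulary from an empty record set")
    names: list[str] = []
    seen: set[str] = set()
    for rec in records:
        for herb in sorted(rec.herbs):
            if herb not in seen:
                seen.add(herb)
                names.append(herb)
    return HerbVocabulary(tuple(names))


def encode(record: PrescriptionRecord, vocab: HerbVocabulary) -> np.ndarray:
    """Binary presence/absence vector of ``record`` over ``vocab``.

    Entry j is 1 iff the j-th vocabulary herb appears in the record.
    Raises ``KeyError`` naming the first herb missing from the vocabulary.
    """
    vec = np.zeros(vocab.size, dtype=np.uint8)
    for herb in record.herbs:
        vec[vocab.index_of(herb)] = 1
    return vec


def decode(vector: np.ndarray, vocab: HerbVocabulary) -> frozenset[str]:
    """Inverse of :func:`encode`: names of the set positions."""
    vector = np.asarray(vector)
    if vector.shape != (vocab.size,):
        raise ValueError(f"vector length {vector.shape} != vocabulary size {vocab.size}")
    return frozenset(vocab.names[i] for i in np.flatnonzero(vector))


def recode_outcome(outcome: Outcome) -> int:
    """Binary efficacy label: remission/stable -> 1, progression -> 0."""
    return 1 if Outcome(outcome) in EFFECTIVE_OUTCOMES else 0


@dataclass(frozen=True)
class EncodedCohort:
    """Dense binary prescription matrix plus binary efficacy labels."""

    matrix: np.ndarray  # (n_records, vocab_size) uint8 in {0,1}
    labels: np.ndarray  # (n_records,) uint8 in {0,1}; 1 = effective
    case_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.uint8))
        labels = np.asarray(self.labels, dtype=np.uint8)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if labels.shape != (matrix.shape[0],):
            raise ValueError("labels length must equal matrix row count")
        if len(self.case_ids) != matrix.shape[0]:
            raise ValueError("case_ids length must equal matrix row count")
        if matrix.size and matrix.max() > 1:
            raise ValueError("matrix entries must be 0/1")
        if labels.size and labels.max() > 1:
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "case_ids", tuple(self.case_ids))

    @property
    def n_records(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx: np.ndarray) -> "EncodedCohort":
        idx = np.asarray(idx)
        return EncodedCohort(
            self.matrix[idx],
            self.labels[idx],
            tuple(self.case_ids[i] for i in idx),
        )


def encode_cohort(
    records: Sequence[PrescriptionRecord], vocab: HerbVocabulary
) -> EncodedCohort:
    """Encode every record against ``vocab`` and recode its outcome."""
    if len(records) == 0:
        raise ValueError("cannot encode an empty record set")
    matrix = np.stack([encode(r, vocab) for r in records])
    labels = np.array([recode_outcome(r.outcome) for r in records], dtype=np.uint8)
    return EncodedCohort(matrix, labels, tuple(r.case_id for r in records))


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters; defaults realize an 8:2 split."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split(cohort: EncodedCohort, spec: SplitSpec) -> tuple[EncodedCohort, EncodedCohort]:
    """Disjoint, exhaustive train/test partition of a cohort.

    The training set receives floor(train_fraction * n) records; the
    remainder goes to the test set.  In stratified mode (the default) class
    proportions are preserved to within one record per class, with the
    per-class remainders resolved by largest fractional part.  The same seed
    always yields the same partition.
    """
    n = cohort.n_records
    n_train = int(np.floor(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        classes = np.unique(cohort.labels)
        if classes.size < 2:
            raise ValueError("stratified split needs at least two classes")
        for c in classes:
            if int((cohort.labels == c).sum()) < 2:
                raise ValueError(f"class {int(c)} has fewer than 2 records")
        # floor allocation per class, spare slots by largest fractional part
        quotas, fracs = {}, {}
        for c in classes:
            exact = spec.train_fraction * int((cohort.labels == c).sum())
            quotas[int(c)] = int(np.floor(exact))
            fracs[int(c)] = exact - np.floor(exact)
        spare = n_train - sum(quotas.values())
        for c in sorted(fracs, key=lambda c: -fracs[c])[: max(spare, 0)]:
            quotas[c] += 1
        train_parts, test_parts = [], []
        for c in classes:
            members = np.flatnonzero(cohort.labels == c)
            members = rng.permutation(members)
            q = quotas[int(c)]
            train_parts.append(members[:q])
            test_parts.append(members[q:])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
        train_idx = rng.permutation(train_idx)
        test_idx = rng.permutation(test_idx)

    return cohort.subset(np.sort(train_idx)), cohort.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# File formats: prescriptions TSV, vocabulary TSV, dense cohort CSV
# ---------------------------------------------------------------------------

_HERB_SEP = ";"


def read_prescriptions(path: str | Path) -> list[PrescriptionRecord]:
    """Read a UTF-8 TSV with columns ``case_id``, ``herbs``, ``outcome``.

    ``herbs`` is a semicolon-separated name list; ``outcome`` one of the
    four outcome literals.  Unknown outcomes or empty herb lists raise
    ``ValueError`` naming the offending case.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"case_id", "herbs", "outcome"}
    if not required.issubset(df.columns):
        raise ValueError(f"prescriptions file must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            outcome = Outcome(row.outcome.strip())
        except ValueError:
            raise ValueError(
                f"case {row.case_id!r}: unrecognized outcome {row.outcome!r}"
            ) from None
        herbs = frozenset(h for h in row.herbs.split(_HERB_SEP) if h.strip())
        if not herbs:
            raise ValueError(f"case {row.case_id!r}: empty herb list")
        records.append(PrescriptionRecord(str(row.case_id), herbs, outcome))
    return records


def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "herbs": [_HERB_SEP.join(sorted(r.herbs)) for r in records],
            "outcome": [r.outcome.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_vocabulary(path: str | Path) -> HerbVocabulary:
    """Read a vocabulary TSV with columns ``index`` (0-based), ``herb_name``."""
    df = pd.read_csv(path, sep="\t", dtype={"index": int, "herb_name": str})
    if not {"index", "herb_name"}.issubset(df.columns):
        raise ValueError("vocabulary file must have columns index, herb_name")
    df = df.sort_values("index")
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise ValueError("vocabulary indices must be 0..size-1 without gaps")
    return HerbVocabulary(tuple(df["herb_name"]))


def write_vocabulary(vocab: HerbVocabulary, path: str | Path) -> None:
    pd.DataFrame(
        {"index": np.arange(vocab.size), "herb_name": list(vocab.names)}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def export_cohort_csv(
    cohort: EncodedCohort, vocab: HerbVocabulary, path: str | Path
) -> None:
    """Dense CSV: one row per case, one 0/1 column per herb, final ``label``."""
    df = pd.DataFrame(cohort.matrix, columns=list(vocab.names))
    df.insert(0, "case_id", list(cohort.case_ids))
    df["label"] = cohort.labels
    df.to_csv(path, index=False, lineterminator="\n")
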
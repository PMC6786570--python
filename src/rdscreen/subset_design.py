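"""The three pairwise diagnostic subsets and their balanced, seeded assembly.

Instead of one four-way classifier, the pipeline trains three independent
binary problems, each contrasting a clinically coherent composite of rare
diseases against one alternative group:

=======  ===============================================  =========  =======
subset   rare-disease side (class 1)                      class 2    sizes
=======  ===============================================  =========  =======
1        pulmonary hypertension (PAH), cystic fibrosis    NRO        90:90
2        sarcoidosis, syringomyelia, SLE, acromegaly,     CD         90:90
         Ehlers-Danlos syndromes, Morbus Still,
         Nail-Patella syndrome
3        CIDP, cluster headache, Meniere's disease,       PSY        42:38
         Fabry disease
=======  ===============================================  =========  =======

Membership is drawn uniformly at random (seeded) from the eligible pool,
without replacement and without reuse across subsets: each questionnaire
belongs to at most one subset.  The drawn record ids are kept as provenance
so every run is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import RespondentRecord

__all__ = [
    "SubsetDesign",
    "SubsetDataset",
    "CapacityError",
    "default_designs",
    "assemble_subset",
    "assemble_subsets",
]


class CapacityError(ValueError):
    """The eligible pool cannot fill a subset's target class sizes."""


def _norm(s: str) -> str:
    return " ".join(s.strip().lower().split())


@dataclass
class SubsetDesign:
    """Declarative description of one pairwise training subset.

    Class 1 eligibility is by diagnosis membership (case-insensitive) among
    records in the RD group; class 2 eligibility is by diagnostic group
    label (optionally narrowed to a diagnosis list).  The mapping is a
    plain editable dictionary because the original subset memberships are
    not published.
    """

    subset_id: int
    class1_label: str
    class1_diagnoses: frozenset[str]
    class2_label: str
    class2_diagnoses: frozenset[str] = frozenset()
    target_sizes: tuple[int, int] = (90, 90)

    def __post_init__(self) -> None:
        if self.subset_id not in (1, 2, 3):
            raise ValueError("subset_id must be 1, 2 or 3")
        n1, n2 = self.target_sizes
        if n1 <= 0 or n2 <= 0:
            raise ValueError("target sizes must be positive")
        c1 = {_norm(d) for d in self.class1_diagnoses}
        c2 = {_norm(d) for d in self.class2_diagnoses}
        if c1 & c2:
            raise ValueError(f"class diagnosis sets overlap: {c1 & c2}")

    def eligible_class1(self, record: RespondentRecord) -> bool:
        return record.group == "RD" and _norm(record.diagnosis) in {
            _norm(d) for d in self.class1_diagnoses
        }

    def eligible_class2(self, record: RespondentRecord) -> bool:
        if record.group != self.class2_label:
            return False
        if self.class2_diagnoses:
            return _norm(record.diagnosis) in {_norm(d) for d in self.class2_diagnoses}
        return True


@dataclass
class SubsetDataset:
    """A materialized subset: records with binary labels and provenance.

    ``labels`` codes class 1 (the rare-disease side) as 0 and class 2 as 1,
    matching the diagnosis-index convention of the base classifiers.
    """

    subset_id: int
    records: list[RespondentRecord]
    labels: np.ndarray  # 0 = class1 (RD side), 1 = class2
    class1_label: str
    class2_label: str
    record_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels length mismatch")
        if not self.record_ids:
            self.record_ids = [r.record_id for r in self.records]

    @property
    def class_counts(self) -> tuple[int, int]:
        labels = np.asarray(self.labels)
        return int(np.sum(labels == 0)), int(np.sum(labels == 1))


def default_designs() -> list[SubsetDesign]:
    """The three standard pairwise designs with sizes 90:90, 90:90, 42:38."""
    return [
        SubsetDesign(
            subset_id=1,
            class1_label="RD1",
            class1_diagnoses=frozenset({"PAH", "cystic fibrosis"}),
            class2_label="NRO",
            target_sizes=(90, 90),
        ),
        SubsetDesign(
            subset_id=2,
            class1_label="RD2",
            class1_diagnoses=frozenset(
                {
                    "sarcoidosis",
                    "syringomyelia",
                    "SLE",
                    "acromegaly",
                    "Ehlers-Danlos syndrome",
                    "Morbus Still",
                    "Nail-Patella syndrome",
                }
            ),
            class2_label="CD",
            target_sizes=(90, 90),
        ),
        SubsetDesign(
            subset_id=3,
            class1_label="RD3",
            class1_diagnoses=frozenset(
                {"CIDP", "cluster headache", "Meniere disease", "Fabry disease"}
            ),
            class2_label="PSY",
            target_sizes=(42, 38),
        ),
    ]


def assemble_subset(
    pool: Sequence[RespondentRecord],
    design: SubsetDesign,
    seed: int,
    consumed: set[str] | None = None,
) -> SubsetDataset:
    """Draw a balanced subset from the pool by seeded uniform sampling.

    ``consumed`` record ids are skipped and the ids drawn here are added to
    it, enforcing the one-subset-per-questionnaire rule when assembling a
    collection.  Raises :class:`CapacityError` naming the short class when
    the eligible pool is too small.
    """
    consumed = consumed if consumed is not None else set()
    rng = np.random.default_rng(seed)
    elig1 = [r for r in pool if r.record_id not in consumed and design.eligible_class1(r)]
    elig2 = [r for r in pool if r.record_id not in consumed and design.eligible_class2(r)]
    n1, n2 = design.target_sizes
    if len(elig1) < n1:
        raise CapacityError(
            f"subset {design.subset_id} class 1 ({design.class1_label}): "
            f"need {n1} eligible records, have {len(elig1)}"
        )
    if len(elig2) < n2:
        raise CapacityError(
            f"subset {design.subset_id} class 2 ({design.class2_label}): "
            f"need {n2} eligible records, have {len(elig2)}"
        )
    pick1 = [elig1[i] for i in rng.choice(len(elig1), size=n1, replace=False)]
    pick2 = [elig2[i] for i in rng.choice(len(elig2), size=n2, replace=False)]
    records = pick1 + pick2
    labels = np.array([0] * n1 + [1] * n2, dtype=int)
    consumed.update(r.record_id for r in records)
    return SubsetDataset(
        subset_id=design.subset_id,
        records=records,
        labels=labels,
        class1_label=design.class1_label,
        class2_label=design.class2_label,
    )


def assemble_subsets(
    pool: Sequence[RespondentRecord],
    designs: Sequence[SubsetDesign] | None = None,
    seed: int = 0,
) -> list[SubsetDataset]:
    """Assemble all designs in order 1 -> 2 -> 3 with a shared consumed set.

    Fixed assembly order is the deterministic tie-break for records whose
    diagnosis could qualify for more than one subset.
    """
    designs = list(designs) if designs is not None else default_designs()
    consumed: set[str] = set()
    out = []
    for i, design in enumerate(sorted(designs, key=lambda d: d.subset_id)):
        out.append(assemble_subset(pool, design, seed=seed + i, consumed=consumed))
    return out
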
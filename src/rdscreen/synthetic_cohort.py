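"""Synthetic questionnaire cohorts with controllable group separation.

Real answer collections are not distributed with the package, so every
pipeline stage is exercised on simulated cohorts.  The generative model is
deliberately the weakest one compatible with a 1-4 ordinal scale: each item
is an independent categorical draw over {1,2,3,4} from a per-group profile.
Group separation is introduced by shifting probability mass toward answer 4
("completely true") on a chosen subset of items — the signature expected of
respondents who lived through a pre-diagnostic odyssey — by an effect size
``delta`` in [0,1]: ``p' = (1-delta) * p + delta * e4``.  ``delta = 0``
makes groups indistinguishable (the chance-level null); ``delta = 1`` makes
affected items degenerate at 4.

Ages are truncated-normal integers, gender Bernoulli, and missing answers
item-wise Bernoulli contamination.  The generator's bookkeeping (true
group, missingness mask) is exported so completeness filtering and metrics
can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model import ANSWER_LEVELS, N_ITEMS, RespondentRecord, item_ids

#: Default per-item answer distribution over {1,2,3,4} for an unaffected
#: respondent: most answers lean "false" on odyssey-experience items.
DEFAULT_BASE_PROBS = (0.40, 0.30, 0.20, 0.10)

#: Default affected-item set: 20 of the 53 items carry the group signal.
DEFAULT_AFFECTED_ITEMS = frozenset(item_ids()[:20])

#: Default effect-size grid spanning chance to near-separable regimes.
DELTA_GRID = (0.0, 0.2, 0.4, 0.6)


class ProfileError(ValueError):
    """Invalid profile or effect configuration."""


@dataclass(frozen=True)
class GroupProfile:
    """Answer/demographic distribution for one diagnostic group.

    ``item_probs`` is (53, 4): per item, the categorical probabilities of
    answers 1..4 (rows sum to 1).  Ages are drawn normal(mean, sd) and
    clipped to bounds; ``p_female`` is the gender ratio; ``missingness`` is
    the per-item blank probability.
    """

    label: str
    item_probs: tuple  # (53, 4) nested tuple, hashable/immutable
    age_mean: float = 45.0
    age_sd: float = 15.0
    age_bounds: tuple[int, int] = (5, 90)
    p_female: float = 0.6
    missingness: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.item_probs, dtype=float)
        if probs.shape != (N_ITEMS, len(ANSWER_LEVELS)):
            raise ProfileError(f"item_probs must be ({N_ITEMS}, 4)")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ProfileError("each item's probabilities must be non-negative and sum to 1")
        if not (0.0 <= self.missingness < 1.0):
            raise ProfileError("missingness must be in [0, 1)")

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.item_probs, dtype=float)


def uniform_profile(label: str, base: Sequence[float] = DEFAULT_BASE_PROBS, **kwargs) -> GroupProfile:
    """A profile using the same answer distribution for all 53 items."""
    probs = tuple(tuple(float(p) for p in base) for _ in range(N_ITEMS))
    return GroupProfile(label=label, item_probs=probs, **kwargs)


@dataclass(frozen=True)
class EffectSpec:
    """Effect size and the item subset carrying the group signal."""

    delta: float = 0.4
    affected_items: frozenset[str] = DEFAULT_AFFECTED_ITEMS

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ProfileError(f"delta {self.delta} outside [0, 1]")
        unknown = set(self.affected_items) - set(item_ids())
        if unknown:
            raise ProfileError(f"unknown affected item(s): {sorted(unknown)}")


def shift_profile(base: GroupProfile, effect: EffectSpec, label: str | None = None) -> GroupProfile:
    """Shift the affected items' mass toward answer 4 by ``delta``."""
    probs = base.probs.copy()
    e4 = np.zeros(len(ANSWER_LEVELS))
    e4[-1] = 1.0
    idx = [i for i, qid in enumerate(item_ids()) if qid in effect.affected_items]
    probs[idx] = (1.0 - effect.delta) * probs[idx] + effect.delta * e4
    return replace(
        base,
        label=label if label is not None else base.label,
        item_probs=tuple(tuple(row) for row in probs),
    )


def make_profiles(
    base: GroupProfile, effect: EffectSpec, groups: Sequence[str]
) -> dict[str, GroupProfile]:
    """Per-group profiles: the first group carries the shifted signal.

    With ``delta = 0`` all groups share identical distributions.
    """
    if not groups:
        raise ProfileError("need at least one group")
    out = {groups[0]: shift_profile(base, effect, label=groups[0])}
    for g in groups[1:]:
        out[g] = replace(base, label=g)
    return out


def total_variation(p: Sequence[float], q: Sequence[float]) -> float:
    """TV distance between two categorical distributions."""
    return 0.5 * float(np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortBook:
    """Generator bookkeeping: records plus the exact missingness draws."""

    records: list[RespondentRecord]
    missing_mask: np.ndarray  # (n, 53) bool: True where an answer was blanked

    @property
    def n_incomplete(self) -> int:
        return int(np.any(self.missing_mask, axis=1).sum())


def _draw_group(
    rng: np.random.Generator,
    profile: GroupProfile,
    n: int,
    group: str,
    diagnosis: str,
    id_prefix: str,
) -> CohortBook:
    probs = profile.probs
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, N_ITEMS))
    answers = 1 + (u[:, :, None] > cum[None, :, :]).sum(axis=2)  # in 1..4
    mask = rng.random((n, N_ITEMS)) < profile.missingness
    lo, hi = profile.age_bounds
    ages = np.clip(np.rint(rng.normal(profile.age_mean, profile.age_sd, size=n)), lo, hi).astype(int)
    genders = np.where(rng.random(n) < profile.p_female, "F", "M")
    records = []
    for i in range(n):
        row = [None if mask[i, j] else int(answers[i, j]) for j in range(N_ITEMS)]
        records.append(
            RespondentRecord(
                record_id=f"{id_prefix}{i:05d}",
                answers=row,
                age=int(ages[i]),
                gender=str(genders[i]),
                diagnosis=diagnosis,
                group=group,
            )
        )
    return CohortBook(records=records, missing_mask=mask)


def generate_cohort(
    profiles: dict[str, GroupProfile],
    n_per_group: int | dict[str, int],
    seed: int,
) -> CohortBook:
    """Draw i.i.d. respondents per group; deterministic under ``seed``.

    Profile keys are used as both the group label and the diagnosis text.
    """
    rng = np.random.default_rng(seed)
    books = []
    for label in profiles:
        n = n_per_group[label] if isinstance(n_per_group, dict) else int(n_per_group)
        if n < 1:
            raise ProfileError(f"n_per_group for {label!r} must be >= 1")
        profile = profiles[label]
        group = profile.label if profile.label in ("RD", "NRO", "CD", "PSY") else "RD"
        books.append(_draw_group(rng, profile, n, group=group, diagnosis=label, id_prefix=f"{label}-"))
    return CohortBook(
        records=[r for b in books for r in b.records],
        missing_mask=np.vstack([b.missing_mask for b in books]),
    )


#: Diagnosis composition of the default study-shaped pool (1155 records):
#: 758 rare-disease questionnaires split over the named diagnoses plus an
#: umbrella remainder, and 200 NRO / 149 CD / 48 PSY comparison groups.
STUDY_COMPOSITION: dict[str, tuple[str, int]] = {
    # diagnosis: (group, count)
    "PAH": ("RD", 50),
    "cystic fibrosis": ("RD", 40),
    "sarcoidosis": ("RD", 144),
    "syringomyelia": ("RD", 44),
    "SLE": ("RD", 31),
    "acromegaly": ("RD", 12),
    "Ehlers-Danlos syndrome": ("RD", 20),
    "Morbus Still": ("RD", 10),
    "Nail-Patella syndrome": ("RD", 5),
    "CIDP": ("RD", 15),
    "cluster headache": ("RD", 22),
    "Meniere disease": ("RD", 10),
    "Fabry disease": ("RD", 12),
    "umbrella RD": ("RD", 343),
    "NRO": ("NRO", 200),
    "CD": ("CD", 149),
    "PSY": ("PSY", 48),
}


def generate_study_cohort(
    effect: EffectSpec | None = None,
    seed: int = 0,
    base: GroupProfile | None = None,
    composition: dict[str, tuple[str, int]] | None = None,
    missingness: float = 0.0,
) -> CohortBook:
    """A study-shaped labeled pool: 1155 records across RD/NRO/CD/PSY.

    Rare-disease respondents draw from the shifted profile, the three
    comparison groups from the base profile, so the pool feeds directly
    into the three default pairwise subset designs.
    """
    effect = effect or EffectSpec()
    base = base or uniform_profile("base", missingness=missingness)
    composition = composition or STUDY_COMPOSITION
    rd_profile = shift_profile(base, effect, label="RD")
    rng = np.random.default_rng(seed)
    books = []
    for diagnosis, (group, n) in composition.items():
        profile = replace(rd_profile if group == "RD" else base, label=group)
        books.append(
            _draw_group(rng, profile, n, group=group, diagnosis=diagnosis, id_prefix=f"{diagnosis[:8].replace(' ', '_')}-")
        )
    return CohortBook(
        records=[r for b in books for r in b.records],
        missing_mask=np.vstack([b.missing_mask for b in books]),
    )
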
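"""Manual patient selection: rank by count of program-list medications.

The manual method mirrors how a precision-medicine program staffs a fixed
genotyping budget by hand: each patient is scored by how many medications
from the program's own list they filled in the window, ties are broken by
the patient's overall unique medication count, and any remaining ties are
broken randomly (seeded). The cohort is then cut at the "natural
selection point": the score threshold whose cohort size lands closest to
the preset testing target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .claims_io import PatientProfile
from .knowledge_base import KnowledgeBase, method_medications

__all__ = ["ManualScore", "CohortSelection", "manual_score", "rank_manual",
           "select_natural_cut"]


@dataclass(frozen=True)
class ManualScore:
    patient_id: str
    manual_med_count: int
    total_med_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.manual_med_count <= self.total_med_count:
            raise ValueError(
                f"{self.patient_id}: manual count {self.manual_med_count} "
                f"exceeds total {self.total_med_count}"
            )


@dataclass(frozen=True)
class CohortSelection:
    """A ranked population cut at a score threshold near the target size."""

    method: str
    ranking: tuple[str, ...]
    threshold: float
    selected: frozenset[str]
    target: int
    warning: str | None = None


def manual_score(profile: PatientProfile, kb: KnowledgeBase) -> ManualScore:
    """Score one patient: unique manual-list medications in the window."""
    manual_meds = profile.medications & method_medications(kb, "manual")
    return ManualScore(
        patient_id=profile.patient_id,
        manual_med_count=len(manual_meds),
        total_med_count=profile.n_unique_meds,
    )


def _random_keys(ids: Iterable[str], seed: int) -> dict[str, float]:
    """One uniform tie-break key per patient, stable under input order.

    Keys are drawn from a single seeded stream over the id-sorted
    population, so a given (population, seed) pair always produces the
    same keys regardless of how the caller ordered the rows.
    """
    ordered = sorted(set(ids))
    rng = np.random.default_rng(seed)
    return dict(zip(ordered, rng.random(len(ordered))))


def rank_manual(scores: Sequence[ManualScore], seed: int) -> tuple[str, ...]:
    """Rank descending by (manual count, total count), random final tie-break."""
    if not scores:
        raise ValueError("no scores to rank")
    keys = _random_keys((s.patient_id for s in scores), seed)
    ordered = sorted(
        scores,
        key=lambda s: (-s.manual_med_count, -s.total_med_count,
                       keys[s.patient_id]),
    )
    return tuple(s.patient_id for s in ordered)


def select_natural_cut(
    scores: Mapping[str, float],
    target: int,
    method: str = "manual",
    ranking: Sequence[str] | None = None,
) -> CohortSelection:
    """Cut the population at the score threshold closest to the target size.

    Candidate thresholds are the distinct score values; for each, the
    cohort is every patient scoring at or above it. The threshold whose
    cohort size minimizes ``|size - target|`` wins; when two thresholds
    are equidistant the smaller cohort is kept (conserving the testing
    budget). With a single distinct score there is no real choice and the
    selection carries a warning.
    """
    if target < 1:
        raise ValueError("target must be at least 1")
    if not scores:
        raise ValueError("no scores to select from")

    values = np.array(sorted(set(scores.values()), reverse=True))
    sizes = [sum(1 for v in scores.values() if v >= t) for t in values]
    best = min(range(len(values)), key=lambda i: (abs(sizes[i] - target), sizes[i]))
    threshold = float(values[best])
    selected = frozenset(pid for pid, v in scores.items() if v >= threshold)
    warning = "all scores identical; single candidate threshold" if len(values) == 1 else None

    if ranking is None:
        ranking = tuple(sorted(scores, key=lambda p: (-scores[p], p)))
    else:
        extra = set(ranking) - set(scores)
        if extra:
            raise ValueError(f"ranking contains unscored patients: {sorted(extra)[:5]}")
        ranking = tuple(ranking)
    return CohortSelection(
        method=method,
        ranking=ranking,
        threshold=threshold,
        selected=selected,
        target=target,
        warning=warning,
    )
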
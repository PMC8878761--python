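"""Automated patient selection: the pharmacogenomic interaction probability.

The PIP score is the probability that genotyping a patient on the panel
would reveal at least one clinically actionable drug–gene (or
drug–drug–gene) interaction, given their current medications. For each
panel gene g, the chance that a randomly drawn phenotype is actionable
for some current medication is

    p_g = sum over phenotypes phi of  freq(phi) * 1[ exists drug d on the
          profile with a rule (d, g) whose actionable set contains the
          EFFECTIVE phenotype of phi given the co-medications ]

and, treating genes as independent, the PIP is the complement of "no gene
actionable":

    PIP = 1 - prod_g (1 - p_g)

reported as a whole-number percentage (rounded half away from zero).

Phenoconversion makes the effective phenotype differ from the genotypic
one: a strong inhibitor of a metabolizer gene turns genotypic normal and
intermediate metabolizers into phenotypic poor metabolizers; a moderate
inhibitor shifts one step toward poor on the gene's phenotype ladder;
inducers shift toward ultrarapid (one step when moderate, to the top
when strong). Only co-medications other than the victim drug itself can
convert its phenotype. When both an inhibitor and an inducer are present
the effects are taken to cancel.

The exact commercial formulation of this score is proprietary; this
module is a declared reconstruction from its published description, not
a claim of bit-equality with any vendor implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .claims_io import PatientProfile
from .knowledge_base import (
    DDI_SEVERITY_ORDER,
    Gene,
    KnowledgeBase,
    method_medications,
)
from .manual_method import _random_keys

__all__ = [
    "PIPResult",
    "effective_phenotype",
    "effective_phenotype_map",
    "gene_actionable_prob",
    "pip_score",
    "band",
    "count_ddis",
    "rank_automated",
]

BANDS = ("none", "low", "moderate", "high")


@dataclass(frozen=True)
class PIPResult:
    """Per-patient PIP score with its tie-break keys."""

    patient_id: str
    per_gene_prob: dict[str, float]
    pip_percent: int
    band: str
    nnt: float | None
    ddi_severity_counts: dict[str, int]
    total_med_count: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def band(pip_percent: int) -> str:
    """Risk band for a whole-number PIP: 0 none, 1–25 low, 26–50 moderate, ≥51 high.

    The low/moderate edge splits patients at a number needed to test of
    four (more vs. fewer than 1 in 4 patients tested yielding an
    actionable finding); above 50 a finding is more likely than not.
    """
    if not 0 <= pip_percent <= 100:
        raise ValueError(f"PIP percent out of range: {pip_percent}")
    if pip_percent == 0:
        return "none"
    if pip_percent <= 25:
        return "low"
    if pip_percent <= 50:
        return "moderate"
    return "high"


def _net_modifier(
    gene: str, comedications: frozenset[str], kb: KnowledgeBase
) -> tuple[str, str] | None:
    """Net (kind, strength) of phenoconversion perpetrators present, or None.

    The strongest applicable modifier wins; if both an inhibitor and an
    inducer are present they cancel.
    """
    present = [m for m in kb.modifiers_for_gene(gene) if m.medication in comedications]
    if not present:
        return None
    kinds = {m.kind for m in present}
    if kinds == {"inhibitor", "inducer"}:
        return None
    kind = kinds.pop()
    strength = "strong" if any(m.strength == "strong" for m in present) else "moderate"
    return kind, strength


def effective_phenotype(
    gene: str,
    genotypic_phenotype: str,
    comedications: Iterable[str],
    kb: KnowledgeBase,
) -> str:
    """Effective phenotype after phenoconversion by co-medications.

    ``comedications`` must exclude the victim drug itself. Identity for
    non-phenoconvertible genes and when no perpetrator is present.
    """
    g = kb.gene(gene)
    ladder = list(g.phenotypes)  # ordered ultrarapid -> poor
    if genotypic_phenotype not in ladder:
        raise ValueError(
            f"{genotypic_phenotype!r} is not on the {gene} phenotype ladder"
        )
    if not g.phenoconvertible:
        return genotypic_phenotype
    net = _net_modifier(gene, frozenset(comedications), kb)
    if net is None:
        return genotypic_phenotype
    kind, strength = net
    idx = ladder.index(genotypic_phenotype)
    if kind == "inhibitor":
        if strength == "strong":
            # NM, IM and anything between them and PM become phenotypic PM
            return "PM" if idx >= ladder.index("NM") else genotypic_phenotype
        return ladder[min(idx + 1, len(ladder) - 1)]
    if strength == "strong":
        return ladder[0]
    return ladder[max(idx - 1, 0)]


def effective_phenotype_map(
    gene: str, victim: str, profile_medications: Iterable[str], kb: KnowledgeBase
) -> dict[str, str]:
    """Genotypic→effective phenotype map for one victim drug on a profile."""
    comeds = frozenset(profile_medications) - {victim}
    return {
        phi: effective_phenotype(gene, phi, comeds, kb)
        for phi in kb.gene(gene).phenotypes
    }


def gene_actionable_prob(
    gene: str, medications: Iterable[str], kb: KnowledgeBase
) -> float:
    """Probability that a random phenotype of ``gene`` is actionable.

    Sums population frequency over genotypic phenotypes for which at
    least one profile medication's rule fires on the phenoconverted
    (effective) phenotype. Zero when no profile drug has a rule for the
    gene. Only automated-list medications can act as victims (a
    manual-only drug such as warfarin never contributes), but any
    co-medication can act as a phenoconversion perpetrator.
    """
    meds = frozenset(medications)
    scored = meds & method_medications(kb, "automated")
    rules = [r for r in kb.rules_for_gene(gene) if r.medication in scored]
    if not rules:
        return 0.0
    freqs = kb.frequencies[gene]
    maps = {
        r.medication: effective_phenotype_map(gene, r.medication, meds, kb)
        for r in rules
    }
    p = 0.0
    for phi, f in freqs.items():
        if any(maps[r.medication][phi] in r.actionable_phenotypes for r in rules):
            p += f
    return min(p, 1.0)


def count_ddis(medications: Iterable[str], kb: KnowledgeBase) -> dict[str, int]:
    """Count drug–drug interaction rules fully contained in the profile.

    A rule fires once iff its whole drug set is on the medication list;
    counts are binned by severity. Gene-mediated interactions are not in
    this table by construction.
    """
    meds = frozenset(medications)
    counts = {sev: 0 for sev in DDI_SEVERITY_ORDER}
    for rule in kb.ddi_rules:
        if rule.drugs <= meds:
            counts[rule.severity] += 1
    return counts


def moderate_or_higher_ddi(counts: Mapping[str, int]) -> int:
    """Total interactions at moderate severity or above."""
    return sum(counts.get(s, 0) for s in ("moderate", "severe", "contraindicated"))


def pip_score(profile: PatientProfile, kb: KnowledgeBase) -> PIPResult:
    """Score one patient: per-gene probabilities, PIP percent, band, NNT.

    NNT (number needed to test) is the expected number of patients
    genotyped per actionable finding, ``100 / pip_percent``; undefined at
    a PIP of zero.
    """
    per_gene = {
        g.symbol: gene_actionable_prob(g.symbol, profile.medications, kb)
        for g in kb.genes
    }
    p_any = 1.0
    for p in per_gene.values():
        p_any *= 1.0 - p
    pip = _round_half_away(100.0 * (1.0 - p_any))
    return PIPResult(
        patient_id=profile.patient_id,
        per_gene_prob=per_gene,
        pip_percent=pip,
        band=band(pip),
        nnt=(100.0 / pip) if pip > 0 else None,
        ddi_severity_counts=count_ddis(profile.medications, kb),
        total_med_count=profile.n_unique_meds,
    )


def rank_automated(results: Sequence[PIPResult], seed: int) -> tuple[str, ...]:
    """Rank by PIP, then DDI counts most-severe-first, then medication count.

    Remaining ties are broken by a seeded random key, stable under input
    ordering.
    """
    if not results:
        raise ValueError("no results to rank")
    keys = _random_keys((r.patient_id for r in results), seed)

    def sort_key(r: PIPResult):
        ddi_vec = tuple(-r.ddi_severity_counts.get(s, 0) for s in DDI_SEVERITY_ORDER)
        return (-r.pip_percent, ddi_vec, -r.total_med_count, keys[r.patient_id])

    return tuple(r.patient_id for r in sorted(results, key=sort_key))
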
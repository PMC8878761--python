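"""Shared fixtures: the bundled knowledge base and toy-KB builders."""

from __future__ import annotations

import itertools

import pytest

from pgxselect.claims_io import PatientProfile
from pgxselect.knowledge_base import KnowledgeBase, load_kb


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    """The bundled eight-gene panel knowledge base."""
    return load_kb()


def make_kb(
    genes: dict[str, list[str]],
    frequencies: dict[str, dict[str, float]],
    rules: list[tuple[str, str, set[str], str]],
    modifiers: list[tuple[str, str, str, str]] = (),
    ddi_rules: list[tuple[set[str], str]] = (),
    phenoconvertible: set[str] = frozenset(),
) -> KnowledgeBase:
    """Build a small KB from terse tuples; all medications join both methods."""
    meds = sorted(
        {r[0] for r in rules}
        | {m[0] for m in modifiers}
        | set(itertools.chain.from_iterable(d for d, _ in ddi_rules))
    )
    return KnowledgeBase.model_validate({
        "genes": [
            {"symbol": g, "phenotypes": phenos,
             "phenoconvertible": g in phenoconvertible}
            for g, phenos in genes.items()
        ],
        "frequencies": frequencies,
        "medications": [
            {"name": m, "rxcui": str(1000 + i), "drug_class": "test",
             "in_manual": True, "in_automated": True}
            for i, m in enumerate(meds)
        ],
        "drug_gene_rules": [
            {"medication": med, "gene": gene,
             "actionable_phenotypes": sorted(phenos), "severity": sev}
            for med, gene, phenos, sev in rules
        ],
        "modifiers": [
            {"medication": med, "gene": gene, "kind": kind, "strength": strength}
            for med, gene, kind, strength in modifiers
        ],
        "ddi_rules": [
            {"drugs": sorted(drugs), "severity": sev} for drugs, sev in ddi_rules
        ],
    })


def make_profile(patient_id: str = "P1", meds: set[str] = frozenset(),
                 **kwargs) -> PatientProfile:
    defaults = dict(age_years=40, sex="female")
    defaults.update(kwargs)
    return PatientProfile(patient_id=patient_id, medications=frozenset(meds),
                          **defaults)
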
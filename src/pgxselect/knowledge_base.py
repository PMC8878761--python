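"""Pharmacogenomic knowledge base: genes, medications, interaction rules.

The knowledge base is a single JSON document holding the eight-gene test
panel, the phenotype frequency tables, the medication lists for the manual
and automated selection methods, drug–gene interaction rules (with their
actionable phenotype sets and severities), phenoconversion modifiers
(inhibitors/inducers), and a curated drug–drug interaction table.

Both selection methods are entirely driven by this file: nothing about a
specific drug or gene is hard-coded in the scoring algorithms, so a site
can swap in its own panel, medication lists or frequency tables.
"""

from __future__ import annotations

import json
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Severity",
    "DDISeverity",
    "Gene",
    "Medication",
    "DrugGeneRule",
    "InteractionModifier",
    "DDIRule",
    "KnowledgeBase",
    "KBValidationError",
    "load_kb",
    "write_kb",
    "default_kb_path",
    "method_medications",
    "membership_counts",
]

FREQ_TOL = 1e-9


class KBValidationError(ValueError):
    """Raised when a knowledge-base file violates a structural invariant."""


class Severity(IntEnum):
    """Drug–gene interaction level; only moderate or higher is actionable."""

    moderate = 2
    severe = 3
    contraindicated = 4


class DDISeverity(IntEnum):
    """Drug–drug interaction severity ladder, least to most severe."""

    minimal = 0
    minor = 1
    moderate = 2
    severe = 3
    contraindicated = 4


#: DDI severities from most to least severe, the tie-break comparison order.
DDI_SEVERITY_ORDER: tuple[str, ...] = (
    "contraindicated",
    "severe",
    "moderate",
    "minor",
    "minimal",
)


class Gene(BaseModel):
    """A panel gene with its ordered phenotype ladder.

    For CYP metabolizer genes the ladder runs from ultrarapid to poor
    (e.g. UM, RM, NM, IM, PM); phenoconversion shifts a phenotype along
    this ladder. Non-metabolizer genes (transporters, targets) carry an
    arbitrary label list and are never phenoconverted.
    """

    model_config = ConfigDict(frozen=True)

    symbol: str
    phenotypes: tuple[str, ...]
    phenoconvertible: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Gene":
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise KBValidationError(
                f"gene {self.symbol}: duplicate phenotype labels"
            )
        if self.phenoconvertible and not {"NM", "PM"} <= set(self.phenotypes):
            raise KBValidationError(
                f"gene {self.symbol}: phenoconvertible genes need NM and PM "
                "on their phenotype ladder"
            )
        return self


class Medication(BaseModel):
    """An ingredient-level medication and its method membership.

    Salts and dose forms collapse to one lowercase ingredient name keyed
    to a single ingredient-level code.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    rxcui: str
    drug_class: str
    in_manual: bool
    in_automated: bool

    @model_validator(mode="after")
    def _check(self) -> "Medication":
        if self.name != self.name.lower():
            raise KBValidationError(f"medication {self.name!r}: not lowercase")
        if not (self.in_manual or self.in_automated):
            raise KBValidationError(
                f"medication {self.name}: belongs to neither method"
            )
        return self


class DrugGeneRule(BaseModel):
    """One drug–gene interaction row: which phenotypes are actionable.

    A rule below moderate severity carries no clinically actionable
    recommendation and is rejected at load.
    """

    model_config = ConfigDict(frozen=True)

    medication: str
    gene: str
    actionable_phenotypes: frozenset[str]
    severity: str

    @model_validator(mode="after")
    def _check(self) -> "DrugGeneRule":
        if self.severity not in Severity.__members__:
            raise KBValidationError(
                f"rule {self.medication}/{self.gene}: severity "
                f"{self.severity!r} is below moderate or unknown"
            )
        if not self.actionable_phenotypes:
            raise KBValidationError(
                f"rule {self.medication}/{self.gene}: empty actionable set"
            )
        return self


class InteractionModifier(BaseModel):
    """A perpetrator drug that inhibits or induces a metabolizer gene."""

    model_config = ConfigDict(frozen=True)

    medication: str
    gene: str
    kind: Literal["inhibitor", "inducer"]
    strength: Literal["strong", "moderate"]


class DDIRule(BaseModel):
    """A drug–drug (or multi-drug) interaction with an ordinal severity.

    Gene-mediated interactions are deliberately excluded from this table;
    they are handled probabilistically by the PIP score.
    """

    model_config = ConfigDict(frozen=True)

    drugs: frozenset[str]
    severity: str

    @model_validator(mode="after")
    def _check(self) -> "DDIRule":
        if len(self.drugs) < 2:
            raise KBValidationError(
                f"DDI rule {sorted(self.drugs)}: needs at least two distinct drugs"
            )
        if self.severity not in DDISeverity.__members__:
            raise KBValidationError(
                f"DDI rule {sorted(self.drugs)}: unknown severity "
                f"{self.severity!r}"
            )
        return self


class KnowledgeBase(BaseModel):
    """Validated container for the whole PGx knowledge base."""

    model_config = ConfigDict(frozen=True)

    genes: tuple[Gene, ...]
    frequencies: dict[str, dict[str, float]]
    medications: tuple[Medication, ...]
    drug_gene_rules: tuple[DrugGeneRule, ...]
    modifiers: tuple[InteractionModifier, ...] = ()
    ddi_rules: tuple[DDIRule, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "KnowledgeBase":
        genes = {g.symbol: g for g in self.genes}
        if len(genes) != len(self.genes):
            raise KBValidationError("duplicate gene symbols")
        meds = {m.name for m in self.medications}
        if len(meds) != len(self.medications):
            raise KBValidationError("duplicate medication names")

        for symbol, freqs in self.frequencies.items():
            gene = genes.get(symbol)
            if gene is None:
                raise KBValidationError(f"frequencies for unknown gene {symbol}")
            if set(freqs) != set(gene.phenotypes):
                raise KBValidationError(
                    f"frequencies for {symbol}: labels do not match the "
                    "gene's phenotype ladder"
                )
            if any(p < 0 for p in freqs.values()):
                raise KBValidationError(f"frequencies for {symbol}: negative mass")
            total = sum(freqs.values())
            if abs(total - 1.0) > FREQ_TOL:
                raise KBValidationError(
                    f"frequencies for {symbol}: sum {total!r} != 1"
                )
        for gene in self.genes:
            if gene.symbol not in self.frequencies:
                raise KBValidationError(f"gene {gene.symbol}: no frequencies")

        for rule in self.drug_gene_rules:
            if rule.medication not in meds:
                raise KBValidationError(
                    f"rule references undeclared medication {rule.medication!r}"
                )
            gene = genes.get(rule.gene)
            if gene is None:
                raise KBValidationError(
                    f"rule {rule.medication}: unknown gene {rule.gene!r}"
                )
            extra = rule.actionable_phenotypes - set(gene.phenotypes)
            if extra:
                raise KBValidationError(
                    f"rule {rule.medication}/{rule.gene}: actionable "
                    f"phenotypes {sorted(extra)} not on the gene's ladder"
                )
        for mod in self.modifiers:
            if mod.medication not in meds:
                raise KBValidationError(
                    f"modifier references undeclared medication {mod.medication!r}"
                )
            gene = genes.get(mod.gene)
            if gene is None:
                raise KBValidationError(
                    f"modifier {mod.medication}: unknown gene {mod.gene!r}"
                )
            if not gene.phenoconvertible:
                raise KBValidationError(
                    f"modifier {mod.medication}/{mod.gene}: gene is not "
                    "phenoconvertible"
                )
        for ddi in self.ddi_rules:
            missing = ddi.drugs - meds
            if missing:
                raise KBValidationError(
                    f"DDI rule references undeclared medications {sorted(missing)}"
                )
        return self

    # -- convenience lookups -------------------------------------------------

    def gene(self, symbol: str) -> Gene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def rules_for_gene(self, symbol: str) -> tuple[DrugGeneRule, ...]:
        return tuple(r for r in self.drug_gene_rules if r.gene == symbol)

    def modifiers_for_gene(self, symbol: str) -> tuple[InteractionModifier, ...]:
        return tuple(m for m in self.modifiers if m.gene == symbol)

    def medication_names(self) -> frozenset[str]:
        return frozenset(m.name for m in self.medications)


def default_kb_path() -> Path:
    """Path of the bundled eight-gene knowledge base."""
    return Path(str(resources.files("pgxselect").joinpath("data/default_kb.json")))


def load_kb(path: str | Path | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base from a JSON file.

    With no argument, loads the bundled eight-gene panel fixture.

    Raises
    ------
    KBValidationError
        If any structural invariant fails; the message names the
        offending record.
    """
    path = default_kb_path() if path is None else Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return KnowledgeBase.model_validate(raw)
    except KBValidationError:
        raise
    except Exception as exc:  # pydantic wraps our errors; unwrap for callers
        for err in getattr(exc, "errors", lambda: [])():
            ctx_err = err.get("ctx", {}).get("error")
            if isinstance(ctx_err, KBValidationError):
                raise ctx_err from exc
        raise KBValidationError(str(exc)) from exc


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Serialize a knowledge base back to its JSON file format."""
    doc = {
        "genes": [
            {"symbol": g.symbol, "phenotypes": list(g.phenotypes),
             "phenoconvertible": g.phenoconvertible}
            for g in kb.genes
        ],
        "frequencies": kb.frequencies,
        "medications": [m.model_dump() for m in kb.medications],
        "drug_gene_rules": [
            {"medication": r.medication, "gene": r.gene,
             "actionable_phenotypes": sorted(r.actionable_phenotypes),
             "severity": r.severity}
            for r in kb.drug_gene_rules
        ],
        "modifiers": [m.model_dump() for m in kb.modifiers],
        "ddi_rules": [
            {"drugs": sorted(d.drugs), "severity": d.severity}
            for d in kb.ddi_rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def method_medications(
    kb: KnowledgeBase, method: Literal["manual", "automated"]
) -> frozenset[str]:
    """Medication names used by one selection method.

    The manual method scores against its own list (shared drugs plus
    manual-only drugs such as warfarin); the automated method against the
    shared drugs plus automated-only drugs such as metoprolol.
    """
    if method == "manual":
        return frozenset(m.name for m in kb.medications if m.in_manual)
    if method == "automated":
        return frozenset(m.name for m in kb.medications if m.in_automated)
    raise ValueError(f"unknown method {method!r}; expected 'manual' or 'automated'")


def membership_counts(kb: KnowledgeBase) -> tuple[int, int, int]:
    """Count drug–gene rules by method membership.

    Returns ``(n_both, n_manual_only, n_automated_only)`` counted as
    drug–gene entries, so a drug interacting with several panel genes
    contributes one count per gene.
    """
    meds = {m.name: m for m in kb.medications}
    n_both = n_manual = n_auto = 0
    for rule in kb.drug_gene_rules:
        med = meds[rule.medication]
        if med.in_manual and med.in_automated:
            n_both += 1
        elif med.in_manual:
            n_manual += 1
        else:
            n_auto += 1
    return n_both, n_manual, n_auto


def union_medications(kb: KnowledgeBase) -> frozenset[str]:
    """All medications on either method's list."""
    return method_medications(kb, "manual") | method_medications(kb, "automated")
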
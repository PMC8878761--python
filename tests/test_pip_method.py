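"""PIP scoring: phenoconversion, per-gene probabilities, banding, DDIs.

The product-form PIP is checked against an independent oracle that
enumerates every joint genotype vector with its product weight and sums
the probability of "at least one actionable drug–gene pair".
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgxselect.knowledge_base import DDI_SEVERITY_ORDER, KnowledgeBase
from pgxselect.pip_method import (
    PIPResult,
    band,
    count_ddis,
    effective_phenotype,
    gene_actionable_prob,
    pip_score,
    rank_automated,
)

from conftest import make_kb, make_profile


# ---------------------------------------------------------------------------
# independent oracle: exhaustive joint-genotype enumeration
# ---------------------------------------------------------------------------

def joint_enumeration_pip(kb: KnowledgeBase, meds: frozenset[str]) -> float:
    """P(>=1 actionable pair), summed over all genotype vectors."""
    symbols = [g.symbol for g in kb.genes]
    ladders = [kb.gene(s).phenotypes for s in symbols]
    total = 0.0
    for combo in itertools.product(*ladders):
        weight = math.prod(kb.frequencies[s][phi] for s, phi in zip(symbols, combo))
        hit = False
        for s, phi in zip(symbols, combo):
            for rule in kb.rules_for_gene(s):
                if rule.medication not in meds:
                    continue
                eff = effective_phenotype(s, phi, meds - {rule.medication}, kb)
                if eff in rule.actionable_phenotypes:
                    hit = True
                    break
            if hit:
                break
        if hit:
            total += weight
    return total


def random_small_kb(rng: np.random.Generator, with_modifiers: bool = False):
    """A random KB with <=4 genes x <=5 phenotypes and a random drug set."""
    n_genes = int(rng.integers(1, 5))
    genes, freqs = {}, {}
    for gi in range(n_genes):
        # phenoconvertible ladders must reach from NM to PM
        n_ph = int(rng.integers(3, 6)) if with_modifiers else int(rng.integers(2, 6))
        labels = (["UM", "RM", "NM", "IM", "PM"][5 - n_ph:]
                  if with_modifiers else [f"ph{j}" for j in range(n_ph)])
        genes[f"G{gi}"] = labels
        w = rng.dirichlet(np.ones(n_ph))
        f = {lab: float(x) for lab, x in zip(labels, w)}
        f[labels[-1]] = float(1.0 - sum(f[l] for l in labels[:-1]))  # exact sum
        freqs[f"G{gi}"] = f
    drugs = [f"d{i}" for i in range(int(rng.integers(1, 6)))]
    rules = []
    for d in drugs:
        for g, labels in genes.items():
            if rng.random() < 0.6:
                k = int(rng.integers(1, len(labels) + 1))
                actionable = set(rng.choice(labels, size=k, replace=False))
                rules.append((d, g, actionable, "moderate"))
    if not rules:
        rules.append((drugs[0], "G0", {genes["G0"][0]}, "moderate"))
    modifiers = []
    if with_modifiers:
        for d in drugs:
            for g in genes:
                if rng.random() < 0.3:
                    modifiers.append((d, g,
                                      str(rng.choice(["inhibitor", "inducer"])),
                                      str(rng.choice(["strong", "moderate"]))))
        pheno = set(genes)
    else:
        pheno = set()
    kb = make_kb(genes, freqs, rules, modifiers=modifiers, phenoconvertible=pheno)
    n_meds = int(rng.integers(1, len(drugs) + 1))
    meds = frozenset(rng.choice(drugs, size=n_meds, replace=False))
    return kb, meds


# ---------------------------------------------------------------------------
# phenoconversion
# ---------------------------------------------------------------------------

LADDER_KB = make_kb(
    genes={"G": ["UM", "RM", "NM", "IM", "PM"]},
    frequencies={"G": {"UM": 0.04, "RM": 0.26, "NM": 0.4, "IM": 0.25, "PM": 0.05}},
    rules=[("victim", "G", {"PM"}, "moderate")],
    modifiers=[("strongin", "G", "inhibitor", "strong"),
               ("modin", "G", "inhibitor", "moderate"),
               ("stronginduce", "G", "inducer", "strong"),
               ("modinduce", "G", "inducer", "moderate")],
    phenoconvertible={"G"},
)


class TestEffectivePhenotype:
    @pytest.mark.parametrize("genotype", ["NM", "IM"])
    def test_strong_inhibitor_converts_to_poor(self, genotype):
        assert effective_phenotype("G", genotype, {"strongin"}, LADDER_KB) == "PM"

    def test_strong_inhibitor_leaves_ultrarapid_alone(self):
        assert effective_phenotype("G", "UM", {"strongin"}, LADDER_KB) == "UM"

    def test_identity_without_modifiers(self):
        for phi in LADDER_KB.gene("G").phenotypes:
            assert effective_phenotype("G", phi, {"victim"}, LADDER_KB) == phi

    def test_moderate_inhibitor_shifts_one_step_down_full_ladder(self):
        ladder = ["UM", "RM", "NM", "IM", "PM"]
        for i, phi in enumerate(ladder):
            expected = ladder[min(i + 1, 4)]
            assert effective_phenotype("G", phi, {"modin"}, LADDER_KB) == expected

    def test_inducers_shift_toward_ultrarapid(self):
        assert effective_phenotype("G", "IM", {"modinduce"}, LADDER_KB) == "NM"
        assert effective_phenotype("G", "PM", {"stronginduce"}, LADDER_KB) == "UM"
        assert effective_phenotype("G", "UM", {"modinduce"}, LADDER_KB) == "UM"

    def test_opposing_modifiers_cancel(self):
        assert effective_phenotype("G", "NM", {"strongin", "stronginduce"},
                                   LADDER_KB) == "NM"

    def test_strongest_modifier_wins(self):
        assert effective_phenotype("G", "NM", {"strongin", "modin"}, LADDER_KB) == "PM"

    def test_unknown_phenotype_label_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            effective_phenotype("G", "XX", set(), LADDER_KB)

    def test_non_phenoconvertible_gene_is_identity(self, kb):
        assert effective_phenotype("VKORC1", "sensitive", {"paroxetine"}, kb) == "sensitive"


class TestGeneActionableProb:
    def test_single_rule_single_phenotype(self):
        kb = make_kb(genes={"G": ["NM", "PM"]},
                     frequencies={"G": {"NM": 0.93, "PM": 0.07}},
                     rules=[("d", "G", {"PM"}, "moderate")])
        assert gene_actionable_prob("G", {"d"}, kb) == pytest.approx(0.07)

    def test_no_rule_for_gene_gives_zero(self):
        kb = make_kb(genes={"G": ["NM", "PM"], "H": ["NM", "PM"]},
                     frequencies={"G": {"NM": 0.93, "PM": 0.07},
                                  "H": {"NM": 0.5, "PM": 0.5}},
                     rules=[("d", "G", {"PM"}, "moderate")])
        assert gene_actionable_prob("H", {"d"}, kb) == 0.0

    def test_strong_inhibitor_moves_normal_mass_onto_poor(self):
        # victim actionable only for NM; a strong inhibitor converts NM->PM,
        # so the NM mass no longer fires
        kb = make_kb(genes={"G": ["UM", "NM", "IM", "PM"]},
                     frequencies={"G": {"UM": 0.03, "NM": 0.77, "IM": 0.13, "PM": 0.07}},
                     rules=[("victim", "G", {"NM"}, "moderate")],
                     modifiers=[("perp", "G", "inhibitor", "strong")],
                     phenoconvertible={"G"})
        assert gene_actionable_prob("G", {"victim"}, kb) == pytest.approx(0.77)
        assert gene_actionable_prob("G", {"victim", "perp"}, kb) == pytest.approx(0.0)

    def test_matches_enumeration_oracle_on_modifier_bearing_kbs(self):
        rng = np.random.default_rng(20260923)
        for _ in range(60):
            kb, meds = random_small_kb(rng, with_modifiers=True)
            expected = joint_enumeration_pip(kb, meds)
            p_any = 1.0
            for g in kb.genes:
                p_any *= 1.0 - gene_actionable_prob(g.symbol, meds, kb)
            assert 1.0 - p_any == pytest.approx(expected, abs=1e-12)


class TestPipScore:
    def test_two_gene_product_formula(self):
        kb = make_kb(genes={"G": ["a", "b"], "H": ["a", "b"]},
                     frequencies={"G": {"a": 0.1, "b": 0.9},
                                  "H": {"a": 0.2, "b": 0.8}},
                     rules=[("d1", "G", {"a"}, "moderate"),
                            ("d2", "H", {"a"}, "moderate")])
        r = pip_score(make_profile(meds={"d1", "d2"}), kb)
        # 1 - 0.9*0.8 = 0.28
        assert r.pip_percent == 28
        assert r.nnt == pytest.approx(100 / 28)

    def test_empty_medication_list_scores_zero(self, kb):
        r = pip_score(make_profile(meds=set()), kb)
        assert (r.pip_percent, r.band, r.nnt) == (0, "none", None)

    def test_warfarin_only_profile_scores_zero(self, kb):
        # warfarin is on the manual list only, so the automated score ignores it
        r = pip_score(make_profile(meds={"warfarin"}), kb)
        assert r.pip_percent == 0

    def test_equals_joint_enumeration_oracle_before_rounding(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            kb, meds = random_small_kb(rng, with_modifiers=False)
            r = pip_score(make_profile(meds=meds), kb)
            p_any = 1.0
            for p in r.per_gene_prob.values():
                p_any *= 1.0 - p
            assert 1.0 - p_any == pytest.approx(joint_enumeration_pip(kb, meds),
                                                abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_adding_a_medication_never_lowers_pip(self, seed):
        rng = np.random.default_rng(seed)
        kb, meds = random_small_kb(rng, with_modifiers=False)
        all_drugs = kb.medication_names()
        extra = sorted(all_drugs - meds)
        r0 = pip_score(make_profile(meds=meds), kb)
        if extra:
            r1 = pip_score(make_profile(meds=meds | {extra[0]}), kb)
            assert r1.pip_percent >= r0.pip_percent
        assert 0 <= r0.pip_percent <= 100
        assert all(0.0 <= p <= 1.0 for p in r0.per_gene_prob.values())


class TestBand:
    @pytest.mark.parametrize("pip,expected", [
        (0, "none"), (1, "low"), (25, "low"), (26, "moderate"),
        (50, "moderate"), (51, "high"), (100, "high"),
    ])
    def test_band_edges(self, pip, expected):
        assert band(pip) == expected

    @pytest.mark.parametrize("bad", [-1, 101])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            band(bad)


class TestCountDdis:
    def test_pair_rule_fires_when_both_drugs_present(self, kb):
        counts = count_ddis({"warfarin", "mefenamic acid"}, kb)
        assert counts["severe"] == 1

    def test_multidrug_rule_needs_full_set(self, kb):
        # the 3-drug rule requires tramadol + sertraline + ondansetron
        partial = count_ddis({"tramadol", "sertraline"}, kb)
        full = count_ddis({"tramadol", "sertraline", "ondansetron"}, kb)
        assert partial["severe"] == 0 and partial["moderate"] == 1
        assert full["severe"] == 1

    def test_matches_subset_enumeration_oracle(self):
        ddis = [({"a", "b"}, "severe"), ({"a", "c"}, "moderate"),
                ({"b", "c", "d"}, "contraindicated"), ({"d", "e"}, "minor"),
                ({"a", "e"}, "minimal"), ({"b", "d"}, "moderate")]
        kb = make_kb(genes={"G": ["x", "y"]},
                     frequencies={"G": {"x": 0.5, "y": 0.5}},
                     rules=[("a", "G", {"x"}, "moderate")],
                     ddi_rules=ddis)
        profile = {"a", "b", "c", "d", "e"}
        for meds in itertools.chain.from_iterable(
                itertools.combinations(profile, k) for k in range(6)):
            meds = frozenset(meds)
            expected = {s: 0 for s in DDI_SEVERITY_ORDER}
            for drugs, sev in ddis:
                if drugs <= meds:
                    expected[sev] += 1
            assert count_ddis(meds, kb) == expected


class TestRankAutomated:
    def _result(self, pid, pip, ddi=None, total=0):
        counts = {s: 0 for s in DDI_SEVERITY_ORDER}
        counts.update(ddi or {})
        return PIPResult(patient_id=pid, per_gene_prob={}, pip_percent=pip,
                         band=band(pip), nnt=100 / pip if pip else None,
                         ddi_severity_counts=counts, total_med_count=total)

    def test_higher_pip_ranks_first(self):
        order = rank_automated([self._result("A", 60), self._result("B", 55)], seed=0)
        assert order == ("A", "B")

    def test_severity_outranks_raw_ddi_count(self):
        a = self._result("A", 40, ddi={"severe": 1})
        b = self._result("B", 40, ddi={"moderate": 3})
        assert rank_automated([a, b], seed=0) == ("A", "B")

    def test_medication_count_breaks_remaining_ties(self):
        a = self._result("A", 40, total=5)
        b = self._result("B", 40, total=9)
        assert rank_automated([a, b], seed=0) == ("B", "A")

    def test_full_ties_deterministic_per_seed(self):
        results = [self._result(p, 40) for p in "ABCD"]
        for seed in (1, 2, 3):
            assert rank_automated(results, seed=seed) == rank_automated(results, seed=seed)
        assert {rank_automated(results, seed=s) for s in range(10)} != set()
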
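"""Seeded synthetic claims populations for exercising the full pipeline.

Real pharmacy/medical claims of the kind this pipeline consumes are
confidential, so the generator emits a population with the same table
schema and the statistical structure the analysis assumes: adult ages
from a truncated normal, a configurable female fraction, a per-patient
count of panel ("included") medications drawn from a calibrated pmf with
popularity-weighted drug assignment, Poisson background medications off
the panel, 1–3 fills per medication uniformly dated in the window, and
independent Bernoulli ER/inpatient events with log-normal costs. A small
fraction of extra pharmacy claims carry deliberately unmappable NDCs
(non-drug items such as lancets) to exercise the code-mapping drop path.

The default calibration makes the population's included-medication count
marginals land at 57% with exactly one, 13.1% with two, 2.5% with three
and 0.7% with four or more — i.e. 73.3% with at least one — and puts
metoprolol, ondansetron and sertraline at the top of the popularity
ranking. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge_base import KnowledgeBase, load_kb, union_medications

__all__ = ["SimConfig", "SyntheticDataset", "default_config", "generate",
           "BACKGROUND_MEDICATIONS"]

#: Common non-panel ingredients filling out medication lists.
BACKGROUND_MEDICATIONS = (
    "lisinopril", "atorvastatin", "levothyroxine", "amlodipine", "metformin",
    "albuterol", "gabapentin", "hydrochlorothiazide", "losartan",
    "montelukast", "fluticasone", "prednisone", "amoxicillin", "azithromycin",
    "ibuprofen", "naproxen", "cetirizine", "loratadine", "trazodone",
    "bupropion", "duloxetine", "rosuvastatin", "pravastatin", "insulin glargine",
    "apixaban", "furosemide", "spironolactone", "melatonin", "cephalexin",
    "doxycycline",
)

#: Most-dispensed panel drugs, in descending popularity.
TOP_INCLUDED = ("metoprolol", "ondansetron", "sertraline")


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs; defaults come from :func:`default_config`."""

    n_patients: int
    seed: int
    age_mean: float
    age_sd: float
    prop_female: float
    included_med_count_pmf: tuple[float, ...]  # P(K = 0, 1, 2, 3, 4+)
    background_med_rate: float
    er_prob: float
    inpatient_prob: float
    er_cost_log_mu: float
    er_cost_log_sigma: float
    inpatient_cost_log_mu: float
    inpatient_cost_log_sigma: float
    unmappable_claim_frac: float
    window_start: dt.date = dt.date(2018, 10, 1)
    window_end: dt.date = dt.date(2019, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        pmf = np.asarray(self.included_med_count_pmf, dtype=float)
        if pmf.ndim != 1 or len(pmf) < 2 or (pmf < 0).any() or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("included_med_count_pmf must be a probability vector summing to 1")
        for name in ("prop_female", "er_prob", "inpatient_prob", "unmappable_claim_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class SyntheticDataset:
    demographics: pd.DataFrame
    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    mapping: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(outdir / "demographics.csv", index=False)
        self.pharmacy.to_csv(outdir / "pharmacy.csv", index=False)
        self.medical.to_csv(outdir / "medical.csv", index=False)
        self.mapping.to_csv(outdir / "mapping.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def default_config(n_patients: int = 20_000, seed: int = 0) -> SimConfig:
    """Calibrated defaults: the study-population conditions.

    The included-medication pmf puts 57% of patients at exactly one panel
    medication, 13.1% at two, 2.5% at three and 0.7% at four; the 26.7%
    mass at zero is back-derived so the at-least-one fraction is 73.3%.
    Age is 35 ± 17.4 years (truncated at 18) and 62% of patients are
    female. Cost scales are illustrative log-normals of realistic
    magnitude, not calibrated quantities.
    """
    return SimConfig(
        n_patients=n_patients,
        seed=seed,
        age_mean=35.0,
        age_sd=17.4,
        prop_female=0.62,
        included_med_count_pmf=(0.267, 0.57, 0.131, 0.025, 0.007),
        background_med_rate=2.0,
        er_prob=0.08,
        inpatient_prob=0.04,
        er_cost_log_mu=6.9,
        er_cost_log_sigma=1.0,
        inpatient_cost_log_mu=9.3,
        inpatient_cost_log_sigma=1.1,
        unmappable_claim_frac=0.015,
    )


def _popularity_weights(included: list[str]) -> np.ndarray:
    """Zipf-like weights over the panel drugs, top sellers first."""
    ordered = list(TOP_INCLUDED) + sorted(set(included) - set(TOP_INCLUDED))
    rank = {m: i for i, m in enumerate(ordered)}
    return np.array([1.0 / (1.0 + rank[m]) ** 0.8 for m in included])


def _build_mapping(included: list[str], kb: KnowledgeBase) -> pd.DataFrame:
    """Synthetic 11-digit NDC and RxCUI for every generatable ingredient."""
    rxcui = {m.name: m.rxcui for m in kb.medications}
    rows = []
    for i, name in enumerate(included + list(BACKGROUND_MEDICATIONS)):
        rows.append({
            "ndc": f"{50000000000 + 7 * i:011d}",
            "rxcui": rxcui.get(name, str(900001 + i)),
            "ingredient": name,
        })
    return pd.DataFrame(rows)


def generate(config: SimConfig, kb: KnowledgeBase | None = None) -> SyntheticDataset:
    """Generate one synthetic population; byte-identical per (config, seed)."""
    kb = kb if kb is not None else load_kb()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    window_days = (config.window_end - config.window_start).days

    included = sorted(union_medications(kb))
    weights = _popularity_weights(included)
    probs = weights / weights.sum()
    mapping = _build_mapping(included, kb)
    ndc_of = dict(zip(mapping["ingredient"], mapping["ndc"]))

    # demographics: truncated-normal ages (resample below 18), Bernoulli sex
    ids = [f"P{i:06d}" for i in range(n)]
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    while (ages < 18).any():
        bad = ages < 18
        ages[bad] = rng.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    demographics = pd.DataFrame(
        {"patient_id": ids, "age_years": ages.astype(int), "sex": sex}
    )

    # medication lists: K included meds from the pmf, Poisson background meds
    pmf = np.asarray(config.included_med_count_pmf)
    k_included = rng.choice(len(pmf), size=n, p=pmf)
    n_background = rng.poisson(config.background_med_rate, size=n)

    rx_rows: list[tuple[str, str, str]] = []  # (patient_id, date, ndc)
    bg = list(BACKGROUND_MEDICATIONS)
    for i, pid in enumerate(ids):
        k = int(k_included[i])
        meds = list(rng.choice(included, size=min(k, len(included)),
                               replace=False, p=probs)) if k else []
        nb = int(n_background[i])
        if nb == 0 and not meds:
            nb = 1  # every patient fills something in the window
        meds += list(rng.choice(bg, size=min(nb, len(bg)), replace=False))
        for med in meds:
            for _ in range(int(rng.integers(1, 4))):
                day = int(rng.integers(0, window_days))
                date = config.window_start + dt.timedelta(days=day)
                rx_rows.append((pid, date.isoformat(), ndc_of[med]))

    # extra unmappable claims: non-drug items absent from the mapping table
    n_unmappable = int(round(config.unmappable_claim_frac * len(rx_rows)))
    for j in range(n_unmappable):
        pid = ids[int(rng.integers(0, n))]
        day = int(rng.integers(0, window_days))
        date = config.window_start + dt.timedelta(days=day)
        rx_rows.append((pid, date.isoformat(), f"{99900000000 + j:011d}"))
    pharmacy = pd.DataFrame(rx_rows, columns=["patient_id", "fill_date", "ndc"])

    # ER / inpatient events, independent of medication burden by default
    med_rows: list[tuple[str, str, str, float]] = []
    for visit_type, prob, mu, sigma in (
        ("ER", config.er_prob, config.er_cost_log_mu, config.er_cost_log_sigma),
        ("inpatient", config.inpatient_prob,
         config.inpatient_cost_log_mu, config.inpatient_cost_log_sigma),
    ):
        hit = rng.random(n) < prob
        for i in np.flatnonzero(hit):
            day = int(rng.integers(0, window_days))
            date = config.window_start + dt.timedelta(days=day)
            cost = float(np.round(rng.lognormal(mu, sigma), 2))
            med_rows.append((ids[i], visit_type, date.isoformat(), cost))
    medical = pd.DataFrame(med_rows, columns=["patient_id", "visit_type", "date", "cost"])

    manifest = {"config": asdict(config), "n_pharmacy_claims": len(pharmacy),
                "n_unmappable_claims": n_unmappable, "n_medical_claims": len(medical)}
    return SyntheticDataset(
        demographics=demographics,
        pharmacy=pharmacy,
        medical=medical,
        mapping=mapping,
        manifest=manifest,
    )
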
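"""Claims ingestion: code mapping, eligibility filtering, patient profiles.

Pharmacy claims arrive keyed by 11-digit NDC (a package-level drug code);
scoring works on ingredient names, so claims are first translated through
a local NDC→(RxCUI, ingredient) mapping table. Claims whose NDC is absent
from the table — typically non-drug items such as lancets and test
strips — are dropped and counted.

Eligibility then proceeds through sequential filters (adults, activity in
the analysis window, exposure to a panel medication, complete
demographics), each logged with the number of patients it removes, and
the survivors are summarized into one profile per patient: the set of
unique ingredients filled in the window plus ER/inpatient utilization.

All date windows are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .knowledge_base import KnowledgeBase, union_medications

__all__ = [
    "PHARMACY_COLUMNS",
    "MEDICAL_COLUMNS",
    "DEMOGRAPHICS_COLUMNS",
    "PatientProfile",
    "FilterLog",
    "read_claims_tables",
    "load_ndc_mapping",
    "map_ndc",
    "filter_eligible",
    "build_profiles",
    "profiles_to_frame",
]

PHARMACY_COLUMNS = ["patient_id", "fill_date", "ndc"]
MEDICAL_COLUMNS = ["patient_id", "visit_type", "date", "cost"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "age_years", "sex"]

VISIT_TYPES = ("ER", "inpatient")


@dataclass(frozen=True)
class PatientProfile:
    """One patient's demographics, active medications and utilization."""

    patient_id: str
    age_years: int
    sex: str
    medications: frozenset[str]
    er_visits: int = 0
    er_cost: float = 0.0
    inpatient_visits: int = 0
    inpatient_cost: float = 0.0

    @property
    def n_unique_meds(self) -> int:
        return len(self.medications)


@dataclass
class FilterLog:
    """Per-filter exclusion counts for the eligibility cascade.

    ``n_with_included_claim`` additionally records how many of the final
    eligible patients have at least one claim for a panel medication when
    the panel filter itself is switched off — the two readings of the
    "predefined medication list" are logged side by side.
    """

    n_input: int = 0
    excluded_underage: int = 0
    excluded_no_claim_in_window: int = 0
    excluded_no_included_medication: int = 0
    excluded_incomplete_demographics: int = 0
    n_eligible: int = 0
    n_with_included_claim: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def read_claims_tables(
    pharmacy: str | Path,
    medical: str | Path,
    demographics: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three claims CSVs, enforcing schema and basic invariants."""
    rx = pd.read_csv(pharmacy, dtype={"patient_id": str, "ndc": str},
                     parse_dates=["fill_date"])
    med = pd.read_csv(medical, dtype={"patient_id": str}, parse_dates=["date"])
    demo = pd.read_csv(demographics, dtype={"patient_id": str})

    for name, frame, cols in (
        ("pharmacy", rx, PHARMACY_COLUMNS),
        ("medical", med, MEDICAL_COLUMNS),
        ("demographics", demo, DEMOGRAPHICS_COLUMNS),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")

    if (med["cost"] < 0).any():
        raise ValueError("medical table has negative costs")
    bad_type = set(med["visit_type"]) - set(VISIT_TYPES)
    if bad_type:
        raise ValueError(f"medical table has unknown visit types {sorted(bad_type)}")
    if demo["patient_id"].duplicated().any():
        raise ValueError("demographics table has duplicate patient ids")
    return rx, med, demo


def load_ndc_mapping(path: str | Path) -> pd.DataFrame:
    """Load the local NDC→(rxcui, ingredient) table (columns ndc, rxcui, ingredient)."""
    mapping = pd.read_csv(path, dtype=str)
    missing = {"ndc", "rxcui", "ingredient"} - set(mapping.columns)
    if missing:
        raise ValueError(f"mapping table missing columns {sorted(missing)}")
    if mapping["ndc"].duplicated().any():
        raise ValueError("mapping table has duplicate NDCs")
    return mapping


def map_ndc(
    claims: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach rxcui and ingredient to pharmacy claims via the mapping table.

    Returns ``(mapped, dropped)``: claims whose NDC has no entry in the
    table (non-drug items, malformed codes) go to ``dropped`` unchanged.
    """
    if claims.empty:
        empty = claims.copy()
        mapped = empty.assign(**{c: pd.Series(dtype=str) for c in ("rxcui", "ingredient")})
        return mapped, empty
    well_formed = claims["ndc"].str.fullmatch(r"\d{11}", na=False)
    merged = claims.merge(mapping, on="ndc", how="left")
    ok = well_formed.to_numpy() & merged["ingredient"].notna().to_numpy()
    mapped = merged.loc[ok].reset_index(drop=True)
    dropped = claims.loc[~ok].reset_index(drop=True)
    return mapped, dropped


def filter_eligible(
    demographics: pd.DataFrame,
    mapped_claims: pd.DataFrame,
    window: tuple[dt.date, dt.date],
    kb: KnowledgeBase,
    require_included_medication: bool = True,
) -> tuple[set[str], FilterLog]:
    """Apply the eligibility cascade and log per-filter exclusions.

    Filters, in order: (1) age ≥ 18 at window start; (2) at least one
    pharmacy fill inside the half-open window; (3) at least one in-window
    fill for a medication on the union of the manual and automated lists
    (skipped when ``require_included_medication`` is false, but still
    logged); (4) complete demographics (age and sex present).
    """
    start, end = _as_date(window[0]), _as_date(window[1])
    if start >= end:
        raise ValueError(f"empty analysis window {start}..{end}")

    log = FilterLog(n_input=len(demographics))
    demo = demographics.copy()

    adults = demo[pd.to_numeric(demo["age_years"], errors="coerce") >= 18]
    log.excluded_underage = len(demo) - len(adults)

    dates = pd.to_datetime(mapped_claims["fill_date"]).dt.date if len(mapped_claims) else pd.Series(dtype=object)
    in_window = mapped_claims.loc[[(start <= d < end) for d in dates]] if len(mapped_claims) else mapped_claims
    active_ids = set(in_window["patient_id"]) if len(in_window) else set()
    active = adults[adults["patient_id"].isin(active_ids)]
    log.excluded_no_claim_in_window = len(adults) - len(active)

    included = union_medications(kb)
    with_inc = in_window[in_window["ingredient"].isin(included)] if len(in_window) else in_window
    inc_ids = set(with_inc["patient_id"]) if len(with_inc) else set()
    if require_included_medication:
        exposed = active[active["patient_id"].isin(inc_ids)]
    else:
        exposed = active
    log.excluded_no_included_medication = len(active) - len(exposed)

    complete = exposed[
        pd.to_numeric(exposed["age_years"], errors="coerce").notna()
        & exposed["sex"].isin(["male", "female"])
    ]
    log.excluded_incomplete_demographics = len(exposed) - len(complete)

    eligible = set(complete["patient_id"])
    log.n_eligible = len(eligible)
    log.n_with_included_claim = len(eligible & inc_ids)
    return eligible, log


def build_profiles(
    eligible_ids: Iterable[str],
    mapped_claims: pd.DataFrame,
    medical_claims: pd.DataFrame,
    demographics: pd.DataFrame,
    window: tuple[dt.date, dt.date],
) -> list[PatientProfile]:
    """Build one profile per eligible patient from in-window claims.

    Medications are the unique ingredients with at least one fill in the
    half-open window; ER and inpatient visit counts and costs are summed
    over in-window medical claims. Patients without medical claims get
    zero counts and costs.
    """
    start, end = _as_date(window[0]), _as_date(window[1])
    ids = sorted(set(map(str, eligible_ids)))
    demo = demographics.set_index("patient_id")
    missing = [i for i in ids if i not in demo.index]
    if missing:
        raise KeyError(f"patients without demographics rows: {missing[:5]}")

    if len(mapped_claims):
        rx_dates = pd.to_datetime(mapped_claims["fill_date"]).dt.date
        rx = mapped_claims.loc[[(start <= d < end) for d in rx_dates]]
        meds_by_id = rx.groupby("patient_id")["ingredient"].agg(frozenset)
    else:
        meds_by_id = pd.Series(dtype=object)

    visits: dict[tuple[str, str], tuple[int, float]] = {}
    if len(medical_claims):
        mc_dates = pd.to_datetime(medical_claims["date"]).dt.date
        mc = medical_claims.loc[[(start <= d < end) for d in mc_dates]]
        grouped = mc.groupby(["patient_id", "visit_type"])["cost"].agg(["count", "sum"])
        visits = {
            idx: (int(row["count"]), float(row["sum"]))
            for idx, row in grouped.iterrows()
        }

    profiles = []
    for pid in ids:
        row = demo.loc[pid]
        er_n, er_cost = visits.get((pid, "ER"), (0, 0.0))
        ip_n, ip_cost = visits.get((pid, "inpatient"), (0, 0.0))
        profiles.append(
            PatientProfile(
                patient_id=pid,
                age_years=int(row["age_years"]),
                sex=str(row["sex"]),
                medications=meds_by_id.get(pid, frozenset()),
                er_visits=er_n,
                er_cost=er_cost,
                inpatient_visits=ip_n,
                inpatient_cost=ip_cost,
            )
        )
    return profiles


def profiles_to_frame(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    """Flatten profiles to a DataFrame (medications as a ';'-joined string)."""
    rows = [
        {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "medications": ";".join(sorted(p.medications)),
            "n_unique_meds": p.n_unique_meds,
            "er_visits": p.er_visits,
            "er_cost": p.er_cost,
            "inpatient_visits": p.inpatient_visits,
            "inpatient_cost": p.inpatient_cost,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
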
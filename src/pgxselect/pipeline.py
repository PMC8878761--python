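"""One-call study pipeline: simulate → ingest → select → compare."""

from __future__ import annotations

import pandas as pd

from . import claims_io, cohort_compare, manual_method, pip_method, synthetic_data
from .knowledge_base import KnowledgeBase, load_kb


def cohort_panel(
    profiles: list[claims_io.PatientProfile],
    results: dict[str, pip_method.PIPResult],
    ids: set[str],
) -> pd.DataFrame:
    """Per-patient metric table for a selected cohort, for `compare`."""
    rows = []
    for p in profiles:
        if p.patient_id not in ids:
            continue
        r = results[p.patient_id]
        rows.append({
            "patient_id": p.patient_id,
            "n_unique_meds": p.n_unique_meds,
            "ddi_mod_plus": pip_method.moderate_or_higher_ddi(r.ddi_severity_counts),
            "pip_percent": r.pip_percent,
            "er_visits": p.er_visits,
            "er_cost": p.er_cost,
            "inpatient_visits": p.inpatient_visits,
            "inpatient_cost": p.inpatient_cost,
            "age_years": p.age_years,
            "sex": p.sex,
        })
    return pd.DataFrame(rows)


def run_study(
    n_patients: int,
    seed: int,
    target: int = 250,
    kb: KnowledgeBase | None = None,
) -> dict:
    """Run the full comparison study on one synthetic population.

    Returns the eligibility log, both cohort selections, and the
    two-cohort comparison report.
    """
    kb = kb if kb is not None else load_kb()
    cfg = synthetic_data.default_config(n_patients=n_patients, seed=seed)
    ds = synthetic_data.generate(cfg, kb)
    window = (cfg.window_start, cfg.window_end)

    mapped, dropped = claims_io.map_ndc(ds.pharmacy, ds.mapping)
    eligible, log = claims_io.filter_eligible(ds.demographics, mapped, window, kb)
    profiles = claims_io.build_profiles(eligible, mapped, ds.medical,
                                        ds.demographics, window)

    scores = [manual_method.manual_score(p, kb) for p in profiles]
    manual_sel = manual_method.select_natural_cut(
        {s.patient_id: s.manual_med_count for s in scores}, target,
        method="manual", ranking=manual_method.rank_manual(scores, seed=seed),
    )

    results = {p.patient_id: pip_method.pip_score(p, kb) for p in profiles}
    auto_sel = manual_method.select_natural_cut(
        {pid: r.pip_percent for pid, r in results.items()}, target,
        method="automated",
        ranking=pip_method.rank_automated(list(results.values()), seed=seed),
    )

    report = cohort_compare.compare(
        cohort_panel(profiles, results, set(manual_sel.selected)),
        cohort_panel(profiles, results, set(auto_sel.selected)),
    )
    return {
        "config": cfg,
        "filter_log": log,
        "n_dropped_claims": len(dropped),
        "profiles": profiles,
        "manual_selection": manual_sel,
        "automated_selection": auto_sel,
        "pip_results": results,
        "report": report,
    }
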
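"""Two-cohort comparison: overlap, means with Welch t-tests, proportions.

Reproduces the shape of a selected-cohort comparison table: average
unique medication count, drug-interaction burden, mean PIP, ER and
inpatient utilization and costs, age and sex, each with a two-sided test.
Continuous metrics use the Welch unequal-variance two-sample t-test
(robust to the unequal cohort sizes these selections produce); binary
metrics use a pooled two-proportion z-test. Cost means are computed over
the whole cohort, zero-cost patients included; the per-patient-with-visit
variant is reported alongside. Raw p-values, no multiplicity correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricResult",
    "ComparisonReport",
    "overlap",
    "welch_t",
    "prop_test",
    "compare",
    "report_to_markdown",
]

#: Per-patient columns `compare` expects from each cohort table.
PANEL_COLUMNS = [
    "patient_id", "n_unique_meds", "ddi_mod_plus", "pip_percent",
    "er_visits", "er_cost", "inpatient_visits", "inpatient_cost",
    "age_years", "sex",
]


@dataclass(frozen=True)
class MetricResult:
    metric: str
    group1: str
    group2: str
    statistic: float
    df: float | None
    p_value: float
    test: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.metric}: p-value {self.p_value} outside [0,1]")


@dataclass
class ComparisonReport:
    n_a: int
    n_b: int
    overlap_count: int
    overlap_fraction: float | None
    jaccard: float | None
    metrics: list[MetricResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "overlap_count": self.overlap_count,
            "overlap_fraction": self.overlap_fraction,
            "jaccard": self.jaccard,
            "metrics": [asdict(m) for m in self.metrics],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def overlap(cohort_a: Iterable[str], cohort_b: Iterable[str]) -> tuple[int, float | None]:
    """Shared patients between two cohorts, as count and fraction of the smaller."""
    a, b = set(cohort_a), set(cohort_b)
    count = len(a & b)
    if not a or not b:
        return count, None
    return count, count / min(len(a), len(b))


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def welch_t(
    sample_a: Sequence[float], sample_b: Sequence[float], metric: str = "metric"
) -> MetricResult:
    """Welch unequal-variance two-sample t-test, two-sided.

    Degenerate input (a sample with fewer than two values, or zero
    variance in both samples with differing means) raises, naming the
    metric; two zero-variance samples with equal means compare trivially
    equal (t = 0, p = 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{metric}: each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if not np.isclose(a.mean(), b.mean()):
            raise ValueError(f"{metric}: both samples degenerate with unequal means")
        t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return MetricResult(
        metric=metric,
        group1=_mean_sd(a),
        group2=_mean_sd(b),
        statistic=t,
        df=df,
        p_value=p,
        test="welch_t",
    )


def prop_test(k1: int, n1: int, k2: int, n2: int, metric: str = "metric") -> MetricResult:
    """Two-proportion z-test with pooled variance, no continuity correction."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError(f"{metric}: invalid proportion {k}/{n}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0.0:  # pooled proportion 0 or 1 forces p1 == p2
        z, p = 0.0, 1.0
    else:
        z = (p1 - p2) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return MetricResult(
        metric=metric,
        group1=f"{k1}/{n1} ({100 * p1:.1f}%)",
        group2=f"{k2}/{n2} ({100 * p2:.1f}%)",
        statistic=z,
        df=None,
        p_value=min(p, 1.0),
        test="two_proportion_z",
    )


def _check_columns(frame: pd.DataFrame, label: str) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table {label} missing columns {missing}")


def compare(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> ComparisonReport:
    """Full comparison panel for two per-patient cohort tables.

    Each table needs one row per selected patient with the columns in
    ``PANEL_COLUMNS`` (``ddi_mod_plus`` is the count of moderate-or-higher
    drug–drug interactions; ``pip_percent`` the automated score).
    """
    _check_columns(cohort_a, "A")
    _check_columns(cohort_b, "B")
    if cohort_a.empty or cohort_b.empty:
        raise ValueError("both cohorts must be non-empty")

    ids_a, ids_b = set(cohort_a["patient_id"]), set(cohort_b["patient_id"])
    count, frac = overlap(ids_a, ids_b)
    union = len(ids_a | ids_b)
    report = ComparisonReport(
        n_a=len(ids_a),
        n_b=len(ids_b),
        overlap_count=count,
        overlap_fraction=frac,
        jaccard=count / union if union else None,
    )

    def w(col: str, name: str) -> None:
        report.metrics.append(welch_t(cohort_a[col], cohort_b[col], metric=name))

    def pr(mask_a: pd.Series, mask_b: pd.Series, name: str) -> None:
        report.metrics.append(
            prop_test(int(mask_a.sum()), len(cohort_a),
                      int(mask_b.sum()), len(cohort_b), metric=name)
        )

    w("n_unique_meds", "average unique medication count")
    w("ddi_mod_plus", "drug interactions, moderate-or-higher, mean")
    pr(cohort_a["ddi_mod_plus"] >= 1, cohort_b["ddi_mod_plus"] >= 1,
       "at least one moderate-or-higher drug interaction, % patients")
    w("pip_percent", "average PIP score, %")
    pr(cohort_a["er_visits"] >= 1, cohort_b["er_visits"] >= 1,
       "at least one ER visit, % patients")
    w("er_cost", "ER visit claim cost, overall")
    pr(cohort_a["inpatient_visits"] >= 1, cohort_b["inpatient_visits"] >= 1,
       "at least one inpatient visit, % patients")
    w("inpatient_cost", "inpatient claim cost, overall")
    w("age_years", "age, years")
    pr(cohort_a["sex"] == "female", cohort_b["sex"] == "female", "female sex, % patients")
    return report


def report_to_markdown(report: ComparisonReport) -> str:
    """Render the comparison panel as a Markdown table."""
    lines = [
        f"Cohort A n = {report.n_a}, cohort B n = {report.n_b}; "
        f"overlap {report.overlap_count}"
        + (f" ({100 * report.overlap_fraction:.0f}% of smaller cohort)"
           if report.overlap_fraction is not None else ""),
        "",
        "| Metric | Cohort A | Cohort B | p value |",
        "| --- | --- | --- | --- |",
    ]
    for m in report.metrics:
        p = "<0.0001" if m.p_value < 1e-4 else f"{m.p_value:.4g}"
        lines.append(f"| {m.metric} | {m.group1} | {m.group2} | {p} |")
    return "\n".join(lines) + "\n"
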
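"""Kaplan-Meier estimation, log-rank tests and demographic summaries.

Survival is measured from first surgery until death; alive patients are
censored at last follow-up (``event_observed=False``).  Estimation and the
Mantel-Cox test are delegated to lifelines; this module provides the thin,
typed surface the pipeline works with (curves exportable as TSV, comparisons
as JSON-ready dataclasses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _catalog as cat
from .classifier import SubgroupCall
from .cohort import Cohort


@dataclass
class KMCurve:
    """Product-limit estimate: step function over event times.

    ``times`` start at 0 with survival 1.0; deaths are processed before
    censorings at tied times (standard product-limit convention).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SurvivalComparison:
    groups: list[str]
    chi_square: float
    p_value: float
    degrees_of_freedom: int
    medians: dict[str, float | None] = field(default_factory=dict)


def km_fit(records: list[tuple[float, bool]]) -> KMCurve:
    """Fit the product-limit estimator to (time, event) records."""
    if not records:
        raise ValueError("need at least one record")
    times = np.asarray([t for t, _ in records], float)
    events = np.asarray([bool(e) for _, e in records])
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    grid = table.index.to_numpy(float)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)
    if grid[0] != 0.0:
        grid = np.insert(grid, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        at_risk = np.insert(table["at_risk"].to_numpy(int), 0, len(records))
        observed = np.insert(table["observed"].to_numpy(int), 0, 0)
    else:
        at_risk = table["at_risk"].to_numpy(int)
        observed = table["observed"].to_numpy(int)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk,
                   events=observed)


def km_median(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5; None when never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def landmark_survival(curve: KMCurve, t: float) -> float:
    """S(t) by right-continuous step interpolation; beyond the last event
    time the last estimate carries forward."""
    if t < 0:
        raise ValueError("landmark time must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank(groups: dict[str, list[tuple[float, bool]]]) -> SurvivalComparison:
    """Mantel-Cox log-rank test across >= 2 groups (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    empty = [name for name, recs in groups.items() if not recs]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    durations, events, labels = [], [], []
    medians: dict[str, float | None] = {}
    for name, recs in groups.items():
        durations += [t for t, _ in recs]
        events += [bool(e) for _, e in recs]
        labels += [name] * len(recs)
        medians[name] = km_median(km_fit(recs))
    if not any(events):
        raise ValueError("no events observed in any group")
    res = multivariate_logrank_test(durations, labels, events)
    return SurvivalComparison(
        groups=sorted(groups),
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        degrees_of_freedom=len(groups) - 1,
        medians=medians,
    )


def pairwise_logrank(groups: dict[str, list[tuple[float, bool]]]
                     ) -> pd.DataFrame:
    """All pairwise comparisons; raw p-values plus a Holm-adjusted column
    (the adjustment is an extension beyond the raw reporting convention)."""
    rows = []
    for a, b in combinations(sorted(groups), 2):
        cmp = logrank({a: groups[a], b: groups[b]})
        rows.append({"group_a": a, "group_b": b,
                     "chi_square": cmp.chi_square, "p_raw": cmp.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def tukey_fence_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values inside the Tukey fences (1.5 x IQR)."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def survival_records(cohort: Cohort,
                     subgroup_calls: dict[str, SubgroupCall]
                     ) -> dict[str, list[tuple[float, bool]]]:
    """(time, event) records per subgroup label, DMG excluded."""
    out: dict[str, list[tuple[float, bool]]] = {}
    for case in cohort:
        label = subgroup_calls[case.case_id].label
        if label == cat.DMG:
            continue
        out.setdefault(label, []).append(
            (case.survival_months, case.event_observed))
    return out


def demographic_summary(cohort: Cohort,
                        subgroup_calls: dict[str, SubgroupCall],
                        *, exclude_age_outliers: bool = True
                        ) -> pd.DataFrame:
    """Per-subgroup demographics: age mean +/- SEM and median (Tukey-fence
    outliers excluded from mean/SEM), sex ratio (M:F), ethnicity ratio
    (White:Black), location distribution."""
    rows = []
    for label in cat.ALL_LABELS:
        cases = [c for c in cohort
                 if subgroup_calls[c.case_id].label == label]
        if not cases:
            continue
        ages = np.asarray([c.age for c in cases], float)
        kept = ages[tukey_fence_mask(ages)] if exclude_age_outliers else ages
        n_m = sum(c.sex == "M" for c in cases)
        n_f = sum(c.sex == "F" for c in cases)
        n_w = sum(c.ethnicity == "White" for c in cases)
        n_b = sum(c.ethnicity == "Black" for c in cases)
        loc = pd.Series([c.location for c in cases]).value_counts()
        rows.append({
            "subgroup": label,
            "n": len(cases),
            "age_mean": float(kept.mean()),
            "age_sem": float(stats.sem(kept)) if kept.size > 1 else 0.0,
            "age_median": float(np.median(ages)),
            "male": n_m, "female": n_f,
            "sex_ratio_m_f": round(n_m / n_f, 2) if n_f else np.inf,
            "white": n_w, "black": n_b,
            "ethnicity_ratio_w_b": round(n_w / n_b, 2) if n_b else np.inf,
            **{f"loc_{k}": int(loc.get(k, 0))
               for k in ("frontal", "temporal", "parietal", "other_lobe",
                         "midline", "corpus_callosum")},
        })
    return pd.DataFrame(rows).set_index("subgroup")


def pairwise_age_tests(cohort: Cohort,
                       subgroup_calls: dict[str, SubgroupCall],
                       *, exclude_outliers: bool = True) -> pd.DataFrame:
    """Welch two-tailed t-tests for all subgroup age contrasts; pairs with a
    group of size < 2 are skipped with a note."""
    ages: dict[str, np.ndarray] = {}
    for label in cat.ALL_LABELS:
        a = np.asarray([c.age for c in cohort
                        if subgroup_calls[c.case_id].label == label], float)
        if exclude_outliers and a.size:
            a = a[tukey_fence_mask(a)]
        if a.size:
            ages[label] = a
    rows = []
    for a, b in combinations(sorted(ages), 2):
        if len(ages[a]) < 2 or len(ages[b]) < 2:
            rows.append({"group_a": a, "group_b": b, "t": np.nan,
                         "p_raw": np.nan, "note": "skipped: n < 2"})
            continue
        t, p = stats.ttest_ind(ages[a], ages[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t),
                     "p_raw": float(p), "note": ""})
    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    if tested.any():
        out.loc[tested, "p_holm"] = multipletests(
            out.loc[tested, "p_raw"], method="holm")[1]
    return out
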
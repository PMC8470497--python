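"""Histologic pattern -> cluster mapping and histologic-molecular association.

Twelve expert-assigned morphology patterns aggregate into five histologic
clusters (EGFR-like, Small neuronal-like, Anaplastic, Spindle, Epithelioid).
Pattern assignments without an explicit morphological anchor are tagged
``inferred`` and live in the editable config.  Associations between clusters
and molecular features are tested per (cluster, feature) pair with a
two-sided Fisher exact test on the 2x2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from . import _catalog as cat
from .calls import build_calls
from .classifier import SubgroupCall
from .cohort import Cohort, HISTOLOGIC_PATTERNS
from .pathways import pathway_status, g1_phase_members

HISTOLOGIC_CLUSTERS = (
    "EGFR_like", "Small_neuronal", "Anaplastic", "Spindle", "Epithelioid",
)

#: Default total mapping of the 12 patterns onto the 5 clusters.
DEFAULT_PATTERN_TO_CLUSTER: dict[str, str] = {
    "egfr": "EGFR_like",
    "egfr_fgfr": "EGFR_like",
    "fgfr_small": "Small_neuronal",
    "small_dark_regular": "Small_neuronal",
    "pre_hgne": "Small_neuronal",
    "hgne": "Anaplastic",
    "fibroblastic": "Spindle",
    "gliosarcoma": "Spindle",
    "giant_cell": "Epithelioid",
    "epithelioid": "Epithelioid",
    # inferred: no explicit morphological anchor in the pattern description
    "small_dark_irregular": "Anaplastic",
    "anaplastic_other": "Anaplastic",
}

#: Patterns whose cluster assignment is a config inference, not settled.
INFERRED_PATTERNS = frozenset({"small_dark_irregular", "anaplastic_other",
                               "pre_hgne"})


@dataclass(frozen=True)
class HistologyConfig:
    pattern_to_cluster: tuple[tuple[str, str], ...] = tuple(
        sorted(DEFAULT_PATTERN_TO_CLUSTER.items()))

    def mapping(self) -> dict[str, str]:
        return dict(self.pattern_to_cluster)

    def __post_init__(self) -> None:
        m = self.mapping()
        missing = set(HISTOLOGIC_PATTERNS) - set(m)
        if missing:
            raise ValueError(f"mapping not total; missing {sorted(missing)}")
        bad = set(m.values()) - set(HISTOLOGIC_CLUSTERS)
        if bad:
            raise ValueError(f"unknown clusters {sorted(bad)}")


DEFAULT_HISTOLOGY_CONFIG = HistologyConfig()


def assign_histologic_cluster(pattern: str,
                              config: HistologyConfig =
                              DEFAULT_HISTOLOGY_CONFIG) -> str:
    """Deterministic table lookup; unknown pattern is an error."""
    m = config.mapping()
    if pattern not in m:
        raise ValueError(f"unknown histologic pattern {pattern!r}")
    return m[pattern]


#: Molecular features entered into the association screen.
ASSOCIATION_FEATURES = (
    "CDKN2A_loss", "CDK4_amp", "RB1_mut", "TP53_mut", "tp53_path",
    "pi3k_mtor", "g1_phase",
)


def _case_features(case, calls, status) -> dict[str, bool]:
    members = g1_phase_members(case, calls)
    has_mut = lambda g: any(
        e.is_small_variant and e.is_pathogenic for e in case.events_for(g))
    return {
        "CDKN2A_loss": "CDKN2A" in members,
        "CDK4_amp": "CDK4" in members,
        "RB1_mut": has_mut("RB1"),
        "TP53_mut": has_mut("TP53"),
        "tp53_path": status.tp53_path,
        "pi3k_mtor": status.pi3k_mtor,
        "g1_phase": status.g1_phase,
    }


def histo_molecular_association(
    cohort: Cohort,
    subgroup_calls: dict[str, SubgroupCall],
    *,
    features: tuple[str, ...] = ASSOCIATION_FEATURES,
    config: HistologyConfig = DEFAULT_HISTOLOGY_CONFIG,
) -> pd.DataFrame:
    """One 2x2 table + two-sided Fisher exact p per (cluster, feature) pair.

    Only IDH-wild-type cases with genomic data and a known pattern enter;
    clusters absent from the cohort are skipped with a note row.
    """
    records = []
    for case in cohort:
        label = subgroup_calls[case.case_id].label
        if label in (cat.DMG,) or not case.has_genomic_data:
            continue
        if case.histologic_pattern == "unknown":
            continue
        calls = build_calls(case)
        status = pathway_status(case, calls)
        feats = _case_features(case, calls, status)
        records.append({
            "cluster": assign_histologic_cluster(case.histologic_pattern,
                                                 config),
            **{f: feats[f] for f in features},
        })
    df = pd.DataFrame(records)
    rows = []
    for cluster in HISTOLOGIC_CLUSTERS:
        if df.empty or not (df["cluster"] == cluster).any():
            rows.append({"cluster": cluster, "feature": None,
                         "note": "cluster absent from cohort"})
            continue
        in_cluster = df["cluster"] == cluster
        for feat in features:
            a = int((in_cluster & df[feat]).sum())
            b = int((in_cluster & ~df[feat]).sum())
            c = int((~in_cluster & df[feat]).sum())
            d = int((~in_cluster & ~df[feat]).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")
            rows.append({
                "cluster": cluster, "feature": feat,
                "with_feature_in": a, "without_feature_in": b,
                "with_feature_out": c, "without_feature_out": d,
                "odds_ratio": float(odds), "p_value": float(p),
                "note": "",
            })
    return pd.DataFrame(rows)
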
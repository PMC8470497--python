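"""Per-case pathology-style report: molecular subgroup with driver
evidence, histologic pattern and cluster, composite pathway statuses and
the MGMT call, traceable to the classifier configuration by hash."""

from __future__ import annotations

import dataclasses
import json

from . import __version__
from .calls import build_calls
from .classifier import ClassifierConfig, DEFAULT_CONFIG, classify_case
from .cohort import Case
from .histology import (DEFAULT_HISTOLOGY_CONFIG, HistologyConfig,
                        assign_histologic_cluster)
from .pathways import pathway_status

REPORT_SCHEMA_VERSION = 1


def build_case_report(case: Case,
                      config: ClassifierConfig = DEFAULT_CONFIG,
                      histology_config: HistologyConfig =
                      DEFAULT_HISTOLOGY_CONFIG) -> dict:
    """Assemble the JSON-canonical report for one case."""
    calls = build_calls(case, config.fold_threshold, config.cn_threshold)
    subgroup = classify_case(case, calls, config)
    status = pathway_status(case, calls)
    cluster = None
    if case.histologic_pattern != "unknown":
        cluster = assign_histologic_cluster(case.histologic_pattern,
                                            histology_config)
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "case_id": case.case_id,
        "subgroup": subgroup.label,
        "drivers": [{"gene": g, "evidence": e} for g, e in subgroup.drivers],
        "rules_fired": subgroup.rationale,
        "flags": sorted(subgroup.flags),
        "histologic_pattern": case.histologic_pattern,
        "histologic_cluster": cluster,
        "pathways": {
            k: v for k, v in dataclasses.asdict(status).items()
            if k not in ("mgmt", "tert")
        },
        "telomere_maintenance": status.tert,
        "mgmt_promoter_methylation": status.mgmt,
    }


def render_text(report: dict) -> str:
    """Human-readable rendering; the JSON form is canonical."""
    lines = [
        f"PATHOLOGY REPORT — case {report['case_id']}",
        f"Molecular subgroup: {report['subgroup']}",
    ]
    for d in report["drivers"]:
        lines.append(f"  driver: {d['gene']} ({d['evidence']})")
    if report["flags"]:
        lines.append(f"  flags: {', '.join(report['flags'])}")
    lines.append(
        f"Histologic pattern: {report['histologic_pattern']}"
        + (f" (cluster: {report['histologic_cluster']})"
           if report["histologic_cluster"] else ""))
    active = [k for k, v in report["pathways"].items() if v]
    lines.append("Pathway alterations: " + (", ".join(active) or "none"))
    lines.append(f"Telomere maintenance: {report['telomere_maintenance']}")
    lines.append(
        f"MGMT promoter methylation: {report['mgmt_promoter_methylation']}")
    lines.append(f"(tool {report['tool_version']}, "
                 f"config {report['config_hash']})")
    return "\n".join(lines)


def to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
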
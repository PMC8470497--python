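"""Composite pathway statuses and the subgroup x feature frequency matrix.

Each composite is a boolean OR over a defined gene set with a defined event
kind: amplification for CDK4/MDM2/MDM4/YEATS4, homozygous loss for CDKN2A,
pathogenic small variant otherwise.  Single-gene frequency rows count
somatic pathogenic events only (germline excluded), whereas composites and
the mutual-exclusivity audit include germline events — the convention under
which heterozygous germline RB1 carriers do not inflate the RB1 row but do
register as G1-phase exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import _catalog as cat
from .calls import GeneCall, build_calls, call_mgmt_methylated, tert_status
from .classifier import SubgroupCall
from .cohort import Case, Cohort


@dataclass
class PathwayStatus:
    """Composite pathway booleans for one case (genomic data required)."""

    tert_path: bool
    pi3k_mtor: bool
    g1_phase: bool
    tp53_path: bool
    ddr_path: bool
    mmr: bool
    swi_snf: bool
    other_chrm: bool
    mgmt: str  # positive / negative / unknown
    tert: str  # positive / negative / unknown


def _has_pathogenic_mutation(case: Case, gene: str,
                             include_germline: bool = True) -> bool:
    return any(
        e.is_small_variant and e.is_pathogenic
        and (include_germline or not e.germline)
        for e in case.events_for(gene)
    )


def _has_amplification(call: GeneCall | None) -> bool:
    return call is not None and call.amplified


def _case_tert(case: Case, calls: dict[str, GeneCall]) -> str:
    promoter = any(e.kind == "promoter_mutation" and e.is_pathogenic
                   for e in case.events_for("TERT"))
    fold = case.expression.fold("TERT") if case.expression else None
    return tert_status(promoter, fold)


def pathway_status(case: Case,
                   calls: dict[str, GeneCall] | None = None) -> PathwayStatus:
    """Compute all composite statuses for one case."""
    if calls is None:
        calls = build_calls(case)
    mut = lambda g: _has_pathogenic_mutation(case, g)
    amp = lambda g: _has_amplification(calls.get(g))

    tert = _case_tert(case, calls)
    pi3k = any(mut(g) for g in cat.PI3K_MTOR_GENES)
    cdkn2a = calls.get("CDKN2A")
    g1 = ((cdkn2a is not None and cdkn2a.homozygous_loss)
          or amp("CDK4") or mut("RB1"))
    tp53 = (mut("TP53") or mut("RPL5") or mut("PPM1D")
            or amp("MDM2") or amp("MDM4"))
    mmr = any(mut(g) for g in cat.MMR_GENES)
    ddr = mut("ATM") or mut("BRCA2") or mmr
    swi = any(mut(g) for g in cat.SWI_SNF_GENES)
    chrm = amp("YEATS4") or any(mut(g) for g in cat.CHROMATIN_GENES
                                if g != "YEATS4")
    return PathwayStatus(
        tert_path=(tert == "positive"),
        pi3k_mtor=pi3k, g1_phase=g1, tp53_path=tp53,
        ddr_path=ddr, mmr=mmr, swi_snf=swi, other_chrm=chrm,
        mgmt=call_mgmt_methylated(case.mgmt_value),
        tert=tert,
    )


def g1_phase_members(case: Case,
                     calls: dict[str, GeneCall] | None = None) -> set[str]:
    """Which G1-phase lesions the case carries (germline included) — used
    by the mutual-exclusivity audit."""
    if calls is None:
        calls = build_calls(case)
    members: set[str] = set()
    cdkn2a = calls.get("CDKN2A")
    if cdkn2a is not None and cdkn2a.homozygous_loss:
        members.add("CDKN2A")
    if _has_amplification(calls.get("CDK4")):
        members.add("CDK4")
    if _has_pathogenic_mutation(case, "RB1"):
        members.add("RB1")
    return members


def audit_g1_exclusivity(cohort: Cohort) -> list[str]:
    """Case ids violating G1-phase mutual exclusivity (>= 2 member lesions)."""
    return [c.case_id for c in cohort
            if c.has_genomic_data and len(g1_phase_members(c)) >= 2]


@dataclass
class CohortSummary:
    """Machine form of the subgroup x feature frequency table.

    ``matrix``: percent (0-100) per feature row and subgroup column, NaN for
    an empty denominator.  ``counts``: subgroup case counts (genomic data
    only).  ``numerators``/``denominators`` keep the underlying integers.
    """

    matrix: pd.DataFrame
    counts: pd.Series
    numerators: pd.DataFrame
    denominators: pd.DataFrame

    def to_table(self, decimals: int = 1) -> pd.DataFrame:
        """Display table with an IDH-wt Total column prepended."""
        wt_cols = [s for s in cat.IDH_WT_SUBGROUPS if s in self.matrix.columns]
        num = self.numerators[wt_cols].sum(axis=1)
        den = self.denominators[wt_cols].sum(axis=1)
        total = (100.0 * num / den.where(den > 0)).round(decimals)
        out = self.matrix.round(decimals)
        out.insert(0, "Total_IDH_wt", total)
        return out

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index_label="feature")


def _feature_status(name: str, kind: str, target: str | None,
                    case: Case, calls: dict[str, GeneCall],
                    status: PathwayStatus) -> bool | None:
    """True/False if the feature is determinable for this case, else None."""
    if kind == "mut":
        return _has_pathogenic_mutation(case, target, include_germline=False)
    if kind == "amp":
        return _has_amplification(calls.get(target))
    if kind == "loss":
        call = calls.get(target)
        return call is not None and call.homozygous_loss
    if kind == "composite":
        return getattr(status, target)
    if kind == "tert":
        return None if status.tert == "unknown" else status.tert == "positive"
    if kind == "mgmt":
        return None if status.mgmt == "unknown" else status.mgmt == "positive"
    raise ValueError(f"unknown feature kind {kind!r} for {name}")


def frequency_matrix(cohort: Cohort,
                     subgroup_calls: dict[str, SubgroupCall],
                     *, subgroups: tuple[str, ...] = cat.TABLE_SUBGROUPS
                     ) -> CohortSummary:
    """Per-subgroup percent of cases carrying each single-gene alteration
    and each composite.

    Denominators are subgroup case counts with the feature determinable:
    the full genomic-data count for mutation/CN rows, cases with a known
    methylation value for MGMT, and cases with an assessable telomerase
    status for TERT.  An empty subgroup yields NaN, not 0.
    """
    rows = cat.FEATURE_ROWS
    numer = pd.DataFrame(0, index=[r[0] for r in rows], columns=list(subgroups))
    denom = numer.copy()
    counts = pd.Series(0, index=list(subgroups))
    for case in cohort:
        label = subgroup_calls[case.case_id].label
        if label not in subgroups or not case.has_genomic_data:
            continue
        counts[label] += 1
        calls = build_calls(case)
        status = pathway_status(case, calls)
        for name, kind, target in rows:
            val = _feature_status(name, kind, target, case, calls, status)
            if val is None:
                continue
            denom.loc[name, label] += 1
            if val:
                numer.loc[name, label] += 1
    matrix = 100.0 * numer / denom.where(denom > 0)
    return CohortSummary(matrix=matrix, counts=counts,
                         numerators=numer, denominators=denom)
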
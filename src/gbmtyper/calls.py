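"""Deterministic per-gene call logic.

Gene-level driver evidence is reduced to a :class:`GeneCall`: amplification
(CN >= 7), overexpression (fold >= 5 versus low-grade controls), curated
activating mutations, pathogenic fusions, and biallelic inactivation (two
hits by distinct variants, variant + LOH, or homozygous loss).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PATHOGENIC, AlterationEvent, Case

AMPLIFICATION_CN = 7.0
OVEREXPRESSION_FOLD = 5.0
MGMT_POSITIVE = 5.0


def call_amplification(copy_number: float,
                       threshold: float = AMPLIFICATION_CN) -> bool:
    """Gene amplification: copy number at or above the threshold (default 7)."""
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    return copy_number >= threshold


def call_overexpression(fold: float,
                        threshold: float = OVEREXPRESSION_FOLD) -> bool:
    """Overexpression: fold-change at or above the threshold (default 5)."""
    if fold <= 0:
        raise ValueError("fold-change must be positive")
    return fold >= threshold


def call_tert_activation(promoter_mutated: bool,
                         tert_fold: float | None,
                         threshold: float = OVEREXPRESSION_FOLD) -> bool:
    """Composite telomerase activation: promoter mutation, or overexpression
    in the absence of mutation."""
    if promoter_mutated:
        return True
    return tert_fold is not None and tert_fold >= threshold


def tert_status(promoter_mutated: bool,
                tert_fold: float | None,
                threshold: float = OVEREXPRESSION_FOLD) -> str:
    """Tri-state telomerase status: ``unknown`` when the promoter is
    unmutated and no expression is available (the overexpression arm cannot
    be assessed)."""
    if promoter_mutated:
        return "positive"
    if tert_fold is None:
        return "unknown"
    return "positive" if tert_fold >= threshold else "negative"


def call_mgmt_methylated(value: float | None) -> str:
    """MGMT promoter methylation dichotomized at >= 5; missing -> unknown."""
    if value is None:
        return "unknown"
    if value < 0:
        raise ValueError("MGMT methylation value must be non-negative")
    return "positive" if value >= MGMT_POSITIVE else "negative"


def call_biallelic(gene_events: list[AlterationEvent]) -> bool:
    """Two-hit inactivation of a tumor suppressor.

    True for >= 2 distinct pathogenic/likely-pathogenic hits (small variants
    or fusions), one such hit plus LOH, or homozygous loss.  Germline hits
    count (syndromic first hits).
    """
    genes = {e.gene for e in gene_events}
    if len(genes) > 1:
        raise ValueError(f"events span multiple genes: {sorted(genes)}")
    if any(e.kind == "homozygous_loss" for e in gene_events):
        return True
    hits = [e for e in gene_events
            if (e.is_small_variant or e.kind == "fusion") and e.is_pathogenic]
    distinct = {(e.kind, e.hgvs, e.germline) for e in hits}
    if len(distinct) >= 2:
        return True
    has_loh = any(e.kind == "loh" for e in gene_events)
    return bool(hits) and has_loh


@dataclass
class GeneCall:
    """Reduced per-gene evidence for one case."""

    gene: str
    amplified: bool = False
    overexpressed: bool | None = None  # None iff case has no expression
    fold: float | None = None
    activating_mutation: bool = False
    pathogenic_fusion: bool = False
    biallelic_loss: bool = False
    homozygous_loss: bool = False
    pathogenic_variant: bool = False
    germline_pathogenic: bool = False
    copy_number: float | None = None


def build_gene_call(case: Case, gene: str,
                    fold_threshold: float = OVEREXPRESSION_FOLD,
                    cn_threshold: float = AMPLIFICATION_CN) -> GeneCall:
    """Assemble the :class:`GeneCall` for one gene of one case.

    Secondary-focus events of multifocal tumors are excluded: the case is
    typed on the main focus.
    """
    events = case.events_for(gene)
    fold = case.expression.fold(gene) if case.expression else None
    call = GeneCall(gene=gene, fold=fold)
    if fold is not None:
        call.overexpressed = call_overexpression(fold, fold_threshold)
    for e in events:
        if e.kind == "amplification":
            if call_amplification(e.copy_number, cn_threshold):
                call.amplified = True
                call.copy_number = e.copy_number
        elif e.kind == "homozygous_loss":
            call.homozygous_loss = True
        if e.activating and e.is_pathogenic:
            call.activating_mutation = True
        if e.kind == "fusion" and e.is_pathogenic:
            call.pathogenic_fusion = True
        if e.is_small_variant and e.is_pathogenic:
            call.pathogenic_variant = True
            if e.germline:
                call.germline_pathogenic = True
    call.biallelic_loss = call_biallelic(events) if events else False
    return call


def build_calls(case: Case,
                fold_threshold: float = OVEREXPRESSION_FOLD,
                cn_threshold: float = AMPLIFICATION_CN) -> dict[str, GeneCall]:
    """Per-gene calls for every gene with an event or an above-threshold
    fold-change in this case."""
    genes = set(case.genes_with_events)
    if case.expression:
        genes |= {g for g, f in case.expression.fold_change.items()
                  if f >= fold_threshold}
    return {g: build_gene_call(case, g, fold_threshold, cn_threshold)
            for g in sorted(genes)}
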
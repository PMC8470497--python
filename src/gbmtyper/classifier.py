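"""Rule-based assignment of each case to exactly one molecular subgroup.

The partition is: DMG (H3 K27M), IDH (IDH1/2 mutant), then the seven
IDH-wild-type subgroups G1/EGFR (amplified or mutant-only), G2/FGFR3,
G3/NF1, G4/RAF, G5/PDGFRA, G6/Multi-RTK and G7/Other.  RTK driver evidence
is evaluated first (positive evidence wins over tumor-suppressor loss), so
the resulting subgroups are non-overlapping by construction; a case that
would satisfy two defining conditions carries a ``conflict`` flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict

from . import _catalog as cat
from .calls import GeneCall, build_calls
from .cohort import Case, Cohort, PATHOGENIC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable rule parameters.

    ``high_fold_genes`` lists the RTKs for which very high overexpression
    (>= ``high_fold``) without amplification is accepted as a driver (MET by
    default).  ``locus_groups`` collapse amplification-only drivers on a
    contiguous amplicon (PDGFRA/KIT/KDR on 4q12) to the primary gene.
    """

    rtk_genes: tuple[str, ...] = cat.RTK_GENES
    fold_threshold: float = 5.0
    cn_threshold: float = 7.0
    high_fold: float = 10.0
    high_fold_genes: tuple[str, ...] = ("MET",)
    locus_groups: tuple[tuple[str, ...], ...] = (("PDGFRA", "KIT", "KDR"),)
    amplification_without_expression_is_driver: bool = True
    nf1_single_hit_is_g3: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class SubgroupCall:
    """Assigned label plus the driver evidence chain and rules fired."""

    label: str
    drivers: list[tuple[str, str]] = field(default_factory=list)
    rationale: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.label not in cat.ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _rtk_driver_evidence(call: GeneCall, config: ClassifierConfig) -> list[str]:
    """Evidence kinds making this RTK a driver for the case."""
    ev: list[str] = []
    if call.amplified:
        if call.overexpressed:
            ev.append("amplification+overexpression")
        elif call.overexpressed is None:
            if config.amplification_without_expression_is_driver:
                ev.append("amplification (expression unknown)")
    if call.activating_mutation:
        ev.append("activating mutation")
    if call.pathogenic_fusion:
        ev.append("pathogenic fusion")
    if (call.gene in config.high_fold_genes and not call.amplified
            and call.fold is not None and call.fold >= config.high_fold):
        ev.append(f"overexpression >= {config.high_fold:g}-fold")
    return ev


def _collapse_locus_groups(drivers: dict[str, list[str]],
                           config: ClassifierConfig) -> dict[str, list[str]]:
    """Within a contiguous amplicon, amplification-only co-drivers are
    passengers of the primary gene's amplification."""
    for group in config.locus_groups:
        primary, *rest = group
        if primary not in drivers:
            continue
        for gene in rest:
            ev = drivers.get(gene)
            if ev and all(e.startswith("amplification") for e in ev):
                del drivers[gene]
    return drivers


def classify_case(case: Case,
                  calls: dict[str, GeneCall] | None = None,
                  config: ClassifierConfig = DEFAULT_CONFIG) -> SubgroupCall:
    """Assign one label by ordered rules (IHC triage, RTK driver set,
    NF1, RAF, fallback Other)."""
    if case.ihc.h3_k27m == "positive" and case.ihc.idh1_r132h == "positive":
        raise ValueError(
            f"{case.case_id}: contradictory IHC (IDH1 and H3 K27M positive)")
    if calls is None:
        calls = build_calls(case, config.fold_threshold, config.cn_threshold)

    # R0: histone H3 K27M -> diffuse midline glioma, triaged out of G1-G7.
    if case.ihc.h3_k27m == "positive":
        return SubgroupCall(cat.DMG, drivers=[("H3-K27M", "IHC")],
                            rationale=["R0"])

    # R1: IDH1 R132H IHC or pathogenic IDH1/IDH2 variant.
    idh_variant = any(
        e.is_small_variant and e.is_pathogenic
        for g in ("IDH1", "IDH2") for e in case.events_for(g)
    )
    if case.ihc.idh1_r132h == "positive" or idh_variant:
        drivers = [("IDH1", "IHC" if case.ihc.idh1_r132h == "positive"
                    else "pathogenic variant")]
        return SubgroupCall(cat.IDH, drivers=drivers, rationale=["R1"])

    # R2: RTK driver set.
    drivers: dict[str, list[str]] = {}
    for gene in config.rtk_genes:
        call = calls.get(gene)
        if call is None:
            continue
        ev = _rtk_driver_evidence(call, config)
        if ev:
            drivers[gene] = ev
    drivers = _collapse_locus_groups(drivers, config)

    pdgfra = calls.get("PDGFRA")
    pdgfra_amp_not_over = (pdgfra is not None and pdgfra.amplified
                           and pdgfra.overexpressed is False)

    nf1 = calls.get("NF1")
    nf1_hit = nf1 is not None and (nf1.biallelic_loss or nf1.pathogenic_variant
                                   or nf1.pathogenic_fusion)
    raf_hit = any(
        calls.get(g) is not None and calls[g].activating_mutation
        for g in ("BRAF", "RAF1")
    )

    def _finish(call: SubgroupCall) -> SubgroupCall:
        if drivers and (nf1_hit or raf_hit) and call.label in cat.RTK_SUBGROUPS:
            call.flags.add("conflict")
        return call

    driver_list = [(g, "; ".join(ev)) for g, ev in sorted(drivers.items())]

    # R3: Multi-RTK.
    if len(drivers) >= 2:
        return _finish(SubgroupCall(cat.G6_MULTI_RTK, drivers=driver_list,
                                    rationale=["R2", "R3"]))
    if pdgfra_amp_not_over:
        dl = list(driver_list)
        if "PDGFRA" not in drivers:
            dl.append(("PDGFRA", "amplification without overexpression"))
        return _finish(SubgroupCall(cat.G6_MULTI_RTK, drivers=dl,
                                    rationale=["R2", "R3"]))
    if len(drivers) == 1:
        gene = next(iter(drivers))
        if gene not in ("EGFR", "FGFR3", "PDGFRA"):
            return _finish(SubgroupCall(cat.G6_MULTI_RTK, drivers=driver_list,
                                        rationale=["R2", "R3"]))
        # R4: single-driver RTK subgroups.
        if gene == "EGFR":
            label = (cat.G1_EGFR_AMP if calls["EGFR"].amplified
                     else cat.G1_EGFR_MUT)
        elif gene == "FGFR3":
            label = cat.G2_FGFR3
        else:
            label = cat.G5_PDGFRA
        return _finish(SubgroupCall(label, drivers=driver_list,
                                    rationale=["R2", "R4"]))

    # R5: NF1 inactivation (biallelic, or syndromic germline + somatic hit;
    # single-hit pathogenic flagged monoallelic).
    if nf1_hit:
        if nf1.biallelic_loss:
            return SubgroupCall(cat.G3_NF1,
                                drivers=[("NF1", "biallelic inactivation")],
                                rationale=["R5"])
        if config.nf1_single_hit_is_g3:
            return SubgroupCall(cat.G3_NF1,
                                drivers=[("NF1", "pathogenic single hit")],
                                rationale=["R5"], flags={"monoallelic"})

    # R6: RAF-segment activation.
    if raf_hit:
        gene = "BRAF" if (calls.get("BRAF") is not None
                          and calls["BRAF"].activating_mutation) else "RAF1"
        return SubgroupCall(cat.G4_RAF,
                            drivers=[(gene, "activating mutation")],
                            rationale=["R6"])

    # R7: no ERK/MAPK driver found.
    call = SubgroupCall(cat.G7_OTHER, rationale=["R7"])
    if not case.has_genomic_data:
        call.flags.add("no_molecular_data")
    return call


def classify_cohort(cohort: Cohort,
                    config: ClassifierConfig = DEFAULT_CONFIG
                    ) -> dict[str, SubgroupCall]:
    """Classify every case; total partition (one label per case)."""
    out: dict[str, SubgroupCall] = {}
    for case in cohort:
        try:
            out[case.case_id] = classify_case(case, config=config)
        except ValueError as err:
            raise ValueError(f"case {case.case_id}: {err}") from err
    counts = Counter(c.label for c in out.values())
    logger.info("classified %d cases (config %s): %s", len(out),
                config.config_hash(), dict(counts))
    return out


def subgroup_counts(cohort: Cohort,
                    subgroup_calls: dict[str, SubgroupCall],
                    *, genomic_only: bool = True) -> Counter:
    """Label counts over IDH-wt + IDH cases.  DMG cases and (by default)
    cases without genomic data are excluded from every denominator."""
    counts: Counter = Counter()
    for case in cohort:
        call = subgroup_calls[case.case_id]
        if call.label == cat.DMG:
            continue
        if genomic_only and not case.has_genomic_data:
            continue
        counts[call.label] += 1
    return counts


def idh_wt_fractions(counts: Counter) -> dict[str, float]:
    """Percent of IDH-wild-type cases per subgroup, plus derived composites
    (RTK-driven, EGFR subgroup, ERK/MAPK-altered)."""
    total = sum(counts[s] for s in cat.IDH_WT_SUBGROUPS)
    if total == 0:
        raise ValueError("no IDH-wild-type cases with genomic data")
    pct = {s: 100.0 * counts[s] / total for s in cat.IDH_WT_SUBGROUPS}
    pct["RTK"] = 100.0 * sum(counts[s] for s in cat.RTK_SUBGROUPS) / total
    pct["EGFR"] = pct[cat.G1_EGFR_AMP] + pct[cat.G1_EGFR_MUT]
    pct["ERK_MAPK"] = 100.0 * sum(
        counts[s] for s in cat.ERK_MAPK_SUBGROUPS) / total
    return pct
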
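"""Synthetic cohort generation.

Two entry points:

* :func:`deterministic_fixture` — the checked, non-random cohort whose
  per-subgroup alteration counts equal ``round(frequency x n)`` for every
  cell of the reference frequency table, used by all exact tests.
* :func:`generate` — seeded random cohorts with the same count structure
  (the printed frequencies are the study conditions, so per-cell counts are
  conditioned on exactly; randomness enters through case-assignment
  permutations, fold-change/survival/demographic draws and secondary-event
  sampling).

Both return ``(cohort, truth)`` where ``truth`` maps case_id to the
intended subgroup label; the truth sidecar is never read by the classifier.

Printed percentages for the TERT and MGMT rows imply denominators smaller
than the subgroup n (assay availability); the builder solves each cell for
the largest consistent (numerator, denominator) pair and represents the
unassessed cases as promoter-unmutated without expression (TERT) or with a
missing methylation value (MGMT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _catalog as cat
from .cohort import (AlterationEvent, Case, Cohort, ExpressionProfile,
                     IHCPanel, write_cohort)

# ------------------------------------------------------------------ utils

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _round1(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


def solve_cell(pct: float, n: int) -> tuple[int, int]:
    """Largest denominator m <= n (with numerator k = round(pct*m/100))
    whose percentage reproduces ``pct`` at one printed decimal."""
    for m in range(n, 0, -1):
        k = _round_half_up(pct * m / 100.0)
        if k <= m and abs(_round1(100.0 * k / m) - _round1(pct)) < 1e-9:
            return k, m
    # not exactly realizable at this n (custom subgroup sizes): nearest count
    return min(_round_half_up(pct * n / 100.0), n), n


def allocate(order: list[int],
             members: list[tuple[str, int]],
             union_k: int,
             filler: str | None = None) -> list[tuple[int, str]]:
    """Assign member events to case indices so that exactly ``union_k``
    distinct cases carry at least one event.

    ``members`` are (key, count) pairs placed in order: new cases are
    covered (following ``order``) until the union target is reached, then
    events stack onto already-covered cases (never the same key twice on
    one case).  If the member counts cannot cover the union, ``filler``
    events make up the deficit.  Raises when the target is infeasible.
    """
    total = sum(c for _, c in members)
    items = list(members)
    if total < union_k:
        if filler is None:
            raise ValueError("union target exceeds member counts; no filler")
        items.append((filler, union_k - total))
    covered: set[int] = set()
    per_case: dict[int, set[str]] = {}
    out: list[tuple[int, str]] = []
    for key, count in items:
        for _ in range(count):
            if len(covered) < union_k:
                idx = next(i for i in order if i not in covered)
            else:
                idx = next(i for i in order
                           if i in covered and key not in per_case.get(i, set()))
            covered.add(idx)
            per_case.setdefault(idx, set()).add(key)
            out.append((idx, key))
    if len(covered) != union_k:
        raise ValueError(
            f"infeasible allocation: covered {len(covered)} != {union_k}")
    return out


# ------------------------------------------------------------- config

def _default_sizes() -> dict[str, int]:
    return dict(cat.SUBGROUP_SIZES)


def _default_freqs() -> dict[str, tuple[float, ...]]:
    return dict(cat.SUBGROUP_ALTERATION_FREQUENCIES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for cohort synthesis."""

    seed: int = 0
    subgroup_sizes: dict[str, int] = field(default_factory=_default_sizes)
    frequencies: dict[str, tuple[float, ...]] = field(
        default_factory=_default_freqs)
    survival_medians: dict[str, float] = field(
        default_factory=lambda: dict(cat.SURVIVAL_MEDIANS))
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(cat.AGE_PARAMS))
    expression_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(cat.EXPRESSION_EFFECTS))
    cdk6_means: dict[str, float] = field(
        default_factory=lambda: dict(cat.CDK6_MEANS))
    proliferation_means: dict[str, float] = field(
        default_factory=lambda: dict(cat.PROLIFERATION_MEANS))
    censoring_fraction: float = 0.10
    #: anti-correlate TP53-pathway events with CDKN2A loss (allocation
    #: prefers CDKN2A-intact cases first); qualitative knob, inferred.
    tp53_cdkn2a_anticorrelation: bool = True
    n_dmg: int = 3
    n_idh_wt_no_genomics: int = 3
    n_idh_mut_no_genomics: int = 1

    def validate(self) -> None:
        for label, n in self.subgroup_sizes.items():
            if n < 0:
                raise ValueError(f"negative size for {label}")
        for row, vals in self.frequencies.items():
            for v in vals:
                if not 0 <= v <= 100:
                    raise ValueError(f"{row}: frequency {v} outside [0,100]")
        for label, m in self.survival_medians.items():
            if m <= 0:
                raise ValueError(f"{label}: non-positive survival median")


DEFAULT_GENERATOR_CONFIG = GeneratorConfig()


# --------------------------------------------------------------- plans

@dataclass
class CasePlan:
    label: str
    index: int                       # index within subgroup
    events: list[AlterationEvent] = field(default_factory=list)
    expression: dict[str, float] | None = None
    mgmt_value: float | None = None
    ihc_idh: str = "negative"
    ihc_h3: str = "negative"
    pattern: str = "unknown"
    gfap: str = "high"

    def add(self, *events: AlterationEvent) -> None:
        self.events.extend(events)

    def fold(self, gene: str, value: float) -> None:
        if self.expression is None:
            raise ValueError(f"{self.label}#{self.index}: no expression")
        self.expression[gene] = value

    @property
    def tp53_path(self) -> bool:
        return any(
            (e.gene in ("TP53", "RPL5", "PPM1D") and e.is_small_variant
             and e.is_pathogenic)
            or (e.gene in ("MDM2", "MDM4") and e.kind == "amplification")
            for e in self.events)

    @property
    def cdkn2a_loss(self) -> bool:
        return any(e.gene == "CDKN2A" and e.kind == "homozygous_loss"
                   for e in self.events)

    @property
    def cdk4_amp(self) -> bool:
        return any(e.gene == "CDK4" and e.kind == "amplification"
                   for e in self.events)


#: baseline expression universe (fold 1.0 unless overridden)
EXPRESSION_GENES = (
    "EGFR", "ERBB2", "ERBB3", "PDGFRA", "KIT", "KDR", "MET", "FGFR3",
    "NTRK1", "ALK", "EPHB2", "TERT", "CDK4", "CDK6", "CDKN2A", "MKI67",
)


def _mut(gene: str, kind: str = "missense", hgvs: str = "",
         germline: bool = False, activating: bool | None = None
         ) -> AlterationEvent:
    return AlterationEvent(gene=gene, kind=kind, pathogenicity="pathogenic",
                           hgvs=hgvs, germline=germline, activating=activating)


def _amp(gene: str, cn: float) -> AlterationEvent:
    return AlterationEvent(gene=gene, kind="amplification",
                           pathogenicity="pathogenic", copy_number=cn)


def _loss(gene: str) -> AlterationEvent:
    return AlterationEvent(gene=gene, kind="homozygous_loss",
                           pathogenicity="pathogenic", copy_number=0.0)


def _loh(gene: str) -> AlterationEvent:
    return AlterationEvent(gene=gene, kind="loh", pathogenicity="unknown")


def _gain(gene: str, cn: float = 4.0) -> AlterationEvent:
    return AlterationEvent(gene=gene, kind="cn_gain",
                           pathogenicity="unknown", copy_number=cn)


def _fusion(gene: str, partner: str, frame: str = "in-frame"
            ) -> list[AlterationEvent]:
    return [
        AlterationEvent(gene=gene, kind="fusion", pathogenicity="pathogenic",
                        partner_gene=partner, hgvs=frame),
        AlterationEvent(gene=partner, kind="fusion",
                        pathogenicity="pathogenic", partner_gene=gene,
                        hgvs=frame),
    ]


def _tert_promoter() -> AlterationEvent:
    return AlterationEvent(gene="TERT", kind="promoter_mutation",
                           pathogenicity="pathogenic", hgvs="c.-124C>T")


# ------------------------------------------------------- column builder

#: Per-label TERT plan bookkeeping: (n_promoter_overexpr_only)
_TERT_OVEREXPR_ONLY = {cat.G1_EGFR_AMP: 2}

_G1_MEMBERS = ("CDKN2A_loss", "CDK4_amp", "RB1")
_PI3K_MEMBERS = ("PTEN", "PIK3CA", "PIK3R1")
_TP53_MEMBERS = ("TP53", "MDM2_amp", "MDM4_amp", "RPL5", "PPM1D")
_DDR_MEMBERS = ("ATM", "BRCA2")


def _column(cfg: GeneratorConfig, label: str) -> dict[str, int]:
    """Solved (numerator) counts for every feature row of one subgroup."""
    col = cat.TABLE_SUBGROUPS.index(label)
    n = cfg.subgroup_sizes[label]
    out: dict[str, int] = {}
    for row, values in cfg.frequencies.items():
        k, m = solve_cell(values[col], n)
        out[row] = k
        out[row + "__den"] = m
    return out


def _build_subgroup_plans(cfg: GeneratorConfig, label: str) -> list[CasePlan]:
    n = cfg.subgroup_sizes[label]
    if n == 0:
        return []
    counts = _column(cfg, label)
    plans = [CasePlan(label=label, index=i) for i in range(n)]

    # -- TERT / expression availability ----------------------------------
    k_t, m_t = counts["TERT"], counts["TERT__den"]
    n_over_only = min(_TERT_OVEREXPR_ONLY.get(label, 0), k_t)
    unknown = set(range(m_t, n))          # unassessed: no mutation, no expr
    mutated = set(range(k_t - n_over_only))
    over_only = set(range(k_t - n_over_only, k_t))
    negative = set(range(k_t, m_t))

    # expression availability: everyone except TERT-unknown cases; the RAF
    # and NF1 subgroups had sparser transcriptome coverage.
    if label == cat.G4_RAF:
        with_expr = {0, 1} - unknown
    elif label == cat.G3_NF1:
        with_expr = set(range(3, n)) - unknown
    else:
        with_expr = set(range(n)) - unknown
    with_expr |= over_only | negative     # these need an assessable fold
    for i in with_expr:
        plans[i].expression = {g: 1.0 for g in EXPRESSION_GENES}
    for i in sorted(mutated):
        plans[i].add(_tert_promoter())
        if plans[i].expression is not None:
            plans[i].fold("TERT", 9.0)
    for i in sorted(over_only):
        plans[i].fold("TERT", 12.0)
    for i in sorted(negative):
        plans[i].fold("TERT", 1.2)

    # -- drivers ----------------------------------------------------------
    _plant_drivers(cfg, label, plans)

    # -- G1 phase (mutually exclusive members) ----------------------------
    g1_members = [(m, counts[m]) for m in _G1_MEMBERS]
    for idx, key in allocate(list(range(n)), g1_members, counts["G1_phase"]):
        p = plans[idx]
        if key == "CDKN2A_loss":
            p.add(_loss("CDKN2A"))
            # homozygous losses extend to the adjacent CDKN2B gene, with a
            # single FGFR3-subgroup exception
            if not (label == cat.G2_FGFR3 and idx == 0):
                p.add(_loss("CDKN2B"))
            if p.expression is not None:
                p.fold("CDKN2A", 0.1)
        elif key == "CDK4_amp":
            p.add(_amp("CDK4", 15.0))
            if p.expression is not None:
                p.fold("CDK4", 8.0)   # amplification tracks overexpression
        else:
            p.add(_mut("RB1", "truncating", hgvs=f"p.R{255 + idx}*"))
            p.add(_loh("RB1"))

    # two heterozygous germline RB1 point mutations, planted in
    # CDKN2A-deleted cases of the largest subgroup (the only exceptions to
    # G1-phase mutual exclusivity)
    if label == cat.G1_EGFR_AMP:
        for i in (0, 1):
            plans[i].add(_mut("RB1", "missense", hgvs=f"p.R{661 + i}W",
                              germline=True))

    # -- PI3K/mTOR --------------------------------------------------------
    pi3k_members = [(m, counts[m]) for m in _PI3K_MEMBERS]
    filler = "TSC2" if label != cat.IDH else "MTOR"
    for idx, key in allocate(list(range(n)), pi3k_members,
                             counts["PI3K_mTOR"], filler=filler):
        kind = "truncating" if key == "PTEN" else "missense"
        plans[idx].add(_mut(key if key in ("TSC2", "MTOR") else key, kind,
                            hgvs=f"p.X{idx + 1}"))

    # -- TP53 pathway (prefers CDKN2A-intact cases) -----------------------
    if cfg.tp53_cdkn2a_anticorrelation:
        order = ([i for i in range(n) if not plans[i].cdkn2a_loss]
                 + [i for i in range(n) if plans[i].cdkn2a_loss])
    else:
        order = list(range(n))
    tp53_members = [("TP53", counts["TP53"]),
                    ("MDM2_amp", counts["MDM2_amp"]),
                    ("MDM4_amp", counts["MDM4_amp"]),
                    ("RPL5", counts["RPL5"]),
                    ("PPM1D", counts["PPM1D"])]
    for idx, key in allocate(order, tp53_members, counts["TP53_pathway"]):
        if key.endswith("_amp"):
            plans[idx].add(_amp(key[:-4], 12.0))
        else:
            plans[idx].add(_mut(key, "missense", hgvs=f"p.Y{idx + 1}C"))

    # -- DDR (ATM, BRCA2, mismatch repair) --------------------------------
    back = list(reversed(range(n)))
    mmr_genes = ["MSH6", "PMS2", "MSH5", "MLH3"]
    ddr_members = [("ATM", counts["ATM"]), ("BRCA2", counts["BRCA2"]),
                   ("MMR", counts["MMR"])]
    mmr_planted = 0
    for idx, key in allocate(back, ddr_members, counts["DDR_pathway"]):
        if key == "MMR":
            gene = mmr_genes[mmr_planted % len(mmr_genes)]
            mmr_planted += 1
            plans[idx].add(_mut(gene, "truncating", hgvs=f"p.Q{idx + 1}*"))
        else:
            plans[idx].add(_mut(key, "truncating", hgvs=f"p.E{idx + 1}*"))

    # -- standalone rows --------------------------------------------------
    for idx, _ in allocate(list(range(n)), [("STAG2", counts["STAG2"])],
                           counts["STAG2"]):
        plans[idx].add(_mut("STAG2", "truncating", hgvs=f"p.S{idx + 1}*"))
    swi_genes = ["ARID1A", "SMARCA4", "ARID1B", "PBRM1"]
    for j, (idx, _) in enumerate(allocate(
            back, [("SWI", counts["SWI_SNF"])], counts["SWI_SNF"])):
        plans[idx].add(_mut(swi_genes[j % len(swi_genes)], "truncating",
                            hgvs=f"p.A{idx + 1}*"))
    chrm_genes = ["TET2", "KMT2C", "DNMT3A", "KMT2D", "SUZ12", "CREBBP"]
    chrm_planted = 0
    for idx, _ in allocate(list(range(n)), [("ChRm", counts["ChRm"])],
                           counts["ChRm"]):
        if label == cat.G6_MULTI_RTK and chrm_planted == 0:
            plans[idx].add(_amp("YEATS4", 11.0))
        else:
            gene = chrm_genes[chrm_planted % len(chrm_genes)]
            plans[idx].add(_mut(gene, "missense", hgvs=f"p.C{idx + 1}Y"))
        chrm_planted += 1

    # -- MGMT -------------------------------------------------------------
    k_m, m_m = counts["MGMT_methylated"], counts["MGMT_methylated__den"]
    missing = _mgmt_missing_indices(label, n, n - m_m, unknown)
    assessed = [i for i in range(n) if i not in missing]
    for j, i in enumerate(assessed):
        if j < k_m:
            plans[i].mgmt_value = 5.0 if j == 0 else (5.6 if j == 1 else 20.0)
        else:
            plans[i].mgmt_value = 0.8

    return plans


def _mgmt_missing_indices(label: str, n: int, n_missing: int,
                          tert_unknown: set[int]) -> set[int]:
    """Cases without an MGMT assay; overlap with unassessed-TERT cases
    where possible (same under-sampled specimens)."""
    missing = set(sorted(tert_unknown)[:n_missing])
    i = n - 1
    while len(missing) < n_missing:
        if i not in missing:
            missing.add(i)
        i -= 1
    return missing


# ----------------------------------------------------------- drivers

def _egfr_fold_ladder(n: int) -> list[float]:
    """Deterministic fold spread for EGFR-amplified tumors: mean ~26,
    range 4.5-72."""
    base = [4.5, 6, 8, 9, 10, 11, 12, 13, 14, 15, 16, 18, 20, 22, 24, 26,
            28, 30, 32, 34, 36, 38, 40, 45, 50, 55, 60, 72]
    if n <= len(base):
        return base[:n]
    return base + [26.0] * (n - len(base))


def _plant_drivers(cfg: GeneratorConfig, label: str,
                   plans: list[CasePlan]) -> None:
    n = len(plans)
    if label == cat.G1_EGFR_AMP:
        expr_idx = [i for i in range(n) if plans[i].expression is not None]
        folds = _egfr_fold_ladder(len(expr_idx))
        for i, p in enumerate(plans):
            p.add(_amp("EGFR", 7.0 + 3.0 * i))
        for j, i in enumerate(expr_idx):
            plans[i].fold("EGFR", folds[j])
            if folds[j] < 5.0:  # amplified without overexpression: needs a
                # second EGFR lesion to remain a driver (observed: vIII)
                plans[i].add(_mut("EGFR", "splice_variant", hgvs="vIII",
                                  activating=True))
        # secondary EGFR lesions in the majority of amplified tumors
        secondary = [
            lambda: [_mut("EGFR", "splice_variant", "vIII", activating=True)],
            lambda: _fusion("EGFR", "SEPT14"),
            lambda: [_mut("EGFR", "missense", "p.A289V", activating=True)],
            lambda: _fusion("SEC61G", "EGFR"),
            lambda: [_mut("EGFR", "splice_variant", "vIVa", activating=True)],
            lambda: _fusion("EGFR", "VOPP1"),
        ]
        for j, i in enumerate(range(1, n, 2)):
            plans[i].add(*secondary[j % len(secondary)]())
        # two multifocal tumors: secondary focus carries an EGFR mutation
        # without amplification, stored but flagged
        for i in (4, 30):
            if i < n:
                plans[i].add(AlterationEvent(
                    gene="EGFR", kind="missense", pathogenicity="pathogenic",
                    activating=True, hgvs="p.L861Q", secondary_focus=True))
    elif label == cat.G1_EGFR_MUT:
        hot = ["p.L861Q", "p.G598V", "p.A289T"]
        for i, p in enumerate(plans):
            p.add(_mut("EGFR", "missense", hot[i % len(hot)],
                       activating=True))
            if p.expression is not None:
                p.fold("EGFR", 2.0)
                p.fold("ERBB2", 6.0)   # mild ERBB2 upregulation
    elif label == cat.G5_PDGFRA:
        cns = [10, 12, 15, 20, 30, 44]
        folds = [5.0, 10, 14, 17, 21, 25.7]  # boundary case at threshold
        for i in range(min(6, n)):
            plans[i].add(_amp("PDGFRA", cns[i]))
            plans[i].fold("PDGFRA", folds[i])
        if n >= 1:
            plans[0].add(_mut("PDGFRA", "missense", "p.C235Y",
                              activating=True))
        if n >= 7:
            plans[6].add(_mut("PDGFRA", "missense", "p.D842V",
                              activating=True))
            plans[6].fold("PDGFRA", 18.0)
        # adjacent 4q12 locus co-amplification (KIT/KDR ride the amplicon)
        for i in (4, 5):
            if i < n:
                plans[i].add(_amp("KDR", 9.0), _amp("KIT", 8.0))
                plans[i].fold("KDR", 10.0)
                plans[i].fold("KIT", 3.0)
        for i in range(n):
            if plans[i].expression is not None:
                plans[i].fold("EPHB2", 6.0)  # subgroup-enriched RTK
    elif label == cat.G6_MULTI_RTK:
        met_folds = [5.4, 12.0, 28.0]
        for i in range(min(3, n)):   # PDGFRA amplified without overexpression
            plans[i].add(_amp("PDGFRA", 12.0), _gain("MET", 4.0))
            plans[i].fold("PDGFRA", 1.5 + 0.5 * i)
            plans[i].fold("MET", met_folds[i])
        for i, cn, fold in ((3, 12.0, 45.0), (4, 18.0, 52.0)):
            if i < n:
                plans[i].add(_amp("MET", cn))
                plans[i].fold("MET", fold)
        if n >= 6:
            plans[5].add(_amp("EGFR", 30.0), _gain("MET", 5.0))
            plans[5].fold("EGFR", 20.0)
            plans[5].fold("MET", 15.0)
            plans[5].fold("KIT", 12.0)
        if n >= 7:
            plans[6].add(*_fusion("LMNA", "NTRK1"))
            plans[6].fold("NTRK1", 9.0)
            plans[6].fold("ERBB3", 6.0)
    elif label == cat.G2_FGFR3:
        for i in range(min(4, n)):
            plans[i].add(*_fusion("FGFR3", "TACC3"))
            plans[i].fold("FGFR3", [8.0, 10.0, 12.0, 15.0][i])
        if n >= 5:
            plans[4].add(_mut("FGFR3", "missense", "p.K650E",
                              activating=True))
            plans[4].fold("FGFR3", 6.0)
    elif label == cat.G3_NF1:
        for i, p in enumerate(plans):
            p.add(_mut("NF1", "truncating", hgvs=f"p.R{1000 + 13 * i}*",
                       germline=i in (13, 14)))
        for i in range(min(9, n)):
            plans[i].add(_loh("NF1"))
        # case 9: single-hit (monoallelic) NF1
        if n > 10:
            plans[10].add(_mut("NF1", "frameshift", hgvs="p.T676fs"))
        if n > 11:
            plans[11].add(*_fusion("NF1", "RNF135"))
        if n > 12:
            plans[12].add(*_fusion("NF1", "OMG"))
            plans[12].add(_loh("NF1"))
        for i in (13, 14):
            if i < n:
                plans[i].add(_loh("NF1"))   # somatic second hit, syndromic
        for i in (3, 4):
            if i < n and plans[i].expression is not None:
                plans[i].fold("ALK", 6.0 + i)
    elif label == cat.G4_RAF:
        for i in range(min(3, n)):
            plans[i].add(_mut("BRAF", "missense", "p.V600E",
                              activating=True))
        if n >= 4:
            plans[3].add(_mut("RAF1", "missense", "p.S257L",
                              activating=True))
            plans[3].add(_amp("RAF1", 8.0))
        for i in (0, 1):
            if i < n and plans[i].expression is not None:
                plans[i].fold("NTRK1", 7.0 + 2 * i)
    elif label == cat.IDH:
        for i, p in enumerate(plans):
            hgvs = "p.R132C" if i == n - 1 else "p.R132H"
            p.add(_mut("IDH1", "missense", hgvs))
            p.ihc_idh = "negative" if i == n - 1 else "positive"
    # G7_Other: no ERK/MAPK driver planted.


# ------------------------------------------------- histology assignment

#: (pattern, count, preference) per subgroup; preferences steer the
#: pattern onto cases with (tp53) or without (no_tp53) TP53-pathway events,
#: or onto CDKN2A-deleted TP53-intact cases (egfr_like).
_HISTOLOGY_PLAN: dict[str, list[tuple[str, int, str | None]]] = {
    cat.G1_EGFR_AMP: [("epithelioid", 2, "tp53"), ("giant_cell", 1, "no_tp53"),
                      ("egfr", 18, "egfr_like"), ("egfr_fgfr", 2, "egfr_like"),
                      ("small_dark_regular", 3, None), ("pre_hgne", 3, None),
                      ("hgne", 2, None), ("fibroblastic", 1, None),
                      ("gliosarcoma", 1, None)],
    cat.G1_EGFR_MUT: [("epithelioid", 1, "tp53"),
                      ("small_dark_regular", 2, None)],
    cat.G5_PDGFRA: [("epithelioid", 1, "tp53"), ("hgne", 3, None),
                    ("pre_hgne", 2, None), ("anaplastic_other", 1, None)],
    cat.G6_MULTI_RTK: [("giant_cell", 2, "no_tp53"), ("hgne", 1, None),
                       ("small_dark_irregular", 1, None),
                       ("gliosarcoma", 1, None), ("pre_hgne", 1, None),
                       ("egfr", 1, "egfr_like")],
    cat.G2_FGFR3: [("egfr_fgfr", 3, "egfr_like"), ("fgfr_small", 2, None)],
    cat.G3_NF1: [("epithelioid", 2, "tp53"), ("fibroblastic", 8, None),
                 ("gliosarcoma", 2, None), ("small_dark_regular", 2, None),
                 ("pre_hgne", 1, None)],
    cat.G4_RAF: [("small_dark_regular", 4, None)],
    cat.G7_OTHER: [("epithelioid", 1, "tp53"), ("hgne", 6, None),
                   ("pre_hgne", 3, None), ("small_dark_regular", 2, None),
                   ("egfr", 1, "egfr_like")],
    cat.IDH: [("hgne", 1, None), ("egfr", 2, None), ("pre_hgne", 1, None),
              ("small_dark_regular", 2, None), ("fibroblastic", 1, None)],
}


def _assign_histology(label: str, plans: list[CasePlan]) -> None:
    plan = list(_HISTOLOGY_PLAN.get(label, []))
    free = set(range(len(plans)))

    def take(pred) -> int | None:
        for i in sorted(free):
            if pred(plans[i]):
                free.discard(i)
                return i
        return None

    for pattern, count, pref in plan:
        for _ in range(count):
            idx = None
            if pref == "tp53":
                idx = take(lambda p: p.tp53_path)
            elif pref == "no_tp53":
                idx = take(lambda p: not p.tp53_path)
            elif pref == "egfr_like":
                idx = take(lambda p: p.cdkn2a_loss and not p.tp53_path)
                if idx is None:
                    idx = take(lambda p: p.cdkn2a_loss)
            if idx is None:
                idx = take(lambda p: True)
            if idx is None:
                return  # subgroup smaller than the pattern plan
            plans[idx].pattern = pattern
    for i in sorted(free):   # leftover cases keep the modal pattern
        plans[i].pattern = plan[0][0] if plan else "unknown"


# ------------------------------------------------- demographics/survival

_MALE_FRACTION = {
    cat.G5_PDGFRA: 0.85, cat.G2_FGFR3: 0.2, cat.IDH: 0.0, cat.DMG: 0.6,
}
_DEFAULT_MALE_FRACTION = cat.SEX_RATIO_M_F / (1 + cat.SEX_RATIO_M_F)

_LOCATION_CYCLES: dict[str, list[str]] = {
    cat.G5_PDGFRA: ["frontal", "frontal", "midline", "midline", "frontal",
                    "temporal", "parietal"],
    cat.G3_NF1: ["frontal", "temporal", "corpus_callosum", "parietal",
                 "temporal", "frontal", "corpus_callosum", "temporal",
                 "frontal", "other_lobe", "temporal", "frontal", "midline",
                 "temporal", "frontal"],
    cat.G6_MULTI_RTK: ["frontal", "frontal", "temporal", "frontal",
                       "parietal", "temporal", "frontal"],
    cat.IDH: ["frontal", "frontal", "temporal", "frontal", "parietal",
              "temporal", "frontal"],
    cat.DMG: ["midline", "midline", "parietal"],
}
_DEFAULT_LOCATION_CYCLE = ["frontal", "temporal", "parietal", "frontal",
                           "temporal", "other_lobe"]


def _survival_quantile(median: float, p: float) -> float:
    # S(t) = 2^(-t/median); the p-th quantile of the event-time law
    return median * math.log2(1.0 / (1.0 - p))


def _materialize(cfg: GeneratorConfig, label: str, plans: list[CasePlan],
                 rng: np.random.Generator | None) -> None:
    """Fill demographics, survival, expression means; deterministic ladder
    values without an rng, sampled values with one."""
    n = len(plans)
    mean_age, sd_age = cfg.age_params.get(label, (61.0, 10.0))
    median = cfg.survival_medians.get(label, 10.0)
    male_frac = _MALE_FRACTION.get(label, _DEFAULT_MALE_FRACTION)
    cycle = _LOCATION_CYCLES.get(label, _DEFAULT_LOCATION_CYCLE)
    n_black = 2 if label == cat.G1_EGFR_MUT else max(1, round(0.17 * n)) \
        if n >= 4 else 0
    cdk6 = cfg.cdk6_means.get(label)
    prolif = cfg.proliferation_means.get(label)

    for i, p in enumerate(plans):
        if rng is None:
            z = -1.5 + 3.0 * (i / max(n - 1, 1))
            age = int(round(mean_age + sd_age * z / 2))
            q = (i + 0.5) / n
            t = _survival_quantile(median, q)
            censored = (i % 10) == 9
            time = round(t * (0.6 if censored else 1.0), 1)
            sex = "M" if i < round(male_frac * n) else "F"
        else:
            age = int(np.clip(round(rng.normal(mean_age, sd_age)), 20, 92))
            t = rng.exponential(median / math.log(2))
            c = rng.exponential(9 * median / math.log(2)) \
                if cfg.censoring_fraction > 0 else math.inf
            censored = c < t
            time = round(min(t, c), 1)
            sex = "M" if rng.random() < male_frac else "F"
        p_dict = {
            "age": max(age, 19),
            "sex": sex,
            "ethnicity": "Black" if i < n_black else "White",
            "location": cycle[i % len(cycle)],
            "survival_months": max(time, 0.1),
            "event_observed": not censored,
        }
        p.demographics = p_dict  # type: ignore[attr-defined]
        if p.expression is not None and cdk6 is not None:
            if rng is None:
                p.fold("CDK6", cdk6)
                p.fold("MKI67", prolif)
            else:
                p.fold("CDK6", float(max(0.2, rng.normal(cdk6, cdk6 * 0.2))))
                p.fold("MKI67",
                       float(max(0.2, rng.normal(prolif, prolif * 0.2))))


# ------------------------------------------------------------ assembly

def _extra_plans(cfg: GeneratorConfig) -> list[CasePlan]:
    out: list[CasePlan] = []
    for i in range(cfg.n_dmg):
        out.append(CasePlan(label=cat.DMG, index=i, ihc_h3="positive"))
    for i in range(cfg.n_idh_wt_no_genomics):
        out.append(CasePlan(label=cat.G7_OTHER, index=100 + i))
    for i in range(cfg.n_idh_mut_no_genomics):
        out.append(CasePlan(label=cat.IDH, index=100 + i, ihc_idh="positive"))
    return out


def _build_cohort(cfg: GeneratorConfig,
                  rng: np.random.Generator | None,
                  name: str) -> tuple[Cohort, dict[str, str]]:
    cfg.validate()
    all_plans: list[CasePlan] = []
    for label in cat.TABLE_SUBGROUPS:
        plans = _build_subgroup_plans(cfg, label)
        _assign_histology(label, plans)
        _materialize(cfg, label, plans, rng)
        if rng is not None:
            perm = rng.permutation(len(plans))
            plans = [plans[j] for j in perm]
        all_plans.extend(plans)
    extras = _extra_plans(cfg)
    _materialize(cfg, cat.DMG, [p for p in extras if p.label == cat.DMG], rng)
    for p in extras:
        if not hasattr(p, "demographics"):
            p.demographics = {   # type: ignore[attr-defined]
                "age": 60, "sex": "M", "ethnicity": "White",
                "location": "temporal", "survival_months": 9.0,
                "event_observed": True,
            }
    all_plans.extend(extras)
    if rng is not None:
        perm = rng.permutation(len(all_plans))
        all_plans = [all_plans[j] for j in perm]

    cases: list[Case] = []
    truth: dict[str, str] = {}
    for j, p in enumerate(all_plans):
        case_id = f"GBM-{j + 1:03d}"
        d = p.demographics  # type: ignore[attr-defined]
        expression = (ExpressionProfile(fold_change=dict(p.expression))
                      if p.expression is not None else None)
        cases.append(Case(
            case_id=case_id,
            age=d["age"], sex=d["sex"], ethnicity=d["ethnicity"],
            location=d["location"],
            survival_months=d["survival_months"],
            event_observed=d["event_observed"],
            ihc=IHCPanel(idh1_r132h=p.ihc_idh, h3_k27m=p.ihc_h3,
                         gfap=p.gfap),
            histologic_pattern=p.pattern,
            mgmt_value=p.mgmt_value,
            alterations=list(p.events),
            expression=expression,
        ))
        truth[case_id] = p.label
    return Cohort(cases=cases, name=name), truth


def deterministic_fixture(name: str = "fixture"
                          ) -> tuple[Cohort, dict[str, str]]:
    """The non-random reference cohort: per-subgroup alteration counts equal
    round(frequency x n) for every cell; 87 IDH-wt cases with genomic data
    plus IDH-mutant, DMG and IHC-triage-only cases (101 patients)."""
    return _build_cohort(DEFAULT_GENERATOR_CONFIG, None, name)


def generate(config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
             *, name: str = "simulated"
             ) -> tuple[Cohort, dict[str, str]]:
    """Seeded random cohort with the fixture's count structure."""
    rng = np.random.default_rng(config.seed)
    return _build_cohort(config, rng, name)


def sample_survival(rng: np.random.Generator, median: float, n: int,
                    censoring_fraction: float = 0.10
                    ) -> list[tuple[float, bool]]:
    """Exponential survival sample (months) with independent exponential
    censoring calibrated to the requested censoring fraction."""
    scale = median / math.log(2)
    t = rng.exponential(scale, size=n)
    if censoring_fraction > 0:
        c_scale = scale * (1 - censoring_fraction) / censoring_fraction
        c = rng.exponential(c_scale, size=n)
    else:
        c = np.full(n, np.inf)
    times = np.minimum(t, c)
    events = t <= c
    return [(float(x), bool(e)) for x, e in zip(times, events)]


def write_fixture(directory, *, config: GeneratorConfig | None = None,
                  seed: int | None = None, name: str = "fixture"):
    """Write a cohort (deterministic fixture, or generated when a seed is
    given) plus the ``truth.tsv`` sidecar into ``directory``."""
    if seed is None and config is None:
        cohort, truth = deterministic_fixture(name)
    else:
        cfg = config or DEFAULT_GENERATOR_CONFIG
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        cohort, truth = generate(cfg, name=name)
    extra = pd.DataFrame({
        "gene": ["PTENP1", "RPS4Y1"],
        "is_pseudogene": ["true", "false"],
        "chromosome": ["9", "Y"],
    })
    paths = write_cohort(cohort, directory, extra_annotation=extra)
    truth_path = paths["clinical_table"].parent / "truth.tsv"
    pd.DataFrame(sorted(truth.items()),
                 columns=["case_id", "intended_label"]).to_csv(
        truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
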
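"""Reference catalogs: subgroup labels, gene sets, RTK classes, and the
per-subgroup alteration-frequency configuration that drives the synthetic
cohort and against which the reproduced frequency matrix is checked.

All percentages are the generator's study conditions; the frequency matrix
computed from a cohort built under these conditions must reproduce them
cell-exactly (see :mod:`gbmtyper.simulate`).
"""

from __future__ import annotations

# --- molecular subgroup labels -------------------------------------------

DMG = "DMG"
IDH = "IDH"
G1_EGFR_AMP = "G1_EGFR_amp"
G1_EGFR_MUT = "G1_EGFR_mut"
G2_FGFR3 = "G2_FGFR3"
G3_NF1 = "G3_NF1"
G4_RAF = "G4_RAF"
G5_PDGFRA = "G5_PDGFRA"
G6_MULTI_RTK = "G6_MultiRTK"
G7_OTHER = "G7_Other"

#: IDH-wild-type subgroups in canonical (display) order.
IDH_WT_SUBGROUPS = (
    G1_EGFR_AMP,
    G1_EGFR_MUT,
    G5_PDGFRA,
    G6_MULTI_RTK,
    G2_FGFR3,
    G3_NF1,
    G4_RAF,
    G7_OTHER,
)

#: Column order of the frequency table (IDH-wt subgroups then IDH-mutant).
TABLE_SUBGROUPS = IDH_WT_SUBGROUPS + (IDH,)

ALL_LABELS = (DMG, IDH) + IDH_WT_SUBGROUPS

#: Subgroups driven by a receptor tyrosine kinase.
RTK_SUBGROUPS = (G1_EGFR_AMP, G1_EGFR_MUT, G2_FGFR3, G5_PDGFRA, G6_MULTI_RTK)

#: Subgroups with an ERK/MAPK-activating lesion (RTK, NF1 or RAF driven).
ERK_MAPK_SUBGROUPS = RTK_SUBGROUPS + (G3_NF1, G4_RAF)

# --- RTK catalog ----------------------------------------------------------

#: Receptor tyrosine kinases grouped by the 19 structural classes
#: (ligand-binding ectodomain families).  Flattened below into the default
#: driver-gene catalog used by the classifier.
RTK_CLASSES: dict[str, tuple[str, ...]] = {
    "EGFR": ("EGFR", "ERBB2", "ERBB3", "ERBB4"),
    "INSR": ("INSR", "IGF1R", "INSRR"),
    "PDGFR": ("PDGFRA", "PDGFRB", "KIT", "CSF1R", "FLT3"),
    "VEGFR": ("KDR", "FLT1", "FLT4"),
    "FGFR": ("FGFR1", "FGFR2", "FGFR3", "FGFR4"),
    "PTK7": ("PTK7",),
    "TRK": ("NTRK1", "NTRK2", "NTRK3"),
    "ROR": ("ROR1", "ROR2"),
    "MUSK": ("MUSK",),
    "MET": ("MET", "MST1R"),
    "AXL": ("AXL", "TYRO3", "MERTK"),
    "TIE": ("TIE1", "TEK"),
    "EPH": (
        "EPHA1", "EPHA2", "EPHA3", "EPHA4", "EPHA5", "EPHA6", "EPHA7",
        "EPHA8", "EPHA10", "EPHB1", "EPHB2", "EPHB3", "EPHB4", "EPHB6",
    ),
    "RET": ("RET",),
    "RYK": ("RYK",),
    "DDR": ("DDR1", "DDR2"),
    "ROS": ("ROS1",),
    "LMR": ("AATK", "LMTK2", "LMTK3"),
    "ALK": ("ALK", "LTK"),
}

RTK_GENES: tuple[str, ...] = tuple(g for fam in RTK_CLASSES.values() for g in fam)

# --- composite pathway gene sets -----------------------------------------

PI3K_MTOR_GENES = ("PTEN", "PIK3CA", "PIK3R1", "TSC2", "MTOR")
#: G1-phase cell-cycle lesions: CDKN2A homozygous loss, CDK4 amplification,
#: RB1 pathogenic mutation.
G1_PHASE_GENES = ("CDKN2A", "CDK4", "RB1")
TP53_PATHWAY_GENES = ("TP53", "MDM2", "MDM4", "RPL5", "PPM1D")
MMR_GENES = ("MSH6", "MSH5", "PMS2", "MLH3")
DDR_GENES = ("ATM", "BRCA2") + MMR_GENES
SWI_SNF_GENES = ("ARID1A", "ARID1B", "ARID2", "SMARCA1", "SMARCA4", "PBRM1")
CHROMATIN_GENES = (
    "YEATS4", "DNMT3A", "TET2", "EZH2", "SUZ12", "ASXL1", "ASXL2",
    "KDM5C", "KDM6A", "KMT2C", "KMT2D", "CREBBP",
)

#: Genes whose pathway contribution is an amplification call, not a mutation.
AMPLIFICATION_FEATURE_GENES = ("CDK4", "MDM2", "MDM4", "YEATS4")

# --- reference frequency table -------------------------------------------

#: Per-subgroup case counts of the reference cohort (cases with genomic data).
SUBGROUP_SIZES: dict[str, int] = {
    G1_EGFR_AMP: 33,
    G1_EGFR_MUT: 3,
    G5_PDGFRA: 7,
    G6_MULTI_RTK: 7,
    G2_FGFR3: 5,
    G3_NF1: 15,
    G4_RAF: 4,
    G7_OTHER: 13,
    IDH: 7,
}

IDH_WT_TOTAL = sum(SUBGROUP_SIZES[s] for s in IDH_WT_SUBGROUPS)  # 87

#: Feature rows of the frequency matrix, in display order.  Kinds:
#: ``tert`` composite telomere call, ``mut`` somatic pathogenic small
#: variant, ``amp`` amplification, ``loss`` homozygous loss, ``composite``
#: boolean attribute of PathwayStatus, ``mgmt`` methylation call.
FEATURE_ROWS: tuple[tuple[str, str, str | None], ...] = (
    ("TERT", "tert", None),
    ("PTEN", "mut", "PTEN"),
    ("PIK3CA", "mut", "PIK3CA"),
    ("PIK3R1", "mut", "PIK3R1"),
    ("PI3K_mTOR", "composite", "pi3k_mtor"),
    ("CDKN2A_loss", "loss", "CDKN2A"),
    ("CDK4_amp", "amp", "CDK4"),
    ("RB1", "mut", "RB1"),
    ("G1_phase", "composite", "g1_phase"),
    ("TP53", "mut", "TP53"),
    ("MDM2_amp", "amp", "MDM2"),
    ("MDM4_amp", "amp", "MDM4"),
    ("RPL5", "mut", "RPL5"),
    ("PPM1D", "mut", "PPM1D"),
    ("TP53_pathway", "composite", "tp53_path"),
    ("ATM", "mut", "ATM"),
    ("BRCA2", "mut", "BRCA2"),
    ("MMR", "composite", "mmr"),
    ("DDR_pathway", "composite", "ddr_path"),
    ("STAG2", "mut", "STAG2"),
    ("SWI_SNF", "composite", "swi_snf"),
    ("ChRm", "composite", "other_chrm"),
    ("MGMT_methylated", "mgmt", None),
)

FEATURE_NAMES = tuple(name for name, _, _ in FEATURE_ROWS)

#: Reference alteration frequencies (percent of subgroup cases), one row per
#: feature, columns ordered as TABLE_SUBGROUPS.  These are the generator's
#: target conditions; composites are realized by allocating member-gene
#: events with the exact overlap the column requires.
SUBGROUP_ALTERATION_FREQUENCIES: dict[str, tuple[float, ...]] = {
    #              EGFR+   EGFRm  PDGFRA MultiR FGFR3  NF1    RAF    Other  IDH
    "TERT":            (96.4, 100.0, 42.9, 100.0, 80.0, 73.3, 100.0, 81.8, 28.6),
    "PTEN":            (48.5, 33.3, 28.6, 71.4, 80.0, 46.7, 50.0, 69.2, 0.0),
    "PIK3CA":          (27.3, 0.0, 0.0, 14.3, 0.0, 13.3, 0.0, 15.4, 28.6),
    "PIK3R1":          (9.1, 0.0, 28.6, 0.0, 0.0, 26.7, 25.0, 7.7, 0.0),
    "PI3K_mTOR":       (75.8, 33.3, 42.9, 71.4, 80.0, 80.0, 75.0, 100.0, 42.9),
    "CDKN2A_loss":     (72.7, 0.0, 57.1, 42.9, 80.0, 60.0, 50.0, 15.4, 42.9),
    "CDK4_amp":        (3.0, 0.0, 28.6, 14.3, 0.0, 0.0, 0.0, 46.2, 14.3),
    "RB1":             (0.0, 100.0, 0.0, 28.6, 20.0, 6.7, 0.0, 30.8, 0.0),
    "G1_phase":        (75.8, 100.0, 85.7, 85.7, 100.0, 66.7, 50.0, 92.3, 57.1),
    "TP53":            (18.2, 66.7, 57.1, 57.1, 20.0, 33.3, 0.0, 53.8, 100.0),
    "MDM2_amp":        (0.0, 0.0, 0.0, 14.3, 20.0, 6.7, 0.0, 15.4, 0.0),
    "MDM4_amp":        (9.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 7.7, 0.0),
    "RPL5":            (6.1, 0.0, 0.0, 0.0, 0.0, 13.3, 25.0, 0.0, 0.0),
    "PPM1D":           (0.0, 0.0, 14.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "TP53_pathway":    (33.3, 66.7, 71.4, 71.4, 40.0, 53.3, 25.0, 69.2, 100.0),
    "ATM":             (12.1, 0.0, 42.9, 0.0, 20.0, 13.3, 25.0, 0.0, 0.0),
    "BRCA2":           (9.1, 33.3, 14.3, 0.0, 0.0, 0.0, 0.0, 0.0, 28.6),
    "MMR":             (12.1, 0.0, 28.6, 14.3, 40.0, 6.7, 0.0, 0.0, 14.3),
    "DDR_pathway":     (27.3, 33.3, 71.4, 14.3, 60.0, 20.0, 25.0, 0.0, 42.9),
    "STAG2":           (15.2, 0.0, 14.3, 14.3, 20.0, 13.3, 0.0, 0.0, 0.0),
    "SWI_SNF":         (15.2, 0.0, 14.3, 28.6, 0.0, 20.0, 25.0, 0.0, 57.1),
    "ChRm":            (30.3, 0.0, 14.3, 57.1, 100.0, 20.0, 0.0, 38.5, 14.3),
    "MGMT_methylated": (43.3, 0.0, 0.0, 50.0, 50.0, 27.3, 50.0, 36.4, 42.9),
}

#: Printed whole-cohort (IDH-wt) frequencies for the same rows.  Three rows
#: are internally inconsistent with their own subgroup columns (per-gene
#: panel coverage cannot be reconstructed) and are excluded from exact
#: checks; see docs/methods.md.
REFERENCE_TOTALS: dict[str, float] = {
    "TERT": 85.0,
    "PTEN": 53.0,
    "PIK3CA": 18.4,
    "PIK3R1": 12.6,
    "PI3K_mTOR": 75.9,
    "CDKN2A_loss": 55.2,
    "CDK4_amp": 11.5,
    "RB1": 12.6,
    "G1_phase": 79.3,
    "TP53": 33.3,
    "MDM2_amp": 5.7,
    "MDM4_amp": 4.6,
    "RPL5": 5.7,
    "PPM1D": 1.1,
    "TP53_pathway": 49.4,
    "ATM": 12.6,
    "BRCA2": 5.7,
    "MMR": 11.5,
    "DDR_pathway": 26.4,
    "STAG2": 12.6,
    "SWI_SNF": 13.8,
    "ChRm": 32.2,
    "MGMT_methylated": 36.1,
}

INCONSISTENT_TOTAL_ROWS = frozenset({"PIK3CA", "STAG2", "MGMT_methylated"})

# --- survival and demographic conditions ---------------------------------

#: Median overall survival in months per subgroup (exponential model in the
#: generator; 10% independent censoring).
SURVIVAL_MEDIANS: dict[str, float] = {
    G1_EGFR_AMP: 12.0,
    G1_EGFR_MUT: 6.0,
    G2_FGFR3: 20.0,
    G3_NF1: 6.7,
    G4_RAF: 3.5,
    G5_PDGFRA: 12.0,
    G6_MULTI_RTK: 7.5,
    G7_OTHER: 10.0,
    IDH: 30.0,
    DMG: 11.0,
}

#: Age distribution (mean, SD) per subgroup; Multi-RTK skews older, the
#: IDH-mutant subgroup markedly younger.
AGE_PARAMS: dict[str, tuple[float, float]] = {
    G1_EGFR_AMP: (61.0, 10.0),
    G1_EGFR_MUT: (60.0, 8.0),
    G2_FGFR3: (62.0, 9.0),
    G3_NF1: (60.0, 10.0),
    G4_RAF: (63.0, 9.0),
    G5_PDGFRA: (62.0, 9.0),
    G6_MULTI_RTK: (70.0, 8.0),
    G7_OTHER: (62.0, 10.0),
    IDH: (42.0, 6.0),
    DMG: (35.0, 10.0),
}

#: Fold-change effect sizes for driver overexpression: (mean, low, high).
EXPRESSION_EFFECTS: dict[str, tuple[float, float, float]] = {
    "EGFR_amplified": (26.0, 4.5, 72.0),
    "PDGFRA_overexpressed": (16.8, 4.9, 25.7),
    "MET_amplified": (45.0, 40.0, 60.0),
}

#: Mean CDK6 fold-change and proliferation (MKI67 fold) per subgroup, for
#: cases with expression data.  Chosen from the qualitative description of
#: the expression landscape: CDK6 up mainly in PDGFRA, EGFR-amplified and
#: FGFR3 subgroups; proliferation highest in PDGFRA, lowest in IDH-mutant.
CDK6_MEANS: dict[str, float] = {
    G1_EGFR_AMP: 6.0, G1_EGFR_MUT: 1.5, G5_PDGFRA: 8.0, G6_MULTI_RTK: 2.0,
    G2_FGFR3: 6.0, G3_NF1: 3.0, G4_RAF: 2.0, G7_OTHER: 2.0, IDH: 1.5,
}
PROLIFERATION_MEANS: dict[str, float] = {
    G1_EGFR_AMP: 3.0, G1_EGFR_MUT: 4.0, G5_PDGFRA: 6.0, G6_MULTI_RTK: 3.5,
    G2_FGFR3: 2.5, G3_NF1: 3.0, G4_RAF: 3.5, G7_OTHER: 3.5, IDH: 1.5,
}

#: Whole-cohort parameters that enter the generator but are never
#: recomputed as endpoints: the male:female ratio of IDH-wt cases, the
#: per-subgroup tumor-mutation-burden median range (mutations/Mb), and the
#: cohort-level survival anchors.
SEX_RATIO_M_F = 1.57
TMB_MEDIANS_RANGE = (2.8, 5.8)
COHORT_ONE_YEAR_SURVIVAL_PCT = 37.9
COHORT_MEDIAN_SURVIVAL_MONTHS = 9.5

#: Curated activating-hotspot seed list used by the synthetic cohort when
#: planting gain-of-function variants (ectodomain cysteines and kinase
#: hotspots for the RTKs, BRAF p.V600E, RAF1 gain-of-function).
ACTIVATING_HOTSPOTS: dict[str, tuple[str, ...]] = {
    "EGFR": ("p.A289V", "p.G598V", "p.L861Q", "vIII", "vIVa"),
    "PDGFRA": ("p.C235Y", "p.Y288C", "p.D842V"),
    "FGFR3": ("p.R248C", "p.S249C", "p.K650E"),
    "MET": ("p.D1228N", "exon14_skip"),
    "BRAF": ("p.V600E",),
    "RAF1": ("p.S257L", "p.P261A"),
}
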
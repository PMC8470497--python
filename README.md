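# gbmtyper

Rule-based, multi-platform molecular subtyping of IDH-wild-type
glioblastoma, built for neuro-oncology pipelines that already have
gene-level summaries in hand (variant calls, copy number, fusions, a
normalized expression matrix, clinical data) and want a reproducible,
auditable subgroup call per patient rather than a black-box cluster id.

## The classification

Glioblastomas are partitioned into mutually exclusive molecular subgroups
keyed to the upstream, receptor-to-RAS-RAF segment of the ERK/MAPK
signalling pathway:

| label | driver lesion |
|---|---|
| `DMG` | histone H3 K27M (triaged out by IHC) |
| `IDH` | IDH1/IDH2 mutation (IHC or sequencing) |
| `G1_EGFR_amp` / `G1_EGFR_mut` | *EGFR* amplification (CN ≥ 7) with overexpression, or activating *EGFR* mutation without amplification |
| `G2_FGFR3` | *FGFR3* fusion or activating mutation |
| `G3_NF1` | biallelic *NF1* inactivation (two hits or hit + LOH) |
| `G4_RAF` | *BRAF*/*RAF1* gain-of-function |
| `G5_PDGFRA` | *PDGFRA* amplification with overexpression, or activating mutation |
| `G6_MultiRTK` | ≥ 2 concurrent RTK drivers; amplification without matching overexpression; or a driver in another RTK (*MET*, *NTRK1*, ...) |
| `G7_Other` | no ERK/MAPK driver (PI3K-pathway-only tumors) |

Driver evidence is deterministic: amplification is called at copy number
≥ 7, overexpression at ≥ 5-fold over the mean of low-grade-glioma control
samples (raw-count floor 500; pseudogenes and chrY excluded), telomerase
activation is *TERT* promoter mutation OR overexpression without mutation,
and MGMT promoter methylation is dichotomized at a quantitative value ≥ 5.
Around the classifier the package computes composite pathway statuses
(PI3K/mTOR, cell-cycle G1 phase, p53, DDR/MMR, SWI/SNF, chromatin
remodeling), the subgroup × alteration frequency matrix, correlation-based
hierarchical clustering of subgroups (Pearson distance, exportable as
Newick), Kaplan–Meier survival with log-rank tests (via lifelines),
demographic summaries, histologic pattern → cluster mapping with Fisher
exact association screens, and a per-case pathology-style JSON report.

A first-class synthetic-cohort generator (`gbmtyper.simulate`) emulates
the 101-patient study structure — subgroup sizes, per-subgroup alteration
frequencies, expression effect sizes, survival medians — and is the
test-bed for the whole pipeline; see `docs/methods.md` for what it does
and does not emulate.

## Worked example

```bash
gbmtyper simulate --out demo/            # deterministic reference cohort
gbmtyper classify demo/ --out calls.tsv
gbmtyper report demo/ --case GBM-001 --text
```

prints

```
config 39c1aa07e82b; counts: {'G1_EGFR_amp': 33, 'G1_EGFR_mut': 3,
'G5_PDGFRA': 7, 'G6_MultiRTK': 7, 'G2_FGFR3': 5, 'G3_NF1': 15,
'G4_RAF': 4, 'G7_Other': 13, 'IDH': 7}

PATHOLOGY REPORT — case GBM-001
Molecular subgroup: G1_EGFR_amp
  driver: EGFR (activating mutation)
Histologic pattern: epithelioid (cluster: Epithelioid)
Pathway alterations: tert_path, pi3k_mtor, g1_phase, tp53_path, other_chrm
Telomere maintenance: positive
MGMT promoter methylation: positive
```

The counts are the per-subgroup case totals among the 87 IDH-wild-type
cases with genomic data: the RTK-driven subgroups together are 63.2% of
IDH-wild-type tumors, the EGFR subgroup alone 41.4%, and ERK/MAPK-altered
tumors 85%. `GBM-001` is an *EGFR*-amplified tumor whose amplification sits
at the CN threshold and carries a vIII activating variant — the report
lists each evidence chain explicitly, plus the classifier config hash so a
call can always be traced to the thresholds that produced it.

`gbmtyper summarize demo/ --table1 table1.tsv` writes the subgroup ×
alteration frequency table (percent of cases per subgroup;
assay-unavailable cases are excluded from the relevant denominators), and
`gbmtyper cluster demo/ --newick tree.nwk` writes the subgroup dendrogram
— on the reference cohort the EGFR-amplified, NF1, RAF and FGFR3 subgroups
form one cluster and Multi-RTK/Other another, with PDGFRA, EGFR-mutant and
IDH segregating individually.

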
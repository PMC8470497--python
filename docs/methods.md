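# Methods

## The classification model

The pipeline assigns each patient-tumor exactly one molecular label. IHC
triage runs first (H3 K27M → diffuse midline glioma; IDH1 R132H IHC or an
IDH1/2 pathogenic variant → IDH-mutant), then the classifier builds the
RTK driver set *D* over a catalog of receptor tyrosine kinases grouped in
the 19 structural classes. A gene enters *D* when it is

1. amplified (CN ≥ 7) **and** overexpressed (≥ 5-fold) or of unknown
   expression (genomic fallback — roughly a quarter of real cases lack
   transcriptomes but are still subgroupable),
2. carries a curated activating mutation,
3. carries a pathogenic fusion, or
4. is *MET* with ≥ 10-fold overexpression without amplification
   (config-gated; only *MET* shows this amplification-independent driver
   mode, via chr7 low-level gain or promoter-swapping fusions).

Rules then fire in order: two or more drivers → Multi-RTK; *PDGFRA*
amplified but demonstrably not overexpressed → Multi-RTK regardless of the
rest (amplification without expression is not treated as pathway
activation for this locus); a single driver in EGFR/FGFR3/PDGFRA → the
corresponding subgroup (EGFR split into amplified vs mutant-only); any
other single RTK driver → Multi-RTK; otherwise NF1 inactivation → NF1;
otherwise BRAF/RAF1 gain-of-function → RAF; otherwise Other. RTK evidence
deliberately precedes NF1/RAF: the subgroups are empirically mutually
exclusive, and where a simulated case violates that the RTK call wins and
a `conflict` flag is set, because RTK subgroups are defined by positive
driver evidence rather than by loss.

Two deliberate wrinkles:

* **4q12 locus collapse.** *KIT* and *KDR* are contiguous with *PDGFRA*
  and ride its amplicon. Drivers whose only evidence is amplification
  (± overexpression) within a configured locus group are collapsed onto
  the primary gene, so adjacent-amplicon passengers never manufacture a
  Multi-RTK call. Groups are configurable; only PDGFRA/KIT/KDR is enabled
  by default.
* **Single-hit NF1.** Nearly all NF1 tumors carry two hits; a pathogenic
  single hit still classifies as NF1 but carries a `monoallelic` flag.

Multifocal tumors are one case: the main focus is classified, secondary-
focus events are stored with `secondary_focus=true` and ignored.

## Thresholds and units

| parameter | default | units | note |
|---|---|---|---|
| `cn_threshold` | 7 | absolute copy number | amplification call, inclusive |
| `fold_threshold` | 5 | fold vs control mean | overexpression, inclusive |
| `high_fold` | 10 | fold | amplification-independent driver arm (MET) |
| raw-count floor | 500 | counts in ≥ 1 tumor | genes below are dropped before fold-change |
| MGMT cut | 5 | quantitative methylation value | ≥ 5 positive, missing → unknown |
| TERT overexpression arm | 5-fold | same cut as other genes | whether telomerase overexpression uses the generic cut is not settled; exposed in config |

Fold-change is tumor count over the **arithmetic** mean of low-grade-glioma
control samples (log-space and library-size normalization are config
toggles, off by default; the upstream vendor normalization is not public,
so the ratio definition is this package's own). A zero control mean yields
a NaN sentinel excluded from thresholding.

## Frequency matrix conventions

Single-gene rows count **somatic** pathogenic/likely-pathogenic events of
the row's kind (VUS and germline excluded); composite rows OR their member
lesions and include germline events. This split is what reconciles
G1-phase mutual exclusivity with heterozygous germline *RB1* carriers:
the two planted germline *RB1* point mutations sit in CDKN2A-deleted
cases, inflate no single-gene row, and are exactly what the exclusivity
audit reports. Denominators are per-feature: full genomic-data counts for
mutation/CN rows, cases with a known methylation value for MGMT, and cases
with an assessable telomerase status for TERT (a case with neither a
promoter mutation nor expression data is *unknown*, not negative). Empty
denominators yield NaN, never 0. DMG cases and cases without genomic data
are excluded from every denominator.

The whole-cohort Total column is recomputed from the fixture rather than
copied. For three rows (PIK3CA, STAG2, MGMT) the reference table's own
Total is arithmetically inconsistent with its subgroup columns — plausibly
per-gene panel-coverage differences that cannot be reconstructed from the
printed values — so the fixture reproduces the subgroup columns exactly
and lets the Total fall where the columns put it.

## Subgroup clustering

Subgroups, not samples, are clustered. Each subgroup's vector is its
frequency-matrix column plus two expression means (CDK6 fold-change and a
proliferation score, by default the MKI67 fold; extendable by config).
Features are z-scored across subgroups before Pearson correlation because
percent and fold units are mixed; clustering is agglomerative on
d = 1 − r with average linkage by default (complete and single are
selectable; the topology checks run under both average and complete).
The default feature mask keeps all composite rows and drops single-gene
rows under 10% whole-cohort frequency (MDM2, MDM4, RPL5, PPM1D, BRCA2):
with near-empty rows included, complete linkage becomes unstable on these
short vectors. Labels are canonicalized before linkage, making the tree
invariant to input order and deterministic under ties.

On the reference cohort this reproduces the published grouping — cluster
#1 {EGFR-amplified, NF1, RAF, FGFR3}, cluster #2 {Multi-RTK, Other},
PDGFRA/EGFR-mutant/IDH segregating individually — under both linkages.
One logged discrepancy: on these vectors the single highest off-diagonal
correlation is NF1–RAF, with EGFR-amplified–NF1 second (and EGFR-amp's own
best partner). The narrative ordering of the original figure likely
reflects additional expression features not derivable from the frequency
table; the test suite asserts what recomputation actually gives and warns
on the rank difference rather than hiding it.

## Survival and demographics

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines; medians are the first time S(t) ≤ 0.5 (undefined if never
reached), landmark survival is right-continuous step interpolation.
Survival is measured from first surgery; alive patients carry
`event_observed=false`. Pairwise subgroup p-values are reported raw, with
a clearly-labeled Holm-adjusted column as an extension. Age summaries
exclude outliers by Tukey 1.5×IQR fences (the source marks outliers
without defining them; the fence is this package's choice) and pairwise
age contrasts use Welch's two-tailed t-test.

## The synthetic cohort

The generator's defaults are the study conditions: subgroup sizes
(33/3/7/7/5/15/4/13 IDH-wt plus 7 IDH-mutant with genomic data, 3 DMG and
4 IHC-triage-only extras → 101 patients), per-subgroup alteration
frequencies, driver templates per subgroup (EGFR amplification with
secondary vIII/fusion events, PDGFRA amplicon with KIT/KDR co-amplification,
MET-amplified and PDGFRA-amplified-non-overexpressing Multi-RTK cases,
FGFR3–TACC3 fusions, two-hit NF1 including frameshift fusions and two
syndromic germline cases, BRAF V600E and amplified RAF1), fold-change
effect sizes (EGFR mean 26, range 4.5–72; PDGFRA mean 16.8, range
4.9–25.7; MET-amplified > 40), per-subgroup survival medians (exponential,
10% independent censoring), and demographic structure (Multi-RTK older;
IDH at 42 years; male bias except FGFR3 and IDH).

Because the frequencies themselves are the conditions being emulated, the
generator **conditions on them exactly**: per-cell event counts are fixed
at round(frequency × n) and solved jointly with each composite's printed
union (members fill distinct cases up to the composite count, then
overlap; TSC2/MTOR top up the PI3K union where members fall short).
Randomness enters through which case receives which molecular plan, all
continuous draws (folds from truncated log-normals fitted via SEM·√n,
survival, ages) and cohort ordering. Frequency "recovery" across seeds is
therefore a pipeline-integrity check, not a binomial-noise experiment —
an intentional design choice, stated here so the passing test is read
correctly. TP53-pathway events are allocated to CDKN2A-intact cases first
(a qualitative anti-correlation knob, on by default, tagged inferred).

What the generator does **not** emulate: read-level data, the vendor's
normalization, panel-coverage heterogeneity (except through the TERT/MGMT
assay-availability mechanism), co-occurrence structure beyond the
documented constraints, and real survival-covariate dependence. Passing
tests therefore demonstrate that the pipeline recovers what was planted
under the stated conditions — not that the rule set is correct for data
the study never printed (per-patient survival comparisons, the 37.9%
1-year survival, sex/ethnicity ratios and TMB medians are generator
parameters only and are asserted against nothing).

## Numerical choices and degenerate inputs

Rounding to printed precision is half-away-from-zero. Cell realization
solves for the largest denominator m ≤ n reproducing the printed percent
at one decimal (falling back to the nearest count at m = n for custom
sizes). Ties in KM handle deaths before censorings. Zero-variance
subgroup vectors and empty survival groups are hard errors naming the
offender; empty subgroups yield NaN rows, contradictory IHC (IDH1 and H3
both positive) is a hard error, and a case with no molecular data and
negative IHC classifies as Other with a `no_molecular_data` warning flag
and is excluded from cohort statistics.

## Known limitations

Activating status is taken from curation, not predicted from HGVS; fusion
breakpoints are not interpreted; histologic patterns are expert input, and
three of the twelve pattern→cluster assignments are config inferences
tagged `inferred`; the classifier has no probabilistic mode; and the
reference cohort is a reconstruction from printed marginal counts, so
per-case co-occurrence beyond the documented constraints is synthetic.
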
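"""Domain types for patient-tumor cases and tabular interchange IO.

A :class:`Cohort` bundles one :class:`Case` per patient-tumor.  Molecular
payloads are gene-level summaries (variants, copy number, fusions) plus a
per-gene fold-change expression profile computed against the mean of
low-grade-glioma control samples.  Multifocal tumors are represented as a
single case carrying the main focus's profile; secondary-focus events are
stored but flagged and ignored by the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("M", "F")
ETHNICITIES = ("White", "Black", "Other")
LOCATIONS = (
    "frontal", "temporal", "parietal", "other_lobe", "midline",
    "corpus_callosum",
)

#: Closed 12-pattern histology vocabulary (plus ``unknown``).
HISTOLOGIC_PATTERNS = (
    "egfr",
    "egfr_fgfr",
    "fgfr_small",
    "small_dark_regular",
    "small_dark_irregular",
    "pre_hgne",
    "hgne",
    "fibroblastic",
    "gliosarcoma",
    "giant_cell",
    "epithelioid",
    "anaplastic_other",
)

EVENT_KINDS = (
    "missense", "truncating", "frameshift", "splice_variant",
    "promoter_mutation", "fusion", "amplification", "homozygous_loss",
    "loh", "cn_gain",
)
SMALL_VARIANT_KINDS = ("missense", "truncating", "frameshift", "splice_variant")
PATHOGENICITIES = ("pathogenic", "likely_pathogenic", "vus", "unknown")
PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})

IHC_TRISTATE = ("positive", "negative", "missing")
GFAP_LEVELS = ("high", "low", "absent", "missing")

#: Raw-count floor: a gene must reach this in at least one tumor sample.
MIN_RAW_COUNTS = 500
#: Column-name prefix identifying low-grade-glioma control samples.
CONTROL_PREFIX = "control:"


@dataclass
class IHCPanel:
    """Immunohistochemistry results used for initial triage."""

    idh1_r132h: str = "missing"
    h3_k27m: str = "missing"
    gfap: str = "missing"
    p53: int | None = None
    ki67: float | None = None

    def __post_init__(self) -> None:
        if self.idh1_r132h not in IHC_TRISTATE:
            raise ValueError(f"bad idh1_r132h value: {self.idh1_r132h!r}")
        if self.h3_k27m not in IHC_TRISTATE:
            raise ValueError(f"bad h3_k27m value: {self.h3_k27m!r}")
        if self.gfap not in GFAP_LEVELS:
            raise ValueError(f"bad gfap value: {self.gfap!r}")


@dataclass
class AlterationEvent:
    """One genomic event on one gene with pathogenicity annotation."""

    gene: str
    kind: str
    pathogenicity: str = "unknown"
    activating: bool | None = None
    copy_number: float | None = None
    partner_gene: str | None = None
    germline: bool = False
    secondary_focus: bool = False
    hgvs: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r} on {self.gene}")
        if self.pathogenicity not in PATHOGENICITIES:
            raise ValueError(
                f"unknown pathogenicity {self.pathogenicity!r} on {self.gene}"
            )
        if self.kind == "amplification" and self.copy_number is None:
            raise ValueError(f"amplification on {self.gene} requires copy_number")
        if self.kind == "fusion" and not self.partner_gene:
            raise ValueError(f"fusion on {self.gene} requires partner_gene")

    @property
    def is_pathogenic(self) -> bool:
        return self.pathogenicity in PATHOGENIC

    @property
    def is_small_variant(self) -> bool:
        return self.kind in SMALL_VARIANT_KINDS


@dataclass
class ExpressionProfile:
    """Per-gene fold-change of a tumor versus the control-sample mean.

    Genes failing the raw-count filter, or with a zero control mean, are
    absent from the mapping.
    """

    fold_change: dict[str, float]
    raw_counts_available: bool = True

    def __post_init__(self) -> None:
        bad = {g: f for g, f in self.fold_change.items()
               if not (f > 0) or math.isnan(f)}
        if bad:
            raise ValueError(f"non-positive fold-changes: {sorted(bad)[:5]}")

    def fold(self, gene: str) -> float | None:
        return self.fold_change.get(gene)


@dataclass
class Case:
    """One patient-tumor record (demographics, IHC, histology, survival,
    molecular payloads)."""

    case_id: str
    age: int
    sex: str
    ethnicity: str
    location: str
    survival_months: float
    event_observed: bool
    ihc: IHCPanel = field(default_factory=IHCPanel)
    histologic_pattern: str = "unknown"
    mgmt_value: float | None = None
    alterations: list[AlterationEvent] = field(default_factory=list)
    expression: ExpressionProfile | None = None
    has_genomic_data: bool | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"{self.case_id}: age must be positive")
        if self.survival_months < 0:
            raise ValueError(f"{self.case_id}: negative survival")
        if self.sex not in SEXES:
            raise ValueError(f"{self.case_id}: bad sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"{self.case_id}: bad ethnicity {self.ethnicity!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"{self.case_id}: bad location {self.location!r}")
        if (self.histologic_pattern != "unknown"
                and self.histologic_pattern not in HISTOLOGIC_PATTERNS):
            raise ValueError(
                f"{self.case_id}: bad histologic pattern "
                f"{self.histologic_pattern!r}"
            )
        if self.mgmt_value is not None and self.mgmt_value < 0:
            raise ValueError(f"{self.case_id}: negative MGMT value")
        if self.has_genomic_data is None:
            self.has_genomic_data = bool(self.alterations)

    def events_for(self, gene: str, include_secondary: bool = False):
        return [e for e in self.alterations
                if e.gene == gene and (include_secondary or not e.secondary_focus)]

    @property
    def genes_with_events(self) -> set[str]:
        return {e.gene for e in self.alterations if not e.secondary_focus}


@dataclass
class Cohort:
    cases: list[Case]
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not self.cases:
            raise ValueError("cohort must be non-empty")
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case_ids: {dupes}")

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]


# --- fold-change computation ---------------------------------------------

def compute_fold_change(
    tumor_counts: dict[str, float],
    control_counts: pd.DataFrame,
    *,
    log_space: bool = False,
    library_size_normalize: bool = False,
) -> dict[str, float]:
    """Fold-change of one tumor against the arithmetic mean of controls.

    ``control_counts`` is genes x control-samples.  Genes whose control mean
    is zero receive a NaN sentinel (flagged, excluded from thresholding
    downstream).  With ``log_space``, the ratio is computed on log2 counts
    (geometric-mean controls); ``library_size_normalize`` rescales each
    sample to the mean library size first.
    """
    if control_counts.shape[1] == 0:
        raise ValueError("control table is empty")
    shared = [g for g in tumor_counts if g in control_counts.index]
    if not shared:
        raise ValueError("no genes shared between tumor and controls")
    ctrl = control_counts.loc[shared].astype(float)
    tum = pd.Series({g: float(tumor_counts[g]) for g in shared})
    if (tum < 0).any() or (ctrl.values < 0).any():
        raise ValueError("counts must be non-negative")
    if library_size_normalize:
        sizes = ctrl.sum(axis=0)
        ctrl = ctrl * (sizes.mean() / sizes)
        # the tumor column is rescaled against the mean control library
        tum = tum * (sizes.mean() / tum.sum())
    if log_space:
        ctrl_center = np.exp2(np.log2(ctrl + 1.0).mean(axis=1)) - 1.0
    else:
        ctrl_center = ctrl.mean(axis=1)
    folds: dict[str, float] = {}
    for g in shared:
        c = float(ctrl_center[g])
        folds[g] = float(tum[g]) / c if c > 0 else float("nan")
    return folds


# --- readers / writers ----------------------------------------------------

CLINICAL_COLUMNS = [
    "case_id", "age", "sex", "ethnicity", "location", "survival_months",
    "event_observed", "idh1_r132h", "h3_k27m", "gfap", "p53", "ki67",
    "histologic_pattern", "mgmt_value",
]


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_bool(v, where: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"{where}: cannot parse boolean {v!r}")


def _parse_tristate_bool(v) -> bool | None:
    s = str(v).strip().lower()
    if s in ("", "unknown", "nan", "none"):
        return None
    return s in ("true", "1", "yes")


def read_cohort(
    variant_table: str | Path,
    cn_table: str | Path,
    fusion_table: str | Path,
    expression_matrix: str | Path,
    clinical_table: str | Path,
    gene_annotation: str | Path,
    *,
    name: str = "cohort",
    log_space: bool = False,
    library_size_normalize: bool = False,
) -> Cohort:
    """Assemble a cohort from the six tabular interchange files.

    One case per clinical row; molecular payloads joined on ``case_id``.
    Expression is filtered (raw counts >= 500 in at least one tumor;
    pseudogenes and Y-chromosome genes excluded) before fold-change
    computation against the ``control:``-prefixed columns.
    """
    clin = pd.read_csv(clinical_table, dtype=str, keep_default_na=False)
    if list(clin.columns) != CLINICAL_COLUMNS:
        raise ValueError(
            f"clinical table columns must be {CLINICAL_COLUMNS}, "
            f"got {list(clin.columns)}"
        )
    cases: dict[str, Case] = {}
    for idx, row in clin.iterrows():
        where = f"clinical row {idx + 2}"  # header is line 1
        try:
            ihc = IHCPanel(
                idh1_r132h=row["idh1_r132h"] or "missing",
                h3_k27m=row["h3_k27m"] or "missing",
                gfap=row["gfap"] or "missing",
                p53=int(row["p53"]) if row["p53"] else None,
                ki67=_opt_float(row["ki67"]),
            )
            case = Case(
                case_id=row["case_id"],
                age=int(row["age"]),
                sex=row["sex"],
                ethnicity=row["ethnicity"],
                location=row["location"],
                survival_months=float(row["survival_months"]),
                event_observed=_parse_bool(row["event_observed"], where),
                ihc=ihc,
                histologic_pattern=row["histologic_pattern"] or "unknown",
                mgmt_value=_opt_float(row["mgmt_value"]),
            )
        except ValueError as err:
            raise ValueError(f"{where}: {err}") from err
        cases[case.case_id] = case

    def _require_case(case_id: str, table: str) -> Case:
        if case_id not in cases:
            raise ValueError(f"{table}: unknown case_id {case_id!r}")
        return cases[case_id]

    variants = pd.read_csv(variant_table, sep="\t", dtype=str,
                           keep_default_na=False)
    for idx, row in variants.iterrows():
        case = _require_case(row["case_id"], "variant_table")
        try:
            case.alterations.append(AlterationEvent(
                gene=row["gene"],
                kind=row["kind"],
                pathogenicity=row["pathogenicity"] or "unknown",
                activating=_parse_tristate_bool(row["activating"]),
                germline=_parse_bool(row["germline"], f"variant row {idx + 2}"),
                secondary_focus=_parse_bool(
                    row["secondary_focus"] or "false", f"variant row {idx + 2}")
                if "secondary_focus" in variants.columns else False,
                hgvs=row.get("hgvs", ""),
            ))
        except ValueError as err:
            raise ValueError(f"variant row {idx + 2}: {err}") from err

    cn = pd.read_csv(cn_table, sep="\t", dtype=str, keep_default_na=False)
    for idx, row in cn.iterrows():
        case = _require_case(row["case_id"], "cn_table")
        gene = row["gene"]
        copy_number = _opt_float(row["copy_number"])
        loh = _parse_bool(row["loh"], f"cn row {idx + 2}") if row["loh"] else False
        try:
            for ev in events_from_copy_number(gene, copy_number, loh):
                case.alterations.append(ev)
        except ValueError as err:
            raise ValueError(f"cn row {idx + 2}: {err}") from err

    fus = pd.read_csv(fusion_table, sep="\t", dtype=str, keep_default_na=False)
    for idx, row in fus.iterrows():
        case = _require_case(row["case_id"], "fusion_table")
        g5, g3 = row["gene5"], row["gene3"]
        patho = row["pathogenicity"] or "unknown"
        frame = row["frame"]
        for gene, partner in ((g5, g3), (g3, g5)):
            case.alterations.append(AlterationEvent(
                gene=gene, kind="fusion", pathogenicity=patho,
                partner_gene=partner, hgvs=frame,
            ))

    annot = pd.read_csv(gene_annotation, sep="\t", dtype=str,
                        keep_default_na=False)
    pseudo = set(annot.loc[annot["is_pseudogene"].str.lower()
                           .isin(("true", "1", "yes")), "gene"])
    chry = set(annot.loc[annot["chromosome"].isin(("Y", "chrY")), "gene"])

    expr = pd.read_csv(expression_matrix, sep="\t", index_col=0)
    control_cols = [c for c in expr.columns if c.startswith(CONTROL_PREFIX)]
    tumor_cols = [c for c in expr.columns if not c.startswith(CONTROL_PREFIX)]
    for col in tumor_cols:
        _require_case(col, "expression_matrix")
    if tumor_cols:
        keep = expr.index.difference(pseudo | chry)
        expr = expr.loc[keep]
        passing = expr[tumor_cols].max(axis=1) >= MIN_RAW_COUNTS
        expr = expr.loc[passing]
        controls = expr[control_cols]
        for col in tumor_cols:
            folds = compute_fold_change(
                expr[col].to_dict(), controls,
                log_space=log_space,
                library_size_normalize=library_size_normalize,
            )
            folds = {g: f for g, f in folds.items()
                     if not math.isnan(f) and f > 0}
            cases[col].expression = ExpressionProfile(fold_change=folds)

    for case in cases.values():
        case.has_genomic_data = bool(case.alterations)
    return Cohort(cases=list(cases.values()), name=name)


def events_from_copy_number(
    gene: str, copy_number: float | None, loh: bool,
    *, amplification_threshold: float = 7.0,
) -> list[AlterationEvent]:
    """Translate one gene-level CN row into events.

    CN >= 7 is an amplification; 2 < CN < 7 a low-level gain (never a
    driver); CN <= 0.5 a homozygous loss.  An LOH flag adds a separate
    event.
    """
    events: list[AlterationEvent] = []
    if copy_number is not None:
        if copy_number < 0:
            raise ValueError(f"negative copy number on {gene}")
        if copy_number >= amplification_threshold:
            events.append(AlterationEvent(
                gene=gene, kind="amplification", pathogenicity="pathogenic",
                copy_number=copy_number))
        elif copy_number <= 0.5:
            events.append(AlterationEvent(
                gene=gene, kind="homozygous_loss", pathogenicity="pathogenic",
                copy_number=copy_number))
        elif copy_number > 2:
            events.append(AlterationEvent(
                gene=gene, kind="cn_gain", pathogenicity="unknown",
                copy_number=copy_number))
    if loh:
        events.append(AlterationEvent(gene=gene, kind="loh",
                                      pathogenicity="unknown"))
    return events


def write_cohort(
    cohort: Cohort,
    directory: str | Path,
    *,
    control_baseline: float = 1000.0,
    n_controls: int = 4,
    extra_annotation: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the six interchange files for ``cohort`` into ``directory``.

    Expression is serialized as raw counts: every control sample carries the
    baseline count so that fold-changes round-trip exactly.  Returns the
    mapping of table name to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical_table": directory / "clinical.csv",
        "variant_table": directory / "variants.tsv",
        "cn_table": directory / "cn.tsv",
        "fusion_table": directory / "fusions.tsv",
        "expression_matrix": directory / "expression.tsv",
        "gene_annotation": directory / "gene_annotation.tsv",
    }

    clin_rows = []
    for c in cohort:
        clin_rows.append({
            "case_id": c.case_id, "age": c.age, "sex": c.sex,
            "ethnicity": c.ethnicity, "location": c.location,
            "survival_months": c.survival_months,
            "event_observed": str(c.event_observed).lower(),
            "idh1_r132h": c.ihc.idh1_r132h, "h3_k27m": c.ihc.h3_k27m,
            "gfap": c.ihc.gfap,
            "p53": "" if c.ihc.p53 is None else c.ihc.p53,
            "ki67": "" if c.ihc.ki67 is None else c.ihc.ki67,
            "histologic_pattern": c.histologic_pattern,
            "mgmt_value": "" if c.mgmt_value is None else c.mgmt_value,
        })
    pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS).to_csv(
        paths["clinical_table"], index=False)

    var_rows, cn_rows, fus_rows = [], [], []
    seen_fusions: set[tuple] = set()
    cn_acc: dict[tuple[str, str], dict] = {}
    for c in cohort:
        for e in c.alterations:
            if e.kind in SMALL_VARIANT_KINDS or e.kind == "promoter_mutation":
                var_rows.append({
                    "case_id": c.case_id, "gene": e.gene, "kind": e.kind,
                    "pathogenicity": e.pathogenicity,
                    "activating": "" if e.activating is None
                    else str(e.activating).lower(),
                    "germline": str(e.germline).lower(),
                    "hgvs": e.hgvs,
                    "secondary_focus": str(e.secondary_focus).lower(),
                })
            elif e.kind == "fusion":
                key = (c.case_id, frozenset((e.gene, e.partner_gene)))
                if key in seen_fusions:
                    continue
                seen_fusions.add(key)
                fus_rows.append({
                    "case_id": c.case_id, "gene5": e.gene,
                    "gene3": e.partner_gene,
                    "frame": e.hgvs or "in-frame",
                    "pathogenicity": e.pathogenicity,
                })
            else:  # copy-number class events
                slot = cn_acc.setdefault((c.case_id, e.gene),
                                         {"copy_number": "", "loh": "false"})
                if e.kind == "loh":
                    slot["loh"] = "true"
                else:
                    slot["copy_number"] = e.copy_number

    for (case_id, gene), slot in cn_acc.items():
        cn_rows.append({"case_id": case_id, "gene": gene,
                        "copy_number": slot["copy_number"],
                        "loh": slot["loh"]})
    pd.DataFrame(
        var_rows, columns=["case_id", "gene", "kind", "pathogenicity",
                           "activating", "germline", "hgvs",
                           "secondary_focus"],
    ).to_csv(paths["variant_table"], sep="\t", index=False)
    pd.DataFrame(
        cn_rows, columns=["case_id", "gene", "copy_number", "loh"],
    ).to_csv(paths["cn_table"], sep="\t", index=False)
    pd.DataFrame(
        fus_rows, columns=["case_id", "gene5", "gene3", "frame",
                           "pathogenicity"],
    ).to_csv(paths["fusion_table"], sep="\t", index=False)

    genes = sorted({g for c in cohort if c.expression
                    for g in c.expression.fold_change})
    expr_cases = [c for c in cohort if c.expression is not None]
    expr = pd.DataFrame(index=genes)
    for i in range(n_controls):
        expr[f"{CONTROL_PREFIX}LGG{i + 1}"] = control_baseline
    for c in expr_cases:
        expr[c.case_id] = [
            c.expression.fold_change.get(g, 1.0) * control_baseline
            for g in genes
        ]
    expr.index.name = "gene"
    expr.to_csv(paths["expression_matrix"], sep="\t")

    annot = pd.DataFrame({
        "gene": genes,
        "is_pseudogene": "false",
        "chromosome": "1",
    })
    if extra_annotation is not None:
        annot = pd.concat([annot, extra_annotation], ignore_index=True)
    annot.to_csv(paths["gene_annotation"], sep="\t", index=False)
    return paths
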
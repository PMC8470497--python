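"""Cohort model: domain-type invariants, fold-change, table IO."""

import math

import numpy as np
import pandas as pd
import pytest

import gbmtyper as gt
from gbmtyper.cohort import (AlterationEvent, Case, Cohort, IHCPanel,
                             compute_fold_change, read_cohort)


def _case(case_id="C1", **kw):
    defaults = dict(age=60, sex="M", ethnicity="White", location="frontal",
                    survival_months=10.0, event_observed=True)
    defaults.update(kw)
    return Case(case_id=case_id, **defaults)


class TestDomainInvariants:
    def test_rejects_bad_enums_and_ranges(self):
        with pytest.raises(ValueError):
            _case(age=0)
        with pytest.raises(ValueError):
            _case(survival_months=-1)
        with pytest.raises(ValueError):
            _case(sex="X")
        with pytest.raises(ValueError):
            _case(histologic_pattern="no-such-pattern")
        with pytest.raises(ValueError):
            IHCPanel(idh1_r132h="maybe")

    def test_event_requires_consistent_payload(self):
        with pytest.raises(ValueError):
            AlterationEvent(gene="EGFR", kind="amplification")  # no CN
        with pytest.raises(ValueError):
            AlterationEvent(gene="EGFR", kind="fusion")  # no partner

    def test_cohort_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(cases=[_case("A"), _case("A")])
        with pytest.raises(ValueError):
            Cohort(cases=[])


class TestFoldChange:
    def _controls(self, values):
        return pd.DataFrame(values)

    def test_identity_when_tumor_equals_control_mean(self):
        ctrl = self._controls({"s1": {"G1": 10.0, "G2": 50.0},
                               "s2": {"G1": 30.0, "G2": 150.0}})
        folds = compute_fold_change({"G1": 20.0, "G2": 100.0}, ctrl)
        assert folds == {"G1": 1.0, "G2": 1.0}

    def test_26_fold_overexpression(self):
        ctrl = self._controls({"s1": {"EGFR": 10.0}})
        assert compute_fold_change({"EGFR": 260.0}, ctrl)["EGFR"] == 26.0

    def test_zero_control_mean_yields_sentinel(self):
        ctrl = self._controls({"s1": {"G": 0.0}, "s2": {"G": 0.0}})
        assert math.isnan(compute_fold_change({"G": 100.0}, ctrl)["G"])

    def test_no_shared_genes_is_error(self):
        ctrl = self._controls({"s1": {"A": 1.0}})
        with pytest.raises(ValueError, match="shared"):
            compute_fold_change({"B": 5.0}, ctrl)

    def test_control_folds_center_on_one(self):
        """Geometric mean of any control sample vs the control mean is ~1."""
        rng = np.random.default_rng(42)
        ctrl = pd.DataFrame(rng.lognormal(5, 1, size=(50, 4)),
                            index=[f"G{i}" for i in range(50)])
        for col in ctrl.columns:
            folds = compute_fold_change(ctrl[col].to_dict(), ctrl)
            gm = float(np.exp(np.mean(np.log(list(folds.values())))))
            assert 0.7 < gm < 1.4


class TestReadCohort:
    def _write_minimal(self, d, clinical_rows, expr=None):
        clin = pd.DataFrame(clinical_rows, columns=[
            "case_id", "age", "sex", "ethnicity", "location",
            "survival_months", "event_observed", "idh1_r132h", "h3_k27m",
            "gfap", "p53", "ki67", "histologic_pattern", "mgmt_value"])
        clin.to_csv(d / "clinical.csv", index=False)
        for name, cols in (("variants.tsv", ["case_id", "gene", "kind",
                                             "pathogenicity", "activating",
                                             "germline", "hgvs"]),
                           ("cn.tsv", ["case_id", "gene", "copy_number",
                                       "loh"]),
                           ("fusions.tsv", ["case_id", "gene5", "gene3",
                                            "frame", "pathogenicity"])):
            pd.DataFrame(columns=cols).to_csv(d / name, sep="\t", index=False)
        if expr is None:
            expr = pd.DataFrame({"control:L1": {"EGFR": 100.0}})
            expr.index.name = "gene"
        expr.to_csv(d / "expression.tsv", sep="\t")
        pd.DataFrame({"gene": ["EGFR", "PTENP1", "RPS4Y1"],
                      "is_pseudogene": ["false", "true", "false"],
                      "chromosome": ["7", "9", "Y"]}).to_csv(
            d / "gene_annotation.tsv", sep="\t", index=False)
        return dict(
            variant_table=d / "variants.tsv", cn_table=d / "cn.tsv",
            fusion_table=d / "fusions.tsv",
            expression_matrix=d / "expression.tsv",
            clinical_table=d / "clinical.csv",
            gene_annotation=d / "gene_annotation.tsv")

    def _row(self, cid):
        return [cid, 60, "M", "White", "frontal", 12.0, "true", "negative",
                "negative", "high", "", "", "egfr", ""]

    def test_empty_molecular_tables_yield_empty_alterations(self, tmp_path):
        paths = self._write_minimal(
            tmp_path, [self._row("A"), self._row("B"), self._row("C")])
        cohort = read_cohort(**paths)
        assert len(cohort) == 3
        assert all(not c.alterations for c in cohort)
        assert all(not c.has_genomic_data for c in cohort)

    def test_count_filter_and_gene_exclusions(self, tmp_path):
        expr = pd.DataFrame({
            "control:L1": {"EGFR": 100.0, "LOWG": 100.0, "RPS4Y1": 100.0,
                           "PTENP1": 100.0},
            "A": {"EGFR": 2600.0, "LOWG": 499.0, "RPS4Y1": 5000.0,
                  "PTENP1": 5000.0},
        })
        expr.index.name = "gene"
        paths = self._write_minimal(tmp_path, [self._row("A")], expr=expr)
        cohort = read_cohort(**paths)
        profile = cohort.case("A").expression
        assert profile.fold_change == {"EGFR": 26.0}

    def test_unknown_case_id_in_molecular_table(self, tmp_path):
        paths = self._write_minimal(tmp_path, [self._row("A")])
        pd.DataFrame([{"case_id": "ZZZ", "gene": "PTEN",
                       "kind": "missense", "pathogenicity": "pathogenic",
                       "activating": "", "germline": "false",
                       "hgvs": ""}]).to_csv(
            paths["variant_table"], sep="\t", index=False)
        with pytest.raises(ValueError, match="ZZZ"):
            read_cohort(**paths)

    def test_malformed_enum_reports_row(self, tmp_path):
        rows = [self._row("A")]
        rows[0][2] = "Q"  # bad sex
        paths = self._write_minimal(tmp_path, rows)
        with pytest.raises(ValueError, match="row 2"):
            read_cohort(**paths)


class TestRoundTrip:
    def test_fixture_round_trips_exactly(self, fixture_cohort, fixture_dir):
        cohort, _ = fixture_cohort
        d = fixture_dir
        back = read_cohort(
            variant_table=d / "variants.tsv", cn_table=d / "cn.tsv",
            fusion_table=d / "fusions.tsv",
            expression_matrix=d / "expression.tsv",
            clinical_table=d / "clinical.csv",
            gene_annotation=d / "gene_annotation.tsv")
        assert back.case_ids == cohort.case_ids
        for c1 in cohort:
            c2 = back.case(c1.case_id)
            assert (c1.age, c1.sex, c1.ethnicity, c1.location,
                    c1.survival_months, c1.event_observed,
                    c1.histologic_pattern, c1.mgmt_value) == \
                   (c2.age, c2.sex, c2.ethnicity, c2.location,
                    c2.survival_months, c2.event_observed,
                    c2.histologic_pattern, c2.mgmt_value)
            key = lambda e: (e.gene, e.kind, e.pathogenicity, e.germline,
                             e.secondary_focus, e.copy_number)
            assert sorted(map(key, c1.alterations)) == \
                sorted(map(key, c2.alterations))
            e1 = c1.expression.fold_change if c1.expression else None
            e2 = c2.expression.fold_change if c2.expression else None
            assert e1 == e2
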
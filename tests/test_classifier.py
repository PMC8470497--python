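"""Subgroup classification: rule examples, partition and exclusivity
properties, robustness to non-driver events."""

import copy

import pytest

import gbmtyper as gt
from gbmtyper import _catalog as cat
from gbmtyper.classifier import classify_case, classify_cohort
from gbmtyper.cohort import (AlterationEvent, Case, ExpressionProfile,
                             IHCPanel)
from gbmtyper.simulate import GeneratorConfig, generate


def _case(events=(), folds=None, ihc=None, **kw):
    defaults = dict(age=60, sex="M", ethnicity="White", location="frontal",
                    survival_months=10.0, event_observed=True)
    defaults.update(kw)
    expression = (ExpressionProfile(fold_change=dict(folds))
                  if folds is not None else None)
    return Case(case_id="T1", ihc=ihc or IHCPanel(idh1_r132h="negative",
                                                  h3_k27m="negative"),
                alterations=list(events), expression=expression, **defaults)


def _amp(gene, cn):
    return AlterationEvent(gene=gene, kind="amplification",
                           pathogenicity="pathogenic", copy_number=cn)


def _act(gene, hgvs):
    return AlterationEvent(gene=gene, kind="missense",
                           pathogenicity="pathogenic", activating=True,
                           hgvs=hgvs)


class TestRuleExamples:
    def test_egfr_amplified_overexpressed_with_viii(self):
        viii = AlterationEvent(gene="EGFR", kind="splice_variant",
                               pathogenicity="pathogenic", activating=True,
                               hgvs="vIII")
        call = classify_case(_case([_amp("EGFR", 20.0), viii],
                                   folds={"EGFR": 26.0}))
        assert call.label == "G1_EGFR_amp"
        assert any(g == "EGFR" for g, _ in call.drivers)

    def test_egfr_mutation_without_amplification(self):
        call = classify_case(_case([_act("EGFR", "p.L861Q")],
                                   folds={"EGFR": 2.0}))
        assert call.label == "G1_EGFR_mut"

    def test_pdgfra_amplified_not_overexpressed_with_met_is_multirtk(self):
        events = [_amp("PDGFRA", 10.0),
                  AlterationEvent(gene="MET", kind="cn_gain",
                                  pathogenicity="unknown", copy_number=4.0)]
        call = classify_case(_case(events, folds={"PDGFRA": 1.2,
                                                  "MET": 40.0}))
        assert call.label == "G6_MultiRTK"

    def test_single_met_driver_routes_to_multirtk(self):
        call = classify_case(_case([_amp("MET", 12.0)], folds={"MET": 45.0}))
        assert call.label == "G6_MultiRTK"

    def test_kdr_kit_co_amplification_stays_pdgfra(self):
        """Adjacent 4q12 amplicon passengers do not create Multi-RTK."""
        events = [_amp("PDGFRA", 20.0), _amp("KDR", 9.0), _amp("KIT", 8.0)]
        call = classify_case(_case(events, folds={"PDGFRA": 17.0,
                                                  "KDR": 10.0, "KIT": 3.0}))
        assert call.label == "G5_PDGFRA"

    def test_nf1_biallelic_without_rtk_driver(self):
        events = [AlterationEvent(gene="NF1", kind="truncating",
                                  pathogenicity="pathogenic",
                                  hgvs="p.R1000*"),
                  AlterationEvent(gene="NF1", kind="loh",
                                  pathogenicity="unknown")]
        call = classify_case(_case(events))
        assert call.label == "G3_NF1"
        assert "monoallelic" not in call.flags

    def test_nf1_single_hit_flagged_monoallelic(self):
        events = [AlterationEvent(gene="NF1", kind="truncating",
                                  pathogenicity="pathogenic", hgvs="p.Q5*")]
        call = classify_case(_case(events))
        assert call.label == "G3_NF1"
        assert "monoallelic" in call.flags

    def test_braf_v600e(self):
        call = classify_case(_case([_act("BRAF", "p.V600E")]))
        assert call.label == "G4_RAF"

    def test_pten_tert_only_is_other(self):
        events = [AlterationEvent(gene="PTEN", kind="truncating",
                                  pathogenicity="pathogenic"),
                  AlterationEvent(gene="TERT", kind="promoter_mutation",
                                  pathogenicity="pathogenic")]
        assert classify_case(_case(events)).label == "G7_Other"

    def test_empty_case_is_other_with_warning(self):
        call = classify_case(_case([]))
        assert call.label == "G7_Other"
        assert "no_molecular_data" in call.flags

    def test_h3_k27m_triages_to_dmg(self):
        ihc = IHCPanel(h3_k27m="positive")
        assert classify_case(_case([], ihc=ihc)).label == "DMG"

    def test_idh_by_variant_without_ihc(self):
        ev = AlterationEvent(gene="IDH1", kind="missense",
                             pathogenicity="pathogenic", hgvs="p.R132C")
        assert classify_case(_case([ev])).label == "IDH"

    def test_contradictory_ihc_is_error(self):
        ihc = IHCPanel(idh1_r132h="positive", h3_k27m="positive")
        with pytest.raises(ValueError, match="contradictory"):
            classify_case(_case([], ihc=ihc))

    def test_amplification_with_unknown_expression_is_driver(self):
        """Genomic fallback: cases without transcriptomes are subgroupable."""
        call = classify_case(_case([_amp("EGFR", 30.0)], folds=None))
        assert call.label == "G1_EGFR_amp"

    def test_secondary_focus_events_ignored(self):
        secondary = AlterationEvent(gene="EGFR", kind="missense",
                                    pathogenicity="pathogenic",
                                    activating=True, secondary_focus=True)
        call = classify_case(_case([secondary]))
        assert call.label == "G7_Other"


class TestPartitionProperties:
    def test_fixture_partition_counts(self, fixture_cohort, fixture_calls):
        cohort, _ = fixture_cohort
        assert len(fixture_calls) == len(cohort)
        counts = gt.subgroup_counts(cohort, fixture_calls)
        expected = {
            "G1_EGFR_amp": 33, "G1_EGFR_mut": 3, "G5_PDGFRA": 7,
            "G6_MultiRTK": 7, "G2_FGFR3": 5, "G3_NF1": 15, "G4_RAF": 4,
            "G7_Other": 13, "IDH": 7,
        }
        assert dict(counts) == expected
        assert sum(counts[s] for s in cat.IDH_WT_SUBGROUPS) == 87

    def test_labels_match_generator_intent_across_seeds(self):
        for seed in range(12):
            cohort, truth = generate(GeneratorConfig(seed=seed))
            calls = classify_cohort(cohort)
            assert all(calls[cid].label == truth[cid] for cid in truth), seed

    def test_no_case_satisfies_two_single_driver_subgroups(self,
                                                           fixture_cohort):
        """Mutual exclusivity audit: per-case driver sets after locus
        collapse never span two of EGFR/FGFR3/PDGFRA."""
        from gbmtyper.calls import build_calls
        from gbmtyper.classifier import (DEFAULT_CONFIG,
                                         _collapse_locus_groups,
                                         _rtk_driver_evidence)
        cohort, _ = fixture_cohort
        for case in cohort:
            calls = build_calls(case)
            drivers = {}
            for gene in ("EGFR", "FGFR3", "PDGFRA"):
                if gene in calls:
                    ev = _rtk_driver_evidence(calls[gene], DEFAULT_CONFIG)
                    if ev:
                        drivers[gene] = ev
            drivers = _collapse_locus_groups(drivers, DEFAULT_CONFIG)
            assert len(drivers) <= 1, case.case_id

    def test_removing_nondriver_vus_never_changes_label(self, fixture_cohort):
        cohort, _ = fixture_cohort
        vus = AlterationEvent(gene="TTN", kind="missense",
                              pathogenicity="vus")
        for case in list(cohort)[::7]:
            with_vus = copy.deepcopy(case)
            with_vus.alterations.append(copy.deepcopy(vus))
            assert (classify_case(with_vus).label
                    == classify_case(case).label)
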
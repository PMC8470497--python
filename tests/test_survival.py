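"""Survival machinery against closed-form oracles, plus demographics."""

import numpy as np
import pytest

import gbmtyper as gt
from gbmtyper.simulate import sample_survival
from gbmtyper.survival import (demographic_summary, km_fit, km_median,
                               landmark_survival, logrank, pairwise_logrank,
                               pairwise_age_tests, tukey_fence_mask)


class TestKaplanMeier:
    def test_four_deaths_no_censoring_closed_form(self):
        curve = km_fit([(1, True), (2, True), (3, True), (4, True)])
        surv = {t: s for t, s in zip(curve.times, curve.survival)}
        assert surv[1] == pytest.approx(0.75)
        assert surv[2] == pytest.approx(0.5)
        assert surv[3] == pytest.approx(0.25)
        assert surv[4] == pytest.approx(0.0)

    def test_single_death(self):
        curve = km_fit([(5.0, True)])
        assert landmark_survival(curve, 5.0) == 0.0
        assert landmark_survival(curve, 4.9) == 1.0

    def test_all_censored_has_no_drops_and_no_median(self):
        curve = km_fit([(3, False), (7, False)])
        assert (curve.survival == 1.0).all()
        assert km_median(curve) is None

    def test_matches_one_minus_ecdf_without_censoring(self):
        """Oracle: with no censoring KM equals the empirical survival."""
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 200)
        curve = km_fit([(t, True) for t in times])
        for q in (2.0, 5.0, 10.0, 20.0):
            ecdf_surv = float(np.mean(times > q))
            assert landmark_survival(curve, q) == pytest.approx(ecdf_surv,
                                                                abs=1e-9)

    def test_exponential_recovery_large_n(self):
        rng = np.random.default_rng(123)
        lam = 1 / 12.0
        recs = [(t, True) for t in rng.exponential(1 / lam, 2000)]
        curve = km_fit(recs)
        t_med = np.log(2) / lam
        assert landmark_survival(curve, t_med) == pytest.approx(0.5,
                                                                abs=0.03)

    def test_median_at_exact_half_drop(self):
        # 2 deaths at t=12 out of 4 -> S(12)=0.5 exactly
        curve = km_fit([(12, True), (12, True), (20, True), (25, True)])
        assert km_median(curve) == 12.0

    def test_median_recovery_envelope(self):
        rng = np.random.default_rng(7)
        recs = [(t, True) for t in rng.exponential(20 / np.log(2), 500)]
        assert 18 <= km_median(km_fit(recs)) <= 22

    def test_landmark_conventions(self):
        curve = km_fit([(2, True), (4, True)])
        assert landmark_survival(curve, 0.0) == 1.0
        assert landmark_survival(curve, 100.0) == curve.survival[-1]
        with pytest.raises(ValueError):
            landmark_survival(curve, -1.0)


class TestLogrank:
    def test_identical_groups_not_significant(self):
        recs = [(t, True) for t in (1, 3, 5, 7, 9, 11)]
        cmp = logrank({"a": list(recs), "b": list(recs)})
        assert cmp.chi_square == pytest.approx(0.0, abs=1e-9)
        assert cmp.p_value > 0.99
        assert cmp.degrees_of_freedom == 1

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            logrank({"a": [(1, True)], "b": []})

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        a = [(t, True) for t in rng.exponential(5, 40)]
        b = [(t, True) for t in rng.exponential(14, 40)]
        c1 = logrank({"a": a, "b": b})
        c2 = logrank({"a": [(10 * t, e) for t, e in a],
                      "b": [(10 * t, e) for t, e in b]})
        assert c1.chi_square == pytest.approx(c2.chi_square, rel=1e-9)

    def test_power_medians_14_vs_5(self):
        """Exponential medians 14 vs 5 months, n=60/group: rejects at
        alpha=0.05 in over 80% of simulations."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            a = [(t, True) for t in rng.exponential(14 / np.log(2), 60)]
            b = [(t, True) for t in rng.exponential(5 / np.log(2), 60)]
            if logrank({"a": a, "b": b}).p_value < 0.05:
                hits += 1
        assert hits / n_sim > 0.80

    def test_generator_median_recovery(self):
        """Planted subgroup medians recovered within the simulation
        envelope at n=500."""
        rng = np.random.default_rng(11)
        meds = [km_median(km_fit(sample_survival(rng, 20.0, 500)))
                for _ in range(20)]
        assert 18 <= float(np.mean(meds)) <= 22

    def test_pairwise_has_holm_column(self):
        rng = np.random.default_rng(5)
        groups = {k: [(t, True) for t in rng.exponential(m / np.log(2), 30)]
                  for k, m in (("x", 5), ("y", 12), ("z", 20))}
        pw = pairwise_logrank(groups)
        assert len(pw) == 3
        assert (pw["p_holm"] >= pw["p_raw"] - 1e-12).all()


class TestDemographics:
    def test_tukey_fences(self):
        vals = np.array([10, 11, 12, 13, 14, 60.0])
        mask = tukey_fence_mask(vals)
        assert mask.tolist() == [True] * 5 + [False]

    def test_sex_ratio_and_age(self, fixture_cohort, fixture_calls):
        cohort, _ = fixture_cohort
        table = demographic_summary(cohort, fixture_calls)
        idh = table.loc["IDH"]
        assert idh["age_median"] == pytest.approx(42.0, abs=1.0)
        assert idh["age_mean"] == pytest.approx(42.0, abs=1.0)
        # Multi-RTK skews older than the EGFR-amplified subgroup
        assert (table.loc["G6_MultiRTK", "age_mean"]
                > table.loc["G1_EGFR_amp", "age_mean"] + 4)

    def test_ratio_arithmetic(self):
        # 11 males to 7 females prints as 1.57
        assert round(11 / 7, 2) == 1.57

    def test_pairwise_age_welch(self, fixture_cohort, fixture_calls):
        cohort, _ = fixture_cohort
        out = pairwise_age_tests(cohort, fixture_calls)
        tested = out[out["note"] == ""]
        assert (tested["p_raw"] > 0).all() and (tested["p_raw"] <= 1).all()
        idh_rows = tested[(tested.group_a == "IDH") | (tested.group_b == "IDH")]
        # the IDH subgroup is markedly younger than the large IDH-wt groups
        big = idh_rows[(idh_rows.group_a == "G1_EGFR_amp")
                       | (idh_rows.group_b == "G1_EGFR_amp")]
        assert (big["p_raw"] < 0.05).all()
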
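"""Screening pathway mechanics: schedules, tests, biopsies, and detection."""

from dataclasses import replace

import numpy as np
import pytest

from prostasim.errors import ConfigError
from prostasim.natural_history import DiseaseState, LifeHistory
from prostasim.screening import (
    ScreeningDraws,
    ScreeningProtocol,
    TestPanel,
    biopsy_result,
    invitation_ages,
    mpmri_result,
    run_screening,
    run_screening_cohort,
    total_biopsies,
)


def _panel(**kw):
    defaults = dict(psa_sens_by_state=np.full(18, 0.7))
    defaults.update(kw)
    return TestPanel(**defaults)


class TestSchedule:
    def test_triennial_55_to_64(self):
        assert invitation_ages(ScreeningProtocol(55, 64, 3)) == [55.0, 58.0, 61.0, 64.0]

    def test_single_round(self):
        assert invitation_ages(ScreeningProtocol(55, 55, 3)) == [55.0]

    def test_zero_interval_rejected(self):
        with pytest.raises(ConfigError, match="interval"):
            ScreeningProtocol(55, 64, 0)

    def test_out_of_range_attendance_rejected(self):
        with pytest.raises(ConfigError, match="protocol.attendance"):
            ScreeningProtocol(attendance=1.2)


class TestMpmri:
    def test_hgc_sensitivity_frequency(self, rng):
        panel = _panel()
        n = 30_000
        hits = sum(mpmri_result("HGC", panel, rng) for _ in range(n))
        se = np.sqrt(0.94 * 0.06 / n)
        assert abs(hits / n - 0.94) < 3 * se

    def test_lgc_sensitivity_frequency(self, rng):
        panel = _panel()
        n = 30_000
        hits = sum(mpmri_result("LGC", panel, rng) for _ in range(n))
        se = np.sqrt(0.74 * 0.26 / n)
        assert abs(hits / n - 0.74) < 3 * se

    def test_perfect_sensitivity_always_positive(self, rng):
        panel = _panel(mpmri_sens_hgc=1.0)
        assert all(mpmri_result("HGC", panel, rng) for _ in range(100))


class TestBiopsy:
    def test_mrigb_hgc_detection_and_misclassification(self, rng):
        panel = _panel()
        n = 30_000
        results = [biopsy_result("HGC", "MRIGB", panel, rng) for _ in range(n)]
        detected = [r for r in results if r[0]]
        frac = len(detected) / n
        se = np.sqrt(0.91 * 0.09 / n)
        assert abs(frac - 0.91) < 3 * se
        misrec = np.mean([r[1] == "LGC" for r in detected])
        se_m = np.sqrt(0.087 * 0.913 / len(detected))
        assert abs(misrec - 0.087) < 3 * se_m

    def test_trusgb_grade_independent_sensitivity(self, rng):
        panel = _panel()
        n = 30_000
        results = [biopsy_result("LGC", "TRUSGB", panel, rng) for _ in range(n)]
        frac = np.mean([r[0] for r in results])
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.90) < 3 * se
        assert all(r[1] == "LGC" for r in results if r[0])

    def test_zero_misclassification_preserves_grade(self, rng):
        panel = _panel(misclass_trusgb=0.0)
        for _ in range(200):
            detected, recorded = biopsy_result("HGC", "TRUSGB", panel, rng)
            if detected:
                assert recorded == "HGC"

    def test_unknown_modality_rejected(self, rng):
        with pytest.raises(ConfigError, match="modality"):
            biopsy_result("HGC", "SATURATION", _panel(), rng)


def _history(onset=50.0, latent_dx=66.0, oc=80.0, state=DiseaseState(0, 0, 0)):
    hist = LifeHistory(oc_death_age=oc, onset_age=onset)
    hist.trajectory = [(state, onset)]
    hist.latent_clinical_dx_age = latent_dx
    if latent_dx is not None and latent_dx < oc:
        hist.clinical_dx_age = latent_dx
        hist.state_at_clinical_dx = state
    return hist


class TestRunScreening:
    def test_perfect_cascade_detects_at_first_round(self, rng):
        """All sensitivities 1, full attendance/compliance, onset before 55,
        clinical diagnosis at 66: detection at 55 with lead time 11."""
        protocol = ScreeningProtocol(attendance=1.0, biopsy_compliance=1.0)
        panel = _panel(
            psa_sens_by_state=np.ones(18),
            mpmri_sens_hgc=1.0,
            mpmri_sens_lgc=1.0,
            trusgb_sens=1.0,
            mrigb_sens_hgc=1.0,
            mrigb_sens_lgc=1.0,
            misclass_trusgb=0.0,
            misclass_mrigb=0.0,
        )
        for pathway in ("classical", "mri"):
            rec = run_screening(_history(), protocol, pathway, panel, rng)
            assert rec.detection_age == 55.0
            assert rec.detection_round == 0
            assert rec.lead_time == pytest.approx(11.0)
            assert rec.overdiagnosed is False
            assert rec.recorded_grade == "LGC"  # entry state is Gleason < 7

    def test_cancer_free_man_gets_tests_but_no_detection(self, rng):
        protocol = ScreeningProtocol(attendance=1.0)
        hist = LifeHistory(oc_death_age=90.0)
        rec = run_screening(hist, protocol, "classical", _panel(), rng)
        assert rec.detection_age is None
        assert rec.n_psa_tests == 4  # all four rounds attended
        assert rec.n_biopsies_true_positive == 0

    def test_blocked_triage_counts_mpmri_but_never_detects(self, rng):
        protocol = ScreeningProtocol(attendance=1.0, biopsy_compliance=1.0)
        panel = _panel(
            psa_sens_by_state=np.ones(18), mpmri_sens_hgc=0.0, mpmri_sens_lgc=0.0
        )
        rec = run_screening(_history(), protocol, "mri", panel, rng)
        assert rec.detection_age is None
        assert rec.n_mpmri > 0

    def test_unknown_pathway_rejected(self, rng):
        with pytest.raises(ConfigError, match="pathway"):
            run_screening(_history(), ScreeningProtocol(), "fusion", _panel(), rng)

    def test_screening_does_not_mutate_disease_course(self, rng):
        hist = _history()
        before = (hist.onset_age, hist.latent_clinical_dx_age, list(hist.trajectory))
        run_screening(hist, ScreeningProtocol(attendance=1.0), "classical", _panel(), rng)
        assert (hist.onset_age, hist.latent_clinical_dx_age, list(hist.trajectory)) == before


class TestTotalBiopsies:
    @pytest.mark.parametrize("tp, ppv, expected", [(100, 1.0, 100), (100, 0.25, 400), (0, 0.3, 0)])
    def test_ppv_imputation(self, tp, ppv, expected):
        assert total_biopsies(tp, ppv) == pytest.approx(expected)

    def test_invalid_ppv_rejected(self):
        with pytest.raises(ConfigError, match="ppv"):
            total_biopsies(10, 0.0)


class TestCohortScreening:
    def _cohort(self, default_config, n=30_000, seed=5):
        from prostasim.engine import build_cohort

        return build_cohort(default_config, n, seed)

    def test_first_round_triage_only_removes_referrals(self, default_config):
        """At the first round (identical eligibility), the MRI pathway never
        biopsies more cancer men than the classical pathway under shared draws."""
        cohort = self._cohort(default_config)
        det_c = run_screening_cohort(
            cohort.disease,
            cohort.oc_death_age,
            default_config.protocol,
            "classical",
            default_config.tests,
            cohort.screen_draws,
        )
        det_m = run_screening_cohort(
            cohort.disease,
            cohort.oc_death_age,
            default_config.protocol,
            "mri",
            default_config.tests,
            cohort.screen_draws,
        )
        assert det_m.n_cancer_biopsy_round[0] <= det_c.n_cancer_biopsy_round[0]

    def test_mri_pathway_biopsies_fewer_per_1000(self, default_config):
        """With calibrated PPVs the MRI pathway biopsies fewer men (directional)."""
        from prostasim.engine import build_cohort, run_comparison

        for seed in (1, 2, 3):
            cohort = build_cohort(default_config, 30_000, seed)
            totals = run_comparison(cohort, default_config)
            assert totals["mri"].n_biopsies_total < totals["classical"].n_biopsies_total

    def test_equivalence_limit_pathways_identical(self, default_config):
        """With mpMRI forced positive and MRIGB set to TRUSGB characteristics,
        the two pathways produce identical detection outcomes."""
        cohort = self._cohort(default_config, n=20_000)
        p = default_config.tests
        panel_eq = replace(
            p,
            mpmri_sens_hgc=1.0,
            mpmri_sens_lgc=1.0,
            mpmri_pos_rate_nocancer=1.0,
            mrigb_sens_hgc=p.trusgb_sens,
            mrigb_sens_lgc=p.trusgb_sens,
            misclass_mrigb=p.misclass_trusgb,
        )
        args = (cohort.disease, cohort.oc_death_age, default_config.protocol)
        det_c = run_screening_cohort(*args, "classical", panel_eq, cohort.screen_draws)
        det_m = run_screening_cohort(*args, "mri", panel_eq, cohort.screen_draws)
        np.testing.assert_array_equal(det_c.det_age, det_m.det_age)
        np.testing.assert_array_equal(det_c.recorded_hgc, det_m.recorded_hgc)
        np.testing.assert_array_equal(det_c.overdiagnosed, det_m.overdiagnosed)

    def test_scalar_and_vector_detection_rates_agree(self, default_config):
        """Dual-route check: per-man loop and vectorized cohort give the same
        detection probability on the same configuration."""
        from prostasim.natural_history import simulate_disease

        cohort = self._cohort(default_config, n=40_000, seed=21)
        det = run_screening_cohort(
            cohort.disease,
            cohort.oc_death_age,
            default_config.protocol,
            "classical",
            default_config.tests,
            cohort.screen_draws,
        )
        invited = (cohort.oc_death_age > 55) & ~(cohort.disease.latent_dx_age <= 55)
        vec_rate = det.detected[invited].sum() / invited.sum()

        rng = np.random.default_rng(77)
        rng_oc = np.random.default_rng(78)
        from prostasim.population import sample_death_age

        hits = invited_s = 0
        for _ in range(6000):
            oc = sample_death_age(default_config.life_table, rng_oc)
            hist = simulate_disease(default_config.natural_history, oc, rng)
            if oc <= 55 or (hist.clinical_dx_age is not None and hist.clinical_dx_age <= 55):
                continue
            invited_s += 1
            rec = run_screening(
                hist, default_config.protocol, "classical", default_config.tests, rng
            )
            hits += rec.detection_age is not None
        scalar_rate = hits / invited_s
        se = np.sqrt(vec_rate * (1 - vec_rate) * (1 / invited_s + 1 / invited.sum()))
        assert abs(scalar_rate - vec_rate) < 4 * se
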
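"""PERT/truncated-normal sampling and cost-effectiveness statistics."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prostasim.errors import ConfigError
from prostasim.psa_engine import (
    PsaConfig,
    ceac,
    ci95,
    icer,
    inmb,
    one_way_sweep,
    quadrant_probs,
    run_probabilistic,
    sample_pert,
    sample_sens,
    summarize_cea,
)


class TestPert:
    def test_degenerate_interval_returns_mode(self, rng):
        assert sample_pert(5.0, 5.0, 5.0, rng) == 5.0

    def test_mpmri_cost_range_mean_and_bounds(self, rng):
        """(293, 345, 397): all draws in range, mean ≈ (min + 4·mode + max)/6."""
        n = 100_000
        draws = np.array([sample_pert(293, 345, 397, rng) for _ in range(n)])
        assert draws.min() >= 293 and draws.max() <= 397
        expected = (293 + 4 * 345 + 397) / 6  # 348.33
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_symmetric_case_is_unskewed(self, rng):
        draws = np.array([sample_pert(0, 1, 2, rng) for _ in range(50_000)])
        assert abs(draws.mean() - 1.0) < 0.01
        assert abs(stats.skew(draws)) < 0.05

    def test_inverted_bounds_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_pert(10, 5, 1, rng)


class TestTruncatedNormal:
    def test_draws_respect_unit_interval(self, rng):
        draws = np.array([sample_sens(0.94, 0.06, rng) for _ in range(20_000)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_vanishing_spread_collapses_to_mean(self, rng):
        assert sample_sens(0.5, 1e-9, rng) == pytest.approx(0.5, abs=1e-6)

    def test_mean_matches_analytic_truncated_moments(self, rng):
        n = 100_000
        draws = np.array([sample_sens(0.94, 0.06, rng) for _ in range(n)])
        a, b = (0 - 0.94) / 0.06, (1 - 0.94) / 0.06
        expected = stats.truncnorm.mean(a, b, loc=0.94, scale=0.06)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se


class TestCeaStatistics:
    def test_icer_constant_runs(self):
        dc, dq = np.full(10, 2000.0), np.full(10, 0.1)
        assert icer((dc, dq)) == pytest.approx(20_000.0)

    def test_icer_reported_scale(self):
        """Ratio of means at the published scale: 15,413 / 1.3574 ≈ 11,355."""
        assert icer((np.array([15_413.0]), np.array([1.3574]))) == pytest.approx(11_355, abs=1)

    def test_icer_homogeneity(self, rng):
        dc, dq = rng.normal(1000, 100, 50), rng.normal(1.0, 0.1, 50)
        assert icer((2 * dc, dq)) == pytest.approx(2 * icer((dc, dq)))

    def test_icer_undefined_for_zero_qaly_difference(self):
        assert np.isnan(icer((np.array([1.0, 2.0]), np.array([1.0, -1.0]))))

    def test_inmb_break_even(self):
        assert inmb((np.array([20_000.0]), np.array([1.0])), 20_000.0) == 0.0

    def test_inmb_at_zero_wtp_is_negative_mean_cost(self, rng):
        dc = rng.normal(500, 10, 20)
        assert inmb((dc, rng.normal(1, 0.1, 20)), 0.0) == pytest.approx(-dc.mean())

    @given(st.integers(0, 2**31 - 1), st.floats(1000, 100_000))
    @settings(max_examples=30, deadline=None)
    def test_inmb_positive_iff_icer_below_wtp(self, seed, wtp):
        """Algebraic identity on random run sets with positive mean ΔQALY."""
        g = np.random.default_rng(seed)
        dc = g.normal(2000, 500, 40)
        dq = np.abs(g.normal(1.0, 0.2, 40)) + 0.01
        assert (inmb((dc, dq), wtp) > 0) == (icer((dc, dq)) < wtp)

    def test_ceac_at_zero_wtp_counts_cost_saving_runs(self, rng):
        dc = rng.normal(0, 1000, 200)
        dq = rng.normal(1, 0.1, 200)
        [(_, p)] = ceac((dc, dq), [0.0])
        assert p == pytest.approx(np.mean(-dc > 0))

    def test_ceac_monotone_when_all_gains_positive(self, rng):
        dc = rng.normal(2000, 500, 100)
        dq = np.abs(rng.normal(1, 0.3, 100)) + 0.01
        probs = [p for _, p in ceac((dc, dq), np.linspace(0, 50_000, 51))]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_ceac_brute_force_recount(self, rng):
        dc = rng.normal(1000, 2000, 73)
        dq = rng.normal(0.5, 1.0, 73)
        for w, p in ceac((dc, dq), [0, 5_000, 20_000, 50_000]):
            manual = sum(1 for c, q in zip(dc, dq) if w * q - c > 0) / len(dc)
            assert p == pytest.approx(manual)

    def test_quadrants_all_northeast(self):
        assert quadrant_probs((np.ones(5), np.ones(5))) == (1.0, 0.0, 0.0, 0.0)

    def test_quadrants_one_per_cell(self):
        dq = np.array([1.0, 1.0, -1.0, -1.0])
        dc = np.array([1.0, -1.0, 1.0, -1.0])
        assert quadrant_probs((dc, dq)) == (0.25, 0.25, 0.25, 0.25)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_quadrants_partition_to_one(self, seed):
        g = np.random.default_rng(seed)
        probs = quadrant_probs((g.normal(size=30), g.normal(size=30)))
        assert sum(probs) == pytest.approx(1.0)

    def test_ci95_constant_values(self):
        m, lo, hi = ci95([3.0, 3.0, 3.0])
        assert (m, lo, hi) == (3.0, 3.0, 3.0)

    def test_ci95_hand_computation(self):
        """{1,2,3,4}: mean 2.5, half-width t(0.975,3)·sd/√4 = 3.1824·1.2910/2."""
        m, lo, hi = ci95([1, 2, 3, 4])
        assert m == pytest.approx(2.5)
        half = 3.182446 * np.std([1, 2, 3, 4], ddof=1) / 2
        assert hi - m == pytest.approx(half, abs=1e-4)
        assert lo <= m <= hi

    def test_ci95_needs_two_values(self):
        with pytest.raises(ConfigError):
            ci95([1.0])


class TestRunProbabilistic:
    def test_same_master_seed_reproduces_runs(self, default_config):
        cfg = PsaConfig(n_runs=4, n_men=5_000)
        a = run_probabilistic(default_config, cfg, seed=11)
        b = run_probabilistic(default_config, cfg, seed=11)
        assert a.equals(b)

    def test_zero_variance_distributions_collapse(self, default_config):
        """Near-degenerate sensitivity/cost distributions with a shared cohort:
        every replicate is identical."""
        costs = default_config.costs
        frozen = replace(
            costs,
            mpmri_min=costs.mpmri,
            mpmri_max=costs.mpmri,
            mrigb_min=costs.mrigb,
            mrigb_max=costs.mrigb,
            trusgb_min=costs.trusgb,
            trusgb_max=costs.trusgb,
        )
        cfg_model = replace(default_config, costs=frozen)
        cfg = PsaConfig(n_runs=3, n_men=5_000, sens_sd={k: 1e-12 for k in PsaConfig().sens_sd})
        df = run_probabilistic(cfg_model, cfg, seed=2)
        for col in ("delta_cost_total", "delta_qaly"):
            assert df[col].nunique() == 1

    def test_equivalent_pathways_give_exactly_zero_deltas(self, default_config):
        """MRI parameters forced equal to classical (and mpMRI free): the
        incremental outcomes are exactly zero under common random numbers."""
        p = default_config.tests
        panel_eq = replace(
            p,
            mpmri_sens_hgc=1.0,
            mpmri_sens_lgc=1.0,
            mpmri_pos_rate_nocancer=1.0,
            mrigb_sens_hgc=p.trusgb_sens,
            mrigb_sens_lgc=p.trusgb_sens,
            misclass_mrigb=p.misclass_trusgb,
            ppv_mri=p.ppv_classical,
        )
        costs_eq = replace(default_config.costs, mpmri=0.0, mpmri_min=0.0, mpmri_max=0.0)
        # MRIGB priced as TRUSGB so the biopsy ledger matches too
        costs_eq = replace(
            costs_eq,
            mrigb=costs_eq.trusgb,
            mrigb_min=costs_eq.trusgb_min,
            mrigb_max=costs_eq.trusgb_max,
        )
        from prostasim.accounting import UtilityTable

        entries = dict(default_config.utilities.entries)
        entries["biopsy_mrigb"] = dict(entries["biopsy_trusgb"])  # same disutility too
        util_eq = UtilityTable(entries=entries, mrigb_half_loss=False)
        cfg_model = replace(default_config, tests=panel_eq, costs=costs_eq, utilities=util_eq)
        from prostasim.engine import build_cohort, comparison_nets, run_comparison

        cohort = build_cohort(cfg_model, 10_000, 23)
        nets = comparison_nets(run_comparison(cohort, cfg_model))
        assert nets["mri"].cost_total == pytest.approx(nets["classical"].cost_total, abs=1e-6)
        assert nets["mri"].qaly_disc == pytest.approx(nets["classical"].qaly_disc, abs=1e-9)

    def test_summary_consistency(self, default_config):
        cfg = PsaConfig(n_runs=6, n_men=5_000)
        df = run_probabilistic(default_config, cfg, seed=31)
        res = summarize_cea(df, wtp=20_000.0)
        assert res.icer == pytest.approx(
            df["delta_cost_total"].mean() / df["delta_qaly"].mean()
        )
        assert sum(res.quadrant_probs) == pytest.approx(1.0)
        assert 0.0 <= res.prob_cost_effective_at_wtp <= 1.0


class TestOneWaySweep:
    def test_parameter_with_no_differential_effect_leaves_icer_unchanged(self, default_config):
        """The willingness-to-pay threshold never enters the ICER."""
        lo, hi = one_way_sweep(default_config, "wtp", 10_000.0, 30_000.0, n_men=4_000, seed=3)
        assert lo == hi

    def test_higher_palliative_costs_lower_the_icer(self, default_config):
        """Screening averts palliative care, and the MRI pathway averts more of
        it, so pricier advanced-disease care improves the ICER."""
        lo, hi = one_way_sweep(
            default_config, "costs.palliative_terminal", 20_000.0, 32_000.0, n_men=60_000, seed=2
        )
        assert hi < lo

    def test_mpmri_cost_moves_only_the_screening_component(self, default_config):
        from prostasim.engine import build_cohort, comparison_nets, run_comparison

        cohort = build_cohort(default_config, 10_000, 7)
        low = replace(default_config.costs, mpmri=345 * 0.85, mpmri_min=0.0)
        high = replace(default_config.costs, mpmri=345 * 1.15, mpmri_max=345 * 1.15)
        nets_lo = comparison_nets(run_comparison(cohort, default_config, costs=low))
        nets_hi = comparison_nets(run_comparison(cohort, default_config, costs=high))
        assert nets_hi["mri"].cost_screening > nets_lo["mri"].cost_screening
        assert nets_hi["mri"].cost_diagnosis_treatment == pytest.approx(
            nets_lo["mri"].cost_diagnosis_treatment
        )
        assert nets_hi["mri"].cost_palliative == pytest.approx(nets_lo["mri"].cost_palliative)
        assert nets_hi["classical"].cost_screening == pytest.approx(
            nets_lo["classical"].cost_screening
        )

    def test_unknown_parameter_path_rejected(self, default_config):
        with pytest.raises(ConfigError, match="parameter path"):
            one_way_sweep(default_config, "costs.nonexistent", 0, 1, n_men=1_000)
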
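"""Cohort simulation engine.

Builds a seeded cohort once — other-cause death ages, the latent disease
course, and *all* the uniform random numbers screening and survival will ever
need — and then evaluates any strategy (no screening, classical pathway, MRI
pathway) or test-parameter draw against those same numbers. This
common-random-numbers discipline is what makes paired comparisons exact: the
no-screening twin shares the disease course, a screen-detected man who is not
cured dies exactly when his twin does, and probabilistic-sensitivity runs
differ only through the parameters, not through fresh Monte-Carlo noise.

Named substreams (other-cause mortality, disease course, screening tests,
survival) are spawned from one master seed, so every result is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accounting import StrategyOutcome, StrategyTotals, net_vs_no_screening, tally_strategy
from .natural_history import DiseaseArrays, simulate_disease_cohort, state_spread, state_t
from .population import sample_death_age
from .screening import DetectionArrays, ScreeningDraws, invitation_ages, run_screening_cohort
from .survival import TREATMENTS, age_band_index, baseline_cell, cure_probability, weibull_time

__all__ = ["SimulatedCohort", "build_cohort", "run_comparison", "strategy_outcome"]


@dataclass
class SimulatedCohort:
    """A cohort's disease courses plus every pre-drawn uniform."""

    n: int
    seed: int
    oc_death_age: np.ndarray
    disease: DiseaseArrays
    screen_draws: ScreeningDraws
    u_treat: np.ndarray
    u_fate: np.ndarray
    u_surv: np.ndarray
    u_cure: np.ndarray
    _baseline_cache: dict = field(default_factory=dict, repr=False)


def build_cohort(config, n: int, seed: int) -> SimulatedCohort:
    """Simulate natural histories and pre-draw all event uniforms for n men."""
    ss = np.random.SeedSequence(seed)
    s_oc, s_course, s_screen, s_surv = ss.spawn(4)
    oc = sample_death_age(config.life_table, np.random.default_rng(s_oc), size=n)
    disease = simulate_disease_cohort(
        config.natural_history, oc, np.random.default_rng(s_course)
    )
    n_rounds = len(invitation_ages(config.protocol))
    draws = ScreeningDraws.draw(n, n_rounds, np.random.default_rng(s_screen))
    rng_surv = np.random.default_rng(s_surv)
    u_treat = rng_surv.uniform(size=n)
    u_fate = rng_surv.uniform(size=n)
    u_surv = rng_surv.uniform(size=n)
    u_cure = rng_surv.uniform(size=n)
    return SimulatedCohort(
        n=n,
        seed=seed,
        oc_death_age=oc,
        disease=disease,
        screen_draws=draws,
        u_treat=u_treat,
        u_fate=u_fate,
        u_surv=u_surv,
        u_cure=u_cure,
    )


def _assign_treatment_vec(config, dx_age, t_stage, recorded_hgc, spread, u_treat):
    """Vectorized treatment draw; distant disease is managed conservatively (WW)."""
    band = age_band_index(dx_age)
    probs = config.treatment.cell_probs(band, t_stage, recorded_hgc)  # (m, 3)
    cum = np.cumsum(probs, axis=1)
    code = (u_treat[:, None] >= cum).sum(axis=1)
    code = np.minimum(code, len(TREATMENTS) - 1)
    code[spread == 1] = 2  # WW
    return code.astype(np.int8)


def _baseline_outcomes(cohort: SimulatedCohort, config):
    """Unscreened course: clinical diagnoses, treatments, and death ages.

    Cached per (cohort, config identity): survival/treatment parameters are not
    varied inside the probabilistic analysis, so this is computed once.
    """
    # identity-keyed cache holding strong references (no id-reuse hazard)
    cache = cohort._baseline_cache.setdefault("baseline", [])
    for survival, treatment, tests, cached in cache:
        if (
            survival is config.survival
            and treatment is config.treatment
            and tests is config.tests
        ):
            return cached

    d = cohort.disease
    oc = cohort.oc_death_age
    clin = d.latent_dx_age < oc
    dx_age = np.where(clin, d.latent_dx_age, np.nan)
    state = np.where(clin, d.dx_state, 0)
    spread = state_spread(state)
    tstage = state_t(state)
    hgc = config.tests.grade_class_of_state(state)

    treatment = np.full(cohort.n, -1, dtype=np.int8)
    treatment[clin] = _assign_treatment_vec(
        config, dx_age[clin], tstage[clin], hgc[clin], spread[clin], cohort.u_treat[clin]
    )

    p, shape, scale = baseline_cell(config.survival, spread, hgc)
    p = p * config.survival.band_factors[age_band_index(np.where(clin, dx_age, 60.0))]
    rr = config.survival.rr_for(np.where(treatment >= 0, treatment, 2))
    p = np.where(spread == 0, p * rr, p)
    p = np.minimum(p, 1.0)

    fatal = clin & (cohort.u_fate < p)
    surv_t = weibull_time(cohort.u_surv, shape, scale)
    pc_death_age = np.where(fatal, dx_age + surv_t, np.inf)
    death = np.minimum(oc, pc_death_age)
    pc_death = fatal & (pc_death_age < oc)

    base = {
        "clin": clin,
        "dx_age": dx_age,
        "spread": spread,
        "tstage": tstage,
        "hgc": hgc,
        "treatment": treatment,
        "pc_death_age": pc_death_age,
        "death": death,
        "pc_death": pc_death,
    }
    cache.append((config.survival, config.treatment, config.tests, base))
    return base


def _invited_mask(cohort: SimulatedCohort, config):
    start = config.protocol.start_age
    d = cohort.disease
    return (cohort.oc_death_age > start) & ~(d.latent_dx_age <= start)


def strategy_outcome(
    cohort: SimulatedCohort,
    config,
    pathway: str,
    panel=None,
    fp_psa_count: float = 0.0,
) -> StrategyOutcome:
    """Resolve one strategy over the cohort into a costable outcome.

    Per-man arrays are restricted to the *invited* men (alive and undiagnosed
    at the first invitation age): everyone else has identical outcomes in every
    strategy, so they cancel in all comparisons, and the restriction guarantees
    that no dated event precedes the discounting reference age.
    """
    panel = panel if panel is not None else config.tests
    base = _baseline_outcomes(cohort, config)
    invited = _invited_mask(cohort, config)
    round_ages = np.asarray(invitation_ages(config.protocol))

    if pathway == "none":
        zeros = np.zeros(len(round_ages))
        return StrategyOutcome(
            pathway="none",
            n=int(invited.sum()),
            n_invited=int(invited.sum()),
            round_ages=round_ages,
            n_psa_tests_round=zeros,
            n_mpmri_cancer_round=zeros.copy(),
            n_cancer_biopsy_round=zeros.copy(),
            dx_age=base["dx_age"][invited],
            dx_is_screen=np.zeros(int(invited.sum()), dtype=bool),
            dx_distant=(base["spread"] == 1)[invited],
            treatment=base["treatment"][invited],
            death_age=base["death"][invited],
            pc_death=base["pc_death"][invited],
        )

    det: DetectionArrays = run_screening_cohort(
        cohort.disease, cohort.oc_death_age, config.protocol, pathway, panel, cohort.screen_draws
    )
    detected = det.detected

    # Treatment at screen detection: recorded grade, state and age at detection.
    det_spread = state_spread(np.where(detected, det.det_state, 0))
    det_t = state_t(np.where(detected, det.det_state, 0))
    tx_screen = _assign_treatment_vec(
        config,
        np.where(detected, det.det_age, 60.0),
        det_t,
        det.recorded_hgc,
        det_spread,
        cohort.u_treat,
    )

    # Cure: local-regional at detection, curatively treated, twin clinically
    # diagnosed (overdiagnosed cancers have nothing to cure).
    curative = detected & (det_spread == 0) & (tx_screen < 2)
    eligible = curative & ~det.overdiagnosed
    cure_p = np.zeros(cohort.n)
    cure_p[eligible] = cure_probability(det.lead_time[eligible], config.survival)
    cured = eligible & (cohort.u_cure < cure_p)

    # Death: baseline everywhere, overridden for screen detections.
    pc_death_age = base["pc_death_age"].copy()
    pc_death_age[cured | (detected & det.overdiagnosed)] = np.inf
    death = np.minimum(cohort.oc_death_age, pc_death_age)
    pc_death = np.isfinite(pc_death_age) & (pc_death_age < cohort.oc_death_age)

    # Diagnoses: screen detections replace the twin's clinical diagnosis; men
    # never screen-detected keep their clinical course.
    dx_age = np.where(detected, det.det_age, base["dx_age"])
    treatment = np.where(detected, tx_screen, base["treatment"]).astype(np.int8)
    dx_distant = np.where(detected, det_spread == 1, base["spread"] == 1)

    lead = det.lead_time[np.isfinite(det.lead_time)]
    return StrategyOutcome(
        pathway=pathway,
        n=int(invited.sum()),
        n_invited=int(invited.sum()),
        round_ages=round_ages,
        n_psa_tests_round=det.n_psa_tests_round,
        n_mpmri_cancer_round=det.n_mpmri_cancer_round,
        n_cancer_biopsy_round=det.n_cancer_biopsy_round,
        dx_age=dx_age[invited],
        dx_is_screen=detected[invited],
        dx_distant=dx_distant[invited],
        treatment=treatment[invited],
        death_age=death[invited],
        pc_death=pc_death[invited],
        n_overdiagnosed=int(det.overdiagnosed.sum()),
        mean_lead_time=float(lead.mean()) if lead.size else float("nan"),
        fp_psa_count=fp_psa_count,
    )


def run_comparison(
    cohort: SimulatedCohort, config, panel=None, costs=None
) -> dict[str, StrategyTotals]:
    """Totals for no-screening, classical, and MRI strategies on one cohort.

    The MRI arm's mpMRI volume includes cancer-free PSA-positive men imputed
    through the classical arm's biopsy-PPV identity: every biopsied man was
    PSA-positive and compliant, so cancer-free PSA positives =
    (total classical biopsies − simulated cancer biopsies) / compliance.
    """
    panel = panel if panel is not None else config.tests
    costs = costs if costs is not None else config.costs
    ref = config.protocol.start_age
    rate = config.discount_rate

    out_none = strategy_outcome(cohort, config, "none", panel)
    out_classical = strategy_outcome(cohort, config, "classical", panel)

    b_classical = out_classical.n_screen_detected / panel.ppv_classical
    sim_cancer_biopsies = float(out_classical.n_cancer_biopsy_round.sum())
    fp_psa = max(b_classical - sim_cancer_biopsies, 0.0) / config.protocol.biopsy_compliance

    out_mri = strategy_outcome(cohort, config, "mri", panel, fp_psa_count=fp_psa)

    tally = lambda o: tally_strategy(o, costs, config.utilities, panel, ref, rate)  # noqa: E731
    return {"none": tally(out_none), "classical": tally(out_classical), "mri": tally(out_mri)}


def comparison_nets(totals: dict[str, StrategyTotals]):
    """Per-1000 net outcomes of each screening strategy vs no screening."""
    return {
        "classical": net_vs_no_screening(totals["classical"], totals["none"]),
        "mri": net_vs_no_screening(totals["mri"], totals["none"]),
    }
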
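"""Discounted costs, life-years and QALYs, and per-1000-invited net outcomes.

Costs fall in three categories that add up exactly to the total:

* **screening** — PSA tests, mpMRI scans (MRI pathway), and biopsies. Total
  biopsy volume is imputed from detected cancers through the pathway's biopsy
  PPV; the imputed negative biopsies carry the modality's unit cost and (by
  default) the biopsy disutility.
* **diagnosis & treatment** — diagnostic work-up, primary treatment by
  modality, and annual follow-up while alive.
* **palliative** — terminal/palliative care charged once per prostate-cancer
  death.

Both costs and effects are discounted at 3.5%/year by default, continuously in
exact event ages, relative to the age of first invitation (any fixed reference
cancels in incremental comparisons). Quality-of-life losses follow the product
rule: men in a state × (1 − utility) × duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError

__all__ = [
    "CostTable",
    "UtilityTable",
    "StrategyOutcome",
    "StrategyTotals",
    "NetTotals",
    "discount",
    "discounted_life_years",
    "qaly_loss",
    "tally_strategy",
    "net_vs_no_screening",
]


def discount(value, years_from_reference, rate: float):
    """Present value at the reference time: value / (1+rate)**years."""
    if rate < 0:
        raise ConfigError(f"discount rate must be >= 0, got {rate}")
    return value / (1.0 + rate) ** np.asarray(years_from_reference)


def discounted_life_years(death_age, reference_age: float, rate: float):
    """Discounted years lived from the reference age on: ∫_0^(T-ref) (1+r)^-t dt.

    Years lived before the reference age are identical across strategies for
    the same cohort and are deliberately excluded from the discounted total
    (they cancel in every incremental comparison); the undiscounted total
    keeps the full lifespan.
    """
    t = np.maximum(np.asarray(death_age, dtype=float) - reference_age, 0.0)
    if rate == 0.0:
        return t
    return (1.0 - (1.0 + rate) ** (-t)) / np.log1p(rate)


def qaly_loss(n_men, utility: float, duration: float):
    """QALYs lost: n × (1 − utility) × duration."""
    if not (0.0 <= utility <= 1.0):
        raise ConfigError(f"utility must be in [0,1], got {utility}")
    if duration <= 0:
        raise ConfigError(f"duration must be > 0, got {duration}")
    return np.asarray(n_men) * (1.0 - utility) * duration


@dataclass
class CostTable:
    """Unit costs in €. mpMRI/MRIGB/TRUSGB carry (min, mode, max) PERT ranges."""

    psa_test: float = 30.0
    mpmri: float = 345.0
    mpmri_min: float = 293.0
    mpmri_max: float = 397.0
    mrigb: float = 800.0
    mrigb_min: float = 680.0
    mrigb_max: float = 920.0
    trusgb: float = 247.0
    trusgb_min: float = 210.0
    trusgb_max: float = 284.0
    diagnosis_workup: float = 1200.0
    tx_rp: float = 9000.0
    tx_rt: float = 8500.0
    tx_ww: float = 1500.0
    follow_up_annual: float = 350.0
    follow_up_years: int = 10
    palliative_terminal: float = 26000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ConfigError(f"costs.{f.name} must be >= 0, got {v}")
        for base in ("mpmri", "mrigb", "trusgb"):
            lo, mode, hi = (
                getattr(self, f"{base}_min"),
                getattr(self, base),
                getattr(self, f"{base}_max"),
            )
            if not (lo <= mode <= hi):
                raise ConfigError(f"costs.{base}: require min <= mode <= max, got {lo},{mode},{hi}")

    def treatment_cost(self, code) -> np.ndarray:
        """€ by treatment code (0 RP, 1 RT, 2 WW)."""
        return np.array([self.tx_rp, self.tx_rt, self.tx_ww])[np.asarray(code)]


@dataclass
class UtilityTable:
    """Utility value and duration (years) per transient health state.

    ``entries`` maps state name -> {"utility": u, "duration": d}. Unless
    ``mrigb_half_loss`` is overridden, the MRI-guided-biopsy loss is pinned to
    half the TRUSGB loss (fewer complications from targeted biopsies).
    """

    entries: dict[str, dict[str, float]]
    mrigb_half_loss: bool = True
    negative_biopsy_disutility: bool = True  # imputed negative biopsies carry the loss too

    REQUIRED = (
        "screening_visit",
        "biopsy_trusgb",
        "biopsy_mrigb",
        "diagnosis",
        "tx_rp",
        "tx_rt",
        "tx_ww",
        "post_treatment",
        "palliative",
        "terminal",
    )

    def __post_init__(self) -> None:
        import copy

        self.entries = copy.deepcopy(self.entries)  # own the table; the half-loss rule edits it
        for name in self.REQUIRED:
            if name not in self.entries:
                raise ConfigError(f"utilities: missing entry {name!r}")
            cell = self.entries[name]
            u, d = float(cell["utility"]), float(cell["duration"])
            if not (0.0 <= u <= 1.0):
                raise ConfigError(f"utilities.{name}.utility out of [0,1]: {u}")
            if d <= 0:
                raise ConfigError(f"utilities.{name}.duration must be > 0: {d}")
        if self.mrigb_half_loss:
            tr = self.loss("biopsy_trusgb")
            mr = self.entries["biopsy_mrigb"]
            # pin the MRIGB event loss to half the TRUSGB event loss
            mr["utility"] = 1.0 - 0.5 * tr / float(mr["duration"])

    def loss(self, name: str) -> float:
        """QALY loss per man for one episode of the state."""
        cell = self.entries[name]
        return float(qaly_loss(1, float(cell["utility"]), float(cell["duration"])))

    def treatment_loss(self, code) -> np.ndarray:
        losses = np.array([self.loss("tx_rp"), self.loss("tx_rt"), self.loss("tx_ww")])
        return losses[np.asarray(code)]


@dataclass
class StrategyOutcome:
    """Completed cohort simulation for one strategy, ready to be costed.

    All per-man arrays have length n; "absent" is NaN (ages) or -1 (codes).
    ``fp_psa_count`` is the imputed number of cancer-free PSA-positive men
    (classical-arm PPV bridge) who receive an mpMRI in the MRI pathway.
    """

    pathway: str  # "none", "classical", "mri"
    n: int
    n_invited: int
    round_ages: np.ndarray
    n_psa_tests_round: np.ndarray
    n_mpmri_cancer_round: np.ndarray
    n_cancer_biopsy_round: np.ndarray
    dx_age: np.ndarray  # diagnosis age per man (screen or clinical), NaN if never
    dx_is_screen: np.ndarray  # bool
    dx_distant: np.ndarray  # bool: distant at diagnosis
    treatment: np.ndarray  # int code 0/1/2, -1 if undiagnosed
    death_age: np.ndarray
    pc_death: np.ndarray  # bool
    n_overdiagnosed: int = 0
    mean_lead_time: float = float("nan")
    fp_psa_count: float = 0.0

    @property
    def n_screen_detected(self) -> int:
        return int(self.dx_is_screen.sum())

    @property
    def n_clinical_dx(self) -> int:
        return int((np.isfinite(self.dx_age) & ~self.dx_is_screen).sum())


@dataclass
class StrategyTotals:
    """Discounted cohort totals by category, with exact additivity."""

    pathway: str
    n_invited: int
    cost_screening: float
    cost_diagnosis_treatment: float
    cost_palliative: float
    ly_undisc: float
    ly_disc: float
    qaly_disc: float
    n_biopsies_total: float
    n_psa_tests: float
    n_mpmri: float
    n_screen_detected: int
    n_clinical_dx: int
    n_overdiagnosed: int
    n_pc_deaths: int
    mean_lead_time: float

    @property
    def cost_total(self) -> float:
        return self.cost_screening + self.cost_diagnosis_treatment + self.cost_palliative


@dataclass
class NetTotals:
    """Strategy minus no screening, scaled per 1000 invited men."""

    pathway: str
    cost_screening: float
    cost_diagnosis_treatment: float
    cost_palliative: float
    ly_undisc: float
    ly_disc: float
    qaly_disc: float
    n_biopsies_total: float
    n_screen_detected: float
    n_overdiagnosed: float
    n_pc_deaths: float

    @property
    def cost_total(self) -> float:
        return self.cost_screening + self.cost_diagnosis_treatment + self.cost_palliative


def _round_df(round_ages, reference_age, rate):
    return 1.0 / (1.0 + rate) ** (np.asarray(round_ages) - reference_age)


def tally_strategy(
    outcome: StrategyOutcome,
    costs: CostTable,
    utilities: UtilityTable,
    panel,
    reference_age: float,
    rate: float,
) -> StrategyTotals:
    """Convert a completed strategy simulation into discounted totals.

    All dated events must fall at or after the reference age (the outcome is
    restricted to the invited cohort upstream, which guarantees this).
    """
    if np.any(outcome.dx_age[np.isfinite(outcome.dx_age)] < reference_age - 1e-9):
        raise ConfigError("tally: diagnosis event precedes the discounting reference age")
    df_round = _round_df(outcome.round_ages, reference_age, rate)
    weights = outcome.n_psa_tests_round
    avg_df = float(np.average(df_round, weights=weights)) if weights.sum() > 0 else 1.0

    modality_cost = {"classical": costs.trusgb, "mri": costs.mrigb, "none": 0.0}[outcome.pathway]
    biopsy_loss = {
        "classical": utilities.loss("biopsy_trusgb"),
        "mri": utilities.loss("biopsy_mrigb"),
        "none": 0.0,
    }[outcome.pathway]

    n_screen_det = outcome.n_screen_detected
    if outcome.pathway == "none":
        ppv = 1.0
        n_biopsies_total = 0.0
    else:
        ppv = panel.ppv_classical if outcome.pathway == "classical" else panel.ppv_mri
        n_biopsies_total = n_screen_det / ppv

    cancer_biopsies = outcome.n_cancer_biopsy_round
    extra_biopsies = max(n_biopsies_total - float(cancer_biopsies.sum()), 0.0)

    # --- screening category ---
    cost_screening = float(np.sum(outcome.n_psa_tests_round * df_round) * costs.psa_test)
    cost_screening += float(np.sum(cancer_biopsies * df_round) * modality_cost)
    cost_screening += extra_biopsies * avg_df * modality_cost
    n_mpmri = float(outcome.n_mpmri_cancer_round.sum()) + outcome.fp_psa_count
    if outcome.pathway == "mri":
        cost_screening += float(np.sum(outcome.n_mpmri_cancer_round * df_round) * costs.mpmri)
        cost_screening += outcome.fp_psa_count * avg_df * costs.mpmri

    # --- diagnosis & treatment category ---
    diagnosed = np.isfinite(outcome.dx_age)
    dx_age = outcome.dx_age[diagnosed]
    df_dx = 1.0 / (1.0 + rate) ** (dx_age - reference_age)
    tx = outcome.treatment[diagnosed]
    cost_dxtx = float(np.sum((costs.diagnosis_workup + costs.treatment_cost(tx)) * df_dx))
    death_dx = outcome.death_age[diagnosed]
    for k in range(1, int(costs.follow_up_years) + 1):
        at = dx_age + k
        alive = at < death_dx
        cost_dxtx += float(
            np.sum(costs.follow_up_annual / (1.0 + rate) ** (at[alive] - reference_age))
        )

    # --- palliative category ---
    pc = outcome.pc_death
    df_death_pc = 1.0 / (1.0 + rate) ** (outcome.death_age[pc] - reference_age)
    cost_palliative = float(np.sum(costs.palliative_terminal * df_death_pc))

    # --- life years ---
    ly_undisc = float(np.sum(outcome.death_age))
    ly_disc = float(np.sum(discounted_life_years(outcome.death_age, reference_age, rate)))

    # --- QALY losses ---
    loss = 0.0
    loss += float(np.sum(outcome.n_psa_tests_round * df_round) * utilities.loss("screening_visit"))
    loss += float(np.sum(cancer_biopsies * df_round) * biopsy_loss)
    if utilities.negative_biopsy_disutility:
        loss += extra_biopsies * avg_df * biopsy_loss
    loss += float(np.sum((utilities.loss("diagnosis") + utilities.treatment_loss(tx)) * df_dx))
    loss += float(np.sum(utilities.loss("post_treatment") * df_dx))
    pall_loss = utilities.loss("palliative") + utilities.loss("terminal")
    loss += float(np.sum(pall_loss * df_death_pc))
    qaly_disc = ly_disc - loss

    return StrategyTotals(
        pathway=outcome.pathway,
        n_invited=outcome.n_invited,
        cost_screening=cost_screening,
        cost_diagnosis_treatment=cost_dxtx,
        cost_palliative=cost_palliative,
        ly_undisc=ly_undisc,
        ly_disc=ly_disc,
        qaly_disc=qaly_disc,
        n_biopsies_total=n_biopsies_total,
        n_psa_tests=float(outcome.n_psa_tests_round.sum()),
        n_mpmri=n_mpmri if outcome.pathway == "mri" else 0.0,
        n_screen_detected=n_screen_det,
        n_clinical_dx=outcome.n_clinical_dx,
        n_overdiagnosed=outcome.n_overdiagnosed,
        n_pc_deaths=int(pc.sum()),
        mean_lead_time=outcome.mean_lead_time,
    )


def net_vs_no_screening(strategy: StrategyTotals, baseline: StrategyTotals) -> NetTotals:
    """Componentwise (strategy − no screening), per 1000 invited men."""
    if strategy.n_invited != baseline.n_invited:
        raise ConfigError(
            f"cohort mismatch: {strategy.n_invited} vs {baseline.n_invited} invited men"
        )
    scale = 1000.0 / strategy.n_invited
    return NetTotals(
        pathway=strategy.pathway,
        cost_screening=(strategy.cost_screening - baseline.cost_screening) * scale,
        cost_diagnosis_treatment=(
            strategy.cost_diagnosis_treatment - baseline.cost_diagnosis_treatment
        )
        * scale,
        cost_palliative=(strategy.cost_palliative - baseline.cost_palliative) * scale,
        ly_undisc=(strategy.ly_undisc - baseline.ly_undisc) * scale,
        ly_disc=(strategy.ly_disc - baseline.ly_disc) * scale,
        qaly_disc=(strategy.qaly_disc - baseline.qaly_disc) * scale,
        n_biopsies_total=(strategy.n_biopsies_total - baseline.n_biopsies_total) * scale,
        n_screen_detected=(strategy.n_screen_detected - baseline.n_screen_detected) * scale,
        n_overdiagnosed=(strategy.n_overdiagnosed - baseline.n_overdiagnosed) * scale,
        n_pc_deaths=(strategy.n_pc_deaths - baseline.n_pc_deaths) * scale,
    )
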
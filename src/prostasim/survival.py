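"""Post-diagnosis survival, treatment assignment, and lead-time-dependent cure.

Baseline prostate-cancer survival (no screening, conservative management) is a
per-cell mixture: with a cell-specific probability the cancer is eventually
fatal, in which case the time from clinical diagnosis to prostate-cancer death
is Weibull; otherwise the man dies of other causes. Cells are keyed by spread
and grade class at diagnosis, with an age-band multiplier on the fatality
probability. Curative treatment (radical prostatectomy or radiation therapy)
of local-regional disease multiplies the fatality probability by a relative
risk of 0.56 versus watchful waiting.

Screen detection can only improve survival through *cure*: with a probability
that saturates in lead time, an early-detected, curatively treated,
local-regional cancer is cured outright. A screen-detected man who is not
cured dies of his cancer exactly when his unscreened twin would have — the
death clock runs from the original clinical-diagnosis date, so lead time is
never credited as survival (the standard guard against lead-time bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .natural_history import DiseaseState, LifeHistory

__all__ = [
    "TREATMENTS",
    "AGE_BANDS",
    "TreatmentMatrix",
    "SurvivalParams",
    "age_band_index",
    "assign_treatment",
    "apply_treatment_effect",
    "cure_probability",
    "simulate_pc_death",
]

TREATMENTS = ("RP", "RT", "WW")
# Age bands at diagnosis shared by the treatment matrix and survival factors.
AGE_BANDS = (("lt60", 0.0, 60.0), ("a60_69", 60.0, 70.0), ("a70p", 70.0, np.inf))
GRADE_CLASSES = ("LGC", "HGC")
SURVIVAL_CELLS = ("LR.LGC", "LR.HGC", "D.LGC", "D.HGC")


def age_band_index(age) -> np.ndarray:
    """0-based band index for an age (scalar or array)."""
    edges = np.array([b[2] for b in AGE_BANDS[:-1]])
    return np.searchsorted(edges, np.asarray(age), side="right")


@dataclass
class TreatmentMatrix:
    """P(treatment | age band, T-stage, recorded grade class); rows sum to 1.

    ``cells`` maps keys like ``"lt60.T1.LGC"`` to ``{"RP": p, "RT": p, "WW": p}``.
    Distant-stage diagnoses bypass the matrix and are managed conservatively.
    """

    cells: dict[str, dict[str, float]]
    probs: np.ndarray = field(default=None, repr=False)  # (3 bands, 3 T, 2 grade, 3 tx)

    def __post_init__(self) -> None:
        probs = np.full((3, 3, 2, 3), np.nan)
        for key, cell in self.cells.items():
            try:
                band, t, gc = key.split(".")
                bi = [b[0] for b in AGE_BANDS].index(band)
                ti = ("T1", "T2", "T3").index(t)
                gi = GRADE_CLASSES.index(gc)
            except ValueError as exc:
                raise ConfigError(f"treatment: bad cell key {key!r}") from exc
            row = np.array([cell.get(tx, 0.0) for tx in TREATMENTS], dtype=float)
            if np.any(row < 0) or not np.isclose(row.sum(), 1.0):
                raise ConfigError(f"treatment cell {key}: probabilities must be >=0 and sum to 1")
            probs[bi, ti, gi] = row
        if np.isnan(probs).any():
            missing = int(np.isnan(probs[..., 0]).sum())
            raise ConfigError(f"treatment: {missing} matrix cells missing")
        self.probs = probs

    def cell_probs(self, band_idx, t_stage, grade_is_hgc) -> np.ndarray:
        return self.probs[band_idx, t_stage, np.asarray(grade_is_hgc, dtype=int)]


@dataclass
class SurvivalParams:
    """Baseline survival cells, treatment relative risks, and the cure curve."""

    baseline: dict[str, dict[str, float]]  # "LR.LGC" -> {death_prob, shape, scale}
    age_band_factors: dict[str, float]
    rr_rp: float = 0.56
    rr_rt: float = 0.56
    cure_baseline: float = 0.0
    cure_slope: float = 0.25
    cure_max: float = 0.80

    death_prob: np.ndarray = field(default=None, repr=False)  # (2 spread, 2 grade class)
    shape: np.ndarray = field(default=None, repr=False)
    scale: np.ndarray = field(default=None, repr=False)
    band_factors: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("rr_rp", "rr_rt"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"survival.{name} must be in (0,1], got {v}")
        if not (0.0 <= self.cure_baseline <= self.cure_max <= 1.0):
            raise ConfigError("survival.cure: require 0 <= baseline <= max <= 1")
        if self.cure_slope < 0:
            raise ConfigError("survival.cure_slope must be >= 0")
        dp = np.full((2, 2), np.nan)
        sh = np.full((2, 2), np.nan)
        sc = np.full((2, 2), np.nan)
        for key in SURVIVAL_CELLS:
            if key not in self.baseline:
                raise ConfigError(f"survival.baseline: missing cell {key}")
            cell = self.baseline[key]
            spread, gc = key.split(".")
            si = ("LR", "D").index(spread)
            gi = GRADE_CLASSES.index(gc)
            p = float(cell["death_prob"])
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"survival.baseline.{key}.death_prob out of [0,1]")
            if cell["shape"] <= 0 or cell["scale"] <= 0:
                raise ConfigError(f"survival.baseline.{key}: shape/scale must be > 0")
            dp[si, gi], sh[si, gi], sc[si, gi] = p, cell["shape"], cell["scale"]
        self.death_prob, self.shape, self.scale = dp, sh, sc
        bf = np.array([self.age_band_factors[b[0]] for b in AGE_BANDS], dtype=float)
        if np.any(bf < 0):
            raise ConfigError("survival.age_band_factors must be >= 0")
        self.band_factors = bf

    def rr_for(self, treatment) -> np.ndarray:
        """Relative risk multiplier per treatment code (0 RP, 1 RT, 2 WW)."""
        table = np.array([self.rr_rp, self.rr_rt, 1.0])
        return table[np.asarray(treatment)]


def assign_treatment(
    age: float,
    state: DiseaseState,
    recorded_grade: str,
    matrix: TreatmentMatrix,
    rng: np.random.Generator,
) -> str:
    """Draw a treatment from the (age band, T-stage, recorded grade) cell.

    A misclassified high-grade cancer routes to the LGC cell — undertreatment
    is exactly how misclassification bites.
    """
    if recorded_grade not in GRADE_CLASSES:
        raise ConfigError(f"unknown recorded grade {recorded_grade!r}")
    if state.spread == 1:
        return "WW"  # distant disease is managed conservatively/palliatively
    probs = matrix.cell_probs(int(age_band_index(age)), state.t_stage, recorded_grade == "HGC")
    return TREATMENTS[int(rng.choice(3, p=probs))]


def apply_treatment_effect(death_risk: float, treatment: str, params: SurvivalParams | None = None):
    """Multiply the prostate-cancer death risk by the treatment's relative risk."""
    rr_rp = params.rr_rp if params is not None else 0.56
    rr_rt = params.rr_rt if params is not None else 0.56
    factor = {"RP": rr_rp, "RT": rr_rt, "WW": 1.0}
    try:
        return death_risk * factor[treatment]
    except KeyError as exc:
        raise ConfigError(f"unknown treatment {treatment!r}") from exc


def cure_probability(lead_time, params: SurvivalParams):
    """Saturating-exponential cure curve, anchored at the baseline for zero lead time.

    cure(L) = baseline + (max - baseline) * (1 - exp(-slope * L)); nondecreasing
    in lead time and bounded by the asymptote.
    """
    lead = np.asarray(lead_time, dtype=float)
    if np.any(lead < 0):
        raise ConfigError("lead_time must be >= 0")
    out = params.cure_baseline + (params.cure_max - params.cure_baseline) * (
        1.0 - np.exp(-params.cure_slope * lead)
    )
    return float(out) if np.isscalar(lead_time) else out


def weibull_time(u, shape, scale):
    """Inverse-CDF Weibull draw from a uniform."""
    return scale * (-np.log1p(-np.asarray(u))) ** (1.0 / np.asarray(shape))


def baseline_cell(params: SurvivalParams, spread, grade_is_hgc):
    """(death_prob, shape, scale) arrays for spread / grade-class indices."""
    s = np.asarray(spread, dtype=int)
    g = np.asarray(grade_is_hgc, dtype=int)
    return params.death_prob[s, g], params.shape[s, g], params.scale[s, g]


def simulate_pc_death(
    history: LifeHistory,
    screening_record,
    treatment: str,
    params: SurvivalParams,
    panel,
    rng: np.random.Generator,
    twin_treatment: str = "WW",
) -> float | None:
    """Scalar prostate-cancer death age for one diagnosed history, or None if the
    man never dies of prostate cancer.

    For a clinical diagnosis the fatality probability of the (state, age) cell —
    treatment-adjusted for curatively treated local-regional disease — decides
    whether a Weibull-distributed survival time from diagnosis applies. For a
    screen detection, the man is cured with the lead-time cure probability when
    local-regional and curatively treated; otherwise his death clock is the
    unscreened one, drawn from the original clinical diagnosis.
    """
    detected = screening_record is not None and screening_record.detection_age is not None
    if history.clinical_dx_age is None and not detected:
        raise ConfigError("simulate_pc_death requires a diagnosed history")

    if detected:
        if screening_record.overdiagnosed:
            return None  # the cancer would never have surfaced
        det_state_spread = _spread_at(history, screening_record.detection_age)
        curative = treatment in ("RP", "RT") and det_state_spread == 0
        if curative:
            cp = cure_probability(screening_record.lead_time, params)
            if cp > 0 and rng.uniform() < cp:
                return None
        # not cured: the unscreened clock applies, under the twin's own treatment
        dx_age = history.latent_clinical_dx_age
        dx_state = _state_at_dx(history)
        tx = twin_treatment
    else:
        dx_age = history.clinical_dx_age
        dx_state = history.state_at_clinical_dx
        tx = treatment

    hgc = bool(panel.is_hgc_grade(dx_state.grade))
    p, shape, scale = baseline_cell(params, dx_state.spread, hgc)
    p = p * params.band_factors[int(age_band_index(dx_age))]
    if dx_state.spread == 0:
        p = apply_treatment_effect(p, tx, params)
    p = min(float(p), 1.0)
    if rng.uniform() >= p:
        return None
    return float(dx_age + weibull_time(rng.uniform(), shape, scale))


def _spread_at(history: LifeHistory, age: float) -> int:
    spread = 0
    for st, entry in history.trajectory:
        if entry <= age:
            spread = st.spread
    return spread


def _state_at_dx(history: LifeHistory) -> DiseaseState:
    if history.state_at_clinical_dx is not None:
        return history.state_at_clinical_dx
    return history.trajectory[-1][0]
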
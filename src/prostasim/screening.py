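"""Screening pathways: PSA, mpMRI triage, and biopsy.

Two pathways are modeled. In the *classical* pathway every man with a positive
PSA test (threshold 3 ng/ml, modeled as state-dependent test sensitivity) is
referred for a transrectal ultrasound-guided biopsy (TRUSGB). In the *mri*
pathway a positive PSA test is followed by an mpMRI triage; only mpMRI-positive
men (PI-RADS 3-5) proceed to an MRI-guided biopsy (MRIGB). Both pathways share
the invitation schedule, attendance and biopsy compliance.

PSA positivity is modeled per preclinical state (a standard convention in
screening micro-simulation)
rather than through simulated PSA levels. False-positive PSA tests and
cancer-free biopsies are not simulated man-by-man; total biopsy volumes are
imputed from detected cancers through a biopsy positive predictive value (PPV)
at accounting time.

Biopsy of a high-grade cancer (HGC) may record it as low-grade (LGC): a 36.3%
misclassification rate for TRUSGB versus 8.7% for MRIGB. The recorded grade
drives treatment assignment downstream, which is how misclassification harms
outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .natural_history import N_STATES, DiseaseArrays, LifeHistory, state_grade

__all__ = [
    "ScreeningProtocol",
    "TestPanel",
    "ScreeningRecord",
    "ScreeningDraws",
    "DetectionArrays",
    "invitation_ages",
    "mpmri_result",
    "biopsy_result",
    "run_screening",
    "run_screening_cohort",
    "total_biopsies",
]

PATHWAYS = ("classical", "mri")


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0,1], got {value}")


@dataclass
class ScreeningProtocol:
    """Invitation schedule and participation (defaults: triennial 55-64, 80%/90%)."""

    start_age: float = 55.0
    stop_age: float = 64.0
    interval: float = 3.0
    attendance: float = 0.80
    biopsy_compliance: float = 0.90
    psa_threshold: float = 3.0  # ng/ml; label only — positivity is state-dependent
    persistent_attendance: bool = False  # all-or-none attenders (sensitivity switch)

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ConfigError(f"protocol.interval must be > 0, got {self.interval}")
        if self.start_age > self.stop_age:
            raise ConfigError("protocol.start_age must be <= stop_age")
        _check_prob(self.attendance, "protocol.attendance")
        _check_prob(self.biopsy_compliance, "protocol.biopsy_compliance")


@dataclass
class TestPanel:
    """All test characteristics and PPVs for both pathways."""

    __test__ = False  # keep pytest from collecting this despite the name

    psa_sens_by_state: np.ndarray  # length 18, P(PSA >= threshold | state)
    mpmri_sens_hgc: float = 0.94
    mpmri_sens_lgc: float = 0.74
    mpmri_pos_rate_nocancer: float = 0.30  # PPV-bridge / sensitivity analyses only
    trusgb_sens: float = 0.90
    mrigb_sens_hgc: float = 0.91
    mrigb_sens_lgc: float = 0.44
    misclass_trusgb: float = 0.363
    misclass_mrigb: float = 0.087
    ppv_classical: float = 0.40
    ppv_mri: float = 0.55
    hgc_grades: tuple[int, ...] = (1, 2)  # Gleason =7 and >7 are clinically significant

    def __post_init__(self) -> None:
        self.psa_sens_by_state = np.asarray(self.psa_sens_by_state, dtype=float)
        if self.psa_sens_by_state.shape != (N_STATES,):
            raise ConfigError("tests.psa_sens_by_state must have length 18")
        if np.any((self.psa_sens_by_state < 0) | (self.psa_sens_by_state > 1)):
            raise ConfigError("tests.psa_sens_by_state values must be in [0,1]")
        for name in (
            "mpmri_sens_hgc",
            "mpmri_sens_lgc",
            "mpmri_pos_rate_nocancer",
            "trusgb_sens",
            "mrigb_sens_hgc",
            "mrigb_sens_lgc",
            "misclass_trusgb",
            "misclass_mrigb",
        ):
            _check_prob(getattr(self, name), f"tests.{name}")
        for name in ("ppv_classical", "ppv_mri"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"tests.{name} must be in (0,1], got {v}")
        if not self.hgc_grades or any(g not in (0, 1, 2) for g in self.hgc_grades):
            raise ConfigError("tests.hgc_grades must be a nonempty subset of grade indices 0..2")
        self.hgc_grades = tuple(sorted(set(self.hgc_grades)))

    def is_hgc_grade(self, grade) -> np.ndarray:
        """Boolean: does a grade index dichotomize to clinically significant?"""
        mask = np.zeros(3, dtype=bool)
        mask[list(self.hgc_grades)] = True
        return mask[np.asarray(grade)]

    def grade_class_of_state(self, state_idx) -> np.ndarray:
        return self.is_hgc_grade(state_grade(state_idx))


@dataclass
class ScreeningRecord:
    """Per-man screening outcome for one pathway."""

    rounds_attended: int = 0
    detection_age: float | None = None
    detection_round: int | None = None
    recorded_grade: str | None = None  # "LGC" / "HGC"
    true_grade_at_detection: str | None = None
    lead_time: float | None = None
    n_psa_tests: int = 0
    n_mpmri: int = 0
    n_biopsies: int = 0
    n_biopsies_true_positive: int = 0
    overdiagnosed: bool | None = None


def invitation_ages(protocol: ScreeningProtocol) -> list[float]:
    """Arithmetic invitation schedule from start to stop age inclusive of start."""
    ages = np.arange(protocol.start_age, protocol.stop_age + 1e-9, protocol.interval)
    return [float(a) for a in ages]


def mpmri_result(grade_class: str, panel: TestPanel, rng: np.random.Generator) -> bool:
    """Bernoulli mpMRI positivity by grade class ('HGC', 'LGC', or 'none')."""
    p = {
        "HGC": panel.mpmri_sens_hgc,
        "LGC": panel.mpmri_sens_lgc,
        "none": panel.mpmri_pos_rate_nocancer,
    }[grade_class]
    return bool(rng.uniform() < p)


def biopsy_result(
    grade_class: str, modality: str, panel: TestPanel, rng: np.random.Generator
) -> tuple[bool, str | None]:
    """Biopsy detection and recorded grade.

    TRUSGB has one sensitivity for both grades; MRIGB is grade-specific. A
    detected HGC is recorded as LGC with the modality's misclassification rate.
    """
    if modality == "TRUSGB":
        sens = panel.trusgb_sens
        misclass = panel.misclass_trusgb
    elif modality == "MRIGB":
        sens = panel.mrigb_sens_hgc if grade_class == "HGC" else panel.mrigb_sens_lgc
        misclass = panel.misclass_mrigb
    else:
        raise ConfigError(f"unknown biopsy modality {modality!r}")
    detected = bool(rng.uniform() < sens)
    if not detected:
        return False, None
    if grade_class == "HGC" and rng.uniform() < misclass:
        return True, "LGC"
    return True, grade_class


def _state_at_scalar(history: LifeHistory, age: float):
    """Preclinical state occupied at ``age`` in a scalar history, or None."""
    if history.onset_age is None or history.onset_age > age:
        return None
    latent = history.latent_clinical_dx_age
    if latent is not None and latent <= age:
        return None
    state = None
    for st, entry in history.trajectory:
        if entry <= age:
            state = st
        else:
            break
    return state


def run_screening(
    history: LifeHistory,
    protocol: ScreeningProtocol,
    pathway: str,
    panel: TestPanel,
    rng: np.random.Generator,
) -> ScreeningRecord:
    """Apply one screening pathway to an unscreened life history.

    The history's disease course is left untouched; only test randomness is
    consumed here, so paired pathway comparisons share the disease course.
    """
    if pathway not in PATHWAYS:
        raise ConfigError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    rec = ScreeningRecord()
    persistent_u = rng.uniform() if protocol.persistent_attendance else None
    for r, age in enumerate(invitation_ages(protocol)):
        if age >= history.oc_death_age:
            break
        if history.clinical_dx_age is not None and history.clinical_dx_age <= age:
            break
        u_att = persistent_u if persistent_u is not None else rng.uniform()
        if u_att >= protocol.attendance:
            continue
        rec.rounds_attended += 1
        rec.n_psa_tests += 1
        state = _state_at_scalar(history, age)
        if state is None:
            continue  # cancer-free false positives are not simulated individually
        if rng.uniform() >= panel.psa_sens_by_state[state.index]:
            continue
        grade_class = "HGC" if bool(panel.is_hgc_grade(state.grade)) else "LGC"
        if pathway == "mri":
            rec.n_mpmri += 1
            if not mpmri_result(grade_class, panel, rng):
                continue
        if rng.uniform() >= protocol.biopsy_compliance:
            continue
        rec.n_biopsies += 1
        modality = "MRIGB" if pathway == "mri" else "TRUSGB"
        detected, recorded = biopsy_result(grade_class, modality, panel, rng)
        if detected:
            rec.n_biopsies_true_positive += 1
            rec.detection_age = age
            rec.detection_round = r
            rec.recorded_grade = recorded
            rec.true_grade_at_detection = grade_class
            latent = history.latent_clinical_dx_age
            if latent is not None and latent < history.oc_death_age:
                rec.lead_time = latent - age
                rec.overdiagnosed = False
            else:
                rec.lead_time = None
                rec.overdiagnosed = True
            break  # a detected man exits further screening
    return rec


def total_biopsies(true_positive_biopsies: float, ppv: float) -> float:
    """Impute total biopsies (including negatives) from detections and a PPV."""
    if not (0.0 < ppv <= 1.0):
        raise ConfigError(f"ppv must be in (0,1], got {ppv}")
    return true_positive_biopsies / ppv


@dataclass
class ScreeningDraws:
    """Pre-drawn per-man-per-round uniforms; fixed across pathways and parameter
    draws so that common random numbers carry through the whole comparison."""

    attend: np.ndarray
    psa: np.ndarray
    mpmri: np.ndarray
    comply: np.ndarray
    biopsy: np.ndarray
    misclass: np.ndarray

    @classmethod
    def draw(cls, n: int, n_rounds: int, rng: np.random.Generator) -> "ScreeningDraws":
        return cls(*(rng.uniform(size=(n, n_rounds)) for _ in range(6)))


@dataclass
class DetectionArrays:
    """Cohort-level screening outcome (NaN / -1 encode 'not detected')."""

    det_age: np.ndarray
    det_round: np.ndarray
    det_state: np.ndarray
    recorded_hgc: np.ndarray  # bool; valid only where detected
    true_hgc: np.ndarray
    overdiagnosed: np.ndarray  # bool; valid only where detected
    lead_time: np.ndarray  # NaN where not detected or overdiagnosed
    # per-round counts
    n_psa_tests_round: np.ndarray
    n_mpmri_cancer_round: np.ndarray
    n_cancer_biopsy_round: np.ndarray
    n_detect_round: np.ndarray

    @property
    def detected(self) -> np.ndarray:
        return np.isfinite(self.det_age)


def run_screening_cohort(
    disease: DiseaseArrays,
    oc_death_ages: np.ndarray,
    protocol: ScreeningProtocol,
    pathway: str,
    panel: TestPanel,
    draws: ScreeningDraws,
) -> DetectionArrays:
    """Vectorized counterpart of :func:`run_screening` over a whole cohort.

    Consumes pre-drawn uniforms, so re-running with a different ``panel``
    answers "same men, same luck, different test characteristics".
    """
    if pathway not in PATHWAYS:
        raise ConfigError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    ages = invitation_ages(protocol)
    n = disease.n
    oc = np.asarray(oc_death_ages, dtype=float)
    latent = disease.latent_dx_age

    det_age = np.full(n, np.nan)
    det_round = np.full(n, -1, dtype=np.int32)
    det_state = np.full(n, -1, dtype=np.int16)
    recorded_hgc = np.zeros(n, dtype=bool)
    true_hgc = np.zeros(n, dtype=bool)
    detected = np.zeros(n, dtype=bool)

    n_psa = np.zeros(len(ages))
    n_mpmri = np.zeros(len(ages))
    n_biopsy = np.zeros(len(ages))
    n_detect = np.zeros(len(ages))

    for r, a in enumerate(ages):
        u_att = draws.attend[:, 0] if protocol.persistent_attendance else draws.attend[:, r]
        eligible = (oc > a) & (latent > a) & ~detected
        attends = eligible & (u_att < protocol.attendance)
        n_psa[r] = attends.sum()

        state = disease.state_at(a)
        has_pc = attends & (state >= 0)
        psa_pos = has_pc.copy()
        safe_state = np.where(state >= 0, state, 0)
        psa_pos &= draws.psa[:, r] < panel.psa_sens_by_state[safe_state]

        hgc = panel.grade_class_of_state(safe_state)
        if pathway == "mri":
            n_mpmri[r] = psa_pos.sum()
            mp_sens = np.where(hgc, panel.mpmri_sens_hgc, panel.mpmri_sens_lgc)
            referred = psa_pos & (draws.mpmri[:, r] < mp_sens)
        else:
            referred = psa_pos

        biopsied = referred & (draws.comply[:, r] < protocol.biopsy_compliance)
        n_biopsy[r] = biopsied.sum()

        if pathway == "mri":
            sens = np.where(hgc, panel.mrigb_sens_hgc, panel.mrigb_sens_lgc)
            misclass = panel.misclass_mrigb
        else:
            sens = panel.trusgb_sens
            misclass = panel.misclass_trusgb
        new_det = biopsied & (draws.biopsy[:, r] < sens)
        n_detect[r] = new_det.sum()

        det_age[new_det] = a
        det_round[new_det] = r
        det_state[new_det] = state[new_det]
        true_hgc[new_det] = hgc[new_det]
        recorded_hgc[new_det] = hgc[new_det] & ~(draws.misclass[new_det, r] < misclass)
        detected |= new_det

    overdx = detected & ~(latent < oc)
    lead = np.full(n, np.nan)
    leadable = detected & ~overdx
    lead[leadable] = latent[leadable] - det_age[leadable]

    return DetectionArrays(
        det_age=det_age,
        det_round=det_round,
        det_state=det_state,
        recorded_hgc=recorded_hgc,
        true_hgc=true_hgc,
        overdiagnosed=overdx,
        lead_time=lead,
        n_psa_tests_round=n_psa,
        n_mpmri_cancer_round=n_mpmri,
        n_cancer_biopsy_round=n_biopsy,
        n_detect_round=n_detect,
    )
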
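"""Preclinical prostate-cancer natural history.

A tumor arises at an onset age drawn from a piecewise-constant age hazard and
then walks through a state space of 18 preclinical states — the cross of
T-stage (T1, T2, T3), Gleason category (<7, =7, >7) and spread
(local-regional, distant). From each state four events compete with
exponential waiting times: advance to the next T-stage, advance to the next
Gleason category, metastasize (local-regional → distant), or surface as a
clinical diagnosis. Transitions never move any axis downward. The walk is a
semi-Markov process with competing exponential risks; clinical diagnosis
absorbs it.

Clinical diagnosis is only *recorded* when it precedes other-cause death, but
the latent diagnosis age of the unscreened course is kept: it defines lead
time and overdiagnosis for the screened twin of the same man.

Two implementations of the same walk are provided: a scalar one producing a
readable :class:`LifeHistory` (used for unit-level reasoning and hand traces)
and a vectorized cohort one used by the simulation engine. Both consume the
same :class:`NaturalHistoryParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, PairingError

__all__ = [
    "T_STAGES",
    "GRADES",
    "SPREADS",
    "N_STATES",
    "DiseaseState",
    "NaturalHistoryParams",
    "LifeHistory",
    "DiseaseArrays",
    "enumerate_states",
    "allowed_transitions",
    "state_label",
    "state_from_label",
    "sample_onset",
    "simulate_disease",
    "simulate_disease_cohort",
    "is_overdiagnosed",
]

T_STAGES = ("T1", "T2", "T3")
GRADES = ("Glt7", "Geq7", "Ggt7")
SPREADS = ("LR", "D")
N_STATES = len(T_STAGES) * len(GRADES) * len(SPREADS)

# Event columns in tie-break precedence order (ties are measure-zero under
# continuous draws; argmin keeps the first minimum, so this order decides).
EVENTS = ("clinical_dx", "metastasize", "grade_advance", "t_advance")
# State-index increments per advancement event (index = t*6 + grade*2 + spread).
_EVENT_STEP = {"metastasize": 1, "grade_advance": 2, "t_advance": 6}


@dataclass(frozen=True, order=True)
class DiseaseState:
    """One of the 18 preclinical states; axes are 0-based indices."""

    t_stage: int
    grade: int
    spread: int

    def __post_init__(self) -> None:
        if not (0 <= self.t_stage <= 2 and 0 <= self.grade <= 2 and 0 <= self.spread <= 1):
            raise ConfigError(f"invalid disease state axes: {self!r}")

    @property
    def index(self) -> int:
        return self.t_stage * 6 + self.grade * 2 + self.spread

    @property
    def label(self) -> str:
        return f"{T_STAGES[self.t_stage]}.{GRADES[self.grade]}.{SPREADS[self.spread]}"

    @classmethod
    def from_index(cls, idx: int) -> "DiseaseState":
        return cls(idx // 6, (idx // 2) % 3, idx % 2)


def state_label(idx: int) -> str:
    return DiseaseState.from_index(idx).label


def state_from_label(label: str) -> DiseaseState:
    try:
        t, g, s = label.split(".")
        return DiseaseState(T_STAGES.index(t), GRADES.index(g), SPREADS.index(s))
    except (ValueError, IndexError) as exc:
        raise ConfigError(f"unknown state label {label!r}") from exc


def enumerate_states() -> list[DiseaseState]:
    """All 18 states in canonical order (T-stage major, grade, then spread)."""
    return [DiseaseState.from_index(i) for i in range(N_STATES)]


def allowed_transitions(state: DiseaseState) -> set[str]:
    """Events that can fire from ``state``; clinical diagnosis is always possible."""
    events = {"clinical_dx"}
    if state.t_stage < 2:
        events.add("t_advance")
    if state.grade < 2:
        events.add("grade_advance")
    if state.spread == 0:
        events.add("metastasize")
    return events


# Vectorized axis helpers on state indices.
def state_t(idx):
    return np.asarray(idx) // 6


def state_grade(idx):
    return (np.asarray(idx) // 2) % 3


def state_spread(idx):
    return np.asarray(idx) % 2


@dataclass
class NaturalHistoryParams:
    """Onset hazard, per-state transition rates, and the onset-state distribution.

    ``onset_hazard`` is a list of ``(age_from, age_to, rate)`` bands (per
    person-year); gaps between bands carry zero hazard. ``transition_rates``
    maps each state label to per-year rates for the four competing events.
    """

    onset_hazard: list[tuple[float, float, float]]
    transition_rates: dict[str, dict[str, float]]
    onset_state_probs: np.ndarray | None = None

    # Derived per-state rate arrays (filled by validate()).
    rate_dx: np.ndarray = field(default=None, repr=False)
    rate_met: np.ndarray = field(default=None, repr=False)
    rate_grade: np.ndarray = field(default=None, repr=False)
    rate_t: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        last_end = -np.inf
        for a0, a1, r in self.onset_hazard:
            if a1 <= a0:
                raise ConfigError(f"onset_hazard band ({a0},{a1}) has non-positive width")
            if a0 < last_end:
                raise ConfigError(f"onset_hazard bands overlap at age {a0}")
            if r < 0:
                raise ConfigError(f"onset_hazard rate {r} negative in band ({a0},{a1})")
            last_end = a1

        arrays = {ev: np.zeros(N_STATES) for ev in EVENTS}
        for label, rates in self.transition_rates.items():
            st = state_from_label(label)
            allowed = allowed_transitions(st)
            for ev, r in rates.items():
                if ev not in EVENTS:
                    raise ConfigError(f"unknown event {ev!r} for state {label}")
                if r < 0:
                    raise ConfigError(f"negative rate {ev}={r} for state {label}")
                if r > 0 and ev not in allowed:
                    raise ConfigError(f"impossible move {ev} from state {label} has rate {r} != 0")
                arrays[ev][st.index] = r
        self.rate_dx = arrays["clinical_dx"]
        self.rate_met = arrays["metastasize"]
        self.rate_grade = arrays["grade_advance"]
        self.rate_t = arrays["t_advance"]

        if self.onset_state_probs is None:
            probs = np.zeros(N_STATES)
            probs[0] = 1.0  # onset in (T1, Glt7, LR) unless configured otherwise
            self.onset_state_probs = probs
        else:
            self.onset_state_probs = np.asarray(self.onset_state_probs, dtype=float)
            if self.onset_state_probs.shape != (N_STATES,):
                raise ConfigError("onset_state_probs must have length 18")
            if np.any(self.onset_state_probs < 0) or not np.isclose(
                self.onset_state_probs.sum(), 1.0
            ):
                raise ConfigError("onset_state_probs must be nonnegative and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """(18, 4) rates in EVENTS column order."""
        return np.stack([self.rate_dx, self.rate_met, self.rate_grade, self.rate_t], axis=1)


@dataclass
class LifeHistory:
    """One man's unscreened disease course (screening/survival fields filled later)."""

    oc_death_age: float
    onset_age: float | None = None
    trajectory: list[tuple[DiseaseState, float]] = field(default_factory=list)
    clinical_dx_age: float | None = None
    state_at_clinical_dx: DiseaseState | None = None
    latent_clinical_dx_age: float | None = None  # diagnosis age ignoring other-cause death
    pc_death_age: float | None = None
    screen: object | None = None


def _hazard_edges(onset_hazard):
    """Contiguous (edges, rates) covering gaps with zero rate."""
    bands = sorted(onset_hazard, key=lambda b: b[0])
    edges = [bands[0][0]]
    rates = []
    for a0, a1, r in bands:
        if a0 > edges[-1]:
            rates.append(0.0)
            edges.append(a0)
        edges.append(a1)
        rates.append(r)
    return np.asarray(edges, dtype=float), np.asarray(rates, dtype=float)


def sample_onset_ages(params: NaturalHistoryParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Onset ages from the piecewise-exponential hazard; NaN when onset never occurs."""
    edges, rates = _hazard_edges(params.onset_hazard)
    cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
    e = rng.standard_exponential(n)
    band = np.searchsorted(cum[1:], e, side="right")
    ages = np.full(n, np.nan)
    inside = band < len(rates)
    b = band[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        ages[inside] = edges[b] + (e[inside] - cum[b]) / rates[b]
    return ages


def sample_onset(
    params: NaturalHistoryParams, oc_death_age: float, rng: np.random.Generator
) -> float | None:
    """Single onset age, or None if onset falls after other-cause death (or never)."""
    age = sample_onset_ages(params, 1, rng)[0]
    if not np.isfinite(age) or age >= oc_death_age:
        return None
    return float(age)


def _draw_onset_state(params: NaturalHistoryParams, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(N_STATES, size=n, p=params.onset_state_probs)


def simulate_disease(
    params: NaturalHistoryParams, oc_death_age: float, rng: np.random.Generator
) -> LifeHistory:
    """Simulate one man's unscreened disease course as a competing-risks walk."""
    hist = LifeHistory(oc_death_age=float(oc_death_age))
    onset = sample_onset(params, oc_death_age, rng)
    if onset is None:
        return hist
    hist.onset_age = onset
    idx = int(_draw_onset_state(params, rng, 1)[0])
    age = onset
    rates_mat = params.rate_matrix()
    trajectory = [(DiseaseState.from_index(idx), age)]
    latent_dx = None
    dx_state = None
    for _ in range(2 * N_STATES):  # safety bound; the walk absorbs in <= 6 steps
        rates = rates_mat[idx]
        with np.errstate(divide="ignore"):
            times = rng.standard_exponential(4) / rates
        k = int(np.argmin(times))
        if not np.isfinite(times[k]):
            break  # no event possible: latent forever
        age = age + float(times[k])
        if EVENTS[k] == "clinical_dx":
            latent_dx = age
            dx_state = DiseaseState.from_index(idx)
            break
        idx += _EVENT_STEP[EVENTS[k]]
        trajectory.append((DiseaseState.from_index(idx), age))

    hist.trajectory = [(s, a) for s, a in trajectory if a < oc_death_age]
    hist.latent_clinical_dx_age = latent_dx
    if latent_dx is not None and latent_dx < oc_death_age:
        hist.clinical_dx_age = latent_dx
        hist.state_at_clinical_dx = dx_state
    return hist


MAX_TRAJ = 6  # onset state + at most 5 upward transitions


@dataclass
class DiseaseArrays:
    """Cohort disease courses as flat arrays (NaN/inf/-1 encode 'absent')."""

    onset_age: np.ndarray  # NaN if no onset before other-cause death
    traj_age: np.ndarray  # (n, MAX_TRAJ), inf-padded entry ages
    traj_state: np.ndarray  # (n, MAX_TRAJ) int16, -1 padded
    latent_dx_age: np.ndarray  # inf if never clinically surfaces
    dx_state: np.ndarray  # int16, -1 if never

    @property
    def n(self) -> int:
        return len(self.onset_age)

    def state_at(self, age: float) -> np.ndarray:
        """Per-man state index occupied at ``age`` (-1 if no tumor present then)."""
        pos = np.sum(self.traj_age <= age, axis=1) - 1
        out = np.full(self.n, -1, dtype=np.int16)
        has = pos >= 0
        out[has] = self.traj_state[has.nonzero()[0], pos[has]]
        # tumor no longer preclinical once clinically diagnosed
        out[self.latent_dx_age <= age] = -1
        return out


def simulate_disease_cohort(
    params: NaturalHistoryParams, oc_death_ages: np.ndarray, rng: np.random.Generator
) -> DiseaseArrays:
    """Vectorized cohort version of :func:`simulate_disease` (same walk, same law)."""
    oc = np.asarray(oc_death_ages, dtype=float)
    n = len(oc)
    onset = sample_onset_ages(params, n, rng)
    has = np.isfinite(onset) & (onset < oc)
    onset[~has] = np.nan

    traj_age = np.full((n, MAX_TRAJ), np.inf)
    traj_state = np.full((n, MAX_TRAJ), -1, dtype=np.int16)
    latent_dx = np.full(n, np.inf)
    dx_state = np.full(n, -1, dtype=np.int16)

    idx_has = np.where(has)[0]
    cur_state = np.zeros(n, dtype=np.int64)
    cur_state[idx_has] = _draw_onset_state(params, rng, len(idx_has))
    cur_age = onset.copy()
    traj_age[idx_has, 0] = onset[idx_has]
    traj_state[idx_has, 0] = cur_state[idx_has]

    rates_mat = params.rate_matrix()
    active = has.copy()
    step = 0
    while active.any():
        idx = np.where(active)[0]
        rates = rates_mat[cur_state[idx]]
        with np.errstate(divide="ignore"):
            times = rng.standard_exponential((len(idx), 4)) / rates
        k = np.argmin(times, axis=1)
        tmin = times[np.arange(len(idx)), k]
        stuck = ~np.isfinite(tmin)
        new_age = cur_age[idx] + tmin

        is_dx = (k == 0) & ~stuck
        dxi = idx[is_dx]
        latent_dx[dxi] = new_age[is_dx]
        dx_state[dxi] = cur_state[dxi]
        active[idx[is_dx | stuck]] = False

        adv = ~is_dx & ~stuck
        ai = idx[adv]
        if ai.size:
            step += 1
            if step >= MAX_TRAJ:  # cannot happen: axes saturate after 5 moves
                raise RuntimeError("disease walk exceeded the maximum trajectory length")
            shift = np.choose(k[adv] - 1, [1, 2, 6])
            cur_state[ai] = cur_state[ai] + shift
            cur_age[ai] = new_age[adv]
            traj_age[ai, step] = new_age[adv]
            traj_state[ai, step] = cur_state[ai]

    return DiseaseArrays(onset, traj_age, traj_state, latent_dx, dx_state)


def is_overdiagnosed(history_with_screening: LifeHistory, history_without: LifeHistory) -> bool:
    """True iff the man was screen-detected but his unscreened twin is never
    clinically diagnosed within his lifetime."""
    a, b = history_with_screening, history_without
    same_course = (
        a.oc_death_age == b.oc_death_age
        and a.onset_age == b.onset_age
        and a.latent_clinical_dx_age == b.latent_clinical_dx_age
    )
    if not same_course:
        raise PairingError("histories do not share a disease course")
    rec = a.screen
    detected = rec is not None and getattr(rec, "detection_age", None) is not None
    return bool(detected and b.clinical_dx_age is None)
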
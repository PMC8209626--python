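"""Model configuration: loading, validation, and YAML (de)serialization.

A :class:`ModelConfig` bundles everything one simulation needs — protocol,
test panel, natural history, survival, treatment matrix, costs, utilities, the
life table and the discount rate. Each section validates itself on
construction; :func:`validate_config` collects every violation for a file and
reports them together, naming the offending keys.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .accounting import CostTable, UtilityTable
from .errors import ConfigError
from .natural_history import N_STATES, NaturalHistoryParams, state_from_label, state_label
from .population import LifeTable, load_life_table
from .screening import ScreeningProtocol, TestPanel
from .survival import SurvivalParams, TreatmentMatrix

__all__ = ["ModelConfig", "load_config", "validate_config", "config_digest"]


@dataclass
class ModelConfig:
    protocol: ScreeningProtocol
    tests: TestPanel
    natural_history: NaturalHistoryParams
    survival: SurvivalParams
    treatment: TreatmentMatrix
    costs: CostTable
    utilities: UtilityTable
    life_table: LifeTable
    discount_rate: float = 0.035
    wtp: float = 20000.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.wtp < 0:
            raise ConfigError("wtp must be >= 0")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        import copy

        proto = asdict(self.protocol)
        tests = {
            k: v
            for k, v in vars(self.tests).items()
            if k not in ("psa_sens_by_state", "hgc_grades")
        }
        tests["psa_sens_by_state"] = {
            state_label(i): round(float(p), 10)
            for i, p in enumerate(self.tests.psa_sens_by_state)
        }
        tests["hgc_grades"] = [("Glt7", "Geq7", "Ggt7")[g] for g in self.tests.hgc_grades]
        nh = {
            "onset_hazard": [
                {"age_from": a0, "age_to": a1, "rate": r}
                for a0, a1, r in self.natural_history.onset_hazard
            ],
            "transition_rates": copy.deepcopy(self.natural_history.transition_rates),
            "onset_state_probs": {
                state_label(i): float(p)
                for i, p in enumerate(self.natural_history.onset_state_probs)
                if p > 0
            },
        }
        surv = {
            "baseline": copy.deepcopy(self.survival.baseline),
            "age_band_factors": dict(self.survival.age_band_factors),
            "rr_rp": self.survival.rr_rp,
            "rr_rt": self.survival.rr_rt,
            "cure": {
                "baseline": self.survival.cure_baseline,
                "slope": self.survival.cure_slope,
                "max": self.survival.cure_max,
            },
        }
        util = {
            "entries": copy.deepcopy(self.utilities.entries),
            "mrigb_half_loss": self.utilities.mrigb_half_loss,
            "negative_biopsy_disutility": self.utilities.negative_biopsy_disutility,
        }
        return {
            "protocol": proto,
            "tests": tests,
            "natural_history": nh,
            "survival": surv,
            "treatment": copy.deepcopy(self.treatment.cells),
            "costs": asdict(self.costs),
            "utilities": util,
            "life_table": {
                "ages": [int(a) for a in self.life_table.ages],
                "qx": [float(q) for q in self.life_table.qx],
            },
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        try:
            tests_raw = dict(raw["tests"])
            sens_map = tests_raw.pop("psa_sens_by_state")
            if isinstance(sens_map, dict):
                sens = np.zeros(N_STATES)
                for label, p in sens_map.items():
                    sens[state_from_label(label).index] = p
            else:
                sens = np.asarray(sens_map, dtype=float)
            hgc = tests_raw.pop("hgc_grades", ["Geq7", "Ggt7"])
            hgc_idx = tuple(("Glt7", "Geq7", "Ggt7").index(g) for g in hgc)
            panel = TestPanel(psa_sens_by_state=sens, hgc_grades=hgc_idx, **tests_raw)

            nh_raw = raw["natural_history"]
            onset_probs = None
            if nh_raw.get("onset_state_probs"):
                onset_probs = np.zeros(N_STATES)
                for label, p in nh_raw["onset_state_probs"].items():
                    onset_probs[state_from_label(label).index] = p
            nh = NaturalHistoryParams(
                onset_hazard=[
                    (b["age_from"], b["age_to"], b["rate"]) for b in nh_raw["onset_hazard"]
                ],
                transition_rates=nh_raw["transition_rates"],
                onset_state_probs=onset_probs,
            )

            surv_raw = raw["survival"]
            surv = SurvivalParams(
                baseline=surv_raw["baseline"],
                age_band_factors=surv_raw["age_band_factors"],
                rr_rp=surv_raw.get("rr_rp", 0.56),
                rr_rt=surv_raw.get("rr_rt", 0.56),
                cure_baseline=surv_raw["cure"]["baseline"],
                cure_slope=surv_raw["cure"]["slope"],
                cure_max=surv_raw["cure"]["max"],
            )

            lt_raw = raw["life_table"]
            if "path" in lt_raw:
                life_table = load_life_table(lt_raw["path"])
            else:
                life_table = LifeTable(np.asarray(lt_raw["ages"]), np.asarray(lt_raw["qx"]))

            return cls(
                protocol=ScreeningProtocol(**raw["protocol"]),
                tests=panel,
                natural_history=nh,
                survival=surv,
                treatment=TreatmentMatrix(cells=raw["treatment"]),
                costs=CostTable(**raw["costs"]),
                utilities=UtilityTable(**raw["utilities"]),
                life_table=life_table,
                discount_rate=raw.get("discount_rate", 0.035),
                wtp=raw.get("wtp", 20000.0),
            )
        except KeyError as exc:
            raise ConfigError(f"config: missing key {exc.args[0]!r}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    return ModelConfig.from_dict(raw)


def validate_config(path) -> list[str]:
    """Return a list of violations (empty when the config is valid).

    I/O failures raise; schema problems are collected and returned.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    errors: list[str] = []
    if not isinstance(raw, dict):
        return [f"{path}: top level must be a mapping"]
    for section in (
        "protocol",
        "tests",
        "natural_history",
        "survival",
        "treatment",
        "costs",
        "utilities",
        "life_table",
    ):
        if section not in raw:
            errors.append(f"missing section {section!r}")
    if errors:
        return errors
    # File schema is strict: every cost key must be present (the constructors
    # carry defaults, but a config file is expected to be complete).
    from dataclasses import fields as dc_fields

    want = {f.name for f in dc_fields(CostTable)}
    have = set(raw["costs"]) if isinstance(raw["costs"], dict) else set()
    for key in sorted(want - have):
        errors.append(f"costs: missing key {key!r}")
    # Validate sections independently so every violation is reported at once.
    for name, builder in (
        ("protocol", lambda: ScreeningProtocol(**raw["protocol"])),
        ("costs", lambda: CostTable(**raw["costs"])),
        ("utilities", lambda: UtilityTable(**raw["utilities"])),
        ("treatment", lambda: TreatmentMatrix(cells=raw["treatment"])),
    ):
        try:
            builder()
        except (ConfigError, TypeError) as exc:
            errors.append(f"{name}: {exc}")
    try:
        ModelConfig.from_dict(raw)
    except (ConfigError, TypeError) as exc:
        msg = str(exc)
        if msg not in [e.split(": ", 1)[-1] for e in errors]:
            errors.append(msg)
    return errors


def config_digest(config: ModelConfig) -> str:
    """SHA-256 of the canonical YAML serialization."""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()
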
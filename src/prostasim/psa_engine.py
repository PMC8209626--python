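"""Probabilistic sensitivity analysis and cost-effectiveness statistics.

Each replicate draws the four test sensitivities that differ between pathways
(mpMRI for high/low grade, MRI-guided biopsy for high/low grade) from
truncated normals on [0, 1], and the three imaging/biopsy unit costs from
Beta-PERT distributions (λ = 4) on their (min, mode, max) ranges; everything
else stays fixed. The same cohort and the same event uniforms are reused
across replicates and strategies (common random numbers), so replicate-level
spread reflects parameter uncertainty rather than Monte-Carlo noise — the
desk-scale analogue of eliminating noise with a very large simulated
population.

Per replicate the model reports incremental (MRI − classical) discounted
outcomes per 1000 invited men; from these come the ratio-of-means ICER, the
incremental net monetary benefit at the willingness-to-pay threshold, the
cost-effectiveness acceptability curve, and CE-plane quadrant probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import build_cohort, comparison_nets, run_comparison
from .errors import ConfigError

__all__ = [
    "PsaConfig",
    "CeaResult",
    "sample_pert",
    "sample_sens",
    "run_probabilistic",
    "icer",
    "inmb",
    "ceac",
    "quadrant_probs",
    "ci95",
    "summarize_cea",
    "one_way_sweep",
]


@dataclass
class PsaConfig:
    """Replicate count, cohort size per replicate, and sampling distributions."""

    n_runs: int = 1000
    n_men: int = 200_000
    wtp: float = 20_000.0
    sens_sd: dict = field(
        default_factory=lambda: {
            "mpmri_sens_hgc": 0.06,
            "mpmri_sens_lgc": 0.06,
            "mrigb_sens_hgc": 0.05,
            "mrigb_sens_lgc": 0.05,
        }
    )
    common_random_numbers: bool = True  # one cohort reused across replicates

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ConfigError("psa.n_runs must be >= 2")
        if self.n_men < 1:
            raise ConfigError("psa.n_men must be >= 1")
        for k, sd in self.sens_sd.items():
            if sd <= 0:
                raise ConfigError(f"psa.sens_sd.{k} must be > 0")


def sample_pert(lo: float, mode: float, hi: float, rng: np.random.Generator) -> float:
    """Classic Beta-PERT draw (λ=4) rescaled to [lo, hi]; degenerate range → mode."""
    if lo > hi or not (lo <= mode <= hi):
        raise ConfigError(f"pert: require min <= mode <= max, got {lo}, {mode}, {hi}")
    if hi == lo:
        return float(mode)
    alpha = 1.0 + 4.0 * (mode - lo) / (hi - lo)
    beta = 1.0 + 4.0 * (hi - mode) / (hi - lo)
    return float(lo + (hi - lo) * rng.beta(alpha, beta))


def sample_sens(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal(mean, sd) truncated to [0, 1] by inverse-CDF (exact, no rejection)."""
    if sd <= 0:
        raise ConfigError(f"sens sd must be > 0, got {sd}")
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def _deltas_row(nets) -> dict:
    c, m = nets["classical"], nets["mri"]
    return {
        "delta_cost_screening": m.cost_screening - c.cost_screening,
        "delta_cost_diagnosis_treatment": m.cost_diagnosis_treatment - c.cost_diagnosis_treatment,
        "delta_cost_palliative": m.cost_palliative - c.cost_palliative,
        "delta_cost_total": m.cost_total - c.cost_total,
        "delta_qaly": m.qaly_disc - c.qaly_disc,
        "delta_ly_disc": m.ly_disc - c.ly_disc,
        "net_cost_total_classical": c.cost_total,
        "net_cost_total_mri": m.cost_total,
        "net_qaly_classical": c.qaly_disc,
        "net_qaly_mri": m.qaly_disc,
    }


def run_probabilistic(config, psa_config: PsaConfig, seed: int) -> pd.DataFrame:
    """One row per replicate: parameter draws plus per-1000 incremental outcomes."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_params = ss.spawn(2)
    rng = np.random.default_rng(s_params)

    cohort = None
    if psa_config.common_random_numbers:
        cohort = build_cohort(config, psa_config.n_men, s_cohort.generate_state(1)[0] % 2**31)
    cohort_seeds = np.random.default_rng(s_cohort).integers(0, 2**31, size=psa_config.n_runs)

    rows = []
    base_panel = config.tests
    base_costs = config.costs
    for i in range(psa_config.n_runs):
        draws = {
            name: sample_sens(getattr(base_panel, name), sd, rng)
            for name, sd in psa_config.sens_sd.items()
        }
        cost_draws = {
            "mpmri": sample_pert(base_costs.mpmri_min, base_costs.mpmri, base_costs.mpmri_max, rng),
            "mrigb": sample_pert(base_costs.mrigb_min, base_costs.mrigb, base_costs.mrigb_max, rng),
            "trusgb": sample_pert(
                base_costs.trusgb_min, base_costs.trusgb, base_costs.trusgb_max, rng
            ),
        }
        panel = replace(base_panel, **draws)
        costs = replace(base_costs, **cost_draws)
        run_cohort = cohort
        if run_cohort is None:
            run_cohort = build_cohort(config, psa_config.n_men, int(cohort_seeds[i]))
        totals = run_comparison(run_cohort, config, panel=panel, costs=costs)
        nets = comparison_nets(totals)
        row = {"run": i}
        row.update(draws)
        row.update({f"cost_{k}": v for k, v in cost_draws.items()})
        row.update(_deltas_row(nets))
        rows.append(row)
    return pd.DataFrame(rows)


def _cols(runs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(runs, pd.DataFrame):
        return runs["delta_cost_total"].to_numpy(), runs["delta_qaly"].to_numpy()
    dc, dq = runs
    return np.asarray(dc, dtype=float), np.asarray(dq, dtype=float)


def icer(runs) -> float:
    """Ratio-of-means ICER: mean Δcost / mean ΔQALY (NaN when mean ΔQALY is 0)."""
    dc, dq = _cols(runs)
    if np.mean(dq) == 0:
        return float("nan")
    return float(np.mean(dc) / np.mean(dq))


def icer_mean_of_ratios(runs) -> float:
    """Diagnostic only: mean of per-replicate ratios (not the headline statistic)."""
    dc, dq = _cols(runs)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.mean(dc / dq))


def inmb(runs, wtp: float) -> float:
    """Incremental net monetary benefit: wtp × mean ΔQALY − mean Δcost."""
    dc, dq = _cols(runs)
    return float(wtp * np.mean(dq) - np.mean(dc))


def ceac(runs, wtp_grid) -> list[tuple[float, float]]:
    """For each WTP, the fraction of replicates with positive net benefit."""
    dc, dq = _cols(runs)
    if len(dc) == 0:
        raise ConfigError("ceac requires at least one run")
    return [(float(w), float(np.mean(w * dq - dc > 0))) for w in wtp_grid]


def quadrant_probs(runs) -> tuple[float, float, float, float]:
    """CE-plane quadrant fractions (NE, SE, NW, SW) by sign of (ΔQALY, Δcost).

    Boundary convention: zero ΔQALY counts as non-positive effect, zero Δcost
    as non-positive cost.
    """
    dc, dq = _cols(runs)
    if len(dc) == 0:
        raise ConfigError("quadrant_probs requires at least one run")
    ne = np.mean((dq > 0) & (dc > 0))
    se = np.mean((dq > 0) & (dc <= 0))
    nw = np.mean((dq <= 0) & (dc > 0))
    sw = np.mean((dq <= 0) & (dc <= 0))
    return float(ne), float(se), float(nw), float(sw)


def ci95(values) -> tuple[float, float, float]:
    """(mean, low, high): mean ± t(0.975, n−1) · sd/√n."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ConfigError("ci95 requires at least 2 values")
    m = float(np.mean(x))
    half = float(stats.t.ppf(0.975, len(x) - 1) * np.std(x, ddof=1) / np.sqrt(len(x)))
    return m, m - half, m + half


@dataclass
class CeaResult:
    """Summary statistics of one probabilistic sensitivity analysis."""

    mean_delta_cost: float
    ci_delta_cost: tuple[float, float]
    mean_delta_qaly: float
    ci_delta_qaly: tuple[float, float]
    icer: float
    icer_mean_of_ratios: float
    inmb: float
    wtp: float
    ceac: list[tuple[float, float]]
    quadrant_probs: tuple[float, float, float, float]
    prob_cost_effective_at_wtp: float

    def to_dict(self) -> dict:
        return {
            "mean_delta_cost": self.mean_delta_cost,
            "ci_delta_cost": list(self.ci_delta_cost),
            "mean_delta_qaly": self.mean_delta_qaly,
            "ci_delta_qaly": list(self.ci_delta_qaly),
            "icer": self.icer,
            "icer_mean_of_ratios": self.icer_mean_of_ratios,
            "inmb": self.inmb,
            "wtp": self.wtp,
            "quadrant_probs": dict(zip(("NE", "SE", "NW", "SW"), self.quadrant_probs)),
            "prob_cost_effective_at_wtp": self.prob_cost_effective_at_wtp,
        }


def summarize_cea(runs, wtp: float = 20_000.0, wtp_grid=None) -> CeaResult:
    """ICER, iNMB, CIs, CEAC and quadrant probabilities from replicate deltas."""
    if wtp_grid is None:
        wtp_grid = np.arange(0, 50_001, 1_000)
    dc, dq = _cols(runs)
    mc, lc, hc = ci95(dc)
    mq, lq, hq = ci95(dq)
    curve = ceac(runs, wtp_grid)
    return CeaResult(
        mean_delta_cost=mc,
        ci_delta_cost=(lc, hc),
        mean_delta_qaly=mq,
        ci_delta_qaly=(lq, hq),
        icer=icer(runs),
        icer_mean_of_ratios=icer_mean_of_ratios(runs),
        inmb=inmb(runs, wtp),
        wtp=wtp,
        ceac=curve,
        quadrant_probs=quadrant_probs(runs),
        prob_cost_effective_at_wtp=float(np.mean(wtp * dq - dc > 0)),
    )


def _set_path(d: dict, path: str, value) -> None:
    keys = path.split(".")
    cur = d
    for k in keys[:-1]:
        if not isinstance(cur, dict) or k not in cur:
            raise ConfigError(f"unknown parameter path {path!r}")
        cur = cur[k]
    if not isinstance(cur, dict) or keys[-1] not in cur:
        raise ConfigError(f"unknown parameter path {path!r}")
    cur[keys[-1]] = value


def one_way_sweep(
    config, parameter: str, low, high, n_men: int = 100_000, seed: int = 1
) -> tuple[float, float]:
    """Deterministic ICERs with one parameter at its low and high bound.

    Everything else — including the cohort seed — is held fixed, so a parameter
    that affects both pathways identically leaves the ICER unchanged.
    """
    from .config import ModelConfig

    icers = []
    for value in (low, high):
        raw = config.to_dict()
        _set_path(raw, parameter, value)
        cfg = ModelConfig.from_dict(raw)
        cohort = build_cohort(cfg, n_men, seed)
        nets = comparison_nets(run_comparison(cohort, cfg))
        row = _deltas_row(nets)
        icers.append(row["delta_cost_total"] / row["delta_qaly"])
    return float(icers[0]), float(icers[1])
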
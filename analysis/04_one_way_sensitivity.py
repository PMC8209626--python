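#!/usr/bin/env python
"""One-way sensitivity of the ICER to costs and utilities not varied in the PSA.

Each parameter is moved to a low and a high bound (±15% for costs; ±0.05
utility points, clipped to [0,1], for utilities) with everything else fixed —
including the cohort seed — and the deterministic single-run ICER is recorded
at both bounds. Writes ``results/one_way.csv``.
"""

from pathlib import Path

import pandas as pd

from prostasim.psa_engine import one_way_sweep
from prostasim.synthetic_data import default_parameter_set

ROOT = Path(__file__).resolve().parents[1]
N_MEN = 200_000
SEED = 2026

COST_PARAMETERS = [
    "costs.psa_test",
    "costs.diagnosis_workup",
    "costs.tx_rp",
    "costs.tx_rt",
    "costs.tx_ww",
    "costs.follow_up_annual",
    "costs.palliative_terminal",
]
UTILITY_PARAMETERS = [
    "utilities.entries.diagnosis.utility",
    "utilities.entries.tx_rp.utility",
    "utilities.entries.post_treatment.utility",
    "utilities.entries.palliative.utility",
]


def main() -> None:
    config = default_parameter_set()
    rows = []
    for param in COST_PARAMETERS:
        base = config.to_dict()
        node = base
        for key in param.split(".")[:-1]:
            node = node[key]
        value = node[param.split(".")[-1]]
        lo, hi = 0.85 * value, 1.15 * value
        icer_lo, icer_hi = one_way_sweep(config, param, lo, hi, n_men=N_MEN, seed=SEED)
        rows.append({"parameter": param, "low": lo, "high": hi,
                     "icer_low": icer_lo, "icer_high": icer_hi})
        print(f"{param}: ICER {icer_lo:,.0f} (low) / {icer_hi:,.0f} (high)")
    for param in UTILITY_PARAMETERS:
        node = config.to_dict()
        for key in param.split(".")[:-1]:
            node = node[key]
        value = node[param.split(".")[-1]]
        lo, hi = max(value - 0.05, 0.0), min(value + 0.05, 1.0)
        icer_lo, icer_hi = one_way_sweep(config, param, lo, hi, n_men=N_MEN, seed=SEED)
        rows.append({"parameter": param, "low": lo, "high": hi,
                     "icer_low": icer_lo, "icer_high": icer_hi})
        print(f"{param}: ICER {icer_lo:,.0f} (unfavorable) / {icer_hi:,.0f} (favorable)")

    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "one_way.csv", index=False)
    print(f"\nICER range across one-way sweeps: "
          f"{df[['icer_low', 'icer_high']].min().min():,.0f} – "
          f"{df[['icer_low', 'icer_high']].max().max():,.0f} €/QALY")


if __name__ == "__main__":
    main()
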
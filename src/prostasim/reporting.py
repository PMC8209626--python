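"""Tabular report builders shared by the CLI, fixtures, and analysis drivers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accounting import StrategyTotals, net_vs_no_screening

__all__ = ["per_1000_table"]

ROWS = (
    ("number_biopsied", "n_biopsies_total"),
    ("screen_detected", "n_screen_detected"),
    ("overdiagnosed", "n_overdiagnosed"),
    ("pc_deaths", "n_pc_deaths"),
    ("life_years_gained", "ly_undisc"),
    ("life_years_gained_discounted", "ly_disc"),
    ("qalys_gained_discounted", "qaly_disc"),
    ("net_cost_screening", "cost_screening"),
    ("net_cost_diagnosis_treatment", "cost_diagnosis_treatment"),
    ("net_cost_palliative", "cost_palliative"),
    ("net_cost_total", "cost_total"),
)


def per_1000_table(totals: dict[str, StrategyTotals]) -> pd.DataFrame:
    """Per-1000-invited outcome table: classical and MRI pathways vs no screening.

    The ``difference`` column is MRI − classical; ``percent`` expresses it
    relative to the classical pathway (full precision; round at presentation).
    """
    nets = {
        "classical": net_vs_no_screening(totals["classical"], totals["none"]),
        "mri": net_vs_no_screening(totals["mri"], totals["none"]),
    }
    records = []
    for row_name, attr in ROWS:
        c = float(getattr(nets["classical"], attr))
        m = float(getattr(nets["mri"], attr))
        diff = m - c
        pct = 100.0 * diff / c if c != 0 else np.nan
        records.append(
            {"outcome": row_name, "classical": c, "mri": m, "difference": diff, "percent": pct}
        )
    return pd.DataFrame(records)
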
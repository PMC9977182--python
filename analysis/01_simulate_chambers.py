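#!/usr/bin/env python
"""Simulate the synthetic static-chamber CH4 campaign.

Generates the default campaign (143 wetlands x 5 chambers x 26 biweekly
steps, ~18.6k rows) with its known generating response, writes the full
table to scratch/ (large) and a compact summary to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from prairie_ch4.synthetic import ChamberGeneratorConfig, generate_chamber_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    table, truth = generate_chamber_dataset(ChamberGeneratorConfig(), args.seed)
    (ROOT / "scratch").mkdir(exist_ok=True)
    table.to_csv(ROOT / "scratch" / "chambers.csv", index=False)

    eta = table["log_mean_true"].to_numpy()
    signal_frac = eta.var() / np.log(table["flux"]).var()
    summary = pd.DataFrame([{
        "n_rows": len(table),
        "n_wetlands": table["wetland_id"].nunique(),
        "n_chambers": table["chamber_id"].nunique(),
        "flux_median_mg_m2_h": table["flux"].median(),
        "flux_mean_mg_m2_h": table["flux"].mean(),
        "frac_wetlands_below_1ha": float(
            (table.groupby("wetland_id")["wetland_size"].first() < 1e4).mean()),
        "signal_fraction_of_log_variance": signal_frac,
        "q10_true": truth.q10_true,
    }])
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "chamber_summary.csv", index=False)

    print(f"simulated {len(table)} chamber observations from "
          f"{table['wetland_id'].nunique()} wetlands")
    print(f"median flux {table['flux'].median():.2f} mg m-2 h-1; "
          f"generating signal explains {signal_frac:.0%} of log-flux variance")
    print("full table -> scratch/chambers.csv; summary -> results/chamber_summary.csv")


if __name__ == "__main__":
    main()
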
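#!/usr/bin/env python
"""Close the end-point aggregate-fraction carbon mass balance.

Theoretical soil+biochar C content vs C retained across the four sieve
classes; the difference is the incubation C loss, cross-checked against
cumulative evolved CO2-C. Writes results/balance.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from soilc13 import balance_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--aggregates", type=Path, default=Path("results/data/aggregates.csv"))
    ap.add_argument("--mixtures", type=Path, default=Path("results/data/mixtures.csv"))
    ap.add_argument("--partitioned", type=Path, default=Path("results/partitioned.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/balance.csv"))
    args = ap.parse_args()

    bal = balance_table(pd.read_csv(args.aggregates), pd.read_csv(args.mixtures))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    bal.to_csv(args.out, index=False)
    print("treatment-mean balance (g C kg⁻¹):")
    print(bal.groupby(["site", "dose_class"])[
        ["theoretical_c_g_per_kg", "retention_g_per_kg", "loss_g_per_kg"]
    ].mean().round(2).to_string())

    if args.partitioned.exists():
        part = pd.read_csv(args.partitioned)
        end = part[part["interval_end_day"] == part["interval_end_day"].max()]
        key = ["site", "dose_class", "sucrose", "replicate"]
        merged = bal.merge(end[key + ["cum_ct"]], on=key)
        gap = (merged["loss_g_per_kg"] - merged["cum_ct"]).abs()
        print(f"\nbalance loss vs cumulative CO2-C: max |difference| "
              f"{gap.max():.3g} g C kg⁻¹ over {len(merged)} cores")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
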
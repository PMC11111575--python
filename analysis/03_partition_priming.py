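#!/usr/bin/env python
"""Partition each interval's CO2 into soil- and sucrose-derived pools and
compute priming-effect series.

Uses the measured δt of matched unamended cores as the C3 end member.
Writes results/partitioned.csv and results/priming.csv and prints day-53
cumulative substrate C and PE by treatment.
"""

import argparse
from pathlib import Path

import pandas as pd

from soilc13 import PipelineConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--traps", type=Path, default=Path("results/data/traps.csv"))
    ap.add_argument("--isotopes", type=Path, default=Path("results/data/isotopes.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    traps = pd.read_csv(args.traps)
    isotopes = pd.read_csv(args.isotopes)
    res = run_pipeline(traps, isotopes, PipelineConfig())
    part, priming = res["partitioned"], res["priming"]
    args.outdir.mkdir(parents=True, exist_ok=True)
    part.to_csv(args.outdir / "partitioned.csv", index=False)
    priming.to_csv(args.outdir / "priming.csv", index=False)

    n_clamped = int(part["clamped"].sum())
    print(f"partitioned {len(part)} interval fluxes ({n_clamped} clamped fractions)")
    end = part[part["interval_end_day"] == part["interval_end_day"].max()]
    c4 = end[end["sucrose"]].groupby(["site", "dose_class"])["cum_c4"].mean()
    print("day-53 cumulative sucrose-derived C (mg C g⁻¹, treatment mean):")
    print(c4.to_string())
    pe_end = priming[priming["interval_end_day"] == priming["interval_end_day"].max()]
    pe = pe_end.groupby(["site", "dose_class"])["pe_cumulative"].mean()
    print("day-53 cumulative priming effect (mg C g⁻¹, treatment mean):")
    print(pe.to_string())


if __name__ == "__main__":
    main()
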
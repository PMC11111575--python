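"""NaOH-trap back-titration → CO2-C mass per core per interval.

CO2 absorbed by the trap consumes NaOH (as carbonate), so the sample
aliquot needs less HCl than the blank's. The mole balance is

    n(CO2) = (v_blank − v_sample) × [HCl] × (V_trap / V_aliquot) / s

with s the carbonate stoichiometry: s = 2 when the titration counts the
full 2 mol NaOH consumed per mol CO2 (the usual convention when carbonate
is removed with BaCl2 before the endpoint), s = 1 for a phenolphthalein
endpoint that sees only the first proton. The factor is configuration,
never an assumption — the two differ by exactly 2×.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import PipelineConfig, TrapMeasurement

#: Molar mass of carbon, g mol⁻¹ (= mg mmol⁻¹).
M_CARBON = 12.011


def co2_trapped(trap: TrapMeasurement, stoichiometry: int = 2) -> float:
    """mmol CO2 absorbed by the trap over the interval.

    Sign follows (v_blank − v_sample): an apparent negative flux stays
    negative so cumulative sums are unbiased.
    """
    if stoichiometry not in (1, 2):
        raise ValueError(f"carbonate stoichiometry must be 1 or 2, got {stoichiometry}")
    dv = trap.v_blank - trap.v_sample  # mL HCl
    return dv * trap.hcl_molarity * (trap.trap_volume / trap.aliquot_volume) / stoichiometry


def flux_per_gram(co2_mmol: float, dry_soil_mass: float) -> float:
    """mg CO2-C per g dry soil from mmol CO2."""
    if dry_soil_mass <= 0:
        raise ValueError(f"dry_soil_mass must be positive, got {dry_soil_mass}")
    return co2_mmol * M_CARBON / dry_soil_mass


def blank_correct(
    batch: Sequence[TrapMeasurement],
    policy: str = "per-batch-mean",
    blanks: Mapping[tuple, Sequence[float]] | None = None,
) -> list[TrapMeasurement]:
    """Resolve each record's v_blank according to the blank policy.

    ``per-batch-mean``: every record's v_blank is replaced with the mean
    titration volume of its batch's blank jars, batches keyed by
    (site, interval start day); ``blanks`` maps that key to the blank
    volumes. A batch with no blanks is an error; a single blank is used
    with a warning logged.

    ``paired``: records must already carry their own v_blank; ``blanks``
    is ignored and records pass through unchanged.
    """
    if policy == "paired":
        for t in batch:
            if t.v_blank is None:  # defensive; model forbids None
                raise ValueError("paired policy requires an explicit blank per record")
        return list(batch)
    if policy != "per-batch-mean":
        raise ValueError(f"unknown blank policy {policy!r}")
    if blanks is None:
        raise ValueError("per-batch-mean policy requires blank volumes per (site, interval)")

    out = []
    import logging
    log = logging.getLogger("soilc13")
    for t in batch:
        key = (t.treatment.site, t.interval.start_day)
        if key not in blanks or len(blanks[key]) == 0:
            raise ValueError(f"no blanks for batch {key}")
        vols = list(blanks[key])
        if len(vols) == 1:
            log.warning("batch %s has a single blank (n=1)", key)
        mean = sum(vols) / len(vols)
        out.append(t.model_copy(update={"v_blank": mean}))
    return out


def interval_fluxes(
    traps: Sequence[TrapMeasurement],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-core, per-interval CO2-C, total (mg C) and soil-normalized (mg C g⁻¹).

    One row per trap record, ordered by core then interval. The identity
    ``co2_c_per_gram × dry_soil_g == co2_c_mg`` holds by construction.
    """
    config = config or PipelineConfig()
    rows = []
    for t in traps:
        mmol = co2_trapped(t, config.carbonate_stoichiometry)
        per_g = flux_per_gram(mmol, t.dry_soil_mass)
        tr = t.treatment
        rows.append({
            "site": tr.site, "dose_class": tr.dose_class, "dose_rate": tr.dose_rate,
            "sucrose": tr.sucrose_amended, "replicate": tr.replicate,
            "interval_start_day": t.interval.start_day, "interval_end_day": t.interval.end_day,
            "co2_mmol": mmol, "co2_c_mg": per_g * t.dry_soil_mass,
            "co2_c_mg_per_g": per_g, "dry_soil_g": t.dry_soil_mass,
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["site", "dose_class", "sucrose", "replicate", "interval_start_day"]
    ).reset_index(drop=True)
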
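"""End-point aggregate-fraction carbon mass balance.

The theoretical C content of a soil–biochar mixture is the mass-weighted
mean of the two components, C1·W1 + C2·W2 (g C kg⁻¹). Summing each
aggregate size class's C content weighted by its mass proportion gives
total C retention at the end of the incubation; the shortfall against the
theoretical content is the incubation C loss. Retention + loss equals the
theoretical content by construction, and a negative loss (apparent C gain)
is reported, not clipped — it diagnoses inconsistent inputs.

This module works in g C kg⁻¹, numerically identical to mg C g⁻¹, so flux
results cross-check directly against the balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .datamodel import SIZE_CLASSES, AggregateFraction

logger = logging.getLogger("soilc13")


@dataclass(frozen=True)
class MixtureSpec:
    """Soil–biochar mixture composition (C in g C kg⁻¹, W mass proportions)."""

    c_biochar: float
    w_biochar: float
    c_soil_initial: float
    w_soil: float

    def __post_init__(self):
        if abs(self.w_biochar + self.w_soil - 1.0) > 1e-9:
            raise ValueError(
                f"mixture proportions must sum to 1: W1 + W2 = {self.w_biochar + self.w_soil}"
            )


@dataclass(frozen=True)
class BalanceResult:
    theoretical_c: float
    retention: float
    loss: float


def theoretical_c_content(mix: MixtureSpec) -> float:
    """C1·W1 + C2·W2, g C kg⁻¹."""
    return mix.c_biochar * mix.w_biochar + mix.c_soil_initial * mix.w_soil


def total_c_retention(
    fractions: Sequence[AggregateFraction],
    proportion_tolerance: float = 0.02,
    renormalize: bool = False,
) -> float:
    """Σ Ci·Pi over the four sieve classes, g C kg⁻¹.

    Exactly the four size classes must appear once each. Proportions
    summing outside 1 ± tolerance raise; sieving losses inside the
    tolerance pass through un-renormalized (renormalization is opt-in
    and logged, since the balance as defined uses raw proportions).
    """
    classes = [f.size_class for f in fractions]
    if sorted(classes) != sorted(SIZE_CLASSES):
        raise ValueError(
            f"need each of {SIZE_CLASSES} exactly once, got {classes}"
        )
    total_p = sum(f.proportion for f in fractions)
    if abs(total_p - 1.0) > proportion_tolerance:
        raise ValueError(
            f"aggregate proportions sum to {total_p:.4f}, outside 1 ± {proportion_tolerance}"
        )
    scale = 1.0
    if renormalize and total_p != 0:
        scale = 1.0 / total_p
        logger.info("renormalizing aggregate proportions by %.6f", scale)
    return sum(f.c_content * f.proportion * scale for f in fractions)


def total_c_loss(theoretical: float, retention: float) -> float:
    """Theoretical C content minus retention; negative = apparent C gain."""
    loss = theoretical - retention
    if loss < 0:
        logger.warning(
            "retention %.4g exceeds theoretical %.4g g C kg⁻¹: apparent C gain",
            retention, theoretical,
        )
    return loss


def balance(mix: MixtureSpec, fractions: Sequence[AggregateFraction], **kwargs) -> BalanceResult:
    theo = theoretical_c_content(mix)
    ret = total_c_retention(fractions, **kwargs)
    return BalanceResult(theoretical_c=theo, retention=ret, loss=total_c_loss(theo, ret))


def biochar_mass_fraction(
    dose_rate_mg_ha: float,
    incorporation_depth_m: float = 0.1,
    bulk_density_kg_m3: float = 1300.0,
) -> float:
    """W1 from a field application rate (Mg ha⁻¹), assuming uniform mixing.

    Converts dose into biochar mass per hectare and divides by the soil
    mass of the incorporation layer (area × depth × bulk density) plus the
    biochar itself. The depth and bulk density are explicit assumptions —
    the balance itself takes W1 as input.
    """
    if dose_rate_mg_ha < 0:
        raise ValueError("dose rate must be non-negative")
    soil_mass = 10_000.0 * incorporation_depth_m * bulk_density_kg_m3  # kg ha⁻¹
    biochar_mass = dose_rate_mg_ha * 1000.0  # kg ha⁻¹
    return biochar_mass / (soil_mass + biochar_mass)


def balance_table(aggregates: pd.DataFrame, mixtures: pd.DataFrame) -> pd.DataFrame:
    """Mass balance for every core in an aggregates table.

    ``aggregates``: long format, four rows per core (see io schemas).
    ``mixtures``: one row per (site, dose_class) with columns
    c_biochar_g_per_kg, w_biochar, c_soil_g_per_kg, w_soil.
    """
    rows = []
    for key, grp in aggregates.groupby(["site", "dose_class", "sucrose", "replicate"]):
        site, dose_class, sucrose, replicate = key
        mrow = mixtures[(mixtures["site"] == site) & (mixtures["dose_class"] == dose_class)]
        if len(mrow) != 1:
            raise ValueError(f"need exactly one mixture row for ({site}, {dose_class})")
        m = mrow.iloc[0]
        mix = MixtureSpec(
            c_biochar=float(m["c_biochar_g_per_kg"]), w_biochar=float(m["w_biochar"]),
            c_soil_initial=float(m["c_soil_g_per_kg"]), w_soil=float(m["w_soil"]),
        )
        fracs = [
            AggregateFraction(
                treatment={
                    "site": site, "dose_class": dose_class,
                    "dose_rate": float(r["dose_rate"]),
                    "sucrose_amended": bool(r["sucrose"]), "replicate": int(r["replicate"]),
                },
                size_class=str(r["size_class"]),
                proportion=float(r["proportion"]), c_content=float(r["c_g_per_kg"]),
            )
            for _, r in grp.iterrows()
        ]
        res = balance(mix, fracs)
        rows.append({
            "site": site, "dose_class": dose_class, "sucrose": sucrose, "replicate": replicate,
            "theoretical_c_g_per_kg": res.theoretical_c,
            "retention_g_per_kg": res.retention,
            "loss_g_per_kg": res.loss,
        })
    return pd.DataFrame(rows)
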
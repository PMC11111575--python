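"""Shared domain types for the incubation pipeline.

All records are validated at construction (pydantic). Units are fixed at
ingestion and never inferred: volumes in mL, concentrations in mol L⁻¹,
isotope deltas in ‰ (VPDB), masses in g, times in days, carbon contents in
g C kg⁻¹ (numerically identical to mg C g⁻¹).
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

#: Default NaOH-trap replacement schedule (interval boundaries, days).
DEFAULT_SCHEDULE: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0, 14.0, 28.0, 53.0)

#: Aggregate sieve classes, coarsest first.
SIZE_CLASSES: tuple[str, ...] = (">2 mm", "0.25-2 mm", "0.053-0.25 mm", "<0.053 mm")

DoseClass = Literal["control", "low", "medium", "high"]
DOSE_CLASSES: tuple[str, ...] = ("control", "low", "medium", "high")


class TreatmentSpec(BaseModel):
    """One experimental treatment cell: site × biochar dose × amendment × replicate."""

    model_config = {"frozen": True}

    site: str
    dose_class: DoseClass
    dose_rate: float = Field(ge=0, description="biochar field application, Mg ha⁻¹")
    sucrose_amended: bool
    replicate: int = Field(ge=1)

    @model_validator(mode="after")
    def _control_means_zero_dose(self) -> "TreatmentSpec":
        if (self.dose_class == "control") != (self.dose_rate == 0):
            raise ValueError(
                f"dose_class={self.dose_class!r} inconsistent with dose_rate={self.dose_rate}"
            )
        return self

    def core_id(self) -> tuple:
        return (self.site, self.dose_class, self.sucrose_amended, self.replicate)

    def group_id(self) -> tuple:
        return (self.site, self.dose_class)


class SamplingInterval(BaseModel):
    """One trap-replacement interval [start_day, end_day)."""

    model_config = {"frozen": True}

    index: int = Field(ge=1)
    start_day: float = Field(ge=0)
    end_day: float

    @model_validator(mode="after")
    def _ordered(self) -> "SamplingInterval":
        if not self.end_day > self.start_day:
            raise ValueError(f"end_day {self.end_day} must exceed start_day {self.start_day}")
        return self

    @property
    def length(self) -> float:
        return self.end_day - self.start_day


def schedule_intervals(boundaries: tuple[float, ...] = DEFAULT_SCHEDULE) -> list[SamplingInterval]:
    """Contiguous intervals from a boundary sequence (default 0,1,3,7,14,28,53 d)."""
    return [
        SamplingInterval(index=i + 1, start_day=a, end_day=b)
        for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:]))
    ]


class TrapMeasurement(BaseModel):
    """One back-titration of an NaOH trap aliquot against HCl.

    ``v_blank >= v_sample`` is expected (CO2 consumes trap alkalinity, so the
    sample needs less acid); violations are flagged by ``validate_dataset``
    as warnings, never silently dropped.
    """

    treatment: TreatmentSpec
    interval: SamplingInterval
    v_sample: float = Field(ge=0, description="mL HCl to endpoint, sample trap")
    v_blank: float = Field(ge=0, description="mL HCl to endpoint, blank trap")
    hcl_molarity: float = Field(gt=0, description="mol L⁻¹")
    trap_volume: float = Field(gt=0, description="mL NaOH in the trap")
    aliquot_volume: float = Field(gt=0, description="mL titrated")
    dry_soil_mass: float = Field(gt=0, description="g dry soil in the jar")

    @model_validator(mode="after")
    def _aliquot_fits(self) -> "TrapMeasurement":
        if self.aliquot_volume > self.trap_volume:
            raise ValueError(
                f"aliquot_volume {self.aliquot_volume} mL exceeds trap_volume {self.trap_volume} mL"
            )
        return self


class IsotopeMeasurement(BaseModel):
    """δ13C of CO2 evolved in one interval, with the two mixing end members.

    delta_3 is the C3 (soil + aged biochar) end member, delta_4 the C4
    (cane-sucrose) end member. Deltas are kept within a plausibility window;
    end-member separation is enforced at partition time, not here, so that a
    degenerate record loads and is reported rather than crashing ingestion.
    """

    treatment: TreatmentSpec
    interval: SamplingInterval
    delta_t: float = Field(ge=-60, le=60, description="‰ of evolved CO2")
    delta_3: float = Field(ge=-60, le=60, description="‰ C3 end member")
    delta_4: float = Field(ge=-60, le=60, description="‰ C4 end member")


class AggregateFraction(BaseModel):
    """End-point mass proportion and C content of one sieve class."""

    treatment: TreatmentSpec
    size_class: str
    proportion: float = Field(ge=0, le=1, description="mass fraction of whole soil (Pi)")
    c_content: float = Field(ge=0, description="g C kg⁻¹ (Ci)")

    @model_validator(mode="after")
    def _known_class(self) -> "AggregateFraction":
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {self.size_class!r}; expected one of {SIZE_CLASSES}")
        return self


class PipelineConfig(BaseModel):
    """Run-wide settings; serializes round-trip to YAML (see io.load_config)."""

    carbonate_stoichiometry: Literal[1, 2] = 2
    clamp_partition: bool = True
    min_delta_separation: float = Field(default=5.0, gt=0, description="‰")
    blank_policy: Literal["per-batch-mean", "paired"] = "paired"
    proportion_tolerance: float = Field(default=0.02, ge=0)
    mixture_tolerance: float = Field(default=1e-9, ge=0)
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    seed: int = 0
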
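"""Validated tabular input/output for the incubation pipeline.

Input tables are long-format CSV (RFC 4180, UTF-8, "." decimal), one
observation per row; wide layouts are rejected rather than guessed. Three
schemas are understood:

``traps``      site, dose_class, dose_rate, sucrose, replicate,
               interval_start_day, interval_end_day, v_sample_mL, v_blank_mL,
               hcl_M, trap_mL, aliquot_mL, dry_soil_g
``isotopes``   ... interval columns ..., delta_t_permil, delta3_permil,
               delta4_permil
``aggregates`` site, dose_class, dose_rate, sucrose, replicate, size_class,
               proportion, c_g_per_kg
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pydantic
import yaml

from .datamodel import (
    AggregateFraction,
    IsotopeMeasurement,
    PipelineConfig,
    SamplingInterval,
    TrapMeasurement,
    TreatmentSpec,
)

logger = logging.getLogger("soilc13")


class SchemaError(ValueError):
    """Header does not match the published schema."""


class EmptyTableError(ValueError):
    """File contains no data rows."""


class RowParseError(ValueError):
    """A cell failed validation; carries the 1-based data row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


TRAP_COLUMNS = [
    "site", "dose_class", "dose_rate", "sucrose", "replicate",
    "interval_start_day", "interval_end_day",
    "v_sample_mL", "v_blank_mL", "hcl_M", "trap_mL", "aliquot_mL", "dry_soil_g",
]
ISOTOPE_COLUMNS = [
    "site", "dose_class", "dose_rate", "sucrose", "replicate",
    "interval_start_day", "interval_end_day",
    "delta_t_permil", "delta3_permil", "delta4_permil",
]
AGGREGATE_COLUMNS = [
    "site", "dose_class", "dose_rate", "sucrose", "replicate",
    "size_class", "proportion", "c_g_per_kg",
]

_SCHEMAS = {"traps": TRAP_COLUMNS, "isotopes": ISOTOPE_COLUMNS, "aggregates": AGGREGATE_COLUMNS}


def _treatment(row: pd.Series) -> TreatmentSpec:
    return TreatmentSpec(
        site=str(row["site"]),
        dose_class=str(row["dose_class"]),
        dose_rate=float(row["dose_rate"]),
        sucrose_amended=_parse_bool(row["sucrose"]),
        replicate=int(row["replicate"]),
    )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _interval_index(frame: pd.DataFrame) -> pd.Series:
    """Rank each row's interval start within its core's sorted schedule (1-based)."""
    key = ["site", "dose_class", "sucrose", "replicate"]
    return frame.groupby(key)["interval_start_day"].rank(method="dense").astype(int)


def load_incubation_table(path: str | Path, schema: str):
    """Read one CSV into validated records of the requested kind.

    Returns a list of :class:`TrapMeasurement`, :class:`IsotopeMeasurement`
    or :class:`AggregateFraction` depending on ``schema``. Row order and
    1-based data-row indices are preserved for error reporting.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise EmptyTableError(f"{path} contains no data rows")
    expected = _SCHEMAS[schema]
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: header mismatch for schema {schema!r}"
            + (f"; missing columns {missing}" if missing else "")
            + (f"; unexpected columns {extra}" if extra else "")
        )
    return frame_to_records(frame, schema)


def frame_to_records(frame: pd.DataFrame, schema: str):
    """Convert a long-format DataFrame to validated records (see load_incubation_table)."""
    records = []
    if schema in ("traps", "isotopes"):
        idx = _interval_index(frame)
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            treatment = _treatment(row)
            if schema == "traps":
                interval = SamplingInterval(
                    index=int(idx.iloc[pos - 1]),
                    start_day=float(row["interval_start_day"]),
                    end_day=float(row["interval_end_day"]),
                )
                records.append(TrapMeasurement(
                    treatment=treatment, interval=interval,
                    v_sample=float(row["v_sample_mL"]), v_blank=float(row["v_blank_mL"]),
                    hcl_molarity=float(row["hcl_M"]), trap_volume=float(row["trap_mL"]),
                    aliquot_volume=float(row["aliquot_mL"]), dry_soil_mass=float(row["dry_soil_g"]),
                ))
            elif schema == "isotopes":
                interval = SamplingInterval(
                    index=int(idx.iloc[pos - 1]),
                    start_day=float(row["interval_start_day"]),
                    end_day=float(row["interval_end_day"]),
                )
                records.append(IsotopeMeasurement(
                    treatment=treatment, interval=interval,
                    delta_t=float(row["delta_t_permil"]),
                    delta_3=float(row["delta3_permil"]),
                    delta_4=float(row["delta4_permil"]),
                ))
            else:
                records.append(AggregateFraction(
                    treatment=treatment, size_class=str(row["size_class"]),
                    proportion=float(row["proportion"]), c_content=float(row["c_g_per_kg"]),
                ))
        except (pydantic.ValidationError, ValueError, TypeError) as exc:
            raise RowParseError(pos, _first_message(exc)) from exc
    return records


def _first_message(exc: Exception) -> str:
    if isinstance(exc, pydantic.ValidationError):
        err = exc.errors()[0]
        return err["msg"]
    return str(exc)


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Inverse of :func:`frame_to_records`; column order matches the schema."""
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        t = r.treatment
        base = {
            "site": t.site, "dose_class": t.dose_class, "dose_rate": t.dose_rate,
            "sucrose": t.sucrose_amended, "replicate": t.replicate,
        }
        if isinstance(r, TrapMeasurement):
            base.update(
                interval_start_day=r.interval.start_day, interval_end_day=r.interval.end_day,
                v_sample_mL=r.v_sample, v_blank_mL=r.v_blank, hcl_M=r.hcl_molarity,
                trap_mL=r.trap_volume, aliquot_mL=r.aliquot_volume, dry_soil_g=r.dry_soil_mass,
            )
        elif isinstance(r, IsotopeMeasurement):
            base.update(
                interval_start_day=r.interval.start_day, interval_end_day=r.interval.end_day,
                delta_t_permil=r.delta_t, delta3_permil=r.delta_3, delta4_permil=r.delta_4,
            )
        elif isinstance(r, AggregateFraction):
            base.update(size_class=r.size_class, proportion=r.proportion, c_g_per_kg=r.c_content)
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
        rows.append(base)
    frame = pd.DataFrame(rows)
    kind = type(records[0])
    schema = {TrapMeasurement: "traps", IsotopeMeasurement: "isotopes", AggregateFraction: "aggregates"}[kind]
    return frame[_SCHEMAS[schema]]


def write_table(records: Sequence, path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Problems found in a loaded dataset.

    ``errors`` block the pipeline; ``warnings`` (e.g. an apparent negative
    flux where v_sample > v_blank) propagate with the data.
    Each entry is (record position, message).
    """

    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(records: Sequence, config: PipelineConfig | None = None) -> ValidationReport:
    """Cross-record consistency checks beyond per-record construction.

    Fatal: identical or insufficiently separated end members, duplicated
    (core, interval) observations, non-contiguous interval schedules,
    aggregate proportions not summing to 1 within tolerance.
    Warning: v_sample > v_blank (apparent negative flux), n=1 batches.
    """
    config = config or PipelineConfig()
    report = ValidationReport()
    seen: dict[tuple, int] = {}
    by_core: dict[tuple, list] = {}
    agg_by_core: dict[tuple, list] = {}

    for pos, r in enumerate(records, start=1):
        if isinstance(r, TrapMeasurement):
            if r.v_sample > r.v_blank:
                report.warnings.append(
                    (pos, f"v_sample {r.v_sample} mL exceeds v_blank {r.v_blank} mL: "
                          "apparent negative flux retained")
                )
        if isinstance(r, IsotopeMeasurement):
            sep = abs(r.delta_4 - r.delta_3)
            if sep == 0:
                report.errors.append((pos, "end members identical (delta_4 == delta_3)"))
            elif sep < config.min_delta_separation:
                report.errors.append(
                    (pos, f"end-member separation {sep:.3g} ‰ below minimum "
                          f"{config.min_delta_separation} ‰")
                )
        if isinstance(r, (TrapMeasurement, IsotopeMeasurement)):
            key = (*r.treatment.core_id(), r.interval.start_day, type(r).__name__)
            if key in seen:
                report.errors.append((pos, f"duplicate observation of row {seen[key]}"))
            seen[key] = pos
            by_core.setdefault(r.treatment.core_id() + (type(r).__name__,), []).append(r.interval)
        if isinstance(r, AggregateFraction):
            agg_by_core.setdefault(r.treatment.core_id(), []).append(r)

    for core, intervals in by_core.items():
        ordered = sorted(intervals, key=lambda iv: iv.start_day)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if a.end_day != b.start_day:
                report.errors.append(
                    (0, f"core {core}: intervals not contiguous at day {a.end_day} → {b.start_day}")
                )
    for core, fractions in agg_by_core.items():
        total = sum(f.proportion for f in fractions)
        if abs(total - 1.0) > config.proportion_tolerance:
            report.errors.append(
                (0, f"core {core}: aggregate proportions sum to {total:.4f}, outside "
                    f"1 ± {config.proportion_tolerance}")
            )
    return report


# ---------------------------------------------------------------- config I/O

def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(yaml.safe_load(fh))


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_run(config: PipelineConfig, inputs: Sequence[str | Path], seed: int | None = None) -> None:
    logger.info(
        "run inputs=%s config_hash=%s seed=%s",
        [str(p) for p in inputs], config_hash(config),
        config.seed if seed is None else seed,
    )
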
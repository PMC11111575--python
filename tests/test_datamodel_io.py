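"""Domain-type invariants, CSV ingestion, and dataset validation."""

import pandas as pd
import pydantic
import pytest

import soilc13 as s
from soilc13.io import (
    EmptyTableError,
    RowParseError,
    SchemaError,
    config_hash,
    frame_to_records,
    records_to_frame,
)

TRAP_HEADER = (
    "site,dose_class,dose_rate,sucrose,replicate,interval_start_day,interval_end_day,"
    "v_sample_mL,v_blank_mL,hcl_M,trap_mL,aliquot_mL,dry_soil_g"
)


def trap_csv_lines(n=6, aliquot=5.0):
    lines = [TRAP_HEADER]
    bounds = [0, 1, 3, 7, 14, 28, 53]
    for i in range(n):
        lines.append(
            f"Cambisol,control,0,True,1,{bounds[i]},{bounds[i+1]},8.0,10.0,0.5,20.0,{aliquot},25.0"
        )
    return lines


class TestTypeInvariants:
    def test_control_requires_zero_dose(self):
        with pytest.raises(pydantic.ValidationError):
            s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=25,
                            sucrose_amended=False, replicate=1)
        with pytest.raises(pydantic.ValidationError):
            s.TreatmentSpec(site="Cambisol", dose_class="low", dose_rate=0,
                            sucrose_amended=False, replicate=1)

    def test_interval_must_be_ordered(self):
        with pytest.raises(pydantic.ValidationError):
            s.SamplingInterval(index=1, start_day=3, end_day=3)

    def test_aliquot_cannot_exceed_trap(self):
        t = s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=0,
                            sucrose_amended=True, replicate=1)
        iv = s.SamplingInterval(index=1, start_day=0, end_day=1)
        with pytest.raises(pydantic.ValidationError):
            s.TrapMeasurement(treatment=t, interval=iv, v_sample=8, v_blank=10,
                              hcl_molarity=0.5, trap_volume=20, aliquot_volume=25,
                              dry_soil_mass=25)

    def test_delta_plausibility_window(self):
        t = s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=0,
                            sucrose_amended=True, replicate=1)
        iv = s.SamplingInterval(index=1, start_day=0, end_day=1)
        with pytest.raises(pydantic.ValidationError):
            s.IsotopeMeasurement(treatment=t, interval=iv, delta_t=-75,
                                 delta_3=-26.36, delta_4=-11.97)


class TestLoading:
    def test_wellformed_file_yields_one_record_per_row(self, tmp_path):
        path = tmp_path / "traps.csv"
        path.write_text("\n".join(trap_csv_lines(6)) + "\n")
        records = s.load_incubation_table(path, "traps")
        assert len(records) == 6
        assert all(isinstance(r, s.TrapMeasurement) for r in records)
        # interval indices follow the schedule order
        assert [r.interval.index for r in records] == [1, 2, 3, 4, 5, 6]

    def test_invalid_aliquot_cites_row_number(self, tmp_path):
        lines = trap_csv_lines(6)
        lines[3] = lines[3].replace(",5.0,", ",25.0,")  # row 3: aliquot 25 > trap 20
        path = tmp_path / "traps.csv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(RowParseError, match="row 3"):
            s.load_incubation_table(path, "traps")

    def test_missing_column_named_in_schema_error(self, tmp_path):
        frame = pd.DataFrame([l.split(",") for l in trap_csv_lines(2)[1:]],
                             columns=TRAP_HEADER.split(","))
        frame = frame.drop(columns=["hcl_M"])
        path = tmp_path / "traps.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="hcl_M"):
            s.load_incubation_table(path, "traps")

    def test_empty_file_is_a_distinct_error(self, tmp_path):
        path = tmp_path / "traps.csv"
        path.write_text(TRAP_HEADER + "\n")
        with pytest.raises(EmptyTableError):
            s.load_incubation_table(path, "traps")

    def test_default_design_record_count(self, zero_noise_dataset, tmp_path):
        """2 sites × 4 doses × 2 amendments × 3 replicates × 6 intervals = 288."""
        path = tmp_path / "traps.csv"
        zero_noise_dataset["traps"].to_csv(path, index=False)
        records = s.load_incubation_table(path, "traps")
        assert len(records) == 2 * 4 * 2 * 3 * 6 == 288

    def test_round_trip_reproduces_table(self, zero_noise_dataset, tmp_path):
        path = tmp_path / "traps.csv"
        zero_noise_dataset["traps"].to_csv(path, index=False)
        original = pd.read_csv(path)
        records = s.load_incubation_table(path, "traps")
        back = records_to_frame(records)
        pd.testing.assert_frame_equal(back, original)


class TestValidation:
    def test_zero_noise_dataset_is_clean(self, zero_noise_dataset):
        for schema in ("traps", "isotopes", "aggregates"):
            records = frame_to_records(zero_noise_dataset[schema], schema)
            report = s.validate_dataset(records)
            assert report.errors == []
            assert report.warnings == []

    def test_identical_end_members_is_fatal(self):
        t = s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=0,
                            sucrose_amended=True, replicate=1)
        iv = s.SamplingInterval(index=1, start_day=0, end_day=1)
        rec = s.IsotopeMeasurement(treatment=t, interval=iv, delta_t=-20,
                                   delta_3=-26.36, delta_4=-26.36)
        report = s.validate_dataset([rec])
        assert any("identical" in msg for _, msg in report.errors)

    def test_apparent_negative_flux_is_a_warning_not_an_error(self):
        t = s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=0,
                            sucrose_amended=True, replicate=1)
        iv = s.SamplingInterval(index=1, start_day=0, end_day=1)
        rec = s.TrapMeasurement(treatment=t, interval=iv, v_sample=10.5, v_blank=10.0,
                                hcl_molarity=0.5, trap_volume=20, aliquot_volume=5,
                                dry_soil_mass=25)
        report = s.validate_dataset([rec])
        assert report.errors == []
        assert len(report.warnings) == 1

    def test_gapped_intervals_are_fatal(self):
        t = s.TreatmentSpec(site="Cambisol", dose_class="control", dose_rate=0,
                            sucrose_amended=True, replicate=1)
        recs = [
            s.TrapMeasurement(treatment=t,
                              interval=s.SamplingInterval(index=i, start_day=a, end_day=b),
                              v_sample=8, v_blank=10, hcl_molarity=0.5, trap_volume=20,
                              aliquot_volume=5, dry_soil_mass=25)
            for i, (a, b) in enumerate([(0, 1), (3, 7)], start=1)
        ]
        report = s.validate_dataset(recs)
        assert any("contiguous" in msg for _, msg in report.errors)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = s.PipelineConfig(carbonate_stoichiometry=1, clamp_partition=False,
                               min_delta_separation=3.0, seed=42)
        path = tmp_path / "cfg.yaml"
        s.save_config(cfg, path)
        loaded = s.load_config(path)
        assert loaded == cfg
        assert config_hash(loaded) == config_hash(cfg)
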
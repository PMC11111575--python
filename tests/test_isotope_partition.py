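"""δ-notation conversions, two-pool partitioning, cumulative series, priming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilc13 as s
from soilc13.isotope_partition import R_VPDB


class TestDeltaConversions:
    def test_vpdb_anchor(self):
        assert s.delta_to_ratio(0.0) == R_VPDB == 0.0112372

    def test_sucrose_end_member_ratio(self):
        assert s.delta_to_ratio(-11.97) == pytest.approx(0.0111027, abs=5e-8)

    def test_ratio_to_delta_inverse_examples(self):
        assert s.ratio_to_delta(0.0112372) == 0.0
        assert s.ratio_to_delta(2 * R_VPDB) == pytest.approx(1000.0)
        assert s.ratio_to_delta(0.0111027) == pytest.approx(-11.97, abs=5e-3)

    @given(delta=st.floats(-999.0, 1000.0))
    def test_round_trip(self, delta):
        assert s.ratio_to_delta(s.delta_to_ratio(delta)) == pytest.approx(delta, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            s.delta_to_ratio(-1000.0)
        with pytest.raises(ValueError):
            s.ratio_to_delta(0.0)


class TestPartitionSource:
    def test_pure_soil_end_member(self):
        p = s.partition_source(2.0, -26.36, -26.36, -11.97)
        assert p.c_substrate == 0.0 and p.c_soil == 2.0

    def test_pure_substrate_end_member(self):
        p = s.partition_source(2.0, -11.97, -26.36, -11.97)
        assert p.c_substrate == pytest.approx(2.0) and p.c_soil == pytest.approx(0.0)

    def test_forty_percent_mixture(self):
        p = s.partition_source(2.5, -20.604, -26.36, -11.97)
        assert p.c_substrate == pytest.approx(1.000, abs=5e-4)
        assert p.c_soil == pytest.approx(1.500, abs=5e-4)

    def test_end_members_too_close(self):
        with pytest.raises(ValueError, match="too close"):
            s.partition_source(1.0, -20.0, -20.1, -18.0)

    def test_clamping_flags_and_preserves_raw_fraction(self):
        p = s.partition_source(2.0, -10.0, -26.36, -11.97, clamp=True)
        assert p.clamped and p.c_substrate == 2.0 and p.fraction_raw > 1
        q = s.partition_source(2.0, -10.0, -26.36, -11.97, clamp=False)
        assert not q.clamped and q.c_substrate > 2.0
        assert q.c_soil + q.c_substrate == pytest.approx(q.c_total)

    @given(
        ct=st.floats(1e-6, 100.0),
        dt=st.floats(-40.0, 0.0),
        d3=st.floats(-30.0, -20.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, ct, dt, d3, shift):
        """Adding a constant to all three deltas leaves the split unchanged."""
        d4 = d3 + 14.39
        a = s.partition_source(ct, dt, d3, d4, clamp=False)
        b = s.partition_source(ct, dt + shift, d3 + shift, d4 + shift, clamp=False)
        assert b.c_substrate == pytest.approx(a.c_substrate, rel=1e-9, abs=1e-12)

    @given(
        m3=st.floats(1e-3, 10.0),
        m4=st.floats(1e-3, 10.0),
        d3=st.floats(-35.0, -20.0),
        sep=st.floats(6.0, 30.0),
    )
    def test_mix_then_partition_recovers_pools(self, m3, m4, d3, sep):
        d4 = d3 + sep
        dt = s.mass_weighted_delta([m3, m4], [d3, d4])
        p = s.partition_source(m3 + m4, dt, d3, d4, clamp=False)
        total = m3 + m4  # recovery error measured on the mixture scale
        assert abs(p.c_soil - m3) / total <= 1e-12
        assert abs(p.c_substrate - m4) / total <= 1e-12

    def test_delta_vs_atom_fraction_discrepancy_is_small(self):
        """Partitioning on δ (the linear approximation) vs on 13C atom
        fractions differs by < 0.1 % of Ct for the end members in play."""
        d3, d4 = -26.36, -11.97
        for dt in np.linspace(d3, d4, 25):
            f_delta = (dt - d3) / (d4 - d3)
            af = lambda d: (r := s.delta_to_ratio(d)) / (1 + r)
            f_atom = (af(dt) - af(d3)) / (af(d4) - af(d3))
            assert abs(f_delta - f_atom) < 1e-3


class TestMassWeightedDelta:
    def test_equal_masses_midpoint(self):
        assert s.mass_weighted_delta([1.0, 1.0], [-26.36, -11.97]) == pytest.approx(-19.165)

    def test_single_pool_returns_own_delta(self):
        assert s.mass_weighted_delta([2.5], [-24.78]) == -24.78

    def test_all_zero_masses_rejected(self):
        with pytest.raises(ValueError):
            s.mass_weighted_delta([0.0, 0.0], [-26.0, -12.0])


class TestCumulativeSeries:
    def frame(self, values, bounds=((0, 1), (1, 3), (3, 7))):
        return pd.DataFrame({
            "interval_start_day": [a for a, _ in bounds],
            "interval_end_day": [b for _, b in bounds],
            "ct": values, "c3": values, "c4": values,
        })

    def test_single_interval_equals_itself(self):
        out = s.cumulative_series(self.frame([0.7], bounds=((0, 1),)))
        assert out.loc[1.0, "ct"] == 0.7

    def test_running_sum(self):
        out = s.cumulative_series(self.frame([0.5, 0.5, 1.0]))
        assert list(out["c4"]) == [0.5, 1.0, 2.0]

    def test_gap_is_an_error(self):
        with pytest.raises(ValueError, match="gaps"):
            s.cumulative_series(self.frame([1, 1, 1], bounds=((0, 1), (3, 7), (7, 14))))

    @given(st.lists(st.floats(0.0, 5.0), min_size=3, max_size=3))
    def test_monotone_for_nonnegative_fluxes(self, values):
        out = s.cumulative_series(self.frame(values))
        assert (out["ct"].diff().dropna() >= 0).all()


class TestPrimingEffect:
    def test_identical_series_gives_zero(self):
        a = pd.Series([1.0, 2.0], index=[1.0, 3.0])
        assert (s.priming_effect(a, a.copy()) == 0).all()

    def test_subtraction_of_mean_baseline(self):
        amended = pd.Series([1.0, 2.0], index=[1.0, 3.0])
        unamended = pd.DataFrame({"r1": [0.5, 1.1], "r2": [0.7, 1.3]}, index=[1.0, 3.0])
        pe = s.priming_effect(amended, unamended)
        assert list(pe) == pytest.approx([0.4, 0.8])

    def test_mismatched_days_is_an_error(self):
        a = pd.Series([1.0], index=[1.0])
        b = pd.Series([1.0], index=[3.0])
        with pytest.raises(ValueError, match="days"):
            s.priming_effect(a, b)

    def test_negative_priming_permitted(self):
        a = pd.Series([0.5], index=[1.0])
        b = pd.Series([1.0], index=[1.0])
        assert s.priming_effect(a, b).iloc[0] == -0.5


class TestPartitionTable:
    def test_conservation_on_full_dataset(self, pipeline_result):
        part = pipeline_result["partitioned"]
        assert (part["c3"] + part["c4"] - part["ct"]).abs().max() < 1e-12

    def test_unamended_cores_are_single_pool(self, pipeline_result):
        un = pipeline_result["partitioned"].query("~sucrose")
        assert (un["c4"] == 0).all()

    def test_baseline_prefers_matched_unamended_cores(self, zero_noise_dataset):
        """With biochar-shifted unamended δt, the effective δ3 follows it."""
        iso = zero_noise_dataset["isotopes"].copy()
        shift = 1.5
        mask = ~iso["sucrose"] & (iso["site"] == "Cambisol")
        iso.loc[mask, "delta_t_permil"] += shift
        res = s.run_pipeline(zero_noise_dataset["traps"], iso)
        part = res["partitioned"]
        cam = part.query("sucrose and site == 'Cambisol'")
        assert cam["delta3_effective"].unique() == pytest.approx(-26.36 + shift)
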
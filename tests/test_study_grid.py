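import math

import pytest
from hypothesis import given, settings, strategies as st

from bmhvflow import (CaseSpec, GridConfig, PhysicalProperties,
                      enumerate_cases, nondimensional_summary,
                      reynolds_number, stenosis_area_reduction,
                      valve_area_restriction, womersley_number)
from bmhvflow.errors import ConfigurationError, DomainError


class TestEnumerateCases:
    def test_default_grid_has_45_cases(self):
        assert len(enumerate_cases()) == 45

    def test_15_cases_per_cardiac_output(self):
        cases = enumerate_cases()
        for q in (3.0, 5.0, 7.0):
            assert sum(c.cardiac_output_l_min == q for c in cases) == 15

    def test_singleton_lists_give_one_case(self):
        cases = enumerate_cases(GridConfig((27.0,), (0.0,), (5.0,)))
        assert len(cases) == 1
        assert cases[0].case_id == "d27_f0_q5"

    def test_ordering_dysfunction_outer_flow_inner(self):
        cases = enumerate_cases()
        assert cases[0].case_id == "d27_f0_q3"
        assert cases[1].case_id == "d27_f0_q5"   # flow varies fastest
        assert cases[3].case_id == "d25_f0_q3"   # then diameter
        assert cases[15].case_id == "d27_f50_q3"  # dysfunction outermost
        assert len(set(c.case_id for c in cases)) == 45

    def test_value_outside_allowed_set_names_field(self):
        with pytest.raises(ConfigurationError, match="lvot_diameters_mm"):
            enumerate_cases(GridConfig((30.0,), (0.0,), (5.0,)))
        with pytest.raises(ConfigurationError, match="dysfunction_levels_pct"):
            enumerate_cases(GridConfig((27.0,), (25.0,), (5.0,)))
        with pytest.raises(ConfigurationError, match="non-empty"):
            enumerate_cases(GridConfig((), (0.0,), (5.0,)))

    @settings(deadline=None, max_examples=30)
    @given(nd=st.integers(1, 5), nf=st.integers(1, 3), nq=st.integers(1, 3))
    def test_size_is_product_of_list_lengths(self, nd, nf, nq):
        cfg = GridConfig((27.0, 25.0, 23.0, 21.0, 19.0)[:nd],
                         (0.0, 50.0, 100.0)[:nf], (3.0, 5.0, 7.0)[:nq])
        assert len(enumerate_cases(cfg)) == nd * nf * nq


class TestStenosisAreaReduction:
    def test_reference_diameter_has_no_reduction(self):
        assert stenosis_area_reduction(27.0) == 0.0

    def test_19mm_is_half_area_reduction(self):
        # the most severe tunnel stenosis removes ~50% of the circular area
        assert round(stenosis_area_reduction(19.0), 3) == 0.505
        assert round(100 * stenosis_area_reduction(19.0)) == 50

    def test_23mm_derived_value(self):
        assert stenosis_area_reduction(23.0) == pytest.approx(1 - (23 / 27) ** 2)

    def test_strictly_decreasing_in_diameter(self):
        ds = [d / 2.0 for d in range(2, 55)]
        vals = [stenosis_area_reduction(d) for d in ds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [0.0, -1.0, 27.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            stenosis_area_reduction(bad)


class TestValveAreaRestriction:
    @pytest.mark.parametrize("pct,expected", [(0.0, 0.0), (50.0, 0.25), (100.0, 0.5)])
    def test_one_leaflet_halves_the_total_restriction(self, pct, expected):
        assert valve_area_restriction(pct) == expected

    def test_linear_and_bounded(self):
        vals = [valve_area_restriction(p) for p in range(0, 101, 5)]
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        assert all(d == pytest.approx(diffs[0]) for d in diffs)
        assert all(0.0 <= v <= 0.5 for v in vals)

    @pytest.mark.parametrize("bad", [-1.0, 101.0])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            valve_area_restriction(bad)


class TestNondimensional:
    def test_reynolds_blood_unit_velocity(self):
        assert reynolds_number(1.0, 0.027) == pytest.approx(8177, rel=1e-3)

    def test_reynolds_zero_velocity_and_linearity(self):
        assert reynolds_number(0.0, 0.027) == 0.0
        assert reynolds_number(2.0, 0.01) == pytest.approx(2 * reynolds_number(1.0, 0.01))

    def test_womersley_blood_at_70bpm(self):
        # standard definition R*sqrt(omega/nu) with the 13.5 mm valve radius
        assert womersley_number(0.0135, 70.0) == pytest.approx(20.1, abs=0.05)

    def test_womersley_scaling_and_limits(self):
        base = womersley_number(0.01, 70.0, PhysicalProperties())
        thick = PhysicalProperties(density=1060.0, dynamic_viscosity=4 * 0.0035)
        assert womersley_number(0.01, 70.0, thick) == pytest.approx(base / 2.0)
        assert womersley_number(0.0, 70.0) == 0.0

    def test_case_summary_orderings(self):
        s = nondimensional_summary(CaseSpec(27.0, 0.0, 5.0))
        assert s.re_peak >= s.re_mean >= 0
        assert s.womersley_alpha > 0
        # peak/mean ratio follows the half-sine waveform shape
        ratio = (60 / 70) / 0.3 * math.pi / 2.0
        assert s.re_peak / s.re_mean == pytest.approx(ratio)


class TestCaseSpec:
    def test_rejects_off_grid_values(self):
        with pytest.raises(ConfigurationError):
            CaseSpec(26.0, 0.0, 5.0)
        with pytest.raises(ConfigurationError):
            CaseSpec(27.0, 30.0, 5.0)
        with pytest.raises(ConfigurationError):
            CaseSpec(27.0, 0.0, 4.0)

    def test_systole_must_fit_in_cycle(self):
        with pytest.raises(ConfigurationError):
            CaseSpec(27.0, 0.0, 5.0, heart_rate_bpm=70.0, systole_duration_s=0.9)
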
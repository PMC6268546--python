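import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pampa_skin.permeability_core import (
    KpRegression,
    aggregate_triplicates,
    analyze_measurement,
    effective_permeability,
    log_kp_from_log_pe,
    permeation_parameter,
    retention_factor,
    round_half_up,
)
from pampa_skin.plate_model import (
    AssayGeometry,
    PermeabilityResult,
    PlateValidationError,
    WellMeasurement,
)
from pampa_skin.synthetic_data import SimulationParams, simulate_well_timecourse


def _well(c_d0=1e-7, c_dt=5e-8, c_at=2e-8, cid="X", rid="1"):
    return WellMeasurement(cid, rid, C_D0=c_d0, C_Dt=c_dt, C_At=c_at)


class TestRetentionFactor:
    def test_equal_volume_mass_balance(self, geometry):
        m = _well(c_dt=0.4e-7, c_at=0.2e-7)
        r = retention_factor(m, geometry, volume_mode="equal")
        assert r.value == pytest.approx(0.4, rel=1e-12)
        assert not r.clamped

    def test_actual_volume_mass_balance(self, geometry):
        m = _well(c_dt=0.5e-7, c_at=0.21e-7)
        r = retention_factor(m, geometry, volume_mode="actual")
        assert r.value == pytest.approx(1 - 0.5 - (4 / 3) * 0.21, rel=1e-9)

    def test_simulator_round_trip(self, geometry):
        p = SimulationParams(Pe_true=2e-5, R_true=0.35, geometry=geometry)
        c_dt, c_at = simulate_well_timecourse(p, geometry.t_incubation)
        m = _well(c_d0=geometry.C_D0_nominal, c_dt=c_dt, c_at=c_at)
        r = retention_factor(m, geometry, volume_mode="actual")
        assert r.value == pytest.approx(0.35, abs=1e-9)

    @pytest.mark.parametrize("c_dt_ratio, expect_value", [
        (1.02, 0.0),   # slightly negative raw R from noise -> clamp to 0
    ])
    def test_clamp_band(self, geometry, c_dt_ratio, expect_value):
        m = _well(c_dt=c_dt_ratio * 1e-7, c_at=0.0)
        r = retention_factor(m, geometry, volume_mode="actual")
        assert r.value == expect_value
        assert r.clamped

    def test_gross_imbalance_raises(self, geometry):
        m = _well(c_dt=1.2e-7, c_at=0.0)  # raw R = -0.2, far past the band
        with pytest.raises(PlateValidationError):
            retention_factor(m, geometry)


class TestPermeationParameter:
    @pytest.mark.parametrize("c_at, expected", [
        (0.0, 0.0),
        (1e-7, 1.0),
        (7.7e-9, 0.077),  # the reference potent-standard permeation level
    ])
    def test_fraction_of_initial_donor(self, c_at, expected):
        assert permeation_parameter(_well(c_at=c_at)) == pytest.approx(expected)


class TestEffectivePermeability:
    def test_no_transfer_gives_zero(self, geometry):
        assert effective_permeability(0.0, 0.2, geometry) == 0.0

    def test_equal_volume_closed_form(self, geometry):
        # V = 0.3 cm^3, A_eff = 0.196 cm^2, t' = 24000 s, R = 0, perm = 0.25
        # -> Pe = (V / (2 A_eff t')) * ln 2 = 2.2103e-5 cm/s, log Pe = -4.6555
        g = geometry.with_overrides(V_A=0.3, V_D=0.3)
        pe = effective_permeability(0.25, 0.0, g, volume_mode="equal")
        expected = 0.3 / (2 * 0.196 * 24000) * math.log(2)
        assert pe == pytest.approx(expected, rel=1e-12)
        assert pe == pytest.approx(2.2103e-5, rel=1e-4)
        assert math.log10(pe) == pytest.approx(-4.6555, abs=1e-4)

    def test_against_numerical_ode(self, geometry):
        """Pe inverted from a numerically integrated two-compartment model."""
        g = geometry
        pe_true, r_true = 2.2103e-5, 0.15

        def rhs(_t, y):
            c_d, c_a = y
            flux = pe_true * g.A_eff * (c_d - c_a)
            return [-flux / g.V_D, flux / g.V_A]

        sol = solve_ivp(
            rhs, (0.0, g.t_transport),
            [(1 - r_true) * g.C_D0_nominal, 0.0],
            rtol=1e-12, atol=1e-22)
        c_at = sol.y[1, -1]
        perm = c_at / g.C_D0_nominal
        pe = effective_permeability(perm, r_true, g, volume_mode="actual")
        assert pe == pytest.approx(pe_true, rel=1e-8)

    def test_equilibrium_is_flagged_undefined(self, geometry):
        r = 0.2
        perm_eq = (1 - r) * geometry.V_D / (geometry.V_A + geometry.V_D)
        assert effective_permeability(perm_eq, r, geometry) is None
        assert effective_permeability(perm_eq * 1.01, r, geometry) is None

    def test_invalid_inputs(self, geometry):
        with pytest.raises(PlateValidationError):
            effective_permeability(0.1, 1.0, geometry)  # fully retained
        with pytest.raises(PlateValidationError):
            effective_permeability(-0.1, 0.2, geometry)
        with pytest.raises(PlateValidationError):
            effective_permeability(0.1, -0.01, geometry)

    @given(
        perm=st.floats(1e-6, 0.2),
        delta=st.floats(1e-6, 0.05),
        r=st.floats(0.0, 0.6),
    )
    def test_monotone_in_permeation_and_retention(self, perm, delta, r):
        g = AssayGeometry()
        lo = effective_permeability(perm, r, g)
        hi = effective_permeability(perm + delta, r, g)
        assert hi > lo
        # at fixed perm > 0, more retention implies faster transport
        hi_r = effective_permeability(perm, min(r + delta, 0.9), g)
        assert hi_r > lo

    @given(
        perm=st.floats(0.0, 0.3),
        r=st.floats(0.0, 0.35),
        v=st.floats(0.05, 1.0),
    )
    def test_modes_agree_at_equal_volumes(self, perm, r, v):
        g = AssayGeometry(V_A=v, V_D=v)
        assume(1 - 2 * perm / (1 - r) > 1e-9)
        a = effective_permeability(perm, r, g, volume_mode="actual")
        e = effective_permeability(perm, r, g, volume_mode="equal")
        assert a == pytest.approx(e, rel=1e-12)


class TestLogKp:
    @pytest.mark.parametrize("log_pe, expected_2dp", [
        (-4.10, -5.21),
        (-5.26, -6.77),
        (-5.99, -7.75),
        (-5.01, -6.43),
        (-6.23, -8.07),
        (-5.07, -6.51),
        (-5.68, -7.33),
        (0.0, 0.28),
    ])
    def test_regression_reproduces_printed_values(self, log_pe, expected_2dp):
        assert round_half_up(log_kp_from_log_pe(log_pe)) == expected_2dp

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            KpRegression(slope=0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            log_kp_from_log_pe(float("nan"))

    def test_round_half_up_ties(self):
        assert round_half_up(1.005) == 1.01
        assert round_half_up(-1.005) == -1.01  # ties away from zero


def _result(cid, rid, log_pe, r=0.2, perm=0.1):
    pe = None if log_pe is None else 10 ** log_pe
    return PermeabilityResult(
        compound_id=cid, replicate_id=rid, R=r, perm_param=perm, Pe=pe,
        log_Pe=log_pe,
        log_Kp=None if log_pe is None else log_kp_from_log_pe(log_pe))


class TestAggregation:
    def test_mean_and_sample_sd(self):
        results = [_result("X", str(i), lp)
                   for i, lp in enumerate((-4.6, -4.7, -4.6))]
        (s,) = aggregate_triplicates(results)
        assert s.logPe_mean == pytest.approx(-4.63333333, abs=1e-6)
        assert s.logPe_sd == pytest.approx(0.05774, abs=1e-5)
        assert s.logKp_mean == pytest.approx(
            log_kp_from_log_pe(s.logPe_mean))

    def test_single_replicate_has_no_sd(self):
        (s,) = aggregate_triplicates([_result("X", "1", -5.0)])
        assert s.n_replicates == 1
        assert s.R_sd is None and s.perm_sd is None and s.logPe_sd is None

    def test_noise_free_triplicates_have_zero_sd(self, geometry):
        p = SimulationParams(Pe_true=3e-5, R_true=0.5, geometry=geometry)
        c_dt, c_at = simulate_well_timecourse(p, geometry.t_incubation)
        results = [
            analyze_measurement(
                _well(geometry.C_D0_nominal, c_dt, c_at, rid=str(i)), geometry)
            for i in range(3)
        ]
        (s,) = aggregate_triplicates(results)
        assert s.logPe_sd == 0.0
        assert s.R_sd == 0.0
        assert 10 ** s.logPe_mean == pytest.approx(3e-5, rel=1e-9)
        assert s.R_mean == pytest.approx(0.5, abs=1e-12)

    def test_undefined_pe_counted_but_excluded(self):
        results = [_result("X", "1", -5.0), _result("X", "2", None)]
        (s,) = aggregate_triplicates(results)
        assert s.n_replicates == 2
        assert s.n_pe_defined == 1
        assert s.logPe_mean == pytest.approx(-5.0)
        assert s.logPe_sd is None  # only one usable replicate

    def test_all_undefined_yields_undefined_summary(self, caplog):
        results = [_result("X", "1", None), _result("X", "2", None)]
        (s,) = aggregate_triplicates(results)
        assert s.logPe_mean is None and s.logKp_mean is None
        assert s.n_pe_defined == 0

    def test_compound_order_follows_first_appearance(self):
        results = [_result("B", "1", -5.0), _result("A", "1", -5.0),
                   _result("B", "2", -5.1)]
        summaries = aggregate_triplicates(results)
        assert [s.compound_id for s in summaries] == ["B", "A"]


class TestGridRoundTrip:
    def test_pipeline_inverts_simulator_on_grid(self, geometry):
        """Noise-free simulate -> analyze recovers (Pe, R) to 1e-9 rel error."""
        for pe_true in np.logspace(-7, -4, 10):
            for r_true in np.linspace(0.0, 0.9, 10):
                p = SimulationParams(Pe_true=pe_true, R_true=r_true,
                                     geometry=geometry)
                c_dt, c_at = simulate_well_timecourse(p, geometry.t_incubation)
                m = _well(geometry.C_D0_nominal, c_dt, c_at)
                res = analyze_measurement(m, geometry, volume_mode="actual")
                assert res.Pe == pytest.approx(pe_true, rel=1e-9)
                assert res.R == pytest.approx(r_true, rel=1e-9, abs=1e-12)


class TestMassConservation:
    @given(
        pe=st.floats(1e-7, 1e-4),
        r=st.floats(0.0, 0.95),
        t=st.floats(0.0, 25200.0),
    )
    def test_moles_balance_at_all_times(self, pe, r, t):
        g = AssayGeometry()
        p = SimulationParams(Pe_true=pe, R_true=r, geometry=g)
        c_dt, c_at = simulate_well_timecourse(p, t)
        total = c_dt * g.V_D + c_at * g.V_A + r * g.C_D0_nominal * g.V_D
        assert total == pytest.approx(g.C_D0_nominal * g.V_D, rel=1e-12)
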
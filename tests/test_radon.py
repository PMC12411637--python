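"""Radon physics chain: exhalation, indoor balance, transient, dose."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import normdose as nd
from normdose.errors import ValidationError
from normdose.units import per_hour_to_per_second


@pytest.fixture
def dry_nodules() -> nd.RadonMaterialProps:
    return nd.RadonMaterialProps(c_ra226=2317)


@pytest.fixture
def cargo_hold() -> nd.RadonEnvironment:
    # 10 m x 90 m hold footprint, 5 m head space above the nodule surface
    return nd.RadonEnvironment(
        volume=4500, exhaling_area=900, ventilation_rate=per_hour_to_per_second(1)
    )


class TestExhalation:
    def test_dry_nodule_flux(self, dry_nodules):
        """Thick-layer diffusive flux of dry nodules is about 10 Bq/(m2 s)."""
        assert dry_nodules.d_bulk == pytest.approx(6e-6)
        p = nd.exhalation_rate(dry_nodules)
        assert p == pytest.approx(9.7707, abs=1e-3)
        assert round(p) == 10

    def test_no_emanation_no_flux(self):
        m = nd.RadonMaterialProps(c_ra226=2317, emanation=0.0)
        assert nd.exhalation_rate(m) == 0.0

    def test_sqrt_diffusion_scaling(self, dry_nodules):
        """Quadrupling D_bulk (via porosity-equivalent d_ma) doubles P."""
        quadrupled = nd.RadonMaterialProps(c_ra226=2317, d_ma=4e-5)
        assert nd.exhalation_rate(quadrupled) == pytest.approx(
            2 * nd.exhalation_rate(dry_nodules), rel=1e-12
        )

    def test_wet_material_halves_concentration(self, dry_nodules, cargo_hold):
        """Saturated nodules exhale about half as much; the surface-driven
        steady-state concentration halves with the exhalation rate."""
        p_dry = nd.exhalation_rate(dry_nodules)
        c_dry = nd.steady_state_concentration(
            nd.entry_rate_surface(p_dry, cargo_hold), cargo_hold
        )
        c_wet = nd.steady_state_concentration(
            nd.entry_rate_surface(p_dry / 2, cargo_hold), cargo_hold
        )
        assert c_wet == pytest.approx(c_dry / 2, rel=1e-12)

    def test_invalid_props_rejected(self):
        with pytest.raises(ValidationError):
            nd.RadonMaterialProps(c_ra226=-1)
        with pytest.raises(ValidationError):
            nd.RadonMaterialProps(c_ra226=1, emanation=1.5)
        with pytest.raises(ValidationError):
            nd.RadonMaterialProps(c_ra226=1, porosity=0.0)


class TestEntryRates:
    def test_cargo_hold_surface_entry(self, dry_nodules, cargo_hold):
        """P x A / V with a 900 m2 exhaling surface into 4500 m3: ~2 Bq/(m3 s)."""
        e = nd.entry_rate_surface(nd.exhalation_rate(dry_nodules), cargo_hold)
        assert e == pytest.approx(1.954, abs=1e-3)

    def test_zero_area(self, dry_nodules):
        env = nd.RadonEnvironment(volume=100, exhaling_area=0, ventilation_rate=0)
        assert nd.entry_rate_surface(10.0, env) == 0.0

    def test_inverse_volume_scaling(self, cargo_hold):
        doubled = nd.RadonEnvironment(
            volume=2 * cargo_hold.volume,
            exhaling_area=cargo_hold.exhaling_area,
            ventilation_rate=cargo_hold.ventilation_rate,
        )
        assert nd.entry_rate_surface(10.0, doubled) == pytest.approx(
            nd.entry_rate_surface(10.0, cargo_hold) / 2
        )

    def test_comminution_source_term(self, nodules):
        """0.3 of the stored radon released at 95 kg/s: R ~ 66 kBq/s;
        half of it into a 45,000 m3 hall gives ~0.73 Bq/(m3 s)."""
        hall = nd.RadonEnvironment(
            volume=45000, exhaling_area=3000,
            ventilation_rate=per_hour_to_per_second(10),
        )
        r, e = nd.entry_rate_comminution(
            nodules, nd.ComminutionSource(pc_kg_s=95), hall
        )
        assert r == pytest.approx(66034.5)
        assert round(r / 1000) == 66
        assert e == pytest.approx(r * 0.5 / 45000, rel=1e-12)

    def test_zero_release_fraction(self, nodules):
        hall = nd.RadonEnvironment(volume=100, exhaling_area=1, ventilation_rate=0)
        r, e = nd.entry_rate_comminution(
            nodules, nd.ComminutionSource(pc_kg_s=95, f_com=0.0), hall
        )
        assert r == 0.0 and e == 0.0

    def test_missing_ra226(self):
        v = nd.NuclideVector({"Th-232": 100.0})
        hall = nd.RadonEnvironment(volume=100, exhaling_area=1, ventilation_rate=0)
        with pytest.raises(nd.MissingNuclideError):
            nd.entry_rate_comminution(v, nd.ComminutionSource(pc_kg_s=95), hall)


class TestSteadyState:
    @pytest.mark.parametrize(
        "vent_per_h,expected,rel",
        [(1, 7000, 0.05), (24, 300, 0.05)],
    )
    def test_cargo_hold_concentrations(self, dry_nodules, vent_per_h, expected, rel):
        """Natural ventilation (1/h) accumulates ~7000 Bq/m3 in the head
        space; opening the hold (24/h) brings it down to ~300 Bq/m3."""
        env = nd.RadonEnvironment(
            volume=4500, exhaling_area=900,
            ventilation_rate=per_hour_to_per_second(vent_per_h),
        )
        e = nd.entry_rate_surface(nd.exhalation_rate(dry_nodules), env)
        assert nd.steady_state_concentration(e, env) == pytest.approx(expected, rel=rel)

    def test_production_hall_concentration(self, nodules):
        """66 kBq/s source, half indoors, 45,000 m3 hall at 10 air changes
        per hour: ~264 Bq/m3."""
        hall = nd.RadonEnvironment(
            volume=45000, exhaling_area=3000,
            ventilation_rate=per_hour_to_per_second(10),
        )
        _, e = nd.entry_rate_comminution(nodules, nd.ComminutionSource(pc_kg_s=95), hall)
        assert round(nd.steady_state_concentration(e, hall)) == 264

    def test_no_sink_rejected(self):
        env = nd.RadonEnvironment(volume=100, exhaling_area=1, ventilation_rate=0)
        object.__setattr__(env, "lambda_rn", 0.0)  # force degenerate sink
        with pytest.raises(ValidationError):
            nd.steady_state_concentration(1.0, env)

    def test_ventilation_limits(self):
        """v -> infinity flushes the room to ~0; v = 0 accumulates to the
        decay-limited maximum e'/lambda."""
        closed = nd.RadonEnvironment(volume=100, exhaling_area=10, ventilation_rate=0.0)
        assert nd.steady_state_concentration(2.0, closed) == pytest.approx(
            2.0 / nd.LAMBDA_RN222
        )
        gale = nd.RadonEnvironment(volume=100, exhaling_area=10, ventilation_rate=1e3)
        assert nd.steady_state_concentration(2.0, gale) < 0.01

    def test_strictly_decreasing_in_ventilation(self):
        rates = [per_hour_to_per_second(v) for v in (0.5, 1, 2, 5, 10, 24)]
        concs = [
            nd.steady_state_concentration(
                2.0, nd.RadonEnvironment(volume=1, exhaling_area=1, ventilation_rate=v)
            )
            for v in rates
        ]
        assert all(a > b for a, b in zip(concs, concs[1:]))


class TestTransient:
    def test_initial_condition(self, cargo_hold):
        assert nd.transient_concentration(2.0, cargo_hold, c0=123.0, t_s=0.0) == 123.0

    def test_relaxation_to_steady_state(self, cargo_hold):
        """After ten time constants the solution is within 0.005% of the
        steady state."""
        k = cargo_hold.lambda_rn + cargo_hold.ventilation_rate
        c_inf = nd.steady_state_concentration(2.0, cargo_hold)
        c = nd.transient_concentration(2.0, cargo_hold, c0=0.0, t_s=10.0 / k)
        assert c == pytest.approx(c_inf, rel=5e-5)

    def test_pure_decay_closed_form(self):
        """No source, no ventilation: C(t) = c0 exp(-lambda t)."""
        env = nd.RadonEnvironment(volume=1, exhaling_area=0, ventilation_rate=0.0)
        t = 3.0 / nd.LAMBDA_RN222
        c = nd.transient_concentration(0.0, env, c0=500.0, t_s=t)
        assert c == pytest.approx(500.0 * np.exp(-3.0), rel=1e-12)

    def test_negative_time_rejected(self, cargo_hold):
        with pytest.raises(ValidationError):
            nd.transient_concentration(2.0, cargo_hold, c0=0.0, t_s=-1.0)

    def test_against_numerical_integrator(self):
        """Closed-form solution matches a tight-tolerance ODE integration
        of dC/dt = e' + v*C_a - (lambda + v) C to better than 1e-6
        relative error, including a non-zero outdoor concentration."""
        env = nd.RadonEnvironment(
            volume=4500, exhaling_area=900,
            ventilation_rate=per_hour_to_per_second(2),
            outdoor_concentration=10.0,
        )
        e_prime, c0 = 1.5, 50.0
        times = np.linspace(0.0, 4 * 3600.0, 9)

        def rhs(_t, c):
            return (
                e_prime
                + env.ventilation_rate * env.outdoor_concentration
                - (env.lambda_rn + env.ventilation_rate) * c
            )

        numeric = solve_ivp(
            rhs, (0.0, times[-1]), [c0], t_eval=times, rtol=1e-11, atol=1e-12
        ).y[0]
        analytic = nd.transient_concentration(e_prime, env, c0=c0, t_s=times)
        assert np.allclose(analytic, numeric, rtol=1e-6)


class TestRadonDose:
    def test_reference_workplace_dose(self):
        """300 Bq/m3 for 2000 h at F = 0.4 with the ICRP-65-consistent
        conversion factor: 1.87 mSv/a."""
        dose = nd.radon_dose(nd.RadonDoseConfig(c_rn_bq_m3=300, t_exp_h=2000))
        assert round(dose, 2) == 1.87

    def test_zero_exposure(self):
        assert nd.radon_dose(nd.RadonDoseConfig(c_rn_bq_m3=300, t_exp_h=0)) == 0.0

    def test_ordinance_unit_algebra(self):
        """A cumulative exposure of 0.32 MBq h/m3 corresponds to 1 mSv:
        0.32e6 x 0.4 x 7.8e-6 = 0.9984 (unit-algebra oracle for the
        regulatory equivalence the default DCF is calibrated against)."""
        dose = nd.radon_dose(nd.RadonDoseConfig(c_rn_bq_m3=0.32e6, t_exp_h=1.0))
        assert dose == pytest.approx(1.0, rel=2e-3)

    @given(
        c=st.floats(min_value=0, max_value=1e5),
        t=st.floats(min_value=0, max_value=8760),
        f=st.floats(min_value=0, max_value=1),
        k=st.floats(min_value=0, max_value=10),
    )
    def test_linearity_in_every_parameter(self, c, t, f, k):
        base = nd.radon_dose(nd.RadonDoseConfig(c, t, f))
        assert nd.radon_dose(nd.RadonDoseConfig(c * k, t, f)) == pytest.approx(
            k * base, rel=1e-9, abs=1e-12
        )
        assert nd.radon_dose(nd.RadonDoseConfig(c, t * k, f)) == pytest.approx(
            k * base, rel=1e-9, abs=1e-12
        )

    def test_icrp137_alternative_is_larger_but_not_default(self):
        assert nd.DCF_RADON_ICRP137 > nd.DCF_RADON_ICRP65
        assert nd.RadonDoseConfig(1, 1).dcf == nd.DCF_RADON_ICRP65
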
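"""Boussinesq solver: formula oracles, equilibrium, physics sanity.

The heavier physics benchmarks (dispersion sweep, mass conservation,
solitary-wave run-up, roughness monotonicity across a kn grid) live in
tests/test_acceptance.py; here the solver is exercised at unit scale.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reefshield import boussiflow as bf
from reefshield import roughness, synthgen


class TestFrictionFactor:
    def test_value_at_unit_relative_roughness(self):
        assert bf.friction_factor(1.0, 1.0) == pytest.approx(
            np.exp(-0.764), abs=1e-6
        )

    def test_smooth_limit(self):
        # kn/a0 -> 0: f_w -> exp(-5.977)
        assert bf.friction_factor(1e-30, 1.0) == pytest.approx(
            np.exp(-5.977), rel=1e-4
        )

    def test_capped_beyond_unit_ratio(self):
        assert bf.friction_factor(5.0, 1.0) == bf.friction_factor(1.0, 1.0)

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_kn(self, k1, k2):
        lo, hi = sorted((k1, k2))
        assert bf.friction_factor(lo, 1.0) <= bf.friction_factor(hi, 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bf.friction_factor(0.0, 1.0)


class TestBedShear:
    def test_zero_velocity(self):
        assert bf.bed_shear(0.0, 0.1) == 0.0

    def test_odd_symmetry(self):
        assert bf.bed_shear(-2.0, 0.1) == -bf.bed_shear(2.0, 0.1)

    def test_reference_value(self):
        assert bf.bed_shear(1.0, 0.1, rho=1025.0) == pytest.approx(51.25)


class TestStockdon:
    def test_reference_value(self):
        assert bf.stockdon_runup(2.0, 100.0, 0.1) == pytest.approx(1.31, abs=0.01)

    def test_vanishing_wave(self):
        assert bf.stockdon_runup(0.0, 100.0, 0.1) == 0.0

    def test_monotone_in_height(self):
        r = [bf.stockdon_runup(h, 100.0, 0.1) for h in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(r) > 0)


class TestR2Percent:
    def test_equal_maxima(self):
        assert bf.r2_percent(np.full(100, 1.0)) == (1.0, False)

    def test_linear_interpolation_convention(self):
        r2, low = bf.r2_percent(np.arange(1.0, 101.0))
        assert r2 == pytest.approx(98.02)
        assert not low

    @given(st.permutations(list(range(60))))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        base = bf.r2_percent(np.arange(60.0))[0]
        assert bf.r2_percent(np.array(perm, dtype=float))[0] == base

    def test_low_confidence_flag_and_empty(self):
        assert bf.r2_percent(np.ones(10))[1] is True
        with pytest.raises(ValueError):
            bf.r2_percent(np.array([]))


class TestDispersionRelation:
    def test_shallow_limit(self):
        c = bf.boussinesq_phase_speed(0.01, 5.0)
        assert c == pytest.approx(np.sqrt(9.81 * 5.0), rel=1e-4)

    def test_matches_pade_form(self):
        d, om = 10.0, 0.8
        c = bf.boussinesq_phase_speed(om, d)
        k = om / c
        kd2 = (k * d) ** 2
        lhs = om**2
        rhs = 9.81 * d * k**2 * (1 + kd2 / 15) / (1 + (1 / 15 + 1 / 3) * kd2)
        assert lhs == pytest.approx(rhs, rel=1e-8)


def _flat_model(n=101, depth=2.0, **cfg_kw):
    x = np.arange(n) * 1.0
    cfg = bf.ModelConfig(friction=False, breaking=False, **cfg_kw)
    return bf.BoussinesqModel(x, np.full(n, depth), 1e-4, config=cfg)


class TestSolverBasics:
    def test_still_water_equilibrium(self, desk_bathymetry):
        """No forcing: a state of rest stays at rest to machine precision."""
        m = bf.BoussinesqModel(
            desk_bathymetry.x, -desk_bathymetry.z, 0.1,
            config=bf.ModelConfig(friction=False),
        )
        for _ in range(100):
            m.step()
        assert np.max(np.abs(m.zeta - np.where(m.d > 0, 0, -m.d))) == 0.0
        assert np.max(np.abs(m.P)) == 0.0

    def test_calm_state_breaking_terms_zero(self):
        m = _flat_model()
        delta, E = bf.breaking_terms(m)
        assert np.all(delta == 0.0)
        assert np.all(E == 0.0)

    def test_constant_velocity_no_eddy_viscosity(self):
        m = _flat_model()
        m.swash[:] = True
        m.P[:] = 0.5  # uniform flux: dU/dx = 0 -> nu_e = 0
        _, E = bf.breaking_terms(m)
        assert np.allclose(E[2:-2], 0.0)

    def test_instability_detector(self):
        m = _flat_model()
        m.zeta[:] = 1e4
        m.q = m._apply_operator(m.P)
        with pytest.raises(bf.SolverInstability):
            for _ in range(30):
                m.step()

    def test_step_function_wrapper(self):
        m = _flat_model()
        t0 = m.t
        out = bf.step(m)
        assert out is m and m.t > t0


class TestRunSimulation:
    def test_small_amplitude_flat_flume_conserves_flux(self):
        """Tiny non-breaking waves, friction off: dissipated fraction ~ 0."""
        x = np.arange(321) * 1.0
        z = np.full(321, -6.0)
        z[-40:] = -6.0 + 0.15 * np.arange(40)  # gentle beach to close the flume
        labels = np.full(321, "fore_reef", dtype=object)
        labels[:200] = "fore_reef"
        labels[200:281] = "sand"
        labels[281:] = "beach"
        bathy = synthgen.BathymetryProfile(
            x=x, z=z, section_labels=np.asarray(labels, dtype=str)
        )
        cfg = bf.ModelConfig(friction=False, breaking=False)
        res = bf.run_simulation(bathy, 1e-4, 0.1, 8.0, duration=240.0, seed=1, config=cfg)
        assert res.dissipated_fraction < 0.1

    def test_friction_reduces_runup(self, desk_bathymetry):
        """Same forcing, rougher bed: R_2% strictly smaller."""
        r = [
            bf.run_simulation(
                desk_bathymetry, kn, 2.0, 12.0, duration=120.0, seed=9
            ).r2
            for kn in (0.02, 0.6)
        ]
        assert r[1] < r[0]

    def test_determinism(self, desk_bathymetry):
        a = bf.run_simulation(desk_bathymetry, 0.1, 1.5, 10.0, duration=60.0, seed=4)
        b = bf.run_simulation(desk_bathymetry, 0.1, 1.5, 10.0, duration=60.0, seed=4)
        assert a.r2 == b.r2
        np.testing.assert_array_equal(a.hs_x, b.hs_x)

    def test_energy_flux_bookkeeping(self):
        """Non-breaking waves over a rough flat: flux loss ~ friction work."""
        n = 361
        x = np.arange(n) * 1.0
        # shallow drop after the generation pad places the toe station on
        # the rough flat, clear of the sponge
        z = np.where(x < 150, -4.3, -4.0)
        z[150:165] = np.linspace(-4.3, -4.0, 15)
        z[-30:] = -4.0 + 0.2 * np.arange(30)
        labels = np.full(n, "fore_reef", dtype=object)
        labels[200:331] = "sand"
        labels[331:] = "beach"
        bathy = synthgen.BathymetryProfile(
            x=x, z=z, section_labels=np.asarray(labels, dtype=str)
        )
        cfg = bf.ModelConfig(breaking=False)
        res = bf.run_simulation(bathy, 0.3, 0.5, 10.0, duration=300.0, seed=2, config=cfg)
        i0, i1 = res.i_toe, res.i_inner
        flux_loss = res.flux_x[i0] - res.flux_x[i1]
        work = np.sum(res.friction_work[i0:i1]) * 1.0  # dx = 1
        assert flux_loss == pytest.approx(work, rel=0.25)
        assert flux_loss > 0
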
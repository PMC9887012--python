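"""Hs-Tp copula, percentile conditions, and ensemble plumbing."""

import numpy as np
import pandas as pd
import pytest

from reefshield import climate, synthgen
from reefshield.boussiflow import SimulationResult
from reefshield.roughness import KnProfile


@pytest.fixture(scope="module")
def clim():
    return synthgen.generate_wave_climate(30, seed=3)  # rho = 0.5


@pytest.fixture(scope="module")
def copula(clim):
    return climate.fit_hs_tp_copula(clim)


class TestCopulaFit:
    def test_recovers_generator_rho(self, copula):
        assert copula.rho == pytest.approx(0.5, abs=0.05)

    def test_independent_pairs(self):
        c0 = synthgen.generate_wave_climate(
            30, config=synthgen.ClimateConfig(rho=0.0), seed=4
        )
        cop = climate.fit_hs_tp_copula(c0)
        assert abs(cop.tau) < 0.05

    def test_comonotone_limit(self):
        hs = np.sort(np.random.default_rng(0).weibull(1.8, 400)) + 0.1
        cm = synthgen.WaveClimate(
            table=pd.DataFrame(
                {"week_index": np.arange(400), "hs": hs, "tp": 5 + 2 * hs}
            )
        )
        cop = climate.fit_hs_tp_copula(cm)
        assert cop.tau > 0.95

    def test_degenerate_series_rejected(self):
        cm = synthgen.WaveClimate(
            table=pd.DataFrame(
                {"week_index": np.arange(200), "hs": np.ones(200), "tp": np.ones(200)}
            )
        )
        with pytest.raises(ValueError):
            climate.fit_hs_tp_copula(cm)


class TestBuildConditions:
    def test_full_scale_grid(self, clim, copula):
        conds = climate.build_conditions(clim, copula, 1000)
        assert len(conds) == 1000
        assert conds.percentile.iloc[0] == pytest.approx(0.1)
        assert conds.percentile.iloc[-1] == pytest.approx(100.0)
        assert np.all(np.diff(conds.hs) >= 0)
        assert conds.hs.iloc[-1] == clim.hs.max()

    def test_independence_gives_constant_tp(self, clim):
        cop = climate.HsTpCopula(
            rho=0.0, tau=0.0, hs_samples=clim.hs, tp_samples=clim.tp
        )
        conds = climate.build_conditions(clim, cop, 100)
        np.testing.assert_allclose(conds.tp, np.median(clim.tp))

    def test_positive_dependence_raises_tp_with_hs(self, clim, copula):
        conds = climate.build_conditions(clim, copula, 100)
        assert conds.tp.iloc[-1] > conds.tp.iloc[0]


def _surrogate_result(x, r2):
    hs_x = np.full(x.size, 1.0)
    return SimulationResult(
        x=x, hs_x=hs_x, runup=np.array([r2]), runup_dt=0.1, r2=r2,
        r2_low_confidence=False, flux_x=np.linspace(100, 40, x.size),
        incoming_flux=100.0, transmitted_flux=40.0, dissipated_fraction=0.6,
        friction_work=np.zeros(x.size), n_runup_maxima=60, duration=1.0,
    )


def _surrogate_solver(bathy, kn_prof, hs, tp, duration=0.0, seed=0, config=None):
    kn = np.mean(np.asarray(getattr(kn_prof, "kn", kn_prof), dtype=float))
    r2 = 0.4 * hs * np.exp(-kn) + 1e-4 * (seed % 97)
    return _surrogate_result(np.asarray(bathy.x, dtype=float), r2)


@pytest.fixture(scope="module")
def small(desk_bathymetry, clim, copula):
    conds = climate.build_conditions(clim, copula, 3)
    x = desk_bathymetry.x
    states = [
        KnProfile(x=x, kn=np.full(x.size, 0.05), state="healthy"),
        KnProfile(x=x, kn=np.full(x.size, 0.01), state="degraded"),
    ]
    return states, conds, desk_bathymetry


class TestRunEnsemble:

    def test_row_count_smoke(self, small):
        states, conds, bathy = small
        table = climate.run_ensemble(
            states, conds, bathy, seed=1, solver=_surrogate_solver
        )
        assert len(table) == 2 * 3
        assert not table.failed.any()

    def test_state_relabelling_permutes_not_changes(self, small):
        states, conds, bathy = small
        a = climate.run_ensemble(states, conds, bathy, seed=1, solver=_surrogate_solver)
        b = climate.run_ensemble(
            states[::-1], conds, bathy, seed=1, solver=_surrogate_solver
        )
        merged = a.merge(b, on=["state", "condition"], suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(merged.r2_a, merged.r2_b)

    def test_failed_run_logged_and_continues(self, small):
        states, conds, bathy = small

        hs_max = conds.hs.max()

        def flaky(bathy, kn_prof, hs, tp, **kw):
            if hs == hs_max:
                raise RuntimeError("synthetic blow-up")
            return _surrogate_solver(bathy, kn_prof, hs, tp, **kw)

        table = climate.run_ensemble(states, conds, bathy, seed=1, solver=flaky)
        assert len(table) == 6
        assert table.failed.sum() == 2
        assert table.loc[table.failed, "r2"].isna().all()

    def test_resume_skips_completed(self, small):
        states, conds, bathy = small
        first = climate.run_ensemble(
            [states[0]], conds, bathy, seed=1, solver=_surrogate_solver
        )

        def must_not_rerun(bathy, kn_prof, hs, tp, **kw):
            raise AssertionError("completed row was re-run")

        resumed = climate.run_ensemble(
            [states[0]], conds, bathy, seed=1, solver=must_not_rerun, resume=first
        )
        assert len(resumed) == len(first)


class TestEnergyAbsorption:
    def test_fraction_from_fluxes(self, desk_bathymetry):
        res = _surrogate_result(desk_bathymetry.x, 1.0)
        assert climate.energy_absorption(res) == pytest.approx(0.6)

    def test_fully_dissipated(self, desk_bathymetry):
        res = _surrogate_result(desk_bathymetry.x, 1.0)
        res.transmitted_flux = 0.0
        assert climate.energy_absorption(res) == 1.0

    def test_missing_diagnostics_rejected(self, desk_bathymetry):
        res = _surrogate_result(desk_bathymetry.x, 1.0)
        res.incoming_flux = None
        with pytest.raises(ValueError):
            climate.energy_absorption(res)
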
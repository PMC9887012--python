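"""Synthetic-input generators: survey trajectories, shapes, bathymetry, climate."""

import numpy as np
import pytest
from scipy import stats

from reefshield import reef3d, synthgen


class TestSurveyTable:
    def test_disturbance_trajectory_covers(self, survey):
        assert survey.total_cover(2005) == pytest.approx(0.50)
        assert survey.total_cover(2011) == pytest.approx(0.03)
        # recovery dominated by Pocillopora
        t2016 = survey.table[survey.table.year == 2016].set_index("taxon").cover
        assert t2016.idxmax() == "Pocillopora"

    def test_zero_cover_trajectory_is_empty(self):
        table = synthgen.generate_survey_table(
            disturbance_trajectory={2000: (0.0, (1, 1, 1))}, seed=0
        )
        assert table.total_cover(2000) == 0.0
        assert all(arr.size == 0 for arr in table.sizes.values())

    def test_invalid_cover_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_survey_table(
                disturbance_trajectory={2000: (1.4, (1, 1, 1))}
            )

    def test_sizes_positive_and_cover_bounded(self, survey):
        for arr in survey.sizes.values():
            assert np.all(arr > 0)
        for _, g in survey.table.groupby("year"):
            assert g.cover.sum() <= 1.0 + 1e-12

    def test_csv_round_trip(self, survey, tmp_path):
        survey.to_csv(tmp_path / "c.csv", tmp_path / "s.csv")
        back = synthgen.SurveyTable.from_csv(tmp_path / "c.csv", tmp_path / "s.csv")
        assert back.total_cover(2005) == pytest.approx(0.50)
        np.testing.assert_allclose(
            back.sizes[(2016, "Pocillopora")], survey.sizes[(2016, "Pocillopora")]
        )


class TestCoralShapes:
    @pytest.mark.parametrize("taxon", synthgen.TAXA)
    def test_bbox_contract(self, taxon):
        mesh = synthgen.generate_coral_shape(taxon, 0.2, 0.3, 0.1, seed=4)
        np.testing.assert_allclose(
            mesh.bounds[1] - mesh.bounds[0], [0.2, 0.3, 0.1], atol=1e-9
        )

    def test_hemisphere_proxy_area_ratio(self):
        # full hemisphere proxy (width = length = 2h): surface/footprint = 2;
        # the lobed Porites family sits within a few percent of the ideal
        mesh = synthgen.generate_coral_shape(
            "Porites", 0.4, 0.4, 0.2, seed=0, n_psi=200, n_theta=256
        )
        assert reef3d.rumple_index(mesh) == pytest.approx(2.0, abs=0.08)

    def test_seed_determinism(self):
        a = synthgen.generate_coral_shape("Pocillopora", 0.3, 0.3, 0.2, seed=11)
        b = synthgen.generate_coral_shape("Pocillopora", 0.3, 0.3, 0.2, seed=11)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_taxon_rumple_ordering(self):
        """Default shape families order Pocillopora > Acropora > Porites."""
        r = {
            t: reef3d.rumple_index(
                synthgen.generate_coral_shape(t, 0.3, 0.3, 0.2, seed=2, n_psi=96)
            )
            for t in synthgen.TAXA
        }
        assert r["Pocillopora"] > r["Acropora"] > r["Porites"]

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_coral_shape("Porites", 0.0, 0.2, 0.1)

    def test_bank_save_load(self, shape_bank, tmp_path):
        synthgen.save_shape_bank(shape_bank, tmp_path / "bank")
        back = synthgen.load_shape_bank(tmp_path / "bank")
        assert set(back) == set(synthgen.TAXA)
        assert len(back["Porites"]) == len(shape_bank["Porites"])


class TestBathymetry:
    def test_seaward_depth_and_labels(self):
        b = synthgen.generate_bathymetry()
        assert b.z[0] == pytest.approx(-20.0)
        assert np.all(np.diff(b.x) > 0)
        for lab in ("fore_reef", "reef_crest", "reef_flat", "sand", "beach"):
            idx = b.section(lab)
            assert idx.size > 0
            assert np.all(np.diff(idx) == 1)  # contiguous

    def test_crest_is_shallowest_reef_point(self):
        b = synthgen.generate_bathymetry()
        z_crest = b.z[b.section("reef_crest")]
        assert z_crest.max() == pytest.approx(
            b.z[b.section_labels != "beach"].max()
        )
        assert z_crest.max() > b.z[b.section("reef_flat")].max()

    def test_flat_bottom_degenerate_config(self):
        cfg = synthgen.BathymetryConfig(
            offshore_depth=5.0, crest_depth=5.0, flat_depth=5.0, offshore_pad=10.0
        )
        b = synthgen.generate_bathymetry(cfg)
        submerged = b.section_labels != "beach"
        np.testing.assert_allclose(b.z[submerged], -5.0)

    def test_non_monotone_config_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_bathymetry(
                synthgen.BathymetryConfig(crest_depth=3.0, flat_depth=1.0)
            )


class TestWaveClimate:
    def test_weekly_record_count(self):
        clim = synthgen.generate_wave_climate(30, seed=0)
        assert len(clim.table) == 1560

    def test_gaussian_copula_tau(self):
        clim = synthgen.generate_wave_climate(60, seed=1)  # rho = 0.5 default
        tau = stats.kendalltau(clim.hs, clim.tp).statistic
        assert tau == pytest.approx(1.0 / 3.0, abs=0.04)

    def test_independence(self):
        cfg = synthgen.ClimateConfig(rho=0.0)
        clim = synthgen.generate_wave_climate(30, config=cfg, seed=2)
        tau = stats.kendalltau(clim.hs, clim.tp).statistic
        assert abs(tau) < 0.05

    def test_invalid_dependence_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_wave_climate(1, config=synthgen.ClimateConfig(rho=1.0))

    def test_hs_marginal_ks(self):
        """Generated Hs follows the configured Weibull marginal (KS, a=0.01)."""
        cfg = synthgen.ClimateConfig()
        clim = synthgen.generate_wave_climate(30, config=cfg, seed=3)
        dist = synthgen._hs_marginal(cfg)
        p = stats.kstest(clim.hs, dist.cdf).pvalue
        assert p > 0.01


class TestPressureRecords:
    def test_burst_sample_count(self):
        rec = synthgen.generate_pressure_records(
            burst_seconds=900.0, rate_hz=4.0, n_bursts=2, seed=0
        )
        assert rec.pressure["A"].size == 2 * 3600  # 15 min at 4 Hz

    def test_negligible_roughness_conserves_flux(self):
        from reefshield.roughness import _band_flux_and_orbital

        rec = synthgen.generate_pressure_records(
            kn_true=1e-4, n_bursts=1, snr=0.0, seed=1
        )
        eta = {
            k: (rec.pressure[k] - rec.pressure[k].mean()) / (1025 * 9.81)
            for k in ("A", "B")
        }
        # bottom-pressure attenuation is identical at equal depths, so the
        # bed-level flux ratio equals the surface flux ratio
        fa, _ = _band_flux_and_orbital(eta["A"], rec.depths["A"], rec.rate_hz)
        fb, _ = _band_flux_and_orbital(eta["B"], rec.depths["B"], rec.rate_hz)
        assert fb / fa == pytest.approx(1.0, abs=0.02)

    def test_invalid_sensors_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_pressure_records(sensor_depths=(3.0,))
        with pytest.raises(ValueError):
            synthgen.generate_pressure_records(sensor_depths=(3.0, -1.0))
        with pytest.raises(ValueError):
            synthgen.generate_pressure_records(kn_true=0.0)
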
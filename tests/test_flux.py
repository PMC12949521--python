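"""Upscaling kernel, nested Monte Carlo, summaries and spatial output."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hgflux.flux import (
    BIOMES,
    EfficiencyPrior,
    GridSpec,
    SiteRecord,
    flux_map,
    load_areas,
    load_sites,
    sample_site_flux,
    site_flux_mean,
    summarize,
    upscale_global,
    write_ascii_grid,
    write_sites,
)


class TestSitesIO:
    HEADER = ("site_id,biome,lat,lon,c_np_median_ng_g,c_np_gsd,"
              "ra_mean,ra_sd,rho_b_g_cm3,depth_m\n")

    def test_valid_rows_loaded(self, tmp_path):
        f = tmp_path / "sites.csv"
        f.write_text(self.HEADER
                     + "a,forest,10,20,50,1.5,0.01,0.002,1.3,0.2\n"
                     + "b,desert,,,5,1.2,0.003,0.001,1.5,0.1\n"
                     + "c,wetland,0,0,80,2.0,0.02,0.004,1.1,0.3\n")
        sites = load_sites(f)
        assert len(sites) == 3
        assert sites[1].biome == "desert" and sites[1].lat is None

    def test_out_of_range_abundance_rejected_with_row_index(self, tmp_path):
        f = tmp_path / "sites.csv"
        f.write_text(self.HEADER + "a,forest,,,50,1.5,1.2,0.002,1.3,0.2\n")
        with pytest.raises(ValueError, match=r"row 0.*ra_mean"):
            load_sites(f)

    def test_unknown_biome_rejected(self, tmp_path):
        f = tmp_path / "sites.csv"
        f.write_text(self.HEADER + "a,savanna,,,50,1.5,0.01,0.002,1.3,0.2\n")
        with pytest.raises(ValueError, match="biome"):
            load_sites(f)

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "sites.csv"
        f.write_text("site_id,biome\na,forest\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_sites(f)

    def test_write_load_roundtrip(self, tmp_path):
        sites = [
            SiteRecord("s1", "forest", 50.0, 1.5, 0.01, 0.002, 1.3, 0.2,
                       lat=45.0, lon=-120.0),
            SiteRecord("s2", "tundra", 5.0, 1.2, 0.004, 0.001, 1.1, 0.1),
        ]
        f = tmp_path / "sites.csv"
        write_sites(sites, f)
        assert load_sites(f) == sites

    def test_areas_require_all_six_biomes(self, tmp_path):
        f = tmp_path / "areas.csv"
        f.write_text("biome,area_m2\nforest,1e13\n")
        with pytest.raises(ValueError, match="missing biome"):
            load_areas(f)


class TestEfficiencyPrior:
    def test_defaults_are_three_lab_strains(self):
        p = EfficiencyPrior()
        assert p.strains == ((9.7, 1.1), (7.4, 0.8), (7.9, 0.4))
        assert sum(p.weights) == pytest.approx(1.0)

    def test_samples_confined_to_unit_interval(self):
        p = EfficiencyPrior()
        draws = p.sample(np.random.default_rng(0), 5000)
        assert np.all((draws >= 0.0) & (draws <= 1.0))
        # mixture mean approx (9.7+7.4+7.9)/3 percent
        assert draws.mean() == pytest.approx(p.mean(), abs=3 * draws.std() / 70)

    def test_degenerate_strain_yields_constant(self):
        p = EfficiencyPrior(strains=((8.0, 0.0),))
        draws = p.sample(np.random.default_rng(1), 100)
        assert np.all(draws == 0.08)
        assert p.mean() == 0.08

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            EfficiencyPrior(weights=(0.5, 0.5))


class TestSiteFlux:
    def test_zero_pool_gives_zero(self, degenerate_site_factory,
                                  degenerate_prior_factory):
        site = degenerate_site_factory(c=0.0)
        out = sample_site_flux(site, degenerate_prior_factory(),
                               np.random.default_rng(0), n=10)
        assert np.all(out == 0.0)

    def test_deterministic_kernel_product(self, degenerate_site_factory,
                                          degenerate_prior_factory):
        # 100 ng/g * 1.3 g/cm3 * 0.2 m * 0.08 * 1 -> 2.08e-3 g/m2/yr
        site = degenerate_site_factory(c=100.0, rho_b=1.3, depth=0.2, ra=1.0)
        prior = degenerate_prior_factory(mean_pct=8.0, sd_pct=0.0, a_yr=1.0)
        out = sample_site_flux(site, prior, np.random.default_rng(0), n=5,
                               ra_ref=1.0)
        np.testing.assert_allclose(out, 2.08e-3, rtol=1e-15)
        assert site_flux_mean(site, prior, ra_ref=1.0) == pytest.approx(
            2.08e-3, rel=1e-15)

    def test_mc_mean_matches_lognormal_closed_form(
            self, degenerate_prior_factory):
        m, gsd = 50.0, 2.0
        site = SiteRecord("s", "forest", m, gsd, ra_mean=1.0, ra_sd=0.0,
                          rho_b=1.3, depth=0.2)
        prior = degenerate_prior_factory(8.0)
        n = 100_000
        draws = sample_site_flux(site, prior, np.random.default_rng(12), n=n,
                                 ra_ref=1.0)
        fixed = 1.3 * 0.2 * 1e-3 * 0.08
        expected = m * np.exp(0.5 * np.log(gsd) ** 2) * fixed
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_activity_scaling_saturates(self, degenerate_site_factory,
                                        degenerate_prior_factory):
        prior = degenerate_prior_factory(8.0)
        lo = degenerate_site_factory(ra=0.005)
        hi = degenerate_site_factory(ra=0.5)
        f_lo = sample_site_flux(lo, prior, np.random.default_rng(0), ra_ref=0.01)
        f_hi = sample_site_flux(hi, prior, np.random.default_rng(0), ra_ref=0.01)
        assert f_lo[0] == pytest.approx(0.5 * f_hi[0], rel=1e-12)
        capped = degenerate_site_factory(ra=1.0)
        f_cap = sample_site_flux(capped, prior, np.random.default_rng(0),
                                 ra_ref=0.01)
        assert f_cap[0] == f_hi[0]  # both at the cap g = 1


def _degenerate_setup(area=1.0e12, c=100.0):
    site = SiteRecord("only", "forest", c, 1.0, ra_mean=1.0, ra_sd=0.0,
                      rho_b=1.3, depth=0.2)
    areas = {b: (area if b == "forest" else 0.0) for b in BIOMES}
    prior = EfficiencyPrior(strains=((8.0, 0.0),))
    return site, areas, prior


class TestUpscale:
    def test_degenerate_mc_equals_closed_form(self):
        site, areas, prior = _degenerate_setup()
        est = upscale_global([site], areas, prior, n_inner=5, n_outer=50,
                             seed=3, ra_ref=1.0)
        expected = 2.08e-3 * 1.0e12 / 1e6  # areal flux * area, g -> t
        np.testing.assert_allclose(est.draws, expected, rtol=1e-15)
        assert est.sd == 0.0

    def test_all_zero_concentrations(self):
        site, areas, prior = _degenerate_setup(c=0.0)
        est = upscale_global([site], areas, prior, n_inner=5, n_outer=40,
                             seed=1, ra_ref=1.0)
        s = summarize(est)
        assert s.mean == 0.0
        assert s.intervals[0.5] == (0.0, 0.0)
        assert s.intervals[0.9] == (0.0, 0.0)

    def test_duplicated_site_leaves_degenerate_flux_unchanged(self):
        site, areas, prior = _degenerate_setup()
        twin = dataclasses.replace(site, site_id="twin")
        est1 = upscale_global([site], areas, prior, n_inner=5, n_outer=30,
                              seed=3, ra_ref=1.0)
        est2 = upscale_global([site, twin], areas, prior, n_inner=5,
                              n_outer=30, seed=3, ra_ref=1.0)
        np.testing.assert_allclose(est1.draws, est2.draws, rtol=1e-15)

    def test_linearity_in_concentration(self):
        sites = [
            SiteRecord(f"s{i}", b, 10.0 * (i + 1), 1.6, ra_mean=0.01,
                       ra_sd=0.002)
            for i, b in enumerate(BIOMES)
        ]
        areas = {b: 1e12 for b in BIOMES}
        prior = EfficiencyPrior()
        lam = 3.7
        scaled = [dataclasses.replace(s, c_np_median=lam * s.c_np_median)
                  for s in sites]
        e1 = upscale_global(sites, areas, prior, 20, 50, seed=8, ra_ref=1.0)
        e2 = upscale_global(scaled, areas, prior, 20, 50, seed=8, ra_ref=1.0)
        np.testing.assert_allclose(e2.draws, lam * e1.draws, rtol=1e-10)

    def test_biome_additivity_every_draw(self):
        sites = [SiteRecord(f"s{i}", b, 20.0, 1.5, ra_mean=0.01, ra_sd=0.002)
                 for i, b in enumerate(BIOMES)]
        areas = {b: (i + 1) * 1e12 for i, b in enumerate(BIOMES)}
        est = upscale_global(sites, areas, EfficiencyPrior(), 10, 60, seed=2,
                             ra_ref=1.0)
        total = np.sum([est.biome_draws[b] for b in BIOMES], axis=0)
        np.testing.assert_allclose(est.draws, total, rtol=1e-12)

    def test_bit_identical_given_seed(self):
        sites = [SiteRecord(f"s{i}", b, 20.0, 1.5, ra_mean=0.01, ra_sd=0.002)
                 for i, b in enumerate(BIOMES)]
        areas = {b: 1e12 for b in BIOMES}
        e1 = upscale_global(sites, areas, EfficiencyPrior(), 10, 40, seed=5)
        e2 = upscale_global(sites, areas, EfficiencyPrior(), 10, 40, seed=5)
        assert np.array_equal(e1.draws, e2.draws)

    def test_site_order_does_not_perturb_draws(self):
        sites = [SiteRecord(f"s{i}", "forest", 10.0 + i, 1.5, ra_mean=0.01,
                            ra_sd=0.002) for i in range(5)]
        areas = {b: (1e12 if b == "forest" else 0.0) for b in BIOMES}
        e1 = upscale_global(sites, areas, EfficiencyPrior(), 10, 40, seed=5,
                            ra_ref=1.0)
        e2 = upscale_global(sites[::-1], areas, EfficiencyPrior(), 10, 40,
                            seed=5, ra_ref=1.0)
        np.testing.assert_allclose(e1.draws, e2.draws, rtol=1e-15)

    def test_biome_with_area_but_no_sites_rejected(self):
        site, areas, prior = _degenerate_setup()
        areas["desert"] = 1e12
        with pytest.raises(ValueError, match="desert"):
            upscale_global([site], areas, prior, 5, 5, seed=0)


class TestSummarize:
    def test_hand_computed_order_statistics(self):
        draws = np.arange(1.0, 101.0)
        s = summarize(draws, levels=(0.5,))
        assert s.intervals[0.5] == pytest.approx((25.75, 75.25))

    def test_constant_draws(self):
        s = summarize(np.full(20, 7.0))
        assert s.mean == 7.0 and s.sd == 0.0
        assert s.intervals[0.9] == (7.0, 7.0)

    def test_intervals_nested(self):
        draws = np.random.default_rng(0).lognormal(1.0, 0.8, size=500)
        s = summarize(draws, levels=(0.5, 0.9))
        lo50, hi50 = s.intervals[0.5]
        lo90, hi90 = s.intervals[0.9]
        assert lo90 <= lo50 <= hi50 <= hi90

    def test_empty_and_bad_level_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))
        with pytest.raises(ValueError):
            summarize(np.array([1.0, 2.0]), levels=(1.5,))


class TestFluxMap:
    def _two_sites(self):
        return [
            SiteRecord("a", "forest", 10.0, lat=10.0, lon=10.0),
            SiteRecord("b", "desert", 5.0, lat=-10.0, lon=-10.0),
        ]

    def test_two_cells_containing_sites(self):
        grid = GridSpec(lon_min=-20, lat_min=-20, lon_max=20, lat_max=20,
                        res_deg=20.0)
        table, raster = flux_map(self._two_sites(), [1.0, 2.0], grid=grid,
                                 cutoff_km=900.0)
        assert raster.shape == (2, 2)
        assert (raster != grid.nodata).sum() == 2
        assert raster[0, 1] == 1.0  # NE cell centre nearest to site a
        assert raster[1, 0] == 2.0

    def test_zero_cutoff_all_nodata(self):
        grid = GridSpec(-20, -20, 20, 20, 20.0)
        _, raster = flux_map(self._two_sites(), [1.0, 2.0], grid=grid,
                             cutoff_km=0.0)
        assert np.all(raster == grid.nodata)

    def test_point_table_roundtrip(self, tmp_path):
        table, _ = flux_map(self._two_sites(), [1.0, 2.0])
        f = tmp_path / "points.csv"
        table.to_csv(f, index=False)
        back = pd.read_csv(f)
        np.testing.assert_allclose(back["flux_g_m2_yr"], [1.0, 2.0])

    def test_missing_coordinates_rejected_for_raster(self):
        sites = [SiteRecord("a", "forest", 10.0)]
        with pytest.raises(ValueError, match="lat/lon"):
            flux_map(sites, [1.0], grid=GridSpec(-20, -20, 20, 20, 20.0))

    def test_ascii_grid_header(self, tmp_path):
        grid = GridSpec(-20, -20, 20, 20, 20.0)
        _, raster = flux_map(self._two_sites(), [1.0, 2.0], grid=grid,
                             cutoff_km=900.0)
        f = tmp_path / "flux.asc"
        write_ascii_grid(raster, grid, f)
        text = f.read_text().splitlines()
        assert text[0] == "ncols 2" and text[1] == "nrows 2"
        assert text[5] == "NODATA_value -9999"
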
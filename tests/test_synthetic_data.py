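import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from aodkrige.synthetic_data import (
    SimulationConfig,
    apply_cloud_mask,
    assign_population,
    default_lmc,
    generate_subdistricts,
    make_world,
    sample_stations,
    simulate_coregionalized_fields,
)
from aodkrige.variography import (
    CoregionalizationModel,
    VariogramStructure,
    empirical_variogram,
)


def small_cfg(**kw):
    base = dict(grid_size=20, n_days=5, n_stations=30, n_subdistricts=16, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestFieldSimulation:
    def test_fixed_seed_bit_identical(self):
        a = simulate_coregionalized_fields(small_cfg())
        b = simulate_coregionalized_fields(small_cfg())
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_different_seed_differs(self):
        _, t1, _ = simulate_coregionalized_fields(small_cfg(seed=1))
        _, t2, _ = simulate_coregionalized_fields(small_cfg(seed=2))
        assert not np.array_equal(t1, t2)

    def test_zero_cross_coefficients_decorrelate_fields(self):
        lmc = default_lmc(cross_correlation=0.0)
        cfg = small_cfg(lmc=lmc, n_days=50, baseline_mean=200.0)
        _, truth, cov = simulate_coregionalized_fields(cfg)
        r = np.corrcoef(truth.ravel(), cov.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_nonzero_cross_correlation_realized(self):
        cfg = small_cfg(n_days=50, baseline_mean=300.0, seasonal_amplitude=0.0)
        _, truth, cov = simulate_coregionalized_fields(cfg)
        # remove daily means: the LMC governs within-day spatial fluctuation
        t = truth - truth.mean(axis=1, keepdims=True)
        c = cov - cov.mean(axis=1, keepdims=True)
        r = np.corrcoef(t.ravel(), c.ravel())[0, 1]
        assert r == pytest.approx(default_lmc().cross_correlation(), abs=0.1)

    def test_seasonality_peaks_in_winter(self):
        cfg = small_cfg(n_days=365, grid_size=8, start_date="2013-01-01")
        _, truth, _ = simulate_coregionalized_fields(cfg)
        daily = truth.mean(axis=1)
        months = (np.arange(365) // 30.4).astype(int)
        jan = daily[months == 0].mean()
        jul = daily[months == 6].mean()
        assert jan > jul

    def test_non_psd_matrix_rejected(self):
        bad = CoregionalizationModel.__new__(CoregionalizationModel)
        # bypass the constructor check to test the simulator's own guard
        bad.structures = [VariogramStructure("exponential", 100.0)]
        bad.b_mats = [np.array([[1.0, 9.0], [9.0, 1.0]])]
        with pytest.raises(ValueError, match="not PSD"):
            simulate_coregionalized_fields(small_cfg(lmc=bad))

    def test_truth_nonnegative(self):
        _, truth, _ = simulate_coregionalized_fields(small_cfg())
        assert (truth >= 0).all()

    def test_empirical_variogram_matches_generating_model(self):
        """One-structure field reproduces the closed-form curve within 25%
        at lags below the range, averaged over 20 replicates."""
        st = VariogramStructure("exponential", 300.0)
        lmc = CoregionalizationModel(
            [st], [np.array([[100.0, 0.0], [0.0, 1.0]])]
        )
        bins = np.linspace(0, 300, 7)
        gammas = []
        for rep in range(20):
            cfg = SimulationConfig(
                grid_size=24, n_days=1, n_stations=1, lmc=lmc, seed=900 + rep,
                baseline_mean=1000.0, seasonal_amplitude=0.0,
                regional_sd=0.0, cloud_fraction=0.0,
            )
            xy, truth, _ = simulate_coregionalized_fields(cfg)
            emp = empirical_variogram(xy, truth[0], bins)
            gammas.append(np.interp([75, 150, 225], emp.lags, emp.semivariance))
        mean_gamma = np.mean(gammas, axis=0)
        theory = 100.0 * st.unit_variogram(np.array([75.0, 150.0, 225.0]))
        np.testing.assert_allclose(mean_gamma, theory, rtol=0.25)

    def test_clamping_rare_when_baseline_large(self):
        cfg = small_cfg(baseline_mean=200.0, seasonal_amplitude=0.0, n_days=20)
        _, truth, _ = simulate_coregionalized_fields(cfg)
        assert (truth == 0.0).mean() < 0.01


class TestCloudMask:
    def _fields(self):
        cfg = small_cfg(n_days=30)
        xy, _, cov = simulate_coregionalized_fields(cfg)
        return xy, cov

    def test_zero_fraction_masks_nothing(self):
        xy, cov = self._fields()
        masked, mask = apply_cloud_mask(cov, xy, 0.0, 150.0, seed=1)
        assert not mask.any()
        np.testing.assert_array_equal(masked, cov)

    def test_full_fraction_masks_everything(self):
        xy, cov = self._fields()
        masked, mask = apply_cloud_mask(cov, xy, 1.0, 150.0, seed=1)
        assert mask.all()
        assert np.isnan(masked).all()

    def test_realized_fraction_near_target(self):
        xy, cov = self._fields()
        _, mask = apply_cloud_mask(cov, xy, 0.4, 150.0, seed=1)
        assert 0.35 <= mask.mean() <= 0.45

    def test_missing_is_nan_not_sentinel(self):
        xy, cov = self._fields()
        masked, mask = apply_cloud_mask(cov, xy, 0.3, 150.0, seed=1)
        assert np.isnan(masked[mask]).all()
        assert np.isfinite(masked[~mask]).all()


class TestStations:
    def test_zero_noise_reproduces_truth_at_cell(self):
        cfg = small_cfg()
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        recs, st_xy, cells = sample_stations(truth, xy, 10, 0.0, 0.0, seed=5)
        for t in range(truth.shape[0]):
            for i in range(10):
                assert recs[t * 10 + i].pm25 == pytest.approx(truth[t, cells[i]])

    def test_record_count(self):
        cfg = small_cfg(n_days=3)
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        recs, _, _ = sample_stations(truth, xy, 1, 0.0, 0.0, seed=5)
        assert len(recs) == 3

    def test_too_many_stations_rejected(self):
        cfg = small_cfg()
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        with pytest.raises(ValueError, match="exceeds"):
            sample_stations(truth, xy, 10**6, 0.0, 0.0, seed=5)

    def test_unclustered_locations_uniform_by_quadrat_test(self):
        """chi-square on 4x4 quadrat counts non-significant in >= 18/20 reps."""
        cfg = SimulationConfig(grid_size=24, n_days=1, n_stations=160, seed=0)
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        extent = cfg.extent_km
        passed = 0
        for rep in range(20):
            _, st_xy, _ = sample_stations(truth, xy, 160, 0.0, 0.0, seed=rep)
            qx = np.minimum((st_xy[:, 0] / extent * 4).astype(int), 3)
            qy = np.minimum((st_xy[:, 1] / extent * 4).astype(int), 3)
            counts = np.bincount(qy * 4 + qx, minlength=16)
            _, p = chisquare(counts)
            passed += p > 0.01
        assert passed >= 18

    def test_clustering_shifts_stations_toward_polluted_cells(self):
        cfg = small_cfg(n_days=10)
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        annual = truth.mean(axis=0)
        _, _, c0 = sample_stations(truth, xy, 50, 0.0, 0.0, seed=11)
        _, _, c1 = sample_stations(truth, xy, 50, 0.95, 0.0, seed=11)
        assert annual[c1].mean() > annual[c0].mean()


class TestSubdistricts:
    def test_regular_grid_areas(self):
        sds = generate_subdistricts(100.0, 16, seed=0, tessellation="grid")
        assert len(sds) == 16
        for sd in sds:
            assert sd.area_km2 == pytest.approx(625.0)

    @pytest.mark.parametrize("tess,n", [("grid", 25), ("voronoi", 40)])
    def test_areas_sum_to_domain(self, tess, n):
        sds = generate_subdistricts(200.0, n, seed=2, tessellation=tess)
        total = sum(sd.area_km2 for sd in sds)
        assert total == pytest.approx(200.0**2, rel=1e-6)

    def test_voronoi_deterministic(self):
        a = generate_subdistricts(100.0, 20, seed=9)
        b = generate_subdistricts(100.0, 20, seed=9)
        for x, y in zip(a, b):
            assert x.polygon.equals_exact(y.polygon, 0.0)


class TestPopulation:
    def _world_parts(self, n_sd=100, seed=0):
        cfg = SimulationConfig(
            grid_size=24, n_days=5, n_stations=10, n_subdistricts=n_sd, seed=seed
        )
        xy, truth, _ = simulate_coregionalized_fields(cfg)
        sds = generate_subdistricts(cfg.extent_km, n_sd, seed=seed)
        return cfg, xy, truth, sds

    def test_segment_counts_sum_exactly(self):
        cfg, xy, truth, sds = self._world_parts(n_sd=30)
        assign_population(sds, truth, xy, 0.5, (0.2, 0.65, 0.15), seed=1)
        for sd in sds:
            total = sd.total_population
            assert total > 0
            assert total == int(total)  # largest remainder keeps integers

    def test_degenerate_shares(self):
        cfg, xy, truth, sds = self._world_parts(n_sd=16)
        assign_population(sds, truth, xy, 0.0, (0.0, 1.0, 0.0), seed=1)
        for sd in sds:
            assert sd.population["children"] == 0
            assert sd.population["seniors"] == 0

    def test_bad_shares_rejected(self):
        cfg, xy, truth, sds = self._world_parts(n_sd=16)
        with pytest.raises(ValueError, match="sum to 1"):
            assign_population(sds, truth, xy, 0.0, (0.5, 0.2, 0.2), seed=1)

    def test_target_rank_correlation_achieved(self):
        cfg, xy, truth, sds = self._world_parts()
        assign_population(sds, truth, xy, 0.6, (0.2, 0.65, 0.15), seed=4)
        annual = truth.mean(axis=0)
        import shapely

        poll, dens = [], []
        for sd in sds:
            inside = shapely.contains_xy(sd.polygon, xy[:, 0], xy[:, 1])
            poll.append(annual[inside].mean() if inside.any() else annual.mean())
            dens.append(sd.total_population / sd.area_km2)
        rho, _ = spearmanr(poll, dens)
        assert rho == pytest.approx(0.6, abs=0.15)

    def test_zero_target_correlation(self):
        """|Spearman| < 0.15 in >= 16/20 replicates at rho = 0."""
        import shapely

        cfg, xy, truth, sds = self._world_parts()
        annual = truth.mean(axis=0)
        poll = []
        for sd in sds:
            inside = shapely.contains_xy(sd.polygon, xy[:, 0], xy[:, 1])
            poll.append(annual[inside].mean() if inside.any() else annual.mean())
        passed = 0
        for rep in range(20):
            assign_population(sds, truth, xy, 0.0, (0.2, 0.65, 0.15), seed=rep)
            dens = [sd.total_population / sd.area_km2 for sd in sds]
            rho, _ = spearmanr(poll, dens)
            passed += abs(rho) < 0.15
        assert passed >= 16


class TestWorld:
    def test_world_deterministic(self):
        a = make_world(small_cfg())
        b = make_world(small_cfg())
        np.testing.assert_array_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.covariate, b.covariate)
        assert [s.pm25 for s in a.stations] == [s.pm25 for s in b.stations]
        for x, y in zip(a.subdistricts, b.subdistricts):
            assert x.population == y.population
            assert x.polygon.equals_exact(y.polygon, 0.0)
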
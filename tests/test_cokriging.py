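import numpy as np
import pytest
from shapely.geometry import Polygon, box

from aodkrige.cokriging import (
    Neighborhood,
    StationRecord,
    CovariateRecord,
    cov_between,
    discretize_block,
    interpolate_day,
    kriging_variance,
    predict_block,
    solve_bck_system,
)
from aodkrige.variography import CoregionalizationModel, VariogramStructure

from conftest import qp_oracle_weights


def zero_nugget_model(sill=100.0, rng=50.0, rho=0.6, s22=1.0):
    b = np.array(
        [[sill, rho * np.sqrt(sill * s22)], [rho * np.sqrt(sill * s22), s22]]
    )
    return CoregionalizationModel([VariogramStructure("exponential", rng)], [b])


class TestDiscretizeBlock:
    def test_single_point_is_interior(self):
        from shapely.geometry import Point

        poly = box(0, 0, 10, 10)
        pts = discretize_block(poly, 1)
        assert pts.shape == (1, 2)
        assert poly.contains(Point(*pts[0]))

    def test_four_points_symmetric_about_centroid(self):
        poly = box(0, 0, 1, 1)
        pts = discretize_block(poly, 4)
        assert len(pts) == 4
        np.testing.assert_allclose(pts.mean(axis=0), [0.5, 0.5], atol=1e-12)

    def test_block_covariance_converges_in_m(self):
        """Within-block average covariance stabilizes < 1% from m=64 to 256."""
        poly = box(0, 0, 10, 10)
        model = zero_nugget_model()
        vals = []
        for m in (64, 256):
            pts = discretize_block(poly, m)
            vals.append(cov_between(model, "11", pts, pts).mean())
        assert abs(vals[1] - vals[0]) / vals[1] < 0.01

    def test_zero_area_polygon_rejected(self):
        degenerate = Polygon([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ValueError, match="zero area"):
            discretize_block(degenerate, 16)


class TestCovBetween:
    def test_zero_lag_is_total_sill(self, lmc):
        c = cov_between(lmc, "11", np.array([[3.0, 4.0]]), np.array([[3.0, 4.0]]))
        assert c[0, 0] == pytest.approx(lmc.sill("11"))

    def test_nugget_absent_off_origin(self, lmc):
        c = cov_between(
            lmc, "11", np.array([[0.0, 0.0]]), np.array([[1e-6, 0.0]])
        )
        # continuous part barely moves, nugget drops out entirely
        assert c[0, 0] == pytest.approx(lmc.sill("11") - 25.0, rel=1e-4)


class TestSolveSystem:
    def test_single_station_gets_unit_weight(self):
        model = zero_nugget_model()
        sys_ = solve_bck_system(
            np.array([[5.0, 5.0]]), np.array([42.0]), None, None, model,
            np.array([[20.0, 20.0]]),
        )
        np.testing.assert_allclose(sys_.lam1, [1.0], atol=1e-12)
        assert predict_block(sys_).estimate == pytest.approx(42.0)

    def test_symmetric_stations_split_weight(self):
        model = zero_nugget_model()
        block = discretize_block(box(-5, -5, 5, 5), 64)
        sys_ = solve_bck_system(
            np.array([[-20.0, 0.0], [20.0, 0.0]]), np.array([10.0, 30.0]),
            None, None, model, block,
        )
        np.testing.assert_allclose(sys_.lam1, [0.5, 0.5], atol=1e-9)

    def test_constraints_hold_on_random_systems(self, lmc, rng):
        for _ in range(200):
            n1 = rng.integers(1, 8)
            n2 = rng.integers(0, 8)
            sys_ = solve_bck_system(
                rng.uniform(0, 500, (n1, 2)), rng.uniform(10, 100, n1),
                rng.uniform(0, 500, (n2, 2)) if n2 else None,
                rng.uniform(0.1, 1.0, n2) if n2 else None,
                lmc, rng.uniform(200, 300, (8, 2)),
            )
            assert abs(sys_.lam1.sum() - 1.0) < 1e-8
            assert abs(sys_.lam2.sum()) < 1e-8

    def test_weights_match_qp_oracle(self, lmc, rng):
        for _ in range(50):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(0, 6))
            p_xy = rng.uniform(0, 400, (n1, 2))
            s_xy = rng.uniform(0, 400, (n2, 2)) if n2 else None
            bp = rng.uniform(100, 300, (16, 2))
            sys_ = solve_bck_system(
                p_xy, rng.uniform(10, 100, n1), s_xy,
                rng.uniform(0.1, 1.0, n2) if n2 else None, lmc, bp,
            )
            lam_oracle, obj = qp_oracle_weights(lmc, p_xy, s_xy, bp)
            lam = np.concatenate([sys_.lam1, sys_.lam2])
            assert np.max(np.abs(lam - lam_oracle)) < 1e-6
            assert kriging_variance(sys_) == pytest.approx(obj, abs=1e-6)

    def test_duplicate_coordinates_averaged(self, lmc):
        p_xy = np.array([[10.0, 10.0], [10.0, 10.0], [50.0, 50.0]])
        p_val = np.array([20.0, 40.0, 60.0])
        sys_ = solve_bck_system(
            p_xy, p_val, None, None, lmc, np.array([[30.0, 30.0]])
        )
        assert len(sys_.lam1) == 2
        assert 30.0 in sys_.primary_values  # mean of the duplicates


class TestPredictBlock:
    def test_constant_primary_constant_secondary(self, lmc, rng):
        sys_ = solve_bck_system(
            rng.uniform(0, 100, (5, 2)), np.full(5, 42.0),
            rng.uniform(0, 100, (4, 2)), np.full(4, 0.5),
            lmc, rng.uniform(40, 60, (16, 2)),
        )
        assert predict_block(sys_).estimate == pytest.approx(42.0, abs=1e-9)

    def test_secondary_shift_invariance(self, lmc, rng):
        p_xy = rng.uniform(0, 100, (5, 2))
        p_val = rng.uniform(20, 90, 5)
        s_xy = rng.uniform(0, 100, (4, 2))
        s_val = rng.uniform(0.1, 0.9, 4)
        bp = rng.uniform(40, 60, (16, 2))
        a = predict_block(solve_bck_system(p_xy, p_val, s_xy, s_val, lmc, bp))
        b = predict_block(
            solve_bck_system(p_xy, p_val, s_xy, s_val + 123.0, lmc, bp)
        )
        assert a.estimate == pytest.approx(b.estimate, abs=1e-8)

    def test_point_kriging_exactness_zero_nugget(self):
        model = zero_nugget_model()
        p_xy = np.array([[10.0, 10.0], [30.0, 50.0], [70.0, 20.0]])
        p_val = np.array([15.0, 55.0, 95.0])
        sys_ = solve_bck_system(
            p_xy, p_val, None, None, model, p_xy[1][None, :]
        )
        pred = predict_block(sys_)
        assert pred.estimate == pytest.approx(55.0, abs=1e-6)
        assert pred.se == pytest.approx(0.0, abs=1e-4)

    def test_bck_variance_never_exceeds_bk(self, lmc, rng):
        """The BK solution (lam2 = 0) is BCK-feasible, so BCK can't do worse."""
        for _ in range(100):
            p_xy = rng.uniform(0, 400, (6, 2))
            p_val = rng.uniform(10, 100, 6)
            s_xy = rng.uniform(0, 400, (6, 2))
            s_val = rng.uniform(0.1, 1.0, 6)
            bp = rng.uniform(100, 300, (32, 2))
            v_bk = kriging_variance(
                solve_bck_system(p_xy, p_val, None, None, lmc, bp)
            )
            v_bck = kriging_variance(
                solve_bck_system(p_xy, p_val, s_xy, s_val, lmc, bp)
            )
            assert v_bck <= v_bk + 1e-9

    def test_negative_estimate_clamped_and_flagged(self):
        model = zero_nugget_model(rho=0.0)
        # a far block with screened negative-weight geometry is hard to force;
        # instead drive the estimate negative through a negative-valued
        # secondary-free configuration with extreme extrapolation weights
        p_xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        p_val = np.array([0.0, 100.0])
        sys_ = solve_bck_system(
            p_xy, p_val, None, None, model, np.array([[-30.0, 0.0]])
        )
        pred = predict_block(sys_)
        if pred.clamped:
            assert pred.estimate == 0.0
        else:  # geometry did not produce a negative weight combination
            assert pred.estimate >= 0.0


class TestInterpolateDay:
    def _day(self, world, t):
        n = len(world.station_xy)
        stations = world.stations[t * n:(t + 1) * n]
        cov = [
            CovariateRecord(int(c), float(world.cell_xy[c, 0]),
                            float(world.cell_xy[c, 1]), world.dates[t],
                            float(world.covariate[t, c]))
            for c in np.flatnonzero(np.isfinite(world.covariate[t]))
        ]
        return stations, cov

    def test_all_covariate_missing_reduces_to_bk(self, small_world, lmc):
        stations, _ = self._day(small_world, 0)
        nb = Neighborhood(m_points=16)
        with_none = interpolate_day(stations, [], lmc, small_world.subdistricts, nb)
        assert all(p.method == "BK" for p in with_none)
        bk = interpolate_day(stations, [], lmc, small_world.subdistricts, nb)
        for a, b in zip(with_none, bk):
            assert a.estimate == pytest.approx(b.estimate)

    def test_local_equals_global_when_neighborhood_covers_all(self, small_world, lmc):
        stations, cov = self._day(small_world, 0)
        cov = cov[::12]  # thin for speed
        sd = small_world.subdistricts[:4]
        big = Neighborhood(k1=10**6, k2=10**6, radius_km=1e9, m_points=16)
        local = interpolate_day(stations, cov, lmc, sd, big)
        # explicit global solve per subdistrict
        p_xy = np.array([[s.x, s.y] for s in stations])
        p_val = np.array([s.pm25 for s in stations])
        s_xy = np.array([[c.x, c.y] for c in cov])
        s_val = np.array([c.aod for c in cov])
        for pred, block in zip(local, sd):
            bp = discretize_block(block.polygon, 16)
            sys_ = solve_bck_system(p_xy, p_val, s_xy, s_val, lmc, bp)
            assert pred.estimate == pytest.approx(
                predict_block(sys_).estimate, abs=1e-8
            )

    def test_bck_mean_variance_not_worse_than_bk(self, small_world, lmc):
        stations, cov = self._day(small_world, 0)
        nb = Neighborhood(m_points=16)
        bck = interpolate_day(stations, cov, lmc, small_world.subdistricts, nb)
        bk = interpolate_day(stations, [], lmc, small_world.subdistricts, nb)
        assert np.mean([p.se**2 for p in bck]) <= np.mean(
            [p.se**2 for p in bk]
        ) + 1e-9

    def test_too_few_stations_raises(self, small_world, lmc):
        stations, _ = self._day(small_world, 0)
        with pytest.raises(ValueError, match="fewer than the minimum"):
            interpolate_day(
                stations[:3], [], lmc, small_world.subdistricts,
                Neighborhood(min_stations=10),
            )


class TestStationRecordValidation:
    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            StationRecord("s1", 0.0, 0.0, "2013-04-08", -5.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            StationRecord("s1", 0.0, 0.0, "2013-04-08", float("nan"))
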
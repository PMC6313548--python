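import numpy as np
import pytest

from aodkrige.synthetic_data import SimulationConfig, default_lmc, make_world


@pytest.fixture(scope="session")
def lmc():
    """Ground-truth coregionalization model with cross-correlation 0.7."""
    return default_lmc()


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world, shared across read-only tests."""
    return make_world(
        SimulationConfig(
            grid_size=24, n_days=6, n_stations=40, n_subdistricts=25, seed=7
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_variogram(locations, values, lag_bins):
    """O(n^2) reference estimator of the direct semivariogram."""
    locations = np.asarray(locations, float)
    values = np.asarray(values, float)
    n = len(values)
    edges = np.asarray(lag_bins, float)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    lagsum = np.zeros(len(edges) - 1)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(locations[i] - locations[j]))
            for b in range(len(edges) - 1):
                if edges[b] <= d < edges[b + 1]:
                    sums[b] += (values[i] - values[j]) ** 2
                    counts[b] += 1
                    lagsum[b] += d
                    break
    keep = counts > 0
    return lagsum[keep] / counts[keep], sums[keep] / (2 * counts[keep]), counts[keep]


def brute_force_cross_variogram(locations, z1, z2, lag_bins):
    """O(n^2) reference estimator of the cross semivariogram."""
    locations = np.asarray(locations, float)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    ok = np.isfinite(z1) & np.isfinite(z2)
    locations, z1, z2 = locations[ok], z1[ok], z2[ok]
    edges = np.asarray(lag_bins, float)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(z1)):
        for j in range(i + 1, len(z1)):
            d = np.hypot(*(locations[i] - locations[j]))
            for b in range(len(edges) - 1):
                if edges[b] <= d < edges[b + 1]:
                    sums[b] += (z1[i] - z1[j]) * (z2[i] - z2[j])
                    counts[b] += 1
                    break
    keep = counts > 0
    return sums[keep] / (2 * counts[keep]), counts[keep]


def exponential_recovery_stats(nrep=20):
    """Simulation-recovery experiment: exponential field, sill 100 /
    range 30 km, 300 points on a 150 km square; returns (mean sill,
    mean range) of the weighted-least-squares refits."""
    from scipy.spatial.distance import pdist, squareform

    from aodkrige.variography import (
        VariogramStructure,
        empirical_variogram,
        fit_variogram_model,
    )

    true = VariogramStructure("exponential", 30.0)
    sill = 100.0
    sills, ranges = [], []
    for rep in range(nrep):
        r = np.random.default_rng(100 + rep)
        xy = r.uniform(0, 150, (300, 2))
        R = true.unit_correlogram(squareform(pdist(xy)))
        L = np.linalg.cholesky(R + 1e-10 * np.eye(300))
        z = np.sqrt(sill) * (L @ r.standard_normal(300))
        emp = empirical_variogram(xy, z, np.linspace(0, 75, 16))
        fit = fit_variogram_model(emp, families=("exponential",))
        sills.append(fit.nugget + fit.sill)
        ranges.append(fit.range_km)
    return float(np.mean(sills)), float(np.mean(ranges))


def lmc_recovery_errors(nrep=20):
    """Per-replicate mean relative Frobenius error of the coefficient
    matrices of a nugget + spherical(40 km) coregionalization refitted from
    300 simulated points (graded lag bins resolve the nugget)."""
    from scipy.spatial.distance import pdist, squareform

    from aodkrige.variography import (
        VariogramStructure,
        empirical_cross_variogram,
        empirical_variogram,
        fit_lmc,
    )

    structures = [
        VariogramStructure("nugget"),
        VariogramStructure("spherical", 40.0),
    ]
    b_true = [
        np.array([[15.0, 0.0], [0.0, 1.5]]),
        np.array([[45.0, 9.0], [9.0, 4.5]]),
    ]
    errs = []
    for rep in range(nrep):
        r = np.random.default_rng(200 + rep)
        xy = r.uniform(0, 160, (300, 2))
        h = squareform(pdist(xy))
        z = np.zeros((2, 300))
        for st, B in zip(structures, b_true):
            vals, vecs = np.linalg.eigh(B)
            A = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
            if st.family == "nugget":
                lat = r.standard_normal((2, 300))
            else:
                L = np.linalg.cholesky(
                    st.unit_correlogram(h) + 1e-10 * np.eye(300)
                )
                lat = r.standard_normal((2, 300)) @ L.T
            z += A @ lat
        bins = [0, 3, 6, 10, 15, 21, 28, 36, 45, 55]
        d1 = empirical_variogram(xy, z[0], bins, "direct-z1")
        d2 = empirical_variogram(xy, z[1], bins, "direct-z2")
        x12 = empirical_cross_variogram(xy, z[0], z[1], bins)
        fit = fit_lmc(d1, d2, x12, structures)
        errs.append(
            np.mean(
                [
                    np.linalg.norm(bf - bt) / np.linalg.norm(bt)
                    for bf, bt in zip(fit.b_mats, b_true)
                ]
            )
        )
    return errs


def loocv_replicate(seed, n_days=30):
    """One synthetic-world LOOCV comparison under the study conditions:
    cross-correlation 0.7, 60 stations, 40% cloud cover, per-day fitted
    models.  Returns (BK mean RMSE, BCK mean RMSE)."""
    from aodkrige.cokriging import CovariateRecord
    from aodkrige.pipeline_io import fit_daily_models
    from aodkrige.validation import loocv, summarize

    cfg = SimulationConfig(
        grid_size=32, n_days=n_days, n_stations=60, cloud_fraction=0.4,
        seed=seed, n_subdistricts=20,
    )
    world = make_world(cfg)
    cov = []
    for t, date in enumerate(world.dates):
        for c in np.flatnonzero(np.isfinite(world.covariate[t])):
            cov.append(
                CovariateRecord(
                    int(c), float(world.cell_xy[c, 0]),
                    float(world.cell_xy[c, 1]), date,
                    float(world.covariate[t, c]),
                )
            )
    cov_by_day = {}
    for r in cov:
        cov_by_day.setdefault(r.date, []).append(r)
    models = fit_daily_models(
        world.stations, cov_by_day, list(np.linspace(0, 500, 11))
    )
    rec_bk = loocv(world.stations, [], models, method="BK")
    rec_bck = loocv(world.stations, cov, models, method="BCK")
    return summarize(rec_bk).mean_rmse, summarize(rec_bck).mean_rmse


def qp_oracle_weights(model, p_xy, s_xy, block_points):
    """Generic equality-constrained QP solved by the null-space method.

    Minimizes the prediction variance sigma^2(lam) = Cvv - 2 lam'c + lam'C lam
    subject to sum(lam1) = 1, sum(lam2) = 0, without forming the kriging
    system's Lagrangian: the constraints are eliminated through an SVD null
    space and the reduced unconstrained quadratic is solved directly.
    Returns (weights, objective value).
    """
    from scipy.linalg import null_space

    from aodkrige.cokriging import cov_between

    n1 = len(p_xy)
    n2 = 0 if s_xy is None else len(s_xy)
    n = n1 + n2
    C = np.zeros((n, n))
    C[:n1, :n1] = cov_between(model, "11", p_xy, p_xy)
    if n2:
        C[:n1, n1:] = cov_between(model, "12", p_xy, s_xy)
        C[n1:, :n1] = C[:n1, n1:].T
        C[n1:, n1:] = cov_between(model, "22", s_xy, s_xy)
    c = np.zeros(n)
    c[:n1] = cov_between(model, "11", p_xy, block_points).mean(axis=1)
    if n2:
        c[n1:] = cov_between(model, "12", s_xy, block_points).mean(axis=1)
    ncon = 2 if n2 else 1
    A = np.zeros((ncon, n))
    A[0, :n1] = 1.0
    if n2:
        A[1, n1:] = 1.0
    b = np.zeros(ncon)
    b[0] = 1.0
    lam0, *_ = np.linalg.lstsq(A, b, rcond=None)
    N = null_space(A)
    if N.size:
        u = np.linalg.solve(N.T @ C @ N, N.T @ (c - C @ lam0))
        lam = lam0 + N @ u
    else:
        lam = lam0
    cvv = cov_between(model, "11", block_points, block_points).mean()
    obj = float(cvv - 2 * lam @ c + lam @ C @ lam)
    return lam, obj
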
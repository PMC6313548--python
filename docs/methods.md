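# Methods

## Spatial model

Ground PM2.5 (Z₁, µg/m³) and satellite AOD (Z₂, dimensionless) are modelled
as a jointly stationary pair under a **linear model of coregionalization
(LMC)**: a shared, ordered set of elementary correlation structures
ρ_k(h) — nugget, spherical, exponential, gaussian — each weighted by a 2×2
symmetric positive-semidefinite coefficient matrix B_k, so that

    C_ab(h) = Σ_k B_k[a,b] · ρ_k(h),  a, b ∈ {1, 2}.

PSD-ness of every B_k is necessary and sufficient for the joint covariance
to be valid, and is enforced everywhere (model constructor, fitting,
simulation). Exponential and gaussian structures use the *practical-range*
convention, ρ(h) = exp(−3h/a) and exp(−3(h/a)²): the stated range is where
95% of the sill is reached. The nugget contributes to covariance only at
exactly h = 0.

### Variography

Empirical direct semivariograms use the Matheron estimator
γ̂(h) = Σ_pairs (zᵢ−zⱼ)²/(2N(h)); the cross estimator replaces the squared
difference with the product of the two variables' differences. AOD is
collocated to each station's *nearest grid cell* — if that cell is masked
the pair is simply missing; a farther cell is never substituted, to avoid
smuggling smoothed covariate information into the cross variogram.

Single-variable fits are weighted least squares with Cressie weights
N(h)/h², over nugget + one continuous structure per candidate family
{spherical, exponential, gaussian}; a pure-nugget candidate is always
present and a continuous family must *strictly* improve the weighted SSE to
displace it. The LMC is then fitted with the structure set (families and
ranges) frozen from the primary variable's marginal fit, by the
Goulard–Voltz algorithm: coordinate descent over the B_k, each update being
the component-wise WLS solution on the residual variogram followed by
projection to the nearest PSD matrix (eigenvalue clipping at zero). The
procedure is deterministic; non-convergence after 200 sweeps returns the
last iterate flagged `converged=False`.

In the pipeline one LMC is fitted per day from that day's stations; days
with fewer than 30 stations (configurable) reuse the most recent successful
fit, and leading sparse days borrow the first one.

### Kriging system

For block v discretized into m points (default 64, convergence-tested to
<1% change in the block covariance from m=64 to 256), the ordinary block
cokriging weights solve the symmetric linear system of data covariances
bordered with the two unbiasedness constraint rows (Σλ₁ = 1, Σλ₂ = 0) and
Lagrange multipliers; with no secondary data the second constraint row is
dropped and the system is plain ordinary block kriging. The prediction
variance is C̄(v,v) − λᵀc − μ₁. The block-to-block and point-to-block
covariances are discrete averages over the m points, with the nugget
counted only on exactly-zero distances; as m grows the within-block nugget
contribution vanishes like 1/m, matching the continuous-average limit.

Numerical choices: duplicate coordinates are averaged before solving (a
still-singular system raises); ties in neighbor selection break by
ascending station/cell id; negative estimates are clamped to 0 and flagged;
tiny negative variances from round-off are clipped at 0. Neighborhoods
default to the 16 nearest stations and 16 nearest non-missing AOD cells
within 500 km of the block centroid — the classical local-kriging
compromise, all configurable.

The solver is tested against an independent equality-constrained
quadratic-program oracle (null-space elimination of the constraints, no
Lagrangian) on random configurations, and the BCK variance is verified
never to exceed the BK variance on shared data — the BK solution with
λ₂ = 0 is always BCK-feasible.

### Validation

LOOCV predicts each station-day at the station's own location (point
support) from its neighbors, with the held-out record removed from the
primary data and the day's model held fixed (no per-fold refitting); BCK
additionally uses the day's AOD records, BK none. Yearly COR/RMSE are the
unweighted means of per-day statistics (pooled-over-records versions are
also reported); a method is preferred only if it wins on both.

## Exposure indicators

A pollution day is a day whose 24-h mean **meets or exceeds** the daily
standard (the boundary day counts). Missing predicted days are excluded
from the duration count and reported alongside it, never imputed. The
identities E = p·D and EI = D·p/a are computed exactly (integer × float),
and segment results (children ≤14, adults 15–64, seniors ≥65, susceptible =
children+seniors) are linear in p, so segments that partition the
population add up exactly. Durations convert to months at 30 days/month,
and "half a year" is operationalized as 180 days (the calendar alternative
183 is one config value away). The standards registry ships with the
Chinese daily standard (75 µg/m³), the three WHO interim targets (75, 50,
37.5) and the WHO guideline (25); arbitrary standards are accepted.

## Scenarios

A scenario maps region labels to fractional reductions r ∈ [0, 1) of the
annual mean. Every day of every subdistrict in the region is scaled by
(1 − r) — the unique shape-preserving scaling achieving the annual-mean
target — and standard errors scale with it. Where a jurisdiction's target
is stated for a different pollutant (e.g. PM10), no conversion is
attempted: the per-region r is user input. Life-expectancy effects use a
linear dose–response of 3 years per 30 µg/m³ (configurable step and
effect). A population-sensitivity utility recomputes exposure under two
population tables over identical geometries.

## Synthetic worlds

The generator emulates the statistical situation the method assumes:

- **Fields.** Daily (Z₁, Z₂) pairs are drawn exactly from the LMC by dense
  Cholesky factorization of each structure's grid correlation (grids capped
  at 64×64; exactness over speed at desk scale), combined through eigen
  square roots of the B_k. The pollutant mean surface is baseline (60) +
  a sinusoid of amplitude 25 peaking mid-January + a **persistent regional
  anomaly**: one extra coregionalized draw, fixed per world and rescaled to
  sd 15 µg/m³, shared proportionally with the covariate. The anomaly gives
  the world stable hotspots, without which every subdistrict would converge
  to the same annual duration and all between-district exposure contrasts
  would be noise. Given the mean surface, days are independent — each day
  is interpolated independently downstream, so temporal autocorrelation
  would add realism no stage consumes. Negative pollutant values are
  clamped to 0 (rare: <1% of cells once the mean exceeds ~3 sd).
- **Cloud masks.** A smooth gaussian-correlogram field (correlation length
  150 km) thresholded at its per-day quantile produces contiguous missing
  patches with the target daily missing fraction (default 0.4).
- **Stations.** 60 by default, cells sampled without replacement with
  probability (1−c)·uniform + c·pollution-weight (c = clustering, default
  0.5) — pollution standing in for population density, which it is built to
  correlate with — then jittered within the cell. Observations are truth at
  the station's cell; measurement noise is available but defaults to 0
  because the LMC nugget already carries the micro-scale/measurement
  variance.
- **Subdistricts and population.** Voronoi tessellation of uniform seeds
  clipped to the domain (or a regular grid); log-normal population density
  tied to annual-mean pollution through a Gaussian copula at the requested
  Spearman correlation (default 0.5), using ρ_pearson = 2·sin(π·ρ_s/6);
  age-segment counts by largest-remainder rounding so segments always sum
  exactly to the total.

**What passing on synthetic data does not show:** real PM2.5 is
non-Gaussian (right-skewed), temporally autocorrelated, and its AOD
relationship varies with humidity, boundary-layer height and season; real
station networks are far more clustered and the real covariate is biased,
not just noisy. Results here certify the estimator, solver, and accounting
machinery under the model's own assumptions, not real-data skill.

## Coordinates

External data are WGS84 lon/lat; internally everything is planar km via a
spherical Albers equal-area conic (origin 105°E/35°N, standard parallels
26.5°/45°, chosen to minimise the maximum linear scale distortion over
22–48°N). Areas are preserved exactly by construction; meridian distances
are within 1% of the great-circle arc near the parallels and within ~1.4%
at the band edges and midpoint — the unavoidable trade of an equal-area
conic spanning a 26° band. The closed-form inverse round-trips to 1e-6
degrees.

## Problem sizes

Defaults are desk-scale: 32×32 grids (~31 km cells on a 1000 km domain), 60
stations, 100 subdistricts, and study windows of 30–61 days (the
acceptance script samples a full year at a 6-day stride and annualizes
day counts by the stride). All sizes are configuration, not assumptions;
the algorithms are O(n³) only in the local neighborhood (≤ ~34 unknowns per
block) and in the one-off grid Cholesky.

## Known limitations

No anisotropy; no spatiotemporal (3-D) variography; no trend/universal
kriging; variogram-estimation uncertainty is not propagated into the
kriging variance; LOOCV holds the daily model fixed rather than refitting
per fold; the WLS range estimate of the exponential family carries a known
small-sample positive bias (~15% at n = 300).
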
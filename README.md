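# aodkrige

Block cokriging of ground-level PM2.5 with satellite aerosol optical depth
(AOD), leave-one-out validation, and subdistrict-level population-exposure
assessment with policy-scenario simulation.

## The problem

Daily fine-particulate (PM2.5) exposure assessment at national scale needs a
concentration surface, but monitoring stations are sparse and clustered in
cities. Satellite AOD is spatially dense and correlated with ground PM2.5,
yet full of cloud-driven gaps. **Block cokriging (BCK)** handles both
problems at once: it predicts the areal mean of the pollutant over each
administrative unit ("block") as a best linear unbiased combination of
station observations *Z₁* and whatever AOD cells *Z₂* happen to be present,

```
Ẑ₁(v) = Σᵢ λ₁ᵢ(v) Z₁(s₁ᵢ) + Σⱼ λ₂ⱼ(v) Z₂(s₂ⱼ),   Σᵢ λ₁ᵢ = 1,  Σⱼ λ₂ⱼ = 0,
```

with weights minimising the prediction variance under a jointly valid
spatial covariance model (a linear model of coregionalization, LMC). With no
usable AOD the system reduces to ordinary block kriging (BK). Model skill is
scored by leave-one-out cross-validation (LOOCV): Pearson correlation (COR)
and RMSE = √(n⁻¹ Σ (Ẑ₁(vᵢ) − Z₁(vᵢ))²); the preferred method must win on
both.

The predicted daily surfaces feed three exposure indicators per subdistrict
*v* with population *p_v* and area *a_v*, under a daily standard *C*
(pollution day: 24-h mean ≥ C):

- exposure duration `D_v` — number of pollution days in the period,
- total exposure `E_v = p_v · D_v` (person-days),
- exposure intensity `EI_v = D_v · p_v / a_v` (day·persons/km²),

aggregated by population weighting (Σ p x / Σ p), with durations expressed
in 30-day months. A policy scenario scales each region's daily series by
(1 − r) for a fractional annual-mean reduction r and re-runs the exposure
stage; concentration changes convert to life expectancy at 3 years per
30 µg/m³.

Because the station, satellite, and census inputs of such studies are rarely
redistributable, the package ships a first-class synthetic-data generator:
coregionalized Gaussian random fields with winter-peaking seasonality and a
persistent regional anomaly, cloud-like contiguous covariate masks, sparse
clustered station networks, Voronoi subdistrict tessellations, and
age-segmented populations rank-correlated with pollution. Every downstream
stage is testable with no download.

## Worked example

```python
import numpy as np
from aodkrige.synthetic_data import SimulationConfig, make_world
from aodkrige.pipeline_io import fit_daily_models
from aodkrige.cokriging import CovariateRecord, Neighborhood, interpolate_day
from aodkrige.validation import loocv, summarize, compare_methods

cfg = SimulationConfig(grid_size=24, n_days=10, n_stations=50, seed=42)
world = make_world(cfg)

cov_by_day = {}
for t, date in enumerate(world.dates):
    for c in np.flatnonzero(np.isfinite(world.covariate[t])):
        cov_by_day.setdefault(date, []).append(
            CovariateRecord(int(c), *world.cell_xy[c], date,
                            float(world.covariate[t, c])))

models = fit_daily_models(world.stations, cov_by_day,
                          lag_bins=list(np.linspace(0, 500, 11)))
cov_all = [r for recs in cov_by_day.values() for r in recs]
summary_bk = summarize(loocv(world.stations, [], models, method="BK"))
summary_bck = summarize(loocv(world.stations, cov_all, models, method="BCK"))
report = compare_methods(summary_bk, summary_bck)
print(f"BK : COR {summary_bk.mean_cor:.3f}  RMSE {summary_bk.mean_rmse:.1f} ug/m3")
print(f"BCK: COR {summary_bck.mean_cor:.3f}  RMSE {summary_bck.mean_rmse:.1f} ug/m3")
print(f"preferred: {report['preferred']}")

day0 = [s for s in world.stations if s.date == world.dates[0]]
preds = interpolate_day(day0, cov_by_day[world.dates[0]],
                        models[world.dates[0]], world.subdistricts,
                        Neighborhood(m_points=32))
p = preds[0]
print(f"{p.subdistrict_id} {p.date}: {p.estimate:.1f} +/- {p.se:.1f} ug/m3 "
      f"({p.method}, n1={p.n1}, n2={p.n2})")
```

prints

```
BK : COR 0.485  RMSE 25.7 ug/m3
BCK: COR 0.580  RMSE 24.1 ug/m3
preferred: BCK
V0000 2013-04-08: 77.4 +/- 7.5 ug/m3 (BCK, n1=16, n2=16)
```

On this synthetic world the covariate lifts the LOOCV correlation from 0.49
to 0.58 and cuts the RMSE by 1.6 µg/m³, so cokriging is preferred on both
criteria. The last line is one subdistrict-day block prediction with its
kriging standard error and the neighborhood actually used (16 stations, 16
non-missing AOD cells).

## Command line

The same stages are exposed as a CLI over a JSON config:

```
aodkrige run --outdir out --seed 11          # simulate + all stages
aodkrige exposure --config pipeline.json     # one stage, reading artifacts
```

Stages: `simulate`, `fit-variograms`, `interpolate`, `validate`,
`exposure`, `scenario`, `run`. Formats: stations CSV
(`station_id, lon, lat, date, pm25`), covariate NetCDF per day (NaN =
missing), subdistricts GeoJSON (population by segment and a region label),
models/manifests/scenarios JSON. Runs are deterministic for a fixed seed.

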
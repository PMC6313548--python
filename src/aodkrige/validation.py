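"""Leave-one-out cross-validation of BK against BCK.

Each station-day is predicted at the station's own location (point support)
from its neighboring stations, with the held-out record removed from the
primary data; BCK additionally uses all non-missing covariate cells for the
day, BK uses ground observations only.  Agreement is scored by Pearson
correlation (COR) and root-mean-square error (RMSE); the preferred method is
the one that wins on both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cokriging import (
    CovariateRecord,
    Neighborhood,
    StationRecord,
    predict_block,
    solve_bck_system,
)
from .variography import CoregionalizationModel

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "loocv",
    "rmse",
    "pearson_cor",
    "summarize",
    "compare_methods",
]


@dataclass(frozen=True)
class ValidationRecord:
    station_id: str
    date: str
    observed: float
    predicted: float
    method: str


@dataclass
class ValidationSummary:
    method: str
    mean_cor: float  # unweighted mean of per-day Pearson r
    mean_rmse: float  # unweighted mean of per-day RMSE, ug/m3
    pooled_cor: float
    pooled_rmse: float
    per_day: dict[str, tuple[float, float]]  # date -> (cor, rmse)
    n_records: int


def _group_by_date(records):
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.date, []).append(r)
    return out


def loocv(
    stations: list[StationRecord],
    covariate: list[CovariateRecord],
    model: CoregionalizationModel | dict[str, CoregionalizationModel],
    method: str = "BCK",
    neighborhood: Neighborhood | None = None,
) -> list[ValidationRecord]:
    """Hold out each station-day and predict it from its neighbors.

    ``model`` may be one LMC for all days or a per-date mapping.  Days with
    fewer than 2 stations are excluded.  ``method`` is ``BK`` (primary data
    only) or ``BCK`` (primary plus covariate).
    """
    if method not in ("BK", "BCK"):
        raise ValueError(f"unknown method {method!r}")
    nb = neighborhood or Neighborhood()
    by_day = _group_by_date(stations)
    cov_by_day = _group_by_date(covariate) if method == "BCK" else {}
    out: list[ValidationRecord] = []
    for date in sorted(by_day):
        day = by_day[date]
        if len(day) < 2:
            continue
        day_model = model[date] if isinstance(model, dict) else model
        xy = np.array([[s.x, s.y] for s in day])
        vals = np.array([s.pm25 for s in day])
        ids = np.array([s.station_id for s in day])
        cov_day = cov_by_day.get(date, [])
        if cov_day:
            s_xy = np.array([[c.x, c.y] for c in cov_day])
            s_val = np.array([c.aod for c in cov_day])
            s_ids = np.array([c.cell_id for c in cov_day])
        for i, target in enumerate(day):
            keep = np.arange(len(day)) != i
            t_xy = np.array([target.x, target.y])
            d = np.hypot(xy[keep, 0] - t_xy[0], xy[keep, 1] - t_xy[1])
            order = np.lexsort((ids[keep], d))[: nb.k1]
            p_xy = xy[keep][order]
            p_val = vals[keep][order]
            if method == "BCK" and cov_day:
                ds = np.hypot(s_xy[:, 0] - t_xy[0], s_xy[:, 1] - t_xy[1])
                sel = np.lexsort((s_ids, ds))
                sel = sel[ds[sel] <= nb.radius_km][: nb.k2]
                sec_xy = s_xy[sel] if len(sel) else None
                sec_val = s_val[sel] if len(sel) else None
            else:
                sec_xy = sec_val = None
            system = solve_bck_system(
                p_xy, p_val, sec_xy, sec_val, day_model, t_xy[None, :]
            )
            pred = predict_block(system, target.station_id, date)
            out.append(
                ValidationRecord(
                    station_id=target.station_id,
                    date=date,
                    observed=target.pm25,
                    predicted=pred.estimate,
                    method=method,
                )
            )
    return out


def rmse(records: list[ValidationRecord]) -> float:
    """Root-mean-square error of predictions against observations."""
    if not records:
        raise ValueError("no usable validation records")
    err = np.array([r.predicted - r.observed for r in records])
    return float(np.sqrt(np.mean(err**2)))


def pearson_cor(records: list[ValidationRecord]) -> float:
    """Pearson correlation of predicted vs observed."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    obs = np.array([r.observed for r in records])
    pred = np.array([r.predicted for r in records])
    if obs.std() == 0.0 or pred.std() == 0.0:
        raise ValueError("Pearson correlation undefined: zero variance")
    return float(np.corrcoef(obs, pred)[0, 1])


def summarize(records: list[ValidationRecord]) -> ValidationSummary:
    """Yearly summary: unweighted mean of per-day COR/RMSE, plus pooled."""
    if not records:
        raise ValueError("no records to summarize")
    method = records[0].method
    per_day = {}
    for date, recs in sorted(_group_by_date(records).items()):
        day_rmse = rmse(recs)
        try:
            day_cor = pearson_cor(recs)
        except ValueError:
            day_cor = np.nan
        per_day[date] = (day_cor, day_rmse)
    cors = np.array([c for c, _ in per_day.values()])
    rmses = np.array([r for _, r in per_day.values()])
    return ValidationSummary(
        method=method,
        mean_cor=float(np.nanmean(cors)),
        mean_rmse=float(np.mean(rmses)),
        pooled_cor=pearson_cor(records) if len(records) > 1 else np.nan,
        pooled_rmse=rmse(records),
        per_day=per_day,
        n_records=len(records),
    )


def compare_methods(
    summary_bk: ValidationSummary, summary_bck: ValidationSummary
) -> dict:
    """Prefer the method with higher COR *and* lower RMSE, else indeterminate."""
    if summary_bk.n_records != summary_bck.n_records or set(
        summary_bk.per_day
    ) != set(summary_bck.per_day):
        raise ValueError("summaries computed on different record sets")

    def wins(a: ValidationSummary, b: ValidationSummary) -> bool:
        return a.mean_cor > b.mean_cor and a.mean_rmse < b.mean_rmse

    if wins(summary_bck, summary_bk):
        preferred = summary_bck.method
    elif wins(summary_bk, summary_bck):
        preferred = summary_bk.method
    else:
        preferred = "indeterminate"
    return {
        "preferred": preferred,
        summary_bk.method: {
            "mean_cor": summary_bk.mean_cor,
            "mean_rmse": summary_bk.mean_rmse,
        },
        summary_bck.method: {
            "mean_cor": summary_bck.mean_cor,
            "mean_rmse": summary_bck.mean_rmse,
        },
    }
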
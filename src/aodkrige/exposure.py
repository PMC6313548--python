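"""Population-exposure indicators under daily air-quality standards.

A pollution day is a day whose 24-h mean concentration meets or exceeds a
daily standard C.  Over a period of tau days, each subdistrict v with
population p_v and land area a_v gets:

    exposure duration   D_v  = number of pollution days (missing days excluded)
    total exposure      E_v  = p_v * D_v          (person-days)
    exposure intensity  EI_v = D_v * p_v / a_v    (day-persons per km^2)

Durations convert to months at 30 days per month.  Aggregates use the
population-weighted mean, the average experienced by a random person rather
than a random location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Standard",
    "STANDARDS",
    "ExposureSummary",
    "exposure_duration",
    "total_exposure",
    "exposure_intensity",
    "population_weighted_mean",
    "exposed_population_curve",
    "monthly_exceedance_fraction",
    "days_to_months",
    "segment_exposure",
    "summarize_exposure",
]

DAYS_PER_MONTH = 30.0

SEGMENTS = ("children", "adults", "seniors", "susceptible", "total")


@dataclass(frozen=True)
class Standard:
    """A daily concentration standard, e.g. China's 75 ug/m3."""

    name: str
    threshold: float  # C, ug/m3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("standard threshold must be positive")


#: registry: China's daily standard, the WHO interim targets and guideline
STANDARDS = {
    "china-75": Standard("china-75", 75.0),
    "it1-75": Standard("it1-75", 75.0),
    "it2-50": Standard("it2-50", 50.0),
    "it3-37.5": Standard("it3-37.5", 37.5),
    "who-25": Standard("who-25", 25.0),
}


@dataclass
class ExposureSummary:
    subdistrict_id: str
    standard: str
    period_days: int  # tau, non-missing days counted
    missing_days: int
    duration: int  # D
    population: float  # p (segment or total)
    area_km2: float
    total_exposure: float  # E = p * D
    intensity: float  # EI = D * p / a
    segment: str = "total"


def exposure_duration(series, standard: Standard) -> tuple[int, int]:
    """Count pollution days: c >= C, the boundary day included.

    NaN entries are missing days: excluded from the count and reported.
    Returns (duration, missing_days).
    """
    c = np.asarray(series, dtype=float)
    if c.size == 0:
        raise ValueError("empty concentration series")
    missing = np.isnan(c)
    d = int(np.sum(c[~missing] >= standard.threshold))
    return d, int(missing.sum())


def total_exposure(duration: int, population: float) -> float:
    """E = p * D, in person-days."""
    if population < 0:
        raise ValueError("population must be nonnegative")
    return float(population) * duration


def exposure_intensity(duration: int, population: float, area_km2: float) -> float:
    """EI = D * p / a, in day-persons per km^2."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return duration * float(population) / area_km2


def population_weighted_mean(values, populations) -> float:
    """sum(p_v x_v) / sum(p_v)."""
    x = np.asarray(values, dtype=float)
    p = np.asarray(populations, dtype=float)
    if p.sum() <= 0:
        raise ValueError("total population must be positive")
    return float(np.sum(p * x) / p.sum())


def exposed_population_curve(durations, populations, months_grid) -> np.ndarray:
    """P(x) = sum of p_v over subdistricts with D_v >= 30 x.

    The curve of how many people are exposed above the standard for more
    than x months; non-increasing in x with P(0) = total population.
    """
    d = np.asarray(durations, dtype=float)
    p = np.asarray(populations, dtype=float)
    xs = np.asarray(months_grid, dtype=float)
    if (xs < 0).any():
        raise ValueError("months grid must be nonnegative")
    return np.array(
        [p[d >= DAYS_PER_MONTH * x].sum() for x in xs]
    )


def monthly_exceedance_fraction(
    series, dates, standard: Standard
) -> pd.Series:
    """Percentage of non-missing days per calendar month with c >= C.

    ``dates`` are ISO-8601 strings aligned with the series; months with no
    non-missing day are NaN (flagged missing, never 0).
    """
    c = np.asarray(series, dtype=float)
    idx = pd.PeriodIndex(pd.to_datetime(list(dates)), freq="M")
    df = pd.DataFrame({"c": c}, index=idx)
    def frac(g):
        ok = g["c"].notna()
        if ok.sum() == 0:
            return np.nan
        return 100.0 * (g.loc[ok, "c"] >= standard.threshold).sum() / ok.sum()
    return df.groupby(level=0).apply(frac)


def days_to_months(duration: float) -> float:
    """Convert pollution days to months at 30 days per month."""
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    return duration / DAYS_PER_MONTH


def _segment_population(population: dict[str, float], segment: str) -> float:
    if segment == "total":
        return float(sum(population.values()))
    if segment == "susceptible":
        return float(population["children"] + population["seniors"])
    if segment in population:
        return float(population[segment])
    raise ValueError(f"unknown population segment {segment!r}")


def summarize_exposure(
    predictions: pd.DataFrame,
    subdistricts,
    standards=None,
    segments: tuple[str, ...] = ("total",),
) -> pd.DataFrame:
    """Exposure table per subdistrict x standard x segment.

    ``predictions`` has columns (subdistrict_id, date, estimate); NaN
    estimates are missing days.  Returns a tidy DataFrame with D, E and EI
    columns; the identities E = pD and EI = Dp/a hold exactly by
    construction.
    """
    standards = list((standards or STANDARDS).values()) \
        if isinstance(standards or STANDARDS, dict) else list(standards)
    by_sd = {sd.id: sd for sd in subdistricts}
    rows = []
    for sid, grp in predictions.groupby("subdistrict_id", sort=True):
        sd = by_sd[str(sid)]
        series = grp.sort_values("date")["estimate"].to_numpy()
        for std in standards:
            d, miss = exposure_duration(series, std)
            for seg in segments:
                p = _segment_population(sd.population, seg)
                rows.append(
                    {
                        "subdistrict_id": sd.id,
                        "standard": std.name,
                        "segment": seg,
                        "period_days": len(series) - miss,
                        "missing_days": miss,
                        "duration": d,
                        "population": p,
                        "area_km2": sd.area_km2,
                        "total_exposure": total_exposure(d, p),
                        "intensity": exposure_intensity(d, p, sd.area_km2),
                    }
                )
    return pd.DataFrame(rows)


def segment_exposure(summary: pd.DataFrame, segment: str) -> pd.DataFrame:
    """Slice one population segment out of a tidy exposure table."""
    if segment not in SEGMENTS:
        raise ValueError(f"unknown population segment {segment!r}")
    out = summary[summary["segment"] == segment]
    if out.empty:
        raise ValueError(f"segment {segment!r} absent from the summary")
    return out.reset_index(drop=True)
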
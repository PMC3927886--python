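"""Per-generation dispersal distance from isolation-by-distance theory.

For a one-dimensional habitat at migration–drift equilibrium, the slope
``m`` of the regression of ``F_ST/(1-F_ST)`` on along-shore distance
relates to the axial dispersal standard deviation ``sigma`` and the
effective density ``De`` (effective population size per km of coastline)
as

    m = 1 / (4 * De * sigma**2)      <=>      sigma = (4 * De * m) ** -0.5

This module converts coalescent ``theta = 4 Ne mu`` estimates to ``Ne``
using bounds on the microsatellite mutation rate, aggregates per-sample
``Ne`` estimates (mean of the finite values), divides by the sampled span
to get ``De``, solves for ``sigma`` with worst-case interval propagation,
and carries the parallel census arithmetic (SCUBA transect extrapolation,
REEF abundance index, Ne/N).

Interval convention: ``sigma`` decreases in both ``De`` and ``m``, so the
lower sigma bound pairs the upper density and slope bounds and vice versa;
a configurable floor (default 1 fish/km) replaces a vanishing lower
density bound so the upper sigma bound stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MU_MEAN",
    "MU_BOUNDS",
    "NE_INFINITY_THRESHOLD",
    "SPAN_KM_DEFAULT",
    "NeRecord",
    "ThetaRecord",
    "DensityEstimate",
    "DispersalEstimate",
    "CensusEstimate",
    "ne_from_theta",
    "aggregate_finite",
    "effective_density",
    "sigma_point",
    "expected_slope",
    "sigma_interval",
    "census_extrapolate",
    "reef_index",
    "ne_over_n",
]

# microsatellite mutation rate per locus per generation: survey mean over
# published fish pedigrees, with conservative lower/upper bounds
MU_MEAN = 7.2e-4
MU_BOUNDS = (1e-5, 9.1e-3)
# Ne estimates above this are treated as infinite (estimator failure)
NE_INFINITY_THRESHOLD = 1e8
# coastline span covered by the nine-site sampling design, km
SPAN_KM_DEFAULT = 1361.0


@dataclass
class NeRecord:
    """Effective population size estimate with CI, per method and sample.

    ``point``/``low``/``high`` may be ``inf`` (estimator returned an
    unrealistically large value) or ``nan`` (negative/invalid estimate).
    """

    method: str
    population: str
    low: float
    point: float
    high: float

    def finite_point(self) -> bool:
        return bool(np.isfinite(self.point) and self.point >= 0)

    @staticmethod
    def parse_value(x, infinity_threshold: float = NE_INFINITY_THRESHOLD) -> float:
        """Map a table entry to float: 'neg' -> NaN, 'inf' or a value above
        the infinity threshold -> +inf."""
        if isinstance(x, str):
            s = x.strip().lower()
            if s == "neg":
                return math.nan
            if s == "inf":
                return math.inf
            x = float(s)
        x = float(x)
        if x < 0:
            return math.nan
        if x > infinity_threshold:
            return math.inf
        return x


@dataclass
class ThetaRecord:
    """Coalescent ``theta = 4 Ne mu`` with CI, plus mutation-rate bounds."""

    theta: float
    low: float
    high: float
    mu: float = MU_MEAN
    mu_bounds: tuple[float, float] = MU_BOUNDS


@dataclass
class DensityEstimate:
    """Effective density ``De = Ne / L`` in fish per km of coastline."""

    method: str
    low: float
    point: float
    high: float
    span_km: float


@dataclass
class DispersalEstimate:
    """Axial dispersal sigma (km/generation) with propagated CI."""

    method: str
    low: float
    point: float
    high: float
    de_floor: float
    slope: float
    slope_ci: tuple[float, float]


@dataclass
class CensusEstimate:
    """Census population size from transect density extrapolation."""

    n_point: float
    n_low: float
    n_high: float
    density_per_km2: float
    habitat_km2: float
    span_km: float
    mean_count: float
    se_count: float
    transect_area_m2: float


def ne_from_theta(rec: ThetaRecord) -> NeRecord:
    """Convert ``theta`` to ``Ne`` through ``Ne = theta / (4 mu)``.

    The CI combines both uncertainties in the worst case: the lower bound
    uses the upper mutation rate and vice versa.
    """
    mu_low, mu_high = rec.mu_bounds
    if rec.mu <= 0 or mu_low <= 0:
        raise ValueError("mutation rate must be positive")
    return NeRecord(
        method="coalescent",
        population="pooled",
        low=rec.low / (4 * mu_high),
        point=rec.theta / (4 * rec.mu),
        high=rec.high / (4 * mu_low),
    )


def aggregate_finite(
    records: list[NeRecord],
    exclude_pooled: bool = True,
) -> NeRecord:
    """Mean of the finite estimates, applied columnwise to point and bounds.

    Each column (low, point, high) is averaged independently over its own
    finite, non-negative entries — a record whose point estimate failed can
    still contribute a finite bound.  The all-samples-pooled record is
    excluded by default (it is not an independent draw of the
    metapopulation Ne).  If a column has no finite entries the result is
    ``inf`` when any entry was infinite, else ``nan`` (flagged undefined).
    """
    if exclude_pooled:
        records = [r for r in records if r.population != "pooled"]
    if not records:
        raise ValueError("no records to aggregate")

    def col_mean(vals: list[float]) -> float:
        arr = np.array(vals, dtype=float)
        finite = arr[np.isfinite(arr) & (arr >= 0)]
        if finite.size:
            return float(finite.mean())
        return math.inf if np.isinf(arr).any() else math.nan

    method = records[0].method
    return NeRecord(
        method=method,
        population="mean_of_finite",
        low=col_mean([r.low for r in records]),
        point=col_mean([r.point for r in records]),
        high=col_mean([r.high for r in records]),
    )


def effective_density(ne: NeRecord, span_km: float = SPAN_KM_DEFAULT) -> DensityEstimate:
    """``De = Ne / L`` applied to the point estimate and both bounds."""
    if span_km <= 0:
        raise ValueError("span must be positive")
    return DensityEstimate(
        method=ne.method,
        low=ne.low / span_km,
        point=ne.point / span_km,
        high=ne.high / span_km,
        span_km=span_km,
    )


def sigma_point(de: float, m: float) -> float:
    """Axial dispersal sigma (km/generation) from density and IBD slope."""
    if not (m > 0):
        raise ValueError("IBD slope must be positive (no-IBD-signal)")
    if not (de > 0):
        raise ValueError("effective density must be positive")
    return (4.0 * de * m) ** -0.5


def expected_slope(de: float, sigma: float) -> float:
    """Inverse relation: the IBD slope implied by density and dispersal."""
    if de <= 0 or sigma <= 0:
        raise ValueError("density and sigma must be positive")
    return 1.0 / (4.0 * de * sigma**2)


def sigma_interval(
    de: DensityEstimate,
    slope: float,
    slope_ci: tuple[float, float],
    de_floor: float = 1.0,
) -> DispersalEstimate:
    """Propagate density and slope intervals to a sigma interval.

    ``sigma_low = sigma(De_high, m_high)``; ``sigma_high =
    sigma(max(De_low, floor), m_low)``.  The floor (default 1 fish/km)
    applies only to the lower density bound: as ``De -> 0`` sigma diverges,
    so a stated lowest credible density keeps the upper dispersal bound
    finite and conservative.
    """
    m_low, m_high = slope_ci
    if not np.isfinite(de.high) or de.high <= 0:
        raise ValueError("upper density bound must be positive and finite")
    de_low_eff = max(de.low if np.isfinite(de.low) else 0.0, de_floor)
    return DispersalEstimate(
        method=de.method,
        low=sigma_point(de.high, m_high),
        point=sigma_point(de.point, slope),
        high=sigma_point(de_low_eff, m_low),
        de_floor=de_floor,
        slope=slope,
        slope_ci=slope_ci,
    )


def census_extrapolate(
    mean_count: float,
    se_count: float,
    transect_area_m2: float = 90.0,
    habitat_km2_per_coast: float = 113.36 / 431.0,
    span_km: float = SPAN_KM_DEFAULT,
    z: float = 1.96,
) -> CensusEstimate:
    """Scale mean transect counts up to a coastline-wide census size.

    ``density = count / area`` (fish/m^2, converted to fish/km^2) times the
    habitat area ``habitat_km2_per_coast * span_km``; the CI propagates
    ``count +- z * se`` linearly (everything downstream of the count is a
    fixed multiplier).
    """
    if transect_area_m2 <= 0 or span_km <= 0:
        raise ValueError("areas and span must be positive")
    habitat_km2 = habitat_km2_per_coast * span_km
    scale = 1e6 / transect_area_m2 * habitat_km2  # fish per unit count
    return CensusEstimate(
        n_point=mean_count * scale,
        n_low=max(mean_count - z * se_count, 0.0) * scale,
        n_high=(mean_count + z * se_count) * scale,
        density_per_km2=mean_count / transect_area_m2 * 1e6,
        habitat_km2=habitat_km2,
        span_km=span_km,
        mean_count=mean_count,
        se_count=se_count,
        transect_area_m2=transect_area_m2,
    )


def reef_index(
    tallies: dict[str, int],
    total_surveys: int,
) -> tuple[float, float]:
    """REEF-style weighted abundance index and sighting frequency.

    ``tallies`` counts surveys per abundance category (``single``=1,
    ``few``=2, ``many``=3, ``abundant``=4).  The index averages the scores
    over surveys with sightings; SF is sightings / total surveys.  With no
    sightings the index is NaN and SF is 0.
    """
    scores = {"single": 1, "few": 2, "many": 3, "abundant": 4}
    unknown = set(tallies) - set(scores)
    if unknown:
        raise ValueError(f"unknown abundance categories: {sorted(unknown)}")
    if total_surveys <= 0:
        raise ValueError("total_surveys must be positive")
    sightings = sum(tallies.values())
    if sightings > total_surveys:
        raise ValueError("more sightings than surveys")
    if sightings == 0:
        return math.nan, 0.0
    weighted = sum(scores[k] * v for k, v in tallies.items()) / sightings
    return float(weighted), sightings / total_surveys


def ne_over_n(ne: NeRecord, census: CensusEstimate) -> dict:
    """``Ne/N`` with worst-case interval propagation (low = Ne_low/N_high)."""
    if census.n_point <= 0:
        raise ValueError("census size must be positive")
    return {
        "method": ne.method,
        "point": ne.point / census.n_point,
        "low": (ne.low / census.n_high) if census.n_high > 0 else math.nan,
        "high": (ne.high / census.n_low) if census.n_low > 0 else math.inf,
    }


# ---------------------------------------------------------------------------
# fixture-table plumbing

def ne_records_from_table(df: pd.DataFrame, method: str) -> list[NeRecord]:
    """Rows of a Table-6-style CSV (method, population, low, mean, high)
    into NeRecords, mapping 'neg' to NaN and 'inf'/oversize to infinity."""
    sub = df[df["method"] == method]
    out = []
    for _, row in sub.iterrows():
        out.append(
            NeRecord(
                method=method,
                population=str(row["population"]),
                low=NeRecord.parse_value(row["low"]),
                point=NeRecord.parse_value(row["mean"]),
                high=NeRecord.parse_value(row["high"]),
            )
        )
    return out
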
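"""Population-weighted regional life expectancy, gap/shortfall series, gender summaries.

The regional LE for a period and sex is the population-weighted mean of
member-country LE values (weights are each country's population for that
slice). Two comparison series follow the standard health-monitoring framing:
the *gap* (region minus a world average, signed) and the *shortfall* (the
best comparator's LE minus the region's, a non-negative deficit whenever the
comparator set contains the best performer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_model import (
    BOTH,
    EmptySliceError,
    FEMALE,
    MALE,
    Panel,
    Period,
    RegionDefinition,
)

logger = logging.getLogger(__name__)


class DegenerateWeightsError(ValueError):
    """All weights are zero for a requested aggregation."""


@dataclass(frozen=True)
class GenderDisparity:
    """Female/male LE comparison: difference (F − M, years),
    percent difference (100·(F − M)/F) and ratio (F/M)."""

    le_female: float
    le_male: float

    @property
    def difference(self) -> float:
        return self.le_female - self.le_male

    @property
    def pct_difference(self) -> float:
        return 100.0 * (self.le_female - self.le_male) / self.le_female

    @property
    def ratio(self) -> float:
        return self.le_female / self.le_male


@dataclass(frozen=True)
class SeriesPoint:
    period: Period
    weighted_le: float
    total_population: float
    gap: float | None = None
    shortfall: float | None = None


@dataclass(frozen=True)
class RegionalSeries:
    region: str
    sex: str
    points: tuple[SeriesPoint, ...]


def member_slice(
    panel: Panel,
    region: RegionDefinition,
    period: Period | str,
    sex: str,
    derive_both: bool = True,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Member-country LE and population arrays for one (region, period, sex).

    When ``sex == 'both'`` and a country has no 'both' row, the both-sex LE is
    derived as the sex-population-weighted mean of its female and male rows
    (population = female + male). Countries with no usable record are skipped
    and logged; an empty result raises :class:`EmptySliceError`.
    """
    period = Period.parse(period)
    countries: list[str] = []
    les: list[float] = []
    pops: list[float] = []
    missing: list[str] = []
    for member in sorted(region.members):
        rec = panel.get(member, period, sex)
        if rec is not None:
            countries.append(member)
            les.append(rec.le)
            pops.append(rec.population)
            continue
        if sex == BOTH and derive_both:
            f = panel.get(member, period, FEMALE)
            m = panel.get(member, period, MALE)
            if f is not None and m is not None:
                countries.append(member)
                les.append(both_sex_le(f.le, m.le, f.population, m.population))
                pops.append(f.population + m.population)
                continue
        missing.append(member)
    if missing:
        logger.info(
            "region %r, period %s, sex %s: %d member(s) without records: %s",
            region.name, period.label, sex, len(missing), missing,
        )
    if not countries:
        raise EmptySliceError(
            f"no records for region {region.name!r}, period {period.label}, sex {sex}"
        )
    return countries, np.asarray(les, dtype=float), np.asarray(pops, dtype=float)


def weighted_regional_le(
    panel: Panel,
    region: RegionDefinition,
    period: Period | str,
    sex: str,
) -> float:
    """Population-weighted mean LE over the region's members for one slice."""
    _, les, pops = member_slice(panel, region, period, sex)
    total = float(pops.sum())
    if total <= 0:
        raise DegenerateWeightsError(
            f"total population is 0 for region {region.name!r}, "
            f"period {Period.parse(period).label}, sex {sex}"
        )
    return float(np.average(les, weights=pops))


def le_gap(region_le: float, world_le: float) -> float:
    """Signed difference region − world (positive = above the world average)."""
    if not (math.isfinite(region_le) and math.isfinite(world_le)):
        raise ValueError("le_gap requires finite inputs")
    return region_le - world_le


def le_shortfall(region_le: float, comparator_les: Iterable[float]) -> float:
    """Best comparator LE minus the region's LE.

    Non-negative whenever the comparator set includes the best performer
    (in particular when it includes the region itself).
    """
    comparators = [float(c) for c in comparator_les]
    if not comparators:
        raise ValueError("le_shortfall requires a non-empty comparator set")
    return max(comparators) - region_le


def gender_summary(le_female: float, le_male: float) -> GenderDisparity:
    """Female-vs-male LE summary. All quantities are kept at full precision;
    rounding (2 dp) is a display concern."""
    if le_female <= 0 or le_male <= 0:
        raise ValueError("gender_summary requires positive LE values")
    return GenderDisparity(le_female=float(le_female), le_male=float(le_male))


def both_sex_le(
    le_female: float, le_male: float, pop_female: float, pop_male: float
) -> float:
    """Population-weighted both-sex LE from sex-specific LE values."""
    if pop_female < 0 or pop_male < 0:
        raise ValueError("populations must be non-negative")
    total = pop_female + pop_male
    if total <= 0:
        raise DegenerateWeightsError("both_sex_le: zero total population")
    return (le_female * pop_female + le_male * pop_male) / total


def build_regional_series(
    panel: Panel,
    region: RegionDefinition,
    sex: str,
    periods: Sequence[Period | str] | None = None,
    world_le: Mapping[str, float] | None = None,
    comparator_les: Mapping[str, Sequence[float]] | None = None,
) -> RegionalSeries:
    """Weighted-LE series over periods, with optional gap and shortfall fields.

    ``world_le`` maps period labels to the world average; ``comparator_les``
    maps period labels to the comparator LE sets used for the shortfall.
    """
    if periods is None:
        periods = panel.periods
    points = []
    for p in periods:
        period = Period.parse(p)
        _, les, pops = member_slice(panel, region, period, sex)
        total = float(pops.sum())
        if total <= 0:
            raise DegenerateWeightsError(
                f"total population is 0 for {region.name!r} {period.label} {sex}"
            )
        wle = float(np.average(les, weights=pops))
        gap = None
        shortfall = None
        if world_le is not None and period.label in world_le:
            gap = le_gap(wle, world_le[period.label])
        if comparator_les is not None and period.label in comparator_les:
            shortfall = le_shortfall(wle, comparator_les[period.label])
        points.append(
            SeriesPoint(
                period=period,
                weighted_le=wle,
                total_population=total,
                gap=gap,
                shortfall=shortfall,
            )
        )
    return RegionalSeries(region=region.name, sex=sex, points=tuple(points))
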
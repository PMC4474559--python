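"""Between-country disparity metrics over life-expectancy slices.

Six measures, three absolute and three relative, spanning the 'simple'
(range-based) and 'complex' (all-country) families used in health-disparity
monitoring:

* **LED** — LE difference, max − min (years; absolute, simple).
* **LER** — LE ratio, max / min (dimensionless; relative, simple).
* **MD** — mean difference from the best performer,
  (1/n)·Σ (best − leᵢ) (years; absolute, complex).
* **ID** — index of disparity, 100·MD / best (percent; relative, complex).
* **BGV** — between-group variance, Σ pᵢ(leᵢ − μ)² with population shares pᵢ
  and weighted mean μ (years²; absolute, complex).
* **STI** — symmetric Theil index, the average of the Theil index
  T = Σ pᵢ(leᵢ/μ)ln(leᵢ/μ) and the mean log deviation
  MLD = Σ pᵢ ln(μ/leᵢ) (dimensionless; relative, complex), reported times a
  configurable scale constant (default 1000) as is conventional for
  small-magnitude entropy indices.

For LED, MD, ID, BGV and STI zero means equality; for LER one means
equality. Larger values mean more disparity. All are appropriate for
unordered groups such as countries. MD and ID support two denominator
conventions: all n countries (default; the reference contributes a zero
term) or n − 1 (reference excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_model import Panel, Period, RegionDefinition
from .aggregation import member_slice

ABSOLUTE_METRICS = ("led", "md", "bgv")
RELATIVE_METRICS = ("ler", "id_pct", "sti")
ALL_METRICS = ("ler", "led", "md", "id_pct", "sti", "bgv")

#: Default reporting multiplier for the symmetric Theil index.
DEFAULT_STI_SCALE = 1000.0


class UndefinedChangeError(ZeroDivisionError):
    """Percent change from a zero baseline is undefined."""


def _as_array(les: Iterable[float], name: str = "les") -> np.ndarray:
    arr = np.asarray(list(les), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def range_difference(les: Iterable[float]) -> float:
    """LED: best minus worst LE (years)."""
    arr = _as_array(les)
    return float(arr.max() - arr.min())


def range_ratio(les: Iterable[float]) -> float:
    """LER: best divided by worst LE."""
    arr = _as_array(les)
    if arr.min() <= 0:
        raise ValueError("range_ratio requires all LE > 0")
    return float(arr.max() / arr.min())


def mean_difference_from_best(
    les: Iterable[float], include_reference: bool = True
) -> float:
    """MD: mean deficit from the best performer.

    ``include_reference=True`` divides by n (the best country contributes a
    zero term); ``False`` divides by n − 1. A single-country slice is 0 under
    either convention.
    """
    arr = _as_array(les)
    n = arr.size if include_reference else arr.size - 1
    if n <= 0:
        return 0.0
    return float((arr.max() - arr).sum() / n)


def index_of_disparity(
    les: Iterable[float], include_reference: bool = True
) -> float:
    """ID: MD as a percentage of the reference (best) LE."""
    arr = _as_array(les)
    best = float(arr.max())
    if best <= 0:
        raise ValueError("index_of_disparity requires max LE > 0")
    return 100.0 * mean_difference_from_best(arr, include_reference) / best


def _shares_and_mean(les: np.ndarray, populations: Iterable[float]) -> tuple[np.ndarray, float]:
    pops = np.asarray(list(populations), dtype=float)
    if pops.size != les.size:
        raise ValueError(f"length mismatch: {les.size} LE values, {pops.size} populations")
    if (pops < 0).any():
        raise ValueError("populations must be non-negative")
    total = pops.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    shares = pops / total
    return shares, float(shares @ les)


def between_group_variance(
    les: Iterable[float], populations: Iterable[float]
) -> float:
    """BGV: population-share-weighted variance about the weighted mean (years²)."""
    arr = _as_array(les)
    shares, mu = _shares_and_mean(arr, populations)
    return float(shares @ (arr - mu) ** 2)


@dataclass(frozen=True)
class TheilDecomposition:
    theil: float
    mld: float
    sti: float  # scale · (theil + mld) / 2
    scale: float


def symmetric_theil(
    les: Iterable[float],
    populations: Iterable[float],
    scale: float = DEFAULT_STI_SCALE,
) -> TheilDecomposition:
    """Theil index, mean log deviation and their scaled average (STI).

    Weighted by population shares with μ the population-weighted mean,
    matching the weighting of the between-group variance.
    """
    arr = _as_array(les)
    if (arr <= 0).any():
        raise ValueError("symmetric_theil requires all LE > 0")
    shares, mu = _shares_and_mean(arr, populations)
    ratio = arr / mu
    theil = float(shares @ (ratio * np.log(ratio)))
    mld = float(shares @ np.log(mu / arr))
    return TheilDecomposition(theil=theil, mld=mld, sti=scale * (theil + mld) / 2.0,
                              scale=scale)


@dataclass(frozen=True)
class DisparitySuite:
    """All six metrics for one region × period × sex slice."""

    region: str
    period: Period
    sex: str
    n_countries: int
    led: float
    ler: float
    md: float
    id_pct: float
    bgv: float
    theil: float
    mld: float
    sti: float
    reference_country: str
    weighted_mean: float
    sti_scale: float

    def metric(self, name: str) -> float:
        if name not in ALL_METRICS:
            raise KeyError(f"unknown metric {name!r}; expected one of {ALL_METRICS}")
        return getattr(self, name)


def disparity_suite_from_values(
    region: str,
    period: Period | str,
    sex: str,
    countries: Sequence[str],
    les: Iterable[float],
    populations: Iterable[float],
    sti_scale: float = DEFAULT_STI_SCALE,
    include_reference: bool = True,
) -> DisparitySuite:
    """Compute the six-metric suite directly from aligned value arrays."""
    arr = _as_array(les)
    pops = np.asarray(list(populations), dtype=float)
    if len(countries) != arr.size:
        raise ValueError("countries and les must align")
    shares, mu = _shares_and_mean(arr, pops)
    best = float(arr.max())
    # deterministic reference: lexicographically first country at the max LE
    at_best = [c for c, v in zip(countries, arr) if v == best]
    reference = min(at_best)
    dec = symmetric_theil(arr, pops, scale=sti_scale)
    return DisparitySuite(
        region=region,
        period=Period.parse(period),
        sex=sex,
        n_countries=int(arr.size),
        led=range_difference(arr),
        ler=range_ratio(arr),
        md=mean_difference_from_best(arr, include_reference),
        id_pct=index_of_disparity(arr, include_reference),
        bgv=between_group_variance(arr, pops),
        theil=dec.theil,
        mld=dec.mld,
        sti=dec.sti,
        reference_country=reference,
        weighted_mean=mu,
        sti_scale=sti_scale,
    )


def disparity_suite(
    panel: Panel,
    region: RegionDefinition,
    period: Period | str,
    sex: str,
    sti_scale: float = DEFAULT_STI_SCALE,
    include_reference: bool = True,
) -> DisparitySuite:
    """Six-metric suite on a panel slice (see :func:`member_slice` for how
    both-sex values are derived when 'both' rows are absent)."""
    countries, les, pops = member_slice(panel, region, period, sex)
    return disparity_suite_from_values(
        region=region.name,
        period=period,
        sex=sex,
        countries=countries,
        les=les,
        populations=pops,
        sti_scale=sti_scale,
        include_reference=include_reference,
    )


def percent_change(v_from: float, v_to: float) -> float:
    """100·(v_to − v_from)/v_from; undefined for a zero baseline."""
    if v_from == 0:
        raise UndefinedChangeError("percent change from a zero baseline is undefined")
    return 100.0 * (v_to - v_from) / v_from


@dataclass(frozen=True)
class SuiteChange:
    """Per-metric percent changes between two periods plus the averaged
    absolute (LED, MD, BGV) and relative (LER, ID, STI) reductions."""

    from_period: Period
    to_period: Period
    per_metric_pct_change: Mapping[str, float]

    @property
    def avg_absolute_pct_change(self) -> float:
        return float(np.mean([self.per_metric_pct_change[m] for m in ABSOLUTE_METRICS]))

    @property
    def avg_relative_pct_change(self) -> float:
        return float(np.mean([self.per_metric_pct_change[m] for m in RELATIVE_METRICS]))


def suite_change(suite_from: DisparitySuite, suite_to: DisparitySuite) -> SuiteChange:
    """Percent change of each metric between two suites of the same slice."""
    if (suite_from.region, suite_from.sex) != (suite_to.region, suite_to.sex):
        raise ValueError("suite_change requires suites for the same region and sex")
    changes = {m: percent_change(suite_from.metric(m), suite_to.metric(m))
               for m in ALL_METRICS}
    return SuiteChange(
        from_period=suite_from.period,
        to_period=suite_to.period,
        per_metric_pct_change=changes,
    )


def average_reduction(per_metric_pct_change: Mapping[str, float]) -> tuple[float, float]:
    """Averaged absolute and relative percent changes.

    Absolute average over LED, MD, BGV; relative average over LER, ID, STI.
    All six components must be present.
    """
    missing = [m for m in ALL_METRICS if m not in per_metric_pct_change]
    if missing:
        raise ValueError(f"missing per-metric change(s): {missing}")
    avg_abs = float(np.mean([per_metric_pct_change[m] for m in ABSOLUTE_METRICS]))
    avg_rel = float(np.mean([per_metric_pct_change[m] for m in RELATIVE_METRICS]))
    return avg_abs, avg_rel
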
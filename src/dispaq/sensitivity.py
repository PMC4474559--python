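"""Leave-one-out region-membership sensitivity analysis.

Regional aggregates built from membership lists are sensitive to which
territories are included, especially when one member carries a large
population share. This module recomputes the population-weighted regional LE
and selected disparity metrics after removing each member country in turn,
and summarises the extremes (which single removal moves the aggregate, or
the disparity trend, the most).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .panel_model import Panel, Period, RegionDefinition
from .aggregation import weighted_regional_le
from .disparity import (
    DEFAULT_STI_SCALE,
    disparity_suite,
    percent_change,
)

DEFAULT_SENSITIVITY_METRICS = ("md", "id_pct")


def _pct_change_or_nan(v_from: float, v_to: float) -> float:
    """Percent change tolerant of degenerate (equality) slices: a metric that
    is 0 in both periods changed by 0%; 0 only at baseline gives NaN."""
    if v_from == 0:
        return 0.0 if v_to == 0 else float("nan")
    return percent_change(v_from, v_to)


@dataclass(frozen=True)
class SensitivityBaseline:
    """Full-region quantities the leave-one-out rows are compared against."""

    region: str
    sex: str
    base_period: Period
    end_period: Period
    le: Mapping[str, float]  # period label -> weighted LE
    le_change_years: float
    le_change_pct: float
    metric_values: Mapping[str, Mapping[str, float]]  # metric -> period label -> value
    metric_change_pct: Mapping[str, float]


@dataclass(frozen=True)
class SensitivityRow:
    """One leave-one-out result: the region recomputed without one country."""

    removed_country: str
    base_period: Period
    end_period: Period
    le_without: Mapping[str, float]  # period label -> weighted LE of reduced region
    delta_le: Mapping[str, float]  # period label -> le_without − full-region LE
    le_change_years: float  # reduced-region LE change between the two periods
    le_change_pct: float
    metric_change_pct: Mapping[str, float]  # metric -> % change between periods
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def md_change_pct(self) -> float:
        return self.metric_change_pct["md"]

    @property
    def id_change_pct(self) -> float:
        return self.metric_change_pct["id_pct"]


@dataclass(frozen=True)
class SensitivityResult:
    baseline: SensitivityBaseline
    rows: tuple[SensitivityRow, ...]


def leave_one_out(
    panel: Panel,
    region: RegionDefinition,
    periods: tuple[Period | str, Period | str],
    sex: str,
    sti_scale: float = DEFAULT_STI_SCALE,
    metrics: Sequence[str] = DEFAULT_SENSITIVITY_METRICS,
    include_reference: bool = True,
) -> SensitivityResult:
    """Recompute regional LE and disparity trends after each single removal.

    For every member country: the reduced region's weighted LE in both
    periods, its deviation from the full-region aggregate, the LE change
    (years and percent) between periods, and the percent change of each
    selected disparity metric. A member missing from a period is flagged on
    its own row and on every row (its absence changes all reduced slices),
    never silently dropped.
    """
    if len(region.members) < 2:
        raise ValueError(
            f"leave-one-out needs a region of >= 2 members, got {len(region.members)}"
        )
    base_period = Period.parse(periods[0])
    end_period = Period.parse(periods[1])

    def _suite_metrics(reg: RegionDefinition, period: Period) -> dict[str, float]:
        suite = disparity_suite(
            panel, reg, period, sex, sti_scale=sti_scale,
            include_reference=include_reference,
        )
        return {m: suite.metric(m) for m in metrics}

    full_le = {
        p.label: weighted_regional_le(panel, region, p, sex)
        for p in (base_period, end_period)
    }
    full_metrics = {
        p.label: _suite_metrics(region, p) for p in (base_period, end_period)
    }
    baseline = SensitivityBaseline(
        region=region.name,
        sex=sex,
        base_period=base_period,
        end_period=end_period,
        le=full_le,
        le_change_years=full_le[end_period.label] - full_le[base_period.label],
        le_change_pct=percent_change(full_le[base_period.label], full_le[end_period.label]),
        metric_values=full_metrics,
        metric_change_pct={
            m: _pct_change_or_nan(
                full_metrics[base_period.label][m], full_metrics[end_period.label][m]
            )
            for m in metrics
        },
    )

    rows = []
    for removed in sorted(region.members):
        reduced = region.without(removed)
        flags = []
        for p in (base_period, end_period):
            if panel.get(removed, p, sex) is None:
                flags.append(f"removed country has no {sex} record in {p.label}")
        le_without = {
            p.label: weighted_regional_le(panel, reduced, p, sex)
            for p in (base_period, end_period)
        }
        reduced_metrics = {
            p.label: _suite_metrics(reduced, p) for p in (base_period, end_period)
        }
        rows.append(
            SensitivityRow(
                removed_country=removed,
                base_period=base_period,
                end_period=end_period,
                le_without=le_without,
                delta_le={
                    lbl: le_without[lbl] - full_le[lbl] for lbl in le_without
                },
                le_change_years=le_without[end_period.label] - le_without[base_period.label],
                le_change_pct=percent_change(
                    le_without[base_period.label], le_without[end_period.label]
                ),
                metric_change_pct={
                    m: _pct_change_or_nan(
                        reduced_metrics[base_period.label][m],
                        reduced_metrics[end_period.label][m],
                    )
                    for m in metrics
                },
                flags=tuple(flags),
            )
        )
    return SensitivityResult(baseline=baseline, rows=tuple(rows))


@dataclass(frozen=True)
class Extreme:
    value: float
    removed_country: str


@dataclass(frozen=True)
class SensitivitySummary:
    """Extremes across leave-one-out rows, with the responsible removals."""

    baseline: SensitivityBaseline
    le_without_min: Mapping[str, Extreme]  # period label -> extreme
    le_without_max: Mapping[str, Extreme]
    metric_change_min: Mapping[str, Extreme]  # metric -> extreme over rows
    metric_change_max: Mapping[str, Extreme]


def summarize_sensitivity(result: SensitivityResult) -> SensitivitySummary:
    """Min/max reduced-region LE per period and min/max metric-trend change,
    each with the removal responsible (ties broken by country id)."""
    if not result.rows:
        raise ValueError("no sensitivity rows to summarize")
    period_labels = [result.baseline.base_period.label, result.baseline.end_period.label]
    le_min: dict[str, Extreme] = {}
    le_max: dict[str, Extreme] = {}
    for lbl in period_labels:
        ordered = sorted(result.rows, key=lambda r: (r.le_without[lbl], r.removed_country))
        le_min[lbl] = Extreme(ordered[0].le_without[lbl], ordered[0].removed_country)
        le_max[lbl] = Extreme(ordered[-1].le_without[lbl], ordered[-1].removed_country)
    metrics = list(result.rows[0].metric_change_pct)
    ch_min: dict[str, Extreme] = {}
    ch_max: dict[str, Extreme] = {}
    for m in metrics:
        ordered = sorted(result.rows, key=lambda r: (r.metric_change_pct[m], r.removed_country))
        ch_min[m] = Extreme(ordered[0].metric_change_pct[m], ordered[0].removed_country)
        ch_max[m] = Extreme(ordered[-1].metric_change_pct[m], ordered[-1].removed_country)
    return SensitivitySummary(
        baseline=result.baseline,
        le_without_min=le_min,
        le_without_max=le_max,
        metric_change_min=ch_min,
        metric_change_max=ch_max,
    )
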
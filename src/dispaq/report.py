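"""Config-driven trend analysis runs and paper-style plain-text tables.

`run_trend_analysis` ties the stages together: read and validate a panel and
region definitions, build weighted-LE series with gap/shortfall columns,
gender-disparity summaries, the six-metric disparity suites for a from/to
period pair with percent changes, and the averaged absolute/relative
reductions. Everything is written as tidy CSV plus rendered text tables and
a run manifest recording the active modes.

Display rules (applied only at rendering time; all arithmetic is full
precision): LE and metric values at 2 dp, percent changes at 2 dp, headline
averaged reductions as whole-percent magnitudes ("14%").
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .panel_model import (
    BOTH,
    FEMALE,
    MALE,
    Panel,
    Period,
    RegionDefinition,
    load_region_definitions,
    read_panel,
    validate_panel,
)
from .aggregation import build_regional_series, gender_summary, weighted_regional_le
from .disparity import (
    ALL_METRICS,
    DEFAULT_STI_SCALE,
    DisparitySuite,
    SuiteChange,
    average_reduction,
    disparity_suite,
    percent_change,
)

logger = logging.getLogger(__name__)

SUITE_DISPLAY_ORDER = ("ler", "led", "md", "id_pct", "sti", "bgv")
SUITE_DISPLAY_NAMES = {
    "ler": "LE ratio",
    "led": "LE difference",
    "md": "Mean difference",
    "id_pct": "Index of disparity",
    "sti": "Symmetric Theil",
    "bgv": "Between-group var",
}


def round2(x: float) -> float:
    return round(float(x), 2)


def headline(avg_pct_change: float) -> str:
    """Whole-percent magnitude, e.g. −13.90 → '14%'."""
    return f"{round(abs(avg_pct_change)):.0f}%"


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run (file paths plus the mode switches)."""

    panel: str
    regions: str
    out_dir: str = "dispaq_out"
    region_names: tuple[str, ...] | None = None  # None = all regions in config
    comparators: tuple[str, ...] | None = None  # region names for the shortfall
    from_period: str = "1965-1970"
    to_period: str = "2005-2010"
    sexes: tuple[str, ...] = (FEMALE, MALE, BOTH)
    sti_scale: float = DEFAULT_STI_SCALE
    md_denominator: str = "n"  # "n" | "n-1"
    combined_sex_mode: str = "both-sex"  # "both-sex" | "average-of-suites"
    log_level: str = "INFO"
    force: bool = False  # continue despite validation issues

    def __post_init__(self) -> None:
        if self.md_denominator not in ("n", "n-1"):
            raise ValueError("md_denominator must be 'n' or 'n-1'")
        if self.combined_sex_mode not in ("both-sex", "average-of-suites"):
            raise ValueError("combined_sex_mode must be 'both-sex' or 'average-of-suites'")
        if Period.parse(self.from_period) >= Period.parse(self.to_period):
            raise ValueError("from_period must precede to_period")

    @property
    def include_reference(self) -> bool:
        return self.md_denominator == "n"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        for key in ("region_names", "comparators", "sexes"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _suite_for(
    panel: Panel,
    region: RegionDefinition,
    period: Period | str,
    sex: str,
    config: RunConfig,
) -> DisparitySuite:
    """Suite under the configured combined-sex mode."""
    if sex != BOTH or config.combined_sex_mode == "both-sex":
        return disparity_suite(
            panel, region, period, sex,
            sti_scale=config.sti_scale, include_reference=config.include_reference,
        )
    f = _suite_for(panel, region, period, FEMALE, config)
    m = _suite_for(panel, region, period, MALE, config)
    averaged = {name: (f.metric(name) + m.metric(name)) / 2.0 for name in ALL_METRICS}
    return DisparitySuite(
        region=f.region, period=f.period, sex=BOTH,
        n_countries=f.n_countries,
        led=averaged["led"], ler=averaged["ler"], md=averaged["md"],
        id_pct=averaged["id_pct"], bgv=averaged["bgv"],
        theil=(f.theil + m.theil) / 2.0, mld=(f.mld + m.mld) / 2.0,
        sti=averaged["sti"],
        reference_country=f.reference_country,
        weighted_mean=(f.weighted_mean + m.weighted_mean) / 2.0,
        sti_scale=f.sti_scale,
    )


def _safe_suite_change(suite_from: DisparitySuite, suite_to: DisparitySuite) -> SuiteChange:
    """Per-metric percent change with pipeline-friendly zero handling.

    A metric that is exactly 0 in both periods (an equality slice) changed by
    0%; a metric that is 0 only in the base period has no defined percent
    change — the cell becomes NaN and the run continues with a warning.
    """
    changes = {}
    for m in ALL_METRICS:
        v0, v1 = suite_from.metric(m), suite_to.metric(m)
        if v0 == 0:
            if v1 == 0:
                changes[m] = 0.0
            else:
                logger.warning(
                    "region %r sex %s metric %s: zero baseline in %s, "
                    "percent change undefined",
                    suite_from.region, suite_from.sex, m, suite_from.period.label,
                )
                changes[m] = float("nan")
        else:
            changes[m] = percent_change(v0, v1)
    return SuiteChange(
        from_period=suite_from.period,
        to_period=suite_to.period,
        per_metric_pct_change=changes,
    )


@dataclass(frozen=True)
class TrendOutputs:
    series: pd.DataFrame
    gender: pd.DataFrame
    suites: pd.DataFrame
    changes: pd.DataFrame
    reductions: pd.DataFrame
    validation_issue_count: int
    decisions: tuple[str, ...]


def run_trend_analysis(config: RunConfig, panel: Panel | None = None,
                       regions: Sequence[RegionDefinition] | None = None) -> TrendOutputs:
    """Execute the full pipeline and write the output bundle to out_dir.

    The world average used for the gap column is the population-weighted LE
    over every country present in the panel. The shortfall comparator set is
    the configured comparator regions' weighted LE values (default: all
    regions in the config file), so the best-performing configured region is
    the shortfall reference.
    """
    if panel is None:
        panel = read_panel(config.panel)
    if regions is None:
        regions = load_region_definitions(config.regions)
    by_name = {r.name: r for r in regions}
    names = config.region_names or tuple(by_name)
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValueError(f"unknown region name(s): {missing}")
    comparator_names = config.comparators or tuple(by_name)
    missing = [n for n in comparator_names if n not in by_name]
    if missing:
        raise ValueError(f"unresolvable comparator region(s): {missing}")

    report = validate_panel(panel, [by_name[n] for n in names])
    if report.issues:
        logger.warning("validation found %d issue(s)", len(report.issues))
        if not config.force:
            for issue in report.issues[:20]:
                logger.warning("  %s", issue)

    world = RegionDefinition(name="World (panel)", members=frozenset(panel.countries))
    periods = panel.periods
    from_p, to_p = Period.parse(config.from_period), Period.parse(config.to_period)

    decisions = (
        f"md_denominator={config.md_denominator}",
        f"combined_sex_mode={config.combined_sex_mode}",
        f"sti_scale={config.sti_scale}",
        "reference tie-break=lexicographic country id",
        "missing members=computed over available members, logged",
    )
    for d in decisions:
        logger.info("mode: %s", d)

    series_rows, gender_rows, suite_rows, change_rows, reduction_rows = [], [], [], [], []
    for sex in config.sexes:
        world_le = {p.label: weighted_regional_le(panel, world, p, sex) for p in periods}
        comparator_les = {
            p.label: [weighted_regional_le(panel, by_name[c], p, sex) for c in comparator_names]
            for p in periods
        }
        for name in names:
            region = by_name[name]
            series = build_regional_series(
                panel, region, sex, periods=periods,
                world_le=world_le, comparator_les=comparator_les,
            )
            for pt in series.points:
                series_rows.append({
                    "region": name, "sex": sex, "period": pt.period.label,
                    "weighted_le": pt.weighted_le, "gap": pt.gap,
                    "shortfall": pt.shortfall, "population": pt.total_population,
                })
            suites = {}
            for p in (from_p, to_p):
                suite = _suite_for(panel, region, p, sex, config)
                suites[p.label] = suite
                suite_rows.append({
                    "region": name, "sex": sex, "period": p.label,
                    "n_countries": suite.n_countries,
                    **{m: suite.metric(m) for m in SUITE_DISPLAY_ORDER},
                    "reference_country": suite.reference_country,
                    "weighted_mean": suite.weighted_mean,
                })
            change = _safe_suite_change(suites[from_p.label], suites[to_p.label])
            for m in SUITE_DISPLAY_ORDER:
                change_rows.append({
                    "region": name, "sex": sex, "metric": m,
                    "from_period": from_p.label, "to_period": to_p.label,
                    "pct_change": change.per_metric_pct_change[m],
                })
            avg_abs, avg_rel = average_reduction(change.per_metric_pct_change)
            reduction_rows.append({
                "region": name, "sex": sex,
                "avg_absolute_pct_change": avg_abs,
                "avg_relative_pct_change": avg_rel,
                "headline_absolute": headline(avg_abs),
                "headline_relative": headline(avg_rel),
            })

    # gender summaries from the regional weighted sex-specific LE values
    for name in names:
        region = by_name[name]
        for p in (from_p, to_p):
            lf = weighted_regional_le(panel, region, p, FEMALE)
            lm = weighted_regional_le(panel, region, p, MALE)
            g = gender_summary(lf, lm)
            gender_rows.append({
                "region": name, "period": p.label,
                "le_female": lf, "le_male": lm,
                "difference": g.difference, "pct_difference": g.pct_difference,
                "ratio": g.ratio,
            })

    outputs = TrendOutputs(
        series=pd.DataFrame(series_rows),
        gender=pd.DataFrame(gender_rows),
        suites=pd.DataFrame(suite_rows),
        changes=pd.DataFrame(change_rows),
        reductions=pd.DataFrame(reduction_rows),
        validation_issue_count=len(report.issues),
        decisions=decisions,
    )
    _write_bundle(outputs, config)
    return outputs


def _write_bundle(outputs: TrendOutputs, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs.series.to_csv(out / "regional_series.csv", index=False)
    outputs.gender.to_csv(out / "gender_disparity.csv", index=False)
    outputs.suites.to_csv(out / "disparity_suites.csv", index=False)
    outputs.changes.to_csv(out / "suite_changes.csv", index=False)
    outputs.reductions.to_csv(out / "average_reductions.csv", index=False)
    (out / "tables.txt").write_text(format_report_tables(outputs))
    manifest = {
        "dispaq_version": __version__,
        "config": dataclasses.asdict(config),
        "decisions": list(outputs.decisions),
        "validation_issue_count": outputs.validation_issue_count,
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    logger.info("wrote output bundle to %s", out)


def format_gender_table(gender: pd.DataFrame) -> str:
    cols = ["region", "period", "le_female", "le_male",
            "difference", "pct_difference", "ratio"]
    header = f"{'Region':<18}{'Period':<12}{'LE (F)':>8}{'LE (M)':>8}" \
             f"{'F-M':>8}{'% Diff':>8}{'F:M':>7}"
    lines = [header, "-" * len(header)]
    for _, row in gender[cols].iterrows():
        lines.append(
            f"{row['region']:<18}{row['period']:<12}"
            f"{round2(row['le_female']):>8.2f}{round2(row['le_male']):>8.2f}"
            f"{round2(row['difference']):>8.2f}{round2(row['pct_difference']):>8.2f}"
            f"{round2(row['ratio']):>7.2f}"
        )
    return "\n".join(lines)


def format_suite_table(suites: pd.DataFrame, changes: pd.DataFrame) -> str:
    """Suite levels with percent-change rows interleaved per region × sex.

    Column order groups the range-based measures (LER, LED) before the
    all-country measures (MD, ID, STI, BGV); all cells at 2 dp.
    """
    header = f"{'Region':<18}{'Sex':<8}{'Year':<12}" + "".join(
        f"{m.upper().replace('_PCT',''):>9}" for m in SUITE_DISPLAY_ORDER
    )
    lines = [header, "-" * len(header)]
    if suites.empty:
        return "\n".join(lines)
    for (region, sex), block in suites.groupby(["region", "sex"], sort=False):
        block = block.sort_values("period")
        for _, row in block.iterrows():
            lines.append(
                f"{region:<18}{sex:<8}{row['period']:<12}"
                + "".join(f"{round2(row[m]):>9.2f}" for m in SUITE_DISPLAY_ORDER)
            )
        ch = changes[(changes["region"] == region) & (changes["sex"] == sex)]
        by_metric = dict(zip(ch["metric"], ch["pct_change"]))
        if by_metric:
            lines.append(
                f"{'':<18}{'':<8}{'% change':<12}"
                + "".join(f"{round2(by_metric[m]):>9.2f}" for m in SUITE_DISPLAY_ORDER)
            )
    return "\n".join(lines)


def format_reduction_table(reductions: pd.DataFrame) -> str:
    header = f"{'Region':<18}{'Sex':<8}{'Avg abs %':>12}{'Avg rel %':>12}" \
             f"{'Headline':>18}"
    lines = [header, "-" * len(header)]
    for _, row in reductions.iterrows():
        lines.append(
            f"{row['region']:<18}{row['sex']:<8}"
            f"{round2(row['avg_absolute_pct_change']):>12.2f}"
            f"{round2(row['avg_relative_pct_change']):>12.2f}"
            f"{row['headline_absolute'] + ' / ' + row['headline_relative']:>18}"
        )
    return "\n".join(lines)


def format_report_tables(outputs: TrendOutputs) -> str:
    parts = [
        "GENDER DISPARITIES IN LIFE EXPECTANCY",
        format_gender_table(outputs.gender),
        "",
        "BETWEEN-COUNTRY DISPARITY SUITES",
        format_suite_table(outputs.suites, outputs.changes),
        "",
        "AVERAGED ABSOLUTE / RELATIVE REDUCTIONS",
        format_reduction_table(outputs.reductions),
    ]
    return "\n".join(parts) + "\n"
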
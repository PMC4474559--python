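"""Synthetic country-period LE panels shaped like WPP-style regional data.

The generator emulates the structure of UN World Population Prospects
country summaries at desk scale: a couple of dozen countries per region,
nine 5-year periods (1965–70 … 2005–10), sex-specific LE with a female
advantage, log-normally spread population sizes, and optionally one
heavy-population low-LE outlier member (a Haiti-like territory whose
population share dominates the regional weighted mean).

Per-country dynamics are linear with noise: a draw of a baseline both-sex LE
and a constant annual gain, plus period-level Gaussian noise. Female and
male LE sit at ± half a per-country gender gap around the both-sex value.
Populations are constant over periods unless a growth rate is set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .panel_model import BOTH, FEMALE, MALE, Panel, PanelRecord, Period, RegionDefinition

#: Country id given to the configured outlier member.
OUTLIER_ID = "outlier"

_LE_FLOOR = 1.0
_LE_CEIL = 129.0


def default_periods() -> tuple[Period, ...]:
    """The nine 5-year periods 1965–70 … 2005–10."""
    return tuple(Period(y, y + 5) for y in range(1965, 2010, 5))


@dataclass(frozen=True)
class OutlierSpec:
    """A single low-LE, heavy-population member.

    ``le_deficit``: years subtracted from the outlier's drawn baseline.
    ``population_share``: the outlier's share of total regional population,
    set exactly (the other members' populations stay as drawn).
    """

    le_deficit: float
    population_share: float

    def __post_init__(self) -> None:
        if not (0.0 < self.population_share < 1.0):
            raise ValueError("outlier population_share must be in (0, 1)")
        if self.le_deficit < 0:
            raise ValueError("outlier le_deficit must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic panel generator (units in docstrings).

    Defaults sketch a Caribbean-like grouping: 21 countries, both-sex
    baseline LE around 60 years in 1965–70 with a 5-year country spread,
    secular gains near 0.3 years of LE per calendar year, a 5-year female
    advantage, and log-normal populations whose median is a few hundred
    thousand with a heavy upper tail.
    """

    n_countries: int = 21
    periods: tuple[Period, ...] = field(default_factory=default_periods)
    baseline_mean: float = 60.0  # years, both-sex LE in the first period
    baseline_sd: float = 5.0  # years, between-country spread
    annual_gain_mean: float = 0.3  # years of LE per calendar year
    annual_gain_sd: float = 0.1
    gender_gap_mean: float = 5.0  # years, female − male
    gender_gap_sd: float = 1.0
    population_log_mean: float = 13.1  # log persons (median ≈ 4.9e5)
    population_log_sd: float = 1.5
    population_growth_rate: float = 0.0  # per year; 0 = constant populations
    noise_sd: float = 0.5  # years, period-level noise on both-sex LE
    outlier: OutlierSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        for name in ("baseline_sd", "annual_gain_sd", "gender_gap_sd",
                     "population_log_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.periods:
            raise ValueError("periods must be non-empty")

    @property
    def country_ids(self) -> tuple[str, ...]:
        ids = [f"C{i:02d}" for i in range(1, self.n_countries + 1)]
        if self.outlier is not None:
            ids[-1] = OUTLIER_ID
        return tuple(ids)


def generate_panel(config: GeneratorConfig) -> Panel:
    """Draw a reproducible synthetic panel from the configured model.

    Emits female, male and both-sex rows per country × period; both-sex LE is
    exactly the equal-weight mean of the sex-specific values (sex populations
    are split evenly), so derived and supplied 'both' slices agree.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    ids = config.country_ids

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    gains = rng.normal(config.annual_gain_mean, config.annual_gain_sd, size=n)
    gaps = rng.normal(config.gender_gap_mean, config.gender_gap_sd, size=n)
    pops = rng.lognormal(config.population_log_mean, config.population_log_sd, size=n)

    if config.outlier is not None:
        baselines[-1] -= config.outlier.le_deficit
        share = config.outlier.population_share
        pops[-1] = share / (1.0 - share) * pops[:-1].sum()

    t0 = config.periods[0].start
    records: list[PanelRecord] = []
    for j, period in enumerate(config.periods):
        elapsed = period.start - t0
        noise = rng.normal(0.0, config.noise_sd, size=n)
        growth = math.exp(config.population_growth_rate * elapsed)
        for i in range(n):
            both = baselines[i] + gains[i] * elapsed + noise[i]
            half_gap = gaps[i] / 2.0
            female = both + half_gap
            male = both - half_gap
            # keep every sex-specific LE within the panel's validity range
            female = float(np.clip(female, _LE_FLOOR, _LE_CEIL))
            male = float(np.clip(male, _LE_FLOOR, _LE_CEIL))
            both = (female + male) / 2.0
            pop = pops[i] * growth
            records.append(PanelRecord(ids[i], period, FEMALE, female, pop / 2.0))
            records.append(PanelRecord(ids[i], period, MALE, male, pop / 2.0))
            records.append(PanelRecord(ids[i], period, BOTH, both, pop))
    return Panel(
        records=tuple(records),
        provenance=f"synthetic generator (seed={config.seed}, n={n})",
    )


def generate_equality_panel(
    n_countries: int,
    periods: Sequence[Period | str] | None = None,
    le: float = 70.0,
) -> Panel:
    """A degenerate panel where every country, period and sex shares one LE
    value with unit populations — every disparity metric is at its equality
    point on such a panel."""
    if le <= 0:
        raise ValueError("le must be positive")
    period_list = [Period.parse(p) for p in (periods or default_periods())]
    records = []
    for i in range(1, n_countries + 1):
        cid = f"C{i:02d}"
        for period in period_list:
            for sex in (FEMALE, MALE, BOTH):
                records.append(PanelRecord(cid, period, sex, le, 1.0))
    return Panel(records=tuple(records), provenance=f"equality panel (le={le})")


def region_of(panel_or_config: Panel | GeneratorConfig, name: str = "Synthetic") -> RegionDefinition:
    """Region definition covering every country of a generated panel."""
    if isinstance(panel_or_config, GeneratorConfig):
        members = panel_or_config.country_ids
    else:
        members = panel_or_config.countries
    return RegionDefinition(name=name, members=frozenset(members))


# Named scenarios used by the CLI and the test fixtures.
SCENARIOS: dict[str, GeneratorConfig] = {
    "caribbean": GeneratorConfig(),
    "outlier": GeneratorConfig(outlier=OutlierSpec(le_deficit=15.0, population_share=0.22)),
    "equality": GeneratorConfig(
        baseline_sd=0.0, annual_gain_sd=0.0, gender_gap_sd=0.0, noise_sd=0.0
    ),
}


def scenario_config(name: str, seed: int | None = None) -> GeneratorConfig:
    """Preset generator configuration by scenario name."""
    try:
        config = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return config if seed is None else replace(config, seed=seed)
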
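import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from dispaq import Panel, PanelRecord, Period, RegionDefinition
from dispaq.synthetic import (
    GeneratorConfig,
    OutlierSpec,
    generate_equality_panel,
    generate_panel,
    region_of,
)


@pytest.fixture(scope="session")
def outlier_config() -> GeneratorConfig:
    """21-country panel with a Haiti-like member: 15-year LE deficit carrying
    22% of the regional population."""
    return GeneratorConfig(
        outlier=OutlierSpec(le_deficit=15.0, population_share=0.22), seed=42
    )


@pytest.fixture(scope="session")
def outlier_panel(outlier_config) -> Panel:
    return generate_panel(outlier_config)


@pytest.fixture(scope="session")
def outlier_region(outlier_config) -> RegionDefinition:
    return region_of(outlier_config, "Synthetic Caribbean")


@pytest.fixture(scope="session")
def equality_panel() -> Panel:
    return generate_equality_panel(n_countries=5, le=70.0)


@pytest.fixture()
def toy_panel() -> Panel:
    """Three countries, two periods, equal populations, both-sex only."""
    records = []
    for period in ("1965-1970", "2005-2010"):
        for cid, le in (("A", 60.0), ("B", 70.0), ("C", 80.0)):
            bump = 5.0 if period == "2005-2010" else 0.0
            records.append(PanelRecord(cid, period, "both", le + bump, 1.0))
    return Panel(records=tuple(records))


@pytest.fixture()
def toy_region() -> RegionDefinition:
    return RegionDefinition(name="Toy", members=frozenset({"A", "B", "C"}))
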
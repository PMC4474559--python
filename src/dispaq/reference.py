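"""Published sub-regional LE summaries for the Americas (UN WPP 2012 revision).

These are the printed, 2-dp-rounded summary values from a published
WPP-2012-based disparity analysis of the Americas, 1965–70 vs 2005–10:
population-weighted regional LE by sex, gender-disparity columns, the
six-metric disparity suite per sex block with percent changes, the 1965
shortfalls against the best world sub-region, and the headline averaged
reductions. They serve as arithmetic cross-checks: the package's operations
recompute each derived column from the printed inputs.

Because the printed inputs are themselves rounded to 2 dp, a recomputed
derived cell can differ from its printed counterpart by one unit in the last
digit (the original arithmetic ran at full precision before display
rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

P1965 = "1965-1970"
P2005 = "2005-2010"


@dataclass(frozen=True)
class GenderRow:
    region: str
    n_countries: int
    period: str
    le_overall: float
    le_female: float
    le_male: float
    fm_difference: float
    pct_difference: float
    fm_ratio: float


#: Gender disparities in LE by sub-region (printed table).
GENDER_ROWS: tuple[GenderRow, ...] = (
    GenderRow("Caribbean", 21, P1965, 62.08, 63.95, 60.34, 3.62, 5.65, 1.06),
    GenderRow("Caribbean", 21, P2005, 71.79, 74.42, 69.26, 5.16, 6.93, 1.07),
    GenderRow("Central America", 7, P1965, 58.83, 60.95, 56.79, 4.16, 6.83, 1.07),
    GenderRow("Central America", 7, P2005, 75.31, 77.91, 72.59, 5.31, 6.82, 1.07),
    GenderRow("South America", 10, P1965, 59.15, 61.39, 57.04, 4.35, 7.09, 1.08),
    GenderRow("South America", 10, P2005, 73.14, 76.60, 69.77, 6.83, 8.92, 1.10),
    GenderRow("North America", 2, P1965, 70.49, 74.28, 66.95, 7.33, 9.87, 1.11),
    GenderRow("North America", 2, P2005, 78.36, 80.81, 75.83, 4.99, 6.17, 1.07),
    GenderRow("World", 201, P1965, 56.52, 57.92, 55.07, 2.85, 4.91, 1.05),
    GenderRow("World", 201, P2005, 68.72, 71.00, 66.52, 4.48, 6.31, 1.07),
)


@dataclass(frozen=True)
class SuiteRow:
    """Printed six-metric values for one region × sex block at both periods,
    plus the printed percent-change row. Metric order: LER, LED, MD, ID,
    STI, BGV."""

    region: str
    sex: str  # "female" | "male" | "both"
    values_1965: tuple[float, float, float, float, float, float]
    values_2005: tuple[float, float, float, float, float, float]
    pct_change: tuple[float, float, float, float, float, float]


SUITE_METRIC_ORDER = ("ler", "led", "md", "id_pct", "sti", "bgv")

#: Between-country disparity suites by sub-region and sex block (printed table).
SUITE_ROWS: tuple[SuiteRow, ...] = (
    SuiteRow("Caribbean", "female",
             (1.55, 26.22, 8.31, 11.26, 33.19, 26.23),
             (1.33, 20.81, 7.10, 8.53, 20.86, 23.46),
             (-14.19, -20.63, -14.56, -24.25, -37.15, -10.56)),
    SuiteRow("Central America", "female",
             (1.32, 16.16, 10.01, 14.84, 52.41, 36.38),
             (1.10, 7.47, 4.85, 5.98, 5.43, 6.48),
             (-16.67, -53.77, -51.55, -59.70, -89.64, -82.19)),
    SuiteRow("South America", "female",
             (1.52, 24.65, 11.20, 15.58, 70.30, 51.36),
             (1.20, 13.83, 5.54, 6.79, 11.44, 13.02),
             (-21.05, -43.89, -50.54, -56.42, -83.73, -74.65)),
    SuiteRow("North America", "female",
             (1.02, 1.45, 1.45, 1.92, 0.47, 0.53),
             (1.03, 2.21, 2.21, 2.67, 0.91, 1.22),
             (0.98, 52.41, 52.41, 39.06, 93.62, 130.19)),
    SuiteRow("Caribbean", "male",
             (1.51, 22.75, 6.41, 9.47, 34.45, 24.02),
             (1.30, 17.75, 6.28, 8.19, 19.43, 18.78),
             (-13.91, -21.98, -2.03, -13.52, -43.60, -21.82)),
    SuiteRow("Central America", "male",
             (1.30, 14.91, 10.15, 15.88, 57.95, 35.92),
             (1.15, 10.00, 6.44, 8.42, 12.12, 12.22),
             (-11.54, -32.93, -36.55, -46.98, -79.09, -65.98)),
    SuiteRow("South America", "male",
             (1.53, 22.55, 9.10, 13.90, 66.96, 41.28),
             (1.19, 12.06, 5.60, 7.42, 9.12, 8.88),
             (-22.22, -46.52, -38.46, -46.62, -86.38, -78.49)),
    SuiteRow("North America", "male",
             (1.03, 2.19, 2.19, 3.18, 1.30, 1.20),
             (1.03, 2.60, 2.60, 3.33, 1.43, 1.69),
             (0.00, 18.72, 18.72, 4.72, 10.00, 40.83)),
    SuiteRow("Caribbean", "both",
             (1.53, 24.47, 7.31, 10.33, 33.41, 24.78),
             (1.32, 19.43, 6.87, 8.58, 20.16, 21.04),
             (-13.73, -20.60, -6.02, -16.94, -39.66, -15.09)),
    SuiteRow("Central America", "both",
             (1.31, 15.49, 10.05, 15.32, 54.30, 35.60),
             (1.12, 8.52, 5.58, 7.09, 7.79, 8.57),
             (-14.50, -45.00, -44.48, -53.72, -85.65, -75.93)),
    SuiteRow("South America", "both",
             (1.52, 23.50, 10.06, 14.67, 67.85, 45.47),
             (1.20, 13.00, 5.64, 7.18, 10.18, 10.73),
             (-21.05, -44.68, -43.94, -51.06, -85.00, -76.40)),
    SuiteRow("North America", "both",
             (1.02, 1.74, 1.74, 2.41, 0.74, 0.76),
             (1.03, 2.41, 2.41, 2.99, 1.15, 1.45),
             (0.98, 38.51, 38.51, 24.07, 55.41, 90.79)),
)


#: 1965 shortfall inputs: regional both-sex LE vs the best world sub-region
#: (Northern Europe, 71.5 years in 1965), with the printed shortfall.
SHORTFALL_1965 = MappingProxyType({
    "Caribbean": {"region_le": 60.8, "best_subregion_le": 71.5, "shortfall": 10.7},
    "Central America": {"region_le": 57.8, "best_subregion_le": 71.5, "shortfall": 13.7},
    "South America": {"region_le": 58.2, "best_subregion_le": 71.5, "shortfall": 13.3},
})

#: Headline averaged reductions (whole-percent magnitudes, combined sexes):
#: (absolute = mean over LED/MD/BGV changes, relative = mean over LER/ID/STI).
HEADLINE_REDUCTIONS = MappingProxyType({
    "Caribbean": (14, 23),
    "Central America": (55, 51),
    "South America": (55, 52),
})


def suite_row(region: str, sex: str) -> SuiteRow:
    for row in SUITE_ROWS:
        if row.region == region and row.sex == sex:
            return row
    raise KeyError(f"no published suite row for {region!r} / {sex!r}")
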
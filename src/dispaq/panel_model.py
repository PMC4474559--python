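"""Country-period life-expectancy panels: domain types, delimited I/O, region configs.

A *panel* holds one observation per country × period × sex: life expectancy
at birth (LE, in years) and the population used as the aggregation weight.
Periods are half-open calendar intervals, canonically labelled
``"1965-1970"`` (start inclusive, end exclusive); the common demographic
shorthand ``"1965-70"`` (and the en-dash variant) is accepted on input and
normalised. A *region definition* names the set of countries aggregated
together — mirroring how UN World Population Prospects sub-regions are
membership lists over country-level series.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
BOTH = "both"
SEXES = (FEMALE, MALE, BOTH)

#: Canonical column order written by :func:`write_panel`.
PANEL_COLUMNS = ("country", "period", "sex", "le_years", "population")


class PanelFormatError(ValueError):
    """A panel file is structurally unusable (e.g. a required column is missing)."""


class PanelParseError(ValueError):
    """A specific row of a panel file could not be parsed."""


class PanelIntegrityError(ValueError):
    """Duplicate (country, period, sex) keys within one panel."""


class RegionConfigError(ValueError):
    """A region-definition config is malformed."""


class EmptySliceError(ValueError):
    """No records exist for a requested (region, period, sex) slice."""


_PERIOD_RE = re.compile(r"^\s*(\d{4})\s*[-‐-―]\s*(\d{2}|\d{4})\s*$")


@dataclass(frozen=True, order=True)
class Period:
    """Half-open calendar interval [start, end), e.g. Period(1965, 1970)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"period start must precede end, got {self.start}-{self.end}")

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @classmethod
    def parse(cls, text: str | "Period") -> "Period":
        """Parse '1965-1970', '1965-70' or '1965–70' into a Period."""
        if isinstance(text, Period):
            return text
        m = _PERIOD_RE.match(str(text))
        if not m:
            raise ValueError(f"unparseable period label: {text!r}")
        start = int(m.group(1))
        raw_end = m.group(2)
        if len(raw_end) == 4:
            end = int(raw_end)
        else:
            # two-digit shorthand: same century as start, rolling over if needed
            end = (start // 100) * 100 + int(raw_end)
            if end <= start:
                end += 100
        return cls(start, end)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _normalise_sex(value: str) -> str:
    s = str(value).strip().lower()
    aliases = {"f": FEMALE, "m": MALE, "women": FEMALE, "men": MALE,
               "t": BOTH, "total": BOTH, "both sexes": BOTH}
    s = aliases.get(s, s)
    if s not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {value!r}")
    return s


@dataclass(frozen=True)
class PanelRecord:
    """One country × period × sex observation.

    Construction normalises the period label and sex code but does not
    enforce the range invariants (0 < le < 130, population >= 0); those are
    surfaced by :func:`validate_panel` so that dirty input data can be loaded,
    inspected and reported on rather than rejected record-by-record.
    """

    country_id: str
    period: Period
    sex: str
    le: float
    population: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "country_id", str(self.country_id).strip())
        object.__setattr__(self, "period", Period.parse(self.period))
        object.__setattr__(self, "sex", _normalise_sex(self.sex))
        object.__setattr__(self, "le", float(self.le))
        object.__setattr__(self, "population", float(self.population))
        if not self.country_id:
            raise ValueError("country_id must be non-empty")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.country_id, self.period.label, self.sex)

    def violations(self) -> list[str]:
        """Range-invariant violations for this record (empty when clean)."""
        out = []
        if not (0.0 < self.le < 130.0):
            out.append(f"le out of range (0, 130): {self.le}")
        if self.population < 0:
            out.append(f"negative population: {self.population}")
        return out


@dataclass(frozen=True)
class Panel:
    """Immutable collection of :class:`PanelRecord` with unique keys."""

    records: tuple[PanelRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[tuple[str, str, str], int] = {}
        for i, rec in enumerate(self.records):
            if rec.key in seen:
                raise PanelIntegrityError(
                    f"duplicate (country, period, sex) key {rec.key} "
                    f"at records {seen[rec.key]} and {i}"
                )
            seen[rec.key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted({r.country_id for r in self.records}))

    @property
    def periods(self) -> tuple[Period, ...]:
        return tuple(sorted({r.period for r in self.records}))

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(s for s in SEXES if any(r.sex == s for r in self.records))

    def get(self, country_id: str, period: Period | str, sex: str) -> PanelRecord | None:
        key = (str(country_id).strip(), Period.parse(period).label, _normalise_sex(sex))
        return self._index().get(key)

    def _index(self) -> Mapping[tuple[str, str, str], PanelRecord]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {r.key: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx

    def slice(
        self,
        members: Iterable[str] | None = None,
        period: Period | str | None = None,
        sex: str | None = None,
    ) -> list[PanelRecord]:
        """Records matching the given filters, in stable (sorted-country) order."""
        member_set = None if members is None else {str(m).strip() for m in members}
        want_period = None if period is None else Period.parse(period)
        want_sex = None if sex is None else _normalise_sex(sex)
        out = [
            r
            for r in self.records
            if (member_set is None or r.country_id in member_set)
            and (want_period is None or r.period == want_period)
            and (want_sex is None or r.sex == want_sex)
        ]
        out.sort(key=lambda r: (r.country_id, r.period, r.sex))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": [r.country_id for r in self.records],
                "period": [r.period.label for r in self.records],
                "sex": [r.sex for r in self.records],
                "le_years": [r.le for r in self.records],
                "population": [r.population for r in self.records],
            }
        )


@dataclass(frozen=True)
class RegionDefinition:
    """A named aggregation group: region name plus its member country ids."""

    name: str
    members: frozenset[str]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m).strip() for m in self.members))
        if not self.name:
            raise RegionConfigError("region name must be non-empty")
        if not self.members:
            raise RegionConfigError(f"region {self.name!r} has an empty member list")

    def without(self, country_id: str) -> "RegionDefinition":
        """The same region with one member removed (for leave-one-out work)."""
        if country_id not in self.members:
            raise KeyError(f"{country_id!r} is not a member of {self.name!r}")
        return RegionDefinition(
            name=f"{self.name} (without {country_id})",
            members=self.members - {country_id},
            notes=self.notes,
        )


@dataclass(frozen=True)
class Dialect:
    """Delimited-file options for :func:`read_panel` / :func:`write_panel`.

    ``columns`` maps logical field names (country, period, sex, le,
    population) to the header names used in the file.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "country": "country",
            "period": "period",
            "sex": "sex",
            "le": "le_years",
            "population": "population",
        }
    )


def read_panel(path: str | Path, dialect: Dialect | None = None) -> Panel:
    """Read a delimited panel file into a :class:`Panel`.

    Raises :class:`PanelFormatError` when a mapped column is absent,
    :class:`PanelParseError` (with the 1-based data row number) when le or
    population is non-numeric or the period label is unparseable, and
    :class:`PanelIntegrityError` on duplicate keys.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    missing = [v for v in dialect.columns.values() if v not in frame.columns]
    if missing:
        raise PanelFormatError(
            f"{path}: missing column(s) {missing}; found {list(frame.columns)}"
        )
    col = dialect.columns
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        try:
            le = float(raw[col["le"]])
            population = float(raw[col["population"]])
        except (TypeError, ValueError) as exc:
            raise PanelParseError(f"{path}: row {i}: non-numeric value ({exc})") from exc
        try:
            rec = PanelRecord(
                country_id=raw[col["country"]],
                period=raw[col["period"]],
                sex=raw[col["sex"]],
                le=le,
                population=population,
            )
        except ValueError as exc:
            raise PanelParseError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return Panel(records=tuple(records), provenance=str(path))


def write_panel(panel: Panel, path: str | Path, dialect: Dialect | None = None) -> Path:
    """Write a panel as delimited text re-readable by :func:`read_panel`.

    Column order is fixed: country, period, sex, le_years, population
    (header names follow the dialect mapping).
    """
    dialect = dialect or Dialect()
    path = Path(path)
    col = dialect.columns
    frame = panel.to_frame()
    frame.columns = [col["country"], col["period"], col["sex"], col["le"], col["population"]]
    frame.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.10g")
    return path


def load_region_definitions(path: str | Path) -> list[RegionDefinition]:
    """Load region definitions from a YAML (or JSON) config.

    Accepted shapes::

        regions:
          Caribbean: [Cuba, Haiti, ...]
        notes: {Caribbean: "..."}       # optional

    or a bare top-level mapping ``name -> member list``. Definitions are
    returned in file order. Overlapping membership between regions is legal
    (a territory may belong to several groupings) but logged as a warning.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise RegionConfigError(f"{path}: expected a mapping at top level")
    raw = doc.get("regions", doc)
    notes = doc.get("notes", {}) if "regions" in doc else {}
    if not isinstance(raw, Mapping):
        raise RegionConfigError(f"{path}: 'regions' must map names to member lists")

    defs: list[RegionDefinition] = []
    seen_names: set[str] = set()
    for name, members in raw.items():
        if name in ("notes",):
            continue
        if name in seen_names:
            raise RegionConfigError(f"{path}: duplicate region name {name!r}")
        seen_names.add(name)
        if not isinstance(members, Sequence) or isinstance(members, str):
            raise RegionConfigError(f"{path}: region {name!r} must list its members")
        member_list = [str(m).strip() for m in members]
        if len(set(member_list)) != len(member_list):
            raise RegionConfigError(f"{path}: region {name!r} has duplicate members")
        defs.append(
            RegionDefinition(name=str(name), members=frozenset(member_list),
                             notes=str(notes.get(name, "")))
        )

    for i, a in enumerate(defs):
        for b in defs[i + 1:]:
            shared = a.members & b.members
            if shared:
                logger.warning(
                    "regions %r and %r share members: %s", a.name, b.name, sorted(shared)
                )
    return defs


def bundled_region_path(name: str = "caribbean_21") -> Path:
    """Path to a region config shipped with the package."""
    return Path(__file__).parent / "data" / f"{name}.yaml"


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # "missing_coverage" | "invariant_violation"
    region: str | None
    country_id: str
    period: str | None
    sex: str | None
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]
    completeness: Mapping[str, float]  # region name -> fraction of covered cells

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_panel(panel: Panel, regions: Sequence[RegionDefinition]) -> ValidationReport:
    """Report-only validation: coverage of each region's members across the
    panel's period × sex grid, plus record-level range-invariant violations."""
    issues: list[ValidationIssue] = []
    for rec in panel:
        for detail in rec.violations():
            issues.append(
                ValidationIssue(
                    kind="invariant_violation",
                    region=None,
                    country_id=rec.country_id,
                    period=rec.period.label,
                    sex=rec.sex,
                    detail=detail,
                )
            )
    completeness: dict[str, float] = {}
    periods = panel.periods
    sexes = panel.sexes
    for region in regions:
        covered = 0
        total = 0
        for period in periods:
            for sex in sexes:
                for member in sorted(region.members):
                    total += 1
                    if panel.get(member, period, sex) is not None:
                        covered += 1
                    else:
                        issues.append(
                            ValidationIssue(
                                kind="missing_coverage",
                                region=region.name,
                                country_id=member,
                                period=period.label,
                                sex=sex,
                                detail="region member has no record for this slice",
                            )
                        )
        completeness[region.name] = covered / total if total else 1.0
    return ValidationReport(issues=tuple(issues), completeness=completeness)
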
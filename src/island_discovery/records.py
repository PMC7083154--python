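"""Specimen-record and island tables.

The raw inputs are two small CSV tables: one row per endemic taxon recording
its discovery history (earliest collection, type collection, basionym
publication) and its within-archipelago distribution, and one row per island
with physical covariates and a harbor indicator.  This module parses and
validates them and turns them into the cumulative count panel the spatial
model consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YEAR_MIN, YEAR_MAX = 1600, 2100

RECORD_COLUMNS = [
    "taxon_id", "family",
    "earliest_year", "earliest_collector", "earliest_island",
    "type_year", "type_collector", "type_island",
    "publication_year", "describing_author",
    "distribution",
]

ISLAND_COLUMNS = ["code", "name", "lat", "lon", "area_km2", "age_ma",
                  "altitude_m", "tri", "harbor"]


class SchemaError(ValueError):
    """The CSV is missing required columns or is otherwise unreadable."""


class RowError(ValueError):
    """A single row failed validation; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class SpecimenRecord:
    """Discovery history of one endemic taxon.

    Years are calendar years; ``distribution`` is the set of island codes the
    taxon occurs on today.  The description lag is
    ``publication_year - earliest_year`` and is non-negative by invariant.
    """

    taxon_id: str
    family: str
    earliest_year: int | None
    earliest_collector: str
    earliest_island: str
    type_year: int | None
    type_collector: str
    type_island: str
    publication_year: int | None
    describing_author: str
    distribution: frozenset[str]

    def validate(self) -> None:
        if not self.distribution:
            raise ValueError(f"{self.taxon_id}: distribution is empty")
        for name, year in [("earliest_year", self.earliest_year),
                           ("type_year", self.type_year),
                           ("publication_year", self.publication_year)]:
            if year is not None and not (YEAR_MIN <= year <= YEAR_MAX):
                raise ValueError(
                    f"{self.taxon_id}: {name}={year} outside [{YEAR_MIN}, {YEAR_MAX}]")
        if self.earliest_year is not None:
            if self.type_year is not None and self.earliest_year > self.type_year:
                raise ValueError(
                    f"{self.taxon_id}: earliest_year {self.earliest_year} > "
                    f"type_year {self.type_year} (earliest must precede type)")
            if (self.publication_year is not None
                    and self.earliest_year > self.publication_year):
                raise ValueError(
                    f"{self.taxon_id}: earliest_year {self.earliest_year} > "
                    f"publication_year {self.publication_year} "
                    "(description lag must be >= 0)")

    @property
    def lag(self) -> int | None:
        """Description lag in years (publication minus earliest collection)."""
        if self.earliest_year is None or self.publication_year is None:
            return None
        return self.publication_year - self.earliest_year

    @property
    def is_single_island_endemic(self) -> bool:
        return len(self.distribution) == 1


@dataclass(frozen=True)
class Island:
    """One island: coordinates, physical covariates and harbor indicator."""

    code: str
    name: str
    lat: float
    lon: float
    area: float       # km^2
    age: float        # Ma
    altitude: float   # m, maximum elevation
    tri: float        # mean terrain ruggedness index, dimensionless
    harbor: int       # 1 if the island hosts a major historical port

    def validate(self) -> None:
        if self.area <= 0:
            raise ValueError(f"{self.code}: area must be > 0")
        if self.altitude <= 0:
            raise ValueError(f"{self.code}: altitude must be > 0")
        if self.tri < 0:
            raise ValueError(f"{self.code}: tri must be >= 0")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"{self.code}: lat outside [-90, 90]")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"{self.code}: lon outside [-180, 180]")
        if self.harbor not in (0, 1):
            raise ValueError(f"{self.code}: harbor must be 0 or 1")

    def covariate(self, name: str) -> float:
        if name not in ("area", "age", "altitude", "tri"):
            raise ValueError(f"unknown covariate {name!r}")
        return getattr(self, name)


@dataclass
class CountPanel:
    """Cumulative species counts per island per time slice (s_it).

    ``counts[i, t]`` is the number of modelled taxa attributed to island i
    whose attributing event happened in or before the year ``periods[t]``.
    Rows are non-decreasing across periods by construction.
    """

    islands: list[str]
    periods: list[int]
    counts: np.ndarray  # (n_islands, n_periods) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.islands), len(self.periods)):
            raise ValueError("counts shape does not match islands x periods")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (np.diff(self.counts, axis=1) < 0).any():
            raise ValueError("count rows must be non-decreasing (cumulative)")

    def column(self, period: int) -> np.ndarray:
        return self.counts[:, self.periods.index(period)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.islands, columns=self.periods)


DEFAULT_PERIODS = [1850, 1875, 1900, 1925, 1950, 1975]


def _parse_year(value, column: str) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return None
    try:
        return int(float(s))
    except ValueError:
        raise ValueError(f"unparsable year {value!r} in column {column}")


def _row_to_record(row: pd.Series) -> SpecimenRecord:
    dist = frozenset(c.strip() for c in str(row["distribution"]).split(";")
                     if c.strip())
    rec = SpecimenRecord(
        taxon_id=str(row["taxon_id"]),
        family=str(row["family"]),
        earliest_year=_parse_year(row["earliest_year"], "earliest_year"),
        earliest_collector=str(row["earliest_collector"]),
        earliest_island=str(row["earliest_island"]),
        type_year=_parse_year(row["type_year"], "type_year"),
        type_collector=str(row["type_collector"]),
        type_island=str(row["type_island"]),
        publication_year=_parse_year(row["publication_year"], "publication_year"),
        describing_author=str(row["describing_author"]),
        distribution=dist,
    )
    rec.validate()
    return rec


def load_records_report(path, islands: list[Island] | None = None
                        ) -> tuple[list[SpecimenRecord], list[RowError]]:
    """Load records, returning (valid records, per-row rejection report)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"records CSV missing required columns: {missing}")
    known = {isl.code for isl in islands} if islands is not None else None

    records: list[SpecimenRecord] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        try:
            rec = _row_to_record(row)
            if known is not None:
                bad = [c for c in (rec.earliest_island, rec.type_island,
                                   *sorted(rec.distribution)) if c not in known]
                if bad:
                    raise ValueError(f"unknown island code(s) {sorted(set(bad))}")
            records.append(rec)
        except ValueError as exc:
            errors.append(RowError(int(i), str(exc)))
    return records, errors


def load_records(path, islands: list[Island] | None = None,
                 errors: str = "warn") -> list[SpecimenRecord]:
    """Load and validate a specimen-record CSV.

    Parameters
    ----------
    path : str or path-like
        CSV with the documented record header; ``distribution`` is a
        semicolon-separated list of island codes.
    islands : list of Island, optional
        When given, island codes in each record are checked against it.
    errors : {"warn", "raise", "ignore"}
        What to do with rows failing validation: log a warning and drop them
        (default), raise the first RowError, or drop them silently.
    """
    records, report = load_records_report(path, islands=islands)
    if report:
        if errors == "raise":
            raise report[0]
        if errors == "warn":
            for err in report:
                logger.warning("rejected record: %s", err)
            warnings.warn(f"{len(report)} record row(s) rejected; "
                          "see log for details", stacklevel=2)
    return records


def write_records(records: list[SpecimenRecord], path) -> None:
    """Write records in the same CSV dialect ``load_records`` reads."""
    rows = []
    for r in records:
        rows.append({
            "taxon_id": r.taxon_id, "family": r.family,
            "earliest_year": r.earliest_year,
            "earliest_collector": r.earliest_collector,
            "earliest_island": r.earliest_island,
            "type_year": r.type_year, "type_collector": r.type_collector,
            "type_island": r.type_island,
            "publication_year": r.publication_year,
            "describing_author": r.describing_author,
            "distribution": ";".join(sorted(r.distribution)),
        })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def load_islands(path) -> list[Island]:
    df = pd.read_csv(path)
    missing = [c for c in ISLAND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"islands CSV missing required columns: {missing}")
    if df["code"].duplicated().any():
        dupes = df.loc[df["code"].duplicated(), "code"].tolist()
        raise SchemaError(f"duplicate island codes: {dupes}")
    islands = []
    for _, row in df.iterrows():
        isl = Island(code=str(row["code"]), name=str(row["name"]),
                     lat=float(row["lat"]), lon=float(row["lon"]),
                     area=float(row["area_km2"]), age=float(row["age_ma"]),
                     altitude=float(row["altitude_m"]), tri=float(row["tri"]),
                     harbor=int(row["harbor"]))
        isl.validate()
        islands.append(isl)
    return islands


def write_islands(islands: list[Island], path) -> None:
    rows = [{"code": i.code, "name": i.name, "lat": i.lat, "lon": i.lon,
             "area_km2": i.area, "age_ma": i.age, "altitude_m": i.altitude,
             "tri": i.tri, "harbor": i.harbor} for i in islands]
    pd.DataFrame(rows, columns=ISLAND_COLUMNS).to_csv(path, index=False)


def exclude_single_island_endemics(
        records: list[SpecimenRecord]) -> list[SpecimenRecord]:
    """Drop taxa occurring on a single island (SIE), preserving order.

    SIE are removed before spatial modelling: their collection necessarily
    happened on the one island they occupy, so they carry no information
    about which island attributes attract collecting.
    """
    return [r for r in records if not r.is_single_island_endemic]


def build_count_panel(records: list[SpecimenRecord], islands: list[Island],
                      periods: list[int] | None = None,
                      basis: str = "earliest") -> CountPanel:
    """Cumulative per-island counts of discovery events up to each period.

    ``basis`` selects the attributing event: ``"earliest"`` uses the earliest
    collection (island and year of the first record), ``"type"`` the type
    collection.  Year comparison is inclusive (event year <= period bound).
    Records with a missing event year are dropped with a logged warning.
    """
    if basis not in ("earliest", "type"):
        raise ValueError(f"basis must be 'earliest' or 'type', got {basis!r}")
    if periods is None:
        periods = list(DEFAULT_PERIODS)
    if list(periods) != sorted(set(periods)):
        raise ValueError("periods must be strictly increasing")

    codes = [isl.code for isl in islands]
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(periods)), dtype=int)
    for r in records:
        year = r.earliest_year if basis == "earliest" else r.type_year
        island = r.earliest_island if basis == "earliest" else r.type_island
        if year is None:
            logger.warning("record %s has no %s year; excluded from panel",
                           r.taxon_id, basis)
            continue
        if island not in index:
            logger.warning("record %s attributed to unmodelled island %s; "
                           "excluded from panel", r.taxon_id, island)
            continue
        for t, bound in enumerate(periods):
            if year <= bound:
                counts[index[island], t] += 1
    return CountPanel(islands=codes, periods=list(periods), counts=counts)
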
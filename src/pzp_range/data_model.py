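"""Domain types, delimited-file I/O, and dataset validation.

The field database behind a darting program is a set of event-level tables:
a horse registry, confirmed/unconfirmed vaccination deliveries, foaling
events linked to dams, injection-site lesion observations, and a monthly
herd-area residency grid.  This module defines those tables as a
:class:`Dataset` of pandas DataFrames with fixed schemas, reads and writes
them as UTF-8 comma-separated files with ISO-8601 dates, and checks the
referential and logical invariants the downstream stages rely on.

Calendar handling is centralised in :class:`StudyWindow`, which maps dates
onto a 1-based monthly index over the observation window (default January
2019 through December 2022, 48 months).  Dates before the window map onto
non-positive indices — the "pre-window" range — so that pre-program
vaccination history can be retained as ordinary events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "StudyWindow",
    "Dataset",
    "ValidationReport",
    "Violation",
    "SchemaError",
    "IntegrityError",
    "TABLE_SCHEMAS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unreadable layout."""


class IntegrityError(ValueError):
    """A record refers to an entity that does not exist."""


# Column order is the on-disk order; *_DATE columns are parsed as dates,
# *_BOOL as booleans, *_INT as integers; everything else is a string.
TABLE_SCHEMAS: Mapping[str, list[str]] = {
    "horses": [
        "horse_id", "sex", "dob", "dob_known", "status", "status_date",
        "herd_area", "dam_id",
    ],
    "vaccinations": ["event_id", "horse_id", "date", "action", "confirmed"],
    "foalings": [
        "foal_id", "dam_id", "birth_date", "foal_sex", "death_date",
        "removed_date",
    ],
    "lesions": [
        "horse_id", "event_id", "lesion_type", "first_observed", "resolved",
    ],
    "residency": ["horse_id", "year", "month", "herd_area", "darting_permitted"],
}

_DATE_COLS = {
    "horses": ["dob", "status_date"],
    "vaccinations": ["date"],
    "foalings": ["birth_date", "death_date", "removed_date"],
    "lesions": ["first_observed", "resolved"],
    "residency": [],
}
_BOOL_COLS = {
    "horses": ["dob_known"],
    "vaccinations": ["confirmed"],
    "foalings": [],
    "lesions": [],
    "residency": ["darting_permitted"],
}
_INT_COLS = {"residency": ["year", "month"]}

SEXES = {"female", "male"}
STATUSES = {"living", "removed", "deceased"}
ACTIONS = {"P", "RP", "B"}
FOAL_SEXES = {"male", "female", "unknown"}
LESION_TYPES = {"granuloma", "abscess"}


@dataclass(frozen=True)
class StudyWindow:
    """The monthly observation window of a program.

    Months are indexed 1..n_months with 1 = the start month.  Dates before
    the window map onto indices <= 0 (the pre-window range); dates after it
    map onto indices > n_months.
    """

    start_year: int = 2019
    start_month: int = 1
    n_months: int = 48

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be 1..12, got {self.start_month}")
        if self.n_months < 1:
            raise ValueError("n_months must be positive")

    def month_of(self, d: date) -> int:
        """Linear month index of ``d``; <= 0 marks a pre-window date."""
        return (d.year - self.start_year) * 12 + (d.month - self.start_month) + 1

    def in_window(self, index: int) -> bool:
        return 1 <= index <= self.n_months

    def is_pre_window(self, index: int) -> bool:
        return index < 1

    def month_start(self, index: int) -> date:
        """First calendar day of the month with the given index."""
        months = (self.start_year * 12 + self.start_month - 1) + (index - 1)
        return date(months // 12, months % 12 + 1, 1)

    def year_of(self, index: int) -> int:
        return self.month_start(index).year

    def calendar_month(self, index: int) -> int:
        """Month-of-year (1..12) for a month index."""
        return self.month_start(index).month

    def index_of(self, year: int, month: int) -> int:
        return self.month_of(date(year, month, 1))

    @property
    def months(self) -> range:
        return range(1, self.n_months + 1)

    @property
    def end_date(self) -> date:
        from datetime import timedelta

        return self.month_start(self.n_months + 1) - timedelta(days=1)

    @property
    def years(self) -> list[int]:
        return sorted({self.year_of(t) for t in self.months})


@dataclass
class Dataset:
    """In-memory field database: five tables with fixed schemas."""

    horses: pd.DataFrame
    vaccinations: pd.DataFrame
    foalings: pd.DataFrame
    lesions: pd.DataFrame
    residency: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def copy(self) -> "Dataset":
        return Dataset(**{k: v.copy() for k, v in self.tables().items()})

    def equals(self, other: "Dataset") -> bool:
        return all(
            self.tables()[k].reset_index(drop=True).equals(
                other.tables()[k].reset_index(drop=True)
            )
            for k in TABLE_SCHEMAS
        )


@dataclass(frozen=True)
class Violation:
    kind: str
    record_id: str
    detail: str = ""


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def kinds(self) -> list[str]:
        return [v.kind for v in self.violations]

    def add(self, kind: str, record_id: str, detail: str = "") -> None:
        self.violations.append(Violation(kind, str(record_id), detail))


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_SCHEMAS[name]})
    return _coerce_table(name, df)


def empty_dataset() -> Dataset:
    return Dataset(**{name: _empty_table(name) for name in TABLE_SCHEMAS})


def _coerce_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Normalise dtypes: dates to datetime64, booleans to bool, ids to str."""
    df = df.copy()
    for col in TABLE_SCHEMAS[name]:
        if col in _DATE_COLS.get(name, []):
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
        elif col in _BOOL_COLS.get(name, []):
            if df[col].dtype == object:
                df[col] = df[col].map(
                    {"True": True, "False": False, True: True, False: False}
                )
            df[col] = df[col].astype(bool)
        elif col in _INT_COLS.get(name, []):
            df[col] = df[col].astype("int64")
        else:
            df[col] = df[col].astype("object").where(df[col].notna(), None)
            df[col] = df[col].map(lambda v: None if v is None else str(v))
    return df[list(TABLE_SCHEMAS[name])]


def make_table(name: str, records: Iterable[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Build a schema-conforming table from records (convenience for tests
    and the simulator)."""
    df = pd.DataFrame(list(records) if not isinstance(records, pd.DataFrame) else records)
    if df.empty:
        return _empty_table(name)
    for col in TABLE_SCHEMAS[name]:
        if col not in df.columns:
            df[col] = None
    return _coerce_table(name, df)


def default_paths(directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    return {name: d / f"{name}.csv" for name in TABLE_SCHEMAS}


def read_dataset(paths: Mapping[str, str | Path] | str | Path) -> Dataset:
    """Read the five CSV tables and check schema + referential integrity.

    ``paths`` is either a directory containing horses.csv, vaccinations.csv,
    foalings.csv, lesions.csv and residency.csv, or a mapping from table
    name to file path.
    """
    if isinstance(paths, (str, Path)):
        paths = default_paths(paths)
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"missing input file for table '{name}': {p}")
        raw = pd.read_csv(p, dtype="object", keep_default_na=True)
        missing = [c for c in TABLE_SCHEMAS[name] if c not in raw.columns]
        if missing:
            raise SchemaError(
                f"table '{name}' ({p}) is missing column(s): {', '.join(missing)}"
            )
        raw = raw.where(raw.notna(), None)
        tables[name] = _coerce_table(name, raw)
    ds = Dataset(**tables)
    _check_references(ds)
    return ds


def write_dataset(ds: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write all tables as CSV with ISO-8601 dates; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = default_paths(directory)
    for name, df in ds.tables().items():
        out = df.copy()
        for col in _DATE_COLS.get(name, []):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[name], index=False)
    return paths


def _check_references(ds: Dataset) -> None:
    known = set(ds.horses["horse_id"])
    dangling: list[str] = []
    for name, col in [
        ("vaccinations", "horse_id"),
        ("foalings", "dam_id"),
        ("foalings", "foal_id"),
        ("lesions", "horse_id"),
        ("residency", "horse_id"),
    ]:
        vals = ds.tables()[name][col].dropna()
        bad = sorted(set(vals) - known)
        dangling.extend(f"{name}.{col}: {v}" for v in bad)
    if dangling:
        raise IntegrityError(
            "dangling references to unknown horse_id: " + "; ".join(dangling)
        )


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report every invariant violation; never raises, never mutates.

    Checked invariants: unique IDs, valid categorical codes, dob/dob_known
    consistency, status_date presence, death/resolution not before
    birth/onset, one dam per foal, at most one residency row per
    horse-month.
    """
    rep = ValidationReport()
    h = ds.horses
    for hid in h.loc[h["horse_id"].duplicated(), "horse_id"].unique():
        rep.add("duplicate_id", hid, "horse_id appears more than once")
    for _, row in h.iterrows():
        if row["sex"] not in SEXES:
            rep.add("bad_sex", row["horse_id"], f"sex={row['sex']!r}")
        if row["status"] not in STATUSES:
            rep.add("bad_status", row["horse_id"], f"status={row['status']!r}")
        elif row["status"] != "living" and pd.isna(row["status_date"]):
            rep.add("missing_status_date", row["horse_id"], row["status"])
        if pd.isna(row["dob"]) and row["dob_known"]:
            rep.add("dob_known_without_dob", row["horse_id"])

    v = ds.vaccinations
    for eid in v.loc[v["event_id"].duplicated(), "event_id"].unique():
        rep.add("duplicate_id", eid, "event_id appears more than once")
    for _, row in v.iterrows():
        if row["action"] not in ACTIONS:
            rep.add("bad_action", row["event_id"], f"action={row['action']!r}")

    f = ds.foalings
    for fid in f.loc[f["foal_id"].duplicated(), "foal_id"].unique():
        rep.add("multiple_dams", fid, "foal linked to more than one dam record")
    for _, row in f.iterrows():
        if row["foal_sex"] not in FOAL_SEXES:
            rep.add("bad_foal_sex", row["foal_id"], f"foal_sex={row['foal_sex']!r}")
        if pd.notna(row["death_date"]) and row["death_date"] < row["birth_date"]:
            rep.add("death_before_birth", row["foal_id"])

    for i, row in ds.lesions.iterrows():
        if row["lesion_type"] not in LESION_TYPES:
            rep.add("bad_lesion_type", row["horse_id"], f"{row['lesion_type']!r}")
        if pd.notna(row["resolved"]) and row["resolved"] < row["first_observed"]:
            rep.add("resolved_before_observed", row["horse_id"])

    r = ds.residency
    dup = r.duplicated(subset=["horse_id", "year", "month"])
    for hid in r.loc[dup, "horse_id"].unique():
        rep.add("multiple_residency_per_month", hid)
    return rep


def month_of(d: date, w: StudyWindow) -> int:
    """Module-level alias for :meth:`StudyWindow.month_of`."""
    return w.month_of(d)
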
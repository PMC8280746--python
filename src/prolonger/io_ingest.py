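"""Ingestion and interconversion of death records, aggregate tables and population counts.

Two input modes are supported, mirroring what vital-statistics offices can
release: individual-level decedent records (year, age at death, cause group,
geographic unit, optional sex/race) and aggregate death tables (counts per
geounit x year x 5-year age band x cause). Aggregate tables can be expanded
into pseudo-individuals under the conservative assumption that deaths are
uniformly distributed across each age band; the expansion is an exact
right-inverse of aggregation, so no deaths are created or lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeBandSchema",
    "DeathRecordSet",
    "AggregateDeathTable",
    "PopulationTable",
    "SchemaError",
    "ValidationReport",
    "read_individual_deaths",
    "read_aggregate_deaths",
    "read_population",
    "read_covariates",
    "aggregate_individual",
    "make_pseudo_individuals",
]

STRATA_COLUMNS = ("sex", "race")


class SchemaError(ValueError):
    """An input file does not conform to the documented CSV schema."""


@dataclass
class ValidationReport:
    """Row-level problems found while reading or validating an input file."""

    source: str = ""
    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    @property
    def ok(self) -> bool:
        return self.n_dropped == 0

    def add(self, row: int, reason: str) -> None:
        self.dropped.append((int(row), reason))

    def summary(self) -> str:
        lines = [f"{self.source}: read {self.n_read} rows, kept {self.n_kept}, dropped {self.n_dropped}"]
        lines += [f"  row {r}: {why}" for r, why in self.dropped[:50]]
        if self.n_dropped > 50:
            lines.append(f"  ... and {self.n_dropped - 50} more")
        return "\n".join(lines)


@dataclass(frozen=True)
class AgeBandSchema:
    """Contiguous 5-year-style age bands starting at 0 with one open terminal band.

    ``lowers[i]`` is the first single-year age in band *i*; ``uppers[i]`` the
    last (inclusive), ``None`` for the open-ended terminal band. The default
    schema is 0-4, 5-9, ..., 80-84, 85+. ``open_band_span`` controls how many
    single-year ages pseudo-individuals are spread over in the open band
    (default 5, i.e. ages 85-89), keeping symmetry with the closed bands.
    """

    lowers: tuple[int, ...]
    uppers: tuple[int | None, ...]
    open_band_span: int = 5

    def __post_init__(self) -> None:
        if len(self.lowers) != len(self.uppers) or not self.lowers:
            raise ValueError("lowers and uppers must be equally sized, non-empty")
        if self.lowers[0] != 0:
            raise ValueError("bands must start at age 0")
        if any(u is not None for u in self.uppers[:-1]) is False and len(self.uppers) > 1:
            pass
        for i, (lo, up) in enumerate(zip(self.lowers, self.uppers)):
            terminal = i == len(self.lowers) - 1
            if terminal:
                if up is not None:
                    raise ValueError("terminal band must be open-ended")
            else:
                if up is None:
                    raise ValueError("only the terminal band may be open-ended")
                if up < lo:
                    raise ValueError(f"band {i} has upper < lower")
                if self.lowers[i + 1] != up + 1:
                    raise ValueError(f"bands {i} and {i + 1} are not contiguous")
        if self.open_band_span < 1:
            raise ValueError("open_band_span must be >= 1")

    @classmethod
    def default(cls) -> "AgeBandSchema":
        lowers = tuple(range(0, 90, 5))
        uppers = tuple(list(range(4, 85, 5)) + [None])
        return cls(lowers, uppers)

    @classmethod
    def from_labels(cls, labels: Sequence[str], open_band_span: int = 5) -> "AgeBandSchema":
        lowers, uppers = [], []
        for lab in labels:
            lo, up = _parse_band_label(lab)
            lowers.append(lo)
            uppers.append(up)
        return cls(tuple(lowers), tuple(uppers), open_band_span)

    @property
    def n_bands(self) -> int:
        return len(self.lowers)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for lo, up in zip(self.lowers, self.uppers):
            out.append(f"{lo}+" if up is None else f"{lo}-{up}")
        return tuple(out)

    def width(self, i: int) -> int:
        """Single-year ages covered by band i (open band: open_band_span)."""
        up = self.uppers[i]
        return self.open_band_span if up is None else up - self.lowers[i] + 1

    def band_index(self, ages) -> np.ndarray:
        """Map integer ages to band indices (vectorised)."""
        ages = np.asarray(ages)
        if ages.size and ages.min() < 0:
            raise ValueError("negative age")
        edges = np.asarray(self.lowers[1:])
        return np.searchsorted(edges, ages, side="right")

    def band_label(self, ages) -> np.ndarray:
        labs = np.asarray(self.labels, dtype=object)
        return labs[self.band_index(ages)]

    def index_of_label(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown age band label {label!r}") from None


def _parse_band_label(label: str) -> tuple[int, int | None]:
    label = str(label).strip()
    m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", label)
    if m:
        return int(m.group(1)), int(m.group(2))
    m = re.fullmatch(r"(\d+)\s*\+", label)
    if m:
        return int(m.group(1)), None
    raise SchemaError(f"unparseable age band label {label!r} (expected e.g. '0-4' or '85+')")


# ---------------------------------------------------------------------------
# containers


def _present_strata(df: pd.DataFrame) -> list[str]:
    return [c for c in STRATA_COLUMNS if c in df.columns]


@dataclass
class DeathRecordSet:
    """Individual decedent events; the seed data for the lives-saved simulation.

    ``data`` columns: year (int), age (int, completed years), cause (str),
    geounit (str), pseudo (bool: synthesized from aggregate counts), plus
    optional sex / race.
    """

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        required = {"year", "age", "cause", "geounit"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"DeathRecordSet missing columns: {sorted(missing)}")
        if "pseudo" not in self.data.columns:
            self.data = self.data.assign(pseudo=False)
        if len(self.data) and (self.data["age"] < 0).any():
            raise ValueError("age_at_death must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def strata(self) -> list[str]:
        return _present_strata(self.data)

    @property
    def geounits(self) -> list[str]:
        return sorted(self.data["geounit"].unique())

    @property
    def years(self) -> tuple[int, int]:
        return int(self.data["year"].min()), int(self.data["year"].max())

    def filter(self, *, geounit: str | None = None, cause: str | None = None,
               **strata: str) -> "DeathRecordSet":
        df = self.data
        if geounit is not None:
            df = df[df["geounit"] == geounit]
        if cause is not None:
            df = df[df["cause"] == cause]
        for col, val in strata.items():
            df = df[df[col] == val]
        return DeathRecordSet(df.reset_index(drop=True), self.schema)

    def to_csv(self, path: str | Path) -> None:
        cols = ["year", "age", "cause", "geounit", *self.strata]
        self.data[cols].to_csv(path, index=False)


@dataclass
class AggregateDeathTable:
    """Death counts per (geounit, year, age_band, cause[, sex, race]) cell.

    Counts may be fractional after smoothing; raw ingested counts are integers.
    Only nonzero cells need be stored; :meth:`dense` fills in the zeros.
    """

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        required = {"geounit", "year", "age_band", "cause", "deaths"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"AggregateDeathTable missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["deaths"] < 0).any():
            raise ValueError("death counts must be >= 0")
        keys = self.key_columns
        if self.data.duplicated(subset=keys).any():
            dup = self.data[self.data.duplicated(subset=keys, keep=False)].iloc[0]
            raise SchemaError(f"duplicated cell key {tuple(dup[k] for k in keys)}")
        known = set(self.schema.labels)
        bad = set(self.data["age_band"].unique()) - known
        if bad:
            raise SchemaError(f"age bands {sorted(bad)} not in schema {list(known)}")

    @property
    def key_columns(self) -> list[str]:
        return ["geounit", "year", "age_band", "cause", *_present_strata(self.data)]

    @property
    def strata(self) -> list[str]:
        return _present_strata(self.data)

    def total(self) -> float:
        return float(self.data["deaths"].sum())

    def filter(self, *, geounit: str | None = None, cause: str | None = None) -> "AggregateDeathTable":
        df = self.data
        if geounit is not None:
            df = df[df["geounit"] == geounit]
        if cause is not None:
            df = df[df["cause"] == cause]
        return AggregateDeathTable(df.reset_index(drop=True), self.schema)

    def pooled(self, by: Sequence[str] = ("geounit", "age_band")) -> pd.DataFrame:
        """Sum counts over all key dimensions not listed in ``by``."""
        return self.data.groupby(list(by), as_index=False)["deaths"].sum()

    def collapse_strata(self) -> "AggregateDeathTable":
        keys = ["geounit", "year", "age_band", "cause"]
        return AggregateDeathTable(
            self.data.groupby(keys, as_index=False)["deaths"].sum(), self.schema
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.data[self.key_columns + ["deaths"]].sort_values(self.key_columns)
        out.to_csv(path, index=False)

    def sorted_key(self) -> pd.DataFrame:
        """Canonical ordering for equality comparisons (drops zero cells)."""
        df = self.data[self.data["deaths"] > 0]
        return df.sort_values(self.key_columns).reset_index(drop=True)[self.key_columns + ["deaths"]]


@dataclass
class PopulationTable:
    """Population counts per (geounit, year, age_band[, sex, race])."""

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        required = {"geounit", "year", "age_band", "population"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"PopulationTable missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["population"] < 0).any():
            raise ValueError("population must be >= 0")
        keys = ["geounit", "year", "age_band", *_present_strata(self.data)]
        if self.data.duplicated(subset=keys).any():
            dup = self.data[self.data.duplicated(subset=keys, keep=False)].iloc[0]
            raise SchemaError(f"duplicated population key {tuple(dup[k] for k in keys)}")

    @property
    def strata(self) -> list[str]:
        return _present_strata(self.data)

    @property
    def geounits(self) -> list[str]:
        return sorted(self.data["geounit"].unique())

    def collapse_strata(self) -> "PopulationTable":
        if not self.strata:
            return self
        keys = ["geounit", "year", "age_band"]
        return PopulationTable(
            self.data.groupby(keys, as_index=False)["population"].sum(), self.schema
        )

    def filter(self, *, geounit: str | None = None, **strata: str) -> "PopulationTable":
        df = self.data
        if geounit is not None:
            df = df[df["geounit"] == geounit]
        for col, val in strata.items():
            df = df[df[col] == val]
        return PopulationTable(df.reset_index(drop=True), self.schema)

    def person_years(self, geounit: str, window: tuple[int, int]) -> pd.Series:
        """Total person-years per band over the window, indexed by band label."""
        df = self.collapse_strata().data
        df = df[(df["geounit"] == geounit)
                & (df["year"] >= window[0]) & (df["year"] <= window[1])]
        out = df.groupby("age_band")["population"].sum()
        return out.reindex(self.schema.labels, fill_value=0.0).astype(float)

    def to_csv(self, path: str | Path) -> None:
        keys = ["geounit", "year", "age_band", *self.strata]
        self.data[keys + ["population"]].sort_values(keys).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers


def _read_csv(path: str | Path, required: Iterable[str], colmap: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_individual_deaths(
    path: str | Path,
    schema: AgeBandSchema | None = None,
    *,
    colmap: Mapping[str, str] | None = None,
    causes: Sequence[str] | None = None,
    window: tuple[int, int] | None = None,
    max_age: int = 100,
    age_policy: str = "drop",
) -> tuple[DeathRecordSet, ValidationReport]:
    """Read an individual-level deaths CSV (columns year,age,cause,geounit[,sex,race]).

    Rows with missing geounit or cause, non-numeric ages, out-of-window years
    or causes outside the configured cause list are dropped and itemised in
    the validation report. ``age_policy`` governs ages above ``max_age``:
    ``"drop"`` (default) removes the row, ``"clamp"`` truncates to ``max_age``.
    Ages must be whole completed years; fractional ages are rejected row-wise.
    """
    schema = schema or AgeBandSchema.default()
    if age_policy not in ("drop", "clamp"):
        raise ValueError("age_policy must be 'drop' or 'clamp'")
    df = _read_csv(path, ["year", "age", "cause", "geounit"], colmap)
    report = ValidationReport(source=str(path), n_read=len(df))

    keep = np.ones(len(df), dtype=bool)
    for col in ("geounit", "cause"):
        bad = df[col].isna() | (df[col].astype(str).str.strip() == "")
        for i in df.index[bad & keep]:
            report.add(i, f"missing {col}")
        keep &= ~bad

    age = pd.to_numeric(df["age"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    for col_name, vals in (("age", age), ("year", year)):
        bad = vals.isna() & keep
        for i in df.index[bad]:
            report.add(i, f"non-numeric {col_name} {df.loc[i, col_name]!r}")
        keep &= ~bad
    frac = keep & ((age % 1 != 0) | (year % 1 != 0))
    for i in df.index[frac]:
        report.add(i, "fractional age or year")
    keep &= ~frac
    neg = keep & (age < 0)
    for i in df.index[neg]:
        report.add(i, "negative age")
    keep &= ~neg

    if age_policy == "drop":
        over = keep & (age > max_age)
        for i in df.index[over]:
            report.add(i, f"age {int(age[i])} exceeds max_age {max_age}")
        keep &= ~over
    else:
        age = age.clip(upper=max_age)

    if causes is not None:
        allowed = set(causes)
        bad = keep & ~df["cause"].isin(allowed)
        for i in df.index[bad]:
            report.add(i, f"cause {df.loc[i, 'cause']!r} not in configured cause list")
        keep &= ~bad
    if window is not None:
        bad = keep & ((year < window[0]) | (year > window[1]))
        for i in df.index[bad]:
            report.add(i, f"year {int(year[i])} outside window {window}")
        keep &= ~bad

    out = pd.DataFrame({
        "year": year[keep].astype(int),
        "age": age[keep].astype(int),
        "cause": df.loc[keep, "cause"].astype(str),
        "geounit": df.loc[keep, "geounit"].astype(str),
    })
    for col in STRATA_COLUMNS:
        if col in df.columns:
            out[col] = df.loc[keep, col].astype(str)
    out["pseudo"] = False
    report.n_kept = len(out)
    return DeathRecordSet(out.reset_index(drop=True), schema), report


def read_aggregate_deaths(
    path: str | Path,
    schema: AgeBandSchema | None = None,
    *,
    colmap: Mapping[str, str] | None = None,
) -> tuple[AggregateDeathTable, ValidationReport]:
    """Read an aggregate deaths CSV (geounit,year,age_band,cause[,sex,race],deaths)."""
    schema = schema or AgeBandSchema.default()
    df = _read_csv(path, ["geounit", "year", "age_band", "cause", "deaths"], colmap)
    report = ValidationReport(source=str(path), n_read=len(df))
    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    keep = np.ones(len(df), dtype=bool)
    for col_name, vals in (("deaths", deaths), ("year", year)):
        bad = vals.isna() & keep
        for i in df.index[bad]:
            report.add(i, f"non-numeric {col_name} {df.loc[i, col_name]!r}")
        keep &= ~bad
    neg = keep & (deaths < 0)
    for i in df.index[neg]:
        report.add(i, "negative death count")
    keep &= ~neg
    out = df.loc[keep, ["geounit", "age_band", "cause"]].astype(str)
    out.insert(1, "year", year[keep].astype(int))
    out["deaths"] = deaths[keep].astype(float)
    for col in STRATA_COLUMNS:
        if col in df.columns:
            out[col] = df.loc[keep, col].astype(str)
    report.n_kept = len(out)
    table = AggregateDeathTable(out.reset_index(drop=True), schema)
    return table, report


def read_population(
    path: str | Path,
    schema: AgeBandSchema | None = None,
    *,
    colmap: Mapping[str, str] | None = None,
) -> tuple[PopulationTable, ValidationReport]:
    """Read a population CSV (geounit,year,age_band[,sex,race],population)."""
    schema = schema or AgeBandSchema.default()
    df = _read_csv(path, ["geounit", "year", "age_band", "population"], colmap)
    report = ValidationReport(source=str(path), n_read=len(df))
    pop = pd.to_numeric(df["population"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    keep = np.ones(len(df), dtype=bool)
    for col_name, vals in (("population", pop), ("year", year)):
        bad = vals.isna() & keep
        for i in df.index[bad]:
            report.add(i, f"non-numeric {col_name} {df.loc[i, col_name]!r}")
        keep &= ~bad
    out = df.loc[keep, ["geounit", "age_band"]].astype(str)
    out.insert(1, "year", year[keep].astype(int))
    out["population"] = pop[keep].astype(float)
    for col in STRATA_COLUMNS:
        if col in df.columns:
            out[col] = df.loc[keep, col].astype(str)
    report.n_kept = len(out)
    return PopulationTable(out.reset_index(drop=True), schema), report


def read_covariates(
    path: str | Path,
    *,
    colmap: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read geounit-level covariates (geounit + numeric covariate columns)."""
    df = _read_csv(path, ["geounit"], colmap)
    report = ValidationReport(source=str(path), n_read=len(df))
    if df["geounit"].duplicated().any():
        dup = df["geounit"][df["geounit"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated geounit {dup!r}")
    out = df.set_index("geounit").apply(pd.to_numeric, errors="coerce")
    report.n_kept = len(out)
    return out, report


# ---------------------------------------------------------------------------
# interconversion


def aggregate_individual(
    records: DeathRecordSet,
    schema: AgeBandSchema | None = None,
    strata: Sequence[str] = (),
) -> AggregateDeathTable:
    """Aggregate individual records to (geounit, year, age_band, cause[, strata]) counts.

    Total count is preserved exactly: every record maps to exactly one cell.
    """
    schema = schema or records.schema
    df = records.data
    keys = ["geounit", "year", "cause", *strata]
    for s in strata:
        if s not in df.columns:
            raise SchemaError(f"stratum column {s!r} not present in records")
    if len(df) == 0:
        empty = pd.DataFrame(columns=["geounit", "year", "age_band", "cause", *strata, "deaths"])
        empty["year"] = empty["year"].astype(int)
        empty["deaths"] = empty["deaths"].astype(float)
        return AggregateDeathTable(empty, schema)
    work = df[keys].copy()
    work["age_band"] = schema.band_label(df["age"].to_numpy())
    out = work.groupby(["geounit", "year", "age_band", "cause", *strata], as_index=False).size()
    out = out.rename(columns={"size": "deaths"})
    out["deaths"] = out["deaths"].astype(float)
    return AggregateDeathTable(out, schema)


def make_pseudo_individuals(table: AggregateDeathTable, rng_seed: int) -> DeathRecordSet:
    """Expand an aggregate table into pseudo-individual records, uniformly within bands.

    Each cell of *k* deaths in a band of width *w* yields one record per
    counted death: every single-year age in the band receives ``k // w``
    records (round-robin), and the remaining ``k % w`` are placed at ages
    drawn without replacement with a seeded generator. The open terminal band
    spreads over ``schema.open_band_span`` ages (default 85-89). Because
    stratified cells carry their sex/race key, strata are reproduced in
    exactly the observed stratum-specific proportions within each age group.
    Re-aggregating the result returns the input table exactly; the same seed
    always yields the identical record set. Fractional counts (smoothed
    tables) are rejected: expansion is defined for integer counts.
    """
    schema = table.schema
    df = table.data
    counts = df["deaths"].to_numpy(dtype=float)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("make_pseudo_individuals requires integer death counts")
    rng = np.random.default_rng(rng_seed)
    strata = table.strata
    # deterministic cell order so one sequential RNG reproduces exactly
    cells = df.sort_values(table.key_columns).reset_index(drop=True)

    rows: list[pd.DataFrame] = []
    for _, cell in cells.iterrows():
        k = int(round(cell["deaths"]))
        if k == 0:
            continue
        bi = schema.index_of_label(cell["age_band"])
        lo = schema.lowers[bi]
        w = schema.width(bi)
        ages = np.repeat(np.arange(lo, lo + w), k // w)
        r = k % w
        if r:
            extra = lo + rng.choice(w, size=r, replace=False)
            ages = np.concatenate([ages, np.sort(extra)])
        rec = pd.DataFrame({
            "year": int(cell["year"]),
            "age": np.sort(ages).astype(int),
            "cause": cell["cause"],
            "geounit": cell["geounit"],
        })
        for s in strata:
            rec[s] = cell[s]
        rows.append(rec)
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["year", "age", "cause", "geounit", *strata])
        out["year"] = out["year"].astype(int)
        out["age"] = out["age"].astype(int)
    out["pseudo"] = True
    return DeathRecordSet(out, schema)
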
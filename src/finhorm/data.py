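"""Domain types and CSV I/O for whale hormone records and assay data.

Concentrations at the record level are blubber hormone concentrations in
ng per g of blubber; pg/mL values appear only inside assay plate data.
Dates are ISO-8601 in files and day-of-year is derived from the
proleptic Gregorian calendar (leap-day records keep day 60; the seasonal
model always uses a 365-day period regardless).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .mcmc import PosteriorSummary

__all__ = [
    "Sex",
    "Hormone",
    "Stage",
    "HormoneRecord",
    "Dataset",
    "AssayMeasurement",
    "SchemaError",
    "RowValidationError",
    "read_hormone_csv",
    "write_hormone_csv",
    "read_assay_csv",
    "write_summary_table",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Hormone(str, Enum):
    PROGESTERONE = "progesterone"
    TESTOSTERONE = "testosterone"


class Stage(str, Enum):
    LACTATING = "lactating"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowValidationError(ValueError):
    """One or more rows violate a record invariant.

    ``rows`` holds the offending 1-based data row numbers.
    """

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {', '.join(map(str, rows))})")
        self.rows = list(rows)


_SEX_ALIASES = {"f": Sex.FEMALE, "female": Sex.FEMALE,
                "m": Sex.MALE, "male": Sex.MALE}
_HORMONE_ALIASES = {"p4": Hormone.PROGESTERONE, "progesterone": Hormone.PROGESTERONE,
                    "t": Hormone.TESTOSTERONE, "testosterone": Hormone.TESTOSTERONE}


@dataclass(frozen=True)
class HormoneRecord:
    """One individual's blubber hormone concentration with metadata.

    ``replicated`` is False for original observations and True only for
    copies created by winter-replication augmentation (which also pushes
    ``day_of_year`` past 365).
    """

    whale_id: str
    sex: Sex
    hormone: Hormone
    concentration: float  # ng per g blubber
    date: _dt.date
    day_of_year: int = field(default=0)
    region: str | None = None
    stage: Stage | None = None
    replicated: bool = False

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"concentration must be positive (log-scale models), got "
                f"{self.concentration!r} for whale {self.whale_id!r}"
            )
        doy = self.date.timetuple().tm_yday
        if self.day_of_year == 0:
            object.__setattr__(self, "day_of_year", doy)
        elif not self.replicated and self.day_of_year != doy:
            raise ValueError(
                f"day_of_year {self.day_of_year} inconsistent with date "
                f"{self.date.isoformat()} (expected {doy})"
            )
        # The study design pairs progesterone with females and
        # testosterone with males; a crossed record is suspicious but
        # not impossible, so warn rather than refuse.
        expected = (Sex.FEMALE if self.hormone is Hormone.PROGESTERONE else Sex.MALE)
        if self.sex is not expected:
            warnings.warn(
                f"whale {self.whale_id!r}: {self.hormone.value} measured in a "
                f"{self.sex.value}; this study design pairs progesterone with "
                "females and testosterone with males",
                stacklevel=2,
            )


@dataclass
class Dataset:
    """An ordered collection of hormone records with a provenance tag."""

    records: list[HormoneRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, _dt.date, Hormone]] = set()
        for rec in self.records:
            if rec.replicated:
                continue
            key = (rec.whale_id, rec.date, rec.hormone)
            if key in seen:
                raise ValueError(
                    f"duplicate non-replicated record for whale {rec.whale_id!r} "
                    f"on {rec.date.isoformat()}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HormoneRecord]:
        return iter(self.records)

    def filter(self, hormone: Hormone | None = None, sex: Sex | None = None) -> "Dataset":
        recs = [r for r in self.records
                if (hormone is None or r.hormone is hormone)
                and (sex is None or r.sex is sex)]
        return Dataset(recs, provenance=self.provenance)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([r.concentration for r in self.records])

    @property
    def days(self) -> np.ndarray:
        return np.array([r.day_of_year for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "whale_id": [r.whale_id for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "hormone": [r.hormone.value for r in self.records],
                "date": [r.date.isoformat() for r in self.records],
                "day_of_year": [r.day_of_year for r in self.records],
                "concentration": [r.concentration for r in self.records],
                "region": [r.region if r.region is not None else "" for r in self.records],
                "stage": [r.stage.value if r.stage is not None else "" for r in self.records],
                "replicated": [r.replicated for r in self.records],
            }
        )


@dataclass(frozen=True)
class AssayMeasurement:
    """Duplicate (or higher-replicate) plate readings for one sample.

    ``replicate_values`` are back-calculated concentrations in pg/mL.
    """

    sample_id: str
    replicate_values: tuple[float, ...]
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.replicate_values) < 2:
            raise ValueError("need at least 2 replicate values")
        if any(v < 0 for v in self.replicate_values):
            raise ValueError("replicate values must be nonnegative")
        if not self.dilution_factor > 0:
            raise ValueError("dilution_factor must be positive")


_DEFAULT_SCHEMA = {
    "id": "whale_id",
    "sex": "sex",
    "hormone": "hormone",
    "date": "date",
    "concentration": "concentration",
    "region": "region",
    "stage": "stage",
    "replicated": "replicated",
}


def read_hormone_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> Dataset:
    """Read hormone records from a CSV file.

    Parameters
    ----------
    path
        CSV file (RFC 4180, UTF-8, header row) with at least the
        columns mapped by ``schema`` for id, sex, hormone, date and
        concentration.  Dates must be ISO-8601.
    schema
        Optional map from the logical field names
        (``id, sex, hormone, date, concentration, region, stage,
        replicated``) to the column names used in the file.

    Raises
    ------
    SchemaError
        If a required column is absent.
    RowValidationError
        If any row carries a nonpositive concentration or an unparsable
        field; the error lists the offending 1-based data row numbers.
    """
    path = Path(path)
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "sex", "hormone", "date", "concentration"]
    missing = [colmap[k] for k in required if colmap[k] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    records: list[HormoneRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            conc = float(rowd[colmap["concentration"]])
            if not conc > 0:
                raise ValueError("nonpositive concentration")
            date = _dt.date.fromisoformat(rowd[colmap["date"]])
            sex = _SEX_ALIASES[rowd[colmap["sex"]].strip().lower()]
            hormone = _HORMONE_ALIASES[rowd[colmap["hormone"]].strip().lower()]
            region = rowd.get(colmap["region"], "") or None
            stage_raw = rowd.get(colmap["stage"], "").strip().lower()
            stage = Stage(stage_raw) if stage_raw else None
            repl_raw = rowd.get(colmap["replicated"], "").strip().lower()
            replicated = repl_raw in {"true", "1", "yes"}
            doy_raw = rowd.get("day_of_year", "").strip()
            doy = int(doy_raw) if (doy_raw and replicated) else 0
            records.append(
                HormoneRecord(
                    whale_id=str(rowd[colmap["id"]]),
                    sex=sex,
                    hormone=hormone,
                    concentration=conc,
                    date=date,
                    day_of_year=doy,
                    region=region,
                    stage=stage,
                    replicated=replicated,
                )
            )
        except (ValueError, KeyError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        raise RowValidationError(
            f"{path.name}: {len(bad_rows)} malformed row(s): "
            + "; ".join(f"row {i}: {m}" for i, m in bad_rows[:10]),
            [i for i, _ in bad_rows],
        )
    return Dataset(records, provenance=str(path))


def write_hormone_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the dialect :func:`read_hormone_csv` accepts.

    Round-trips all fields bit-identically for well-formed datasets
    (floats use the shortest round-trip decimal representation).
    """
    df = dataset.to_dataframe()
    df["concentration"] = [repr(c) for c in df["concentration"]]
    df.to_csv(path, index=False)


def read_assay_csv(path: str | Path) -> list[AssayMeasurement]:
    """Read plate data: columns sample_id, replicate_1..k, dilution_factor."""
    df = pd.read_csv(path)
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("replicate_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if "sample_id" not in df.columns or not rep_cols:
        raise SchemaError(
            f"{Path(path).name}: need sample_id and replicate_1..k columns"
        )
    out = []
    for _, row in df.iterrows():
        reps = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        dil = float(row["dilution_factor"]) if "dilution_factor" in df.columns else 1.0
        out.append(AssayMeasurement(str(row["sample_id"]), reps, dil))
    return out


#: Column order of the posterior summary table.
SUMMARY_COLUMNS = ["Mean", "SD", "2.5%", "25.0%", "50.0%", "75.0%", "97.5%",
                   "Rhat", "Neff (%)"]


def write_summary_table(
    summaries: Iterable[PosteriorSummary],
    path: str | Path,
) -> pd.DataFrame:
    """Write posterior summaries as a CSV table.

    One row per parameter; columns are Mean, SD, the 2.5/25/50/75/97.5
    percentiles, Rhat and Neff (%), in that order.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to write")
    rows = []
    for s in summaries:
        rows.append(
            {
                "parameter": s.parameter,
                "Mean": s.mean,
                "SD": s.sd,
                "2.5%": s.quantiles[2.5],
                "25.0%": s.quantiles[25.0],
                "50.0%": s.quantiles[50.0],
                "75.0%": s.quantiles[75.0],
                "97.5%": s.quantiles[97.5],
                "Rhat": s.rhat,
                "Neff (%)": s.neff_percent,
            }
        )
    df = pd.DataFrame(rows, columns=["parameter"] + SUMMARY_COLUMNS)
    df.to_csv(path, index=False)
    return df
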
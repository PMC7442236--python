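"""Domain types and validated CSV IO for the three observation streams.

Streams
-------
* larvae: cross-sectional dipnet measurements with *known* age, computed from
  the pond-fill date of the natal wetland (age 0 = pond filling).
* metamorphs: sizes of individuals leaving the wetland; age at metamorphosis
  is latent.
* adults: drift-fence mark-recapture histories; age at first capture is
  latent, recaptures contribute time offsets (delta-t) from first capture.

CSV dialect: comma-separated, UTF-8, ISO-8601 dates, header required.
All date-to-year conversions use a fixed 365.25-day year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "LarvalRecord",
    "MetamorphRecord",
    "CaptureOccasion",
    "AdultCaptureHistory",
    "Dataset",
    "ValidationError",
    "SchemaError",
    "read_larval_csv",
    "read_metamorph_csv",
    "read_adult_captures_csv",
    "write_larval_csv",
    "write_metamorph_csv",
    "write_adult_captures_csv",
    "validate_dataset",
]

DAYS_PER_YEAR = 365.25


class SchemaError(ValueError):
    """A CSV file is missing required columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class LarvalRecord:
    """A known-age larval length observation."""

    wetland_id: str
    capture_date: date
    pond_fill_date: date
    svl_mm: float

    @property
    def age_years(self) -> float:
        return (self.capture_date - self.pond_fill_date).days / DAYS_PER_YEAR

    def __post_init__(self):
        if self.svl_mm <= 0:
            raise ValidationError(f"svl_mm must be positive, got {self.svl_mm}")
        if self.capture_date < self.pond_fill_date:
            raise ValidationError(
                f"capture_date {self.capture_date} precedes pond_fill_date "
                f"{self.pond_fill_date}"
            )
        if not (0 < self.age_years <= 2):
            raise ValidationError(
                f"larval age {self.age_years:.4f} yr outside (0, 2]"
            )


@dataclass(frozen=True)
class MetamorphRecord:
    """Size at emigration from the natal wetland; age at metamorphosis latent."""

    wetland_id: str
    cohort_year: int
    svl_mm: float

    def __post_init__(self):
        if self.svl_mm <= 0:
            raise ValidationError(f"svl_mm must be positive, got {self.svl_mm}")


@dataclass(frozen=True)
class CaptureOccasion:
    """A single adult measurement, timed relative to first capture."""

    time_offset_years: float
    svl_mm: float

    def __post_init__(self):
        if self.time_offset_years < 0:
            raise ValidationError("time_offset_years must be >= 0")
        if self.svl_mm <= 0:
            raise ValidationError(f"svl_mm must be positive, got {self.svl_mm}")


@dataclass(frozen=True)
class AdultCaptureHistory:
    """Ordered capture history of one PIT-tagged adult."""

    individual_id: str
    first_capture_date: date
    occasions: tuple[CaptureOccasion, ...]

    def __post_init__(self):
        occ = tuple(self.occasions)
        object.__setattr__(self, "occasions", occ)
        if not occ:
            raise ValidationError(f"{self.individual_id}: empty capture history")
        if occ[0].time_offset_years != 0:
            raise ValidationError(
                f"{self.individual_id}: first occasion offset must be 0"
            )
        offsets = [o.time_offset_years for o in occ]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValidationError(
                f"{self.individual_id}: offsets must be strictly increasing"
            )

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)


@dataclass
class Dataset:
    """The three observation streams fitted jointly."""

    larvae: list[LarvalRecord] = field(default_factory=list)
    metamorphs: list[MetamorphRecord] = field(default_factory=list)
    adults: list[AdultCaptureHistory] = field(default_factory=list)

    def __post_init__(self):
        ids = [h.individual_id for h in self.adults]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate individual_id among adult histories")


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

_LARVAL_COLS = ["wetland_id", "capture_date", "pond_fill_date", "svl_mm"]
_META_COLS = ["wetland_id", "cohort_year", "svl_mm"]
_ADULT_COLS = ["individual_id", "capture_date", "svl_mm"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_date(value: str, row: int, col: str) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError as exc:
        raise ValueError(f"row {row}: cannot parse {col}={value!r} as a date") from exc


def _parse_float(value: str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValueError(f"row {row}: cannot parse {col}={value!r} as a number") from exc


def read_larval_csv(path) -> list[LarvalRecord]:
    """Read known-age larval records; ``age_years`` derives from the dates."""
    df = _read_csv(path, _LARVAL_COLS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                LarvalRecord(
                    wetland_id=str(row.wetland_id),
                    capture_date=_parse_date(row.capture_date, i, "capture_date"),
                    pond_fill_date=_parse_date(row.pond_fill_date, i, "pond_fill_date"),
                    svl_mm=_parse_float(row.svl_mm, i, "svl_mm"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def read_metamorph_csv(path) -> list[MetamorphRecord]:
    df = _read_csv(path, _META_COLS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MetamorphRecord(
                    wetland_id=str(row.wetland_id),
                    cohort_year=int(_parse_float(row.cohort_year, i, "cohort_year")),
                    svl_mm=_parse_float(row.svl_mm, i, "svl_mm"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def read_adult_captures_csv(path) -> list[AdultCaptureHistory]:
    """Read long-format adult captures and group them into histories.

    Rows may arrive unsorted; within each individual, occasions are sorted by
    date and offsets are day counts from the first capture divided by 365.25.
    A duplicate (individual, date) pair is rejected.
    """
    df = _read_csv(path, _ADULT_COLS)
    parsed = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        parsed.append(
            (
                str(row.individual_id),
                _parse_date(row.capture_date, i, "capture_date"),
                _parse_float(row.svl_mm, i, "svl_mm"),
            )
        )
    histories = []
    by_id: dict[str, list[tuple[date, float]]] = {}
    order: list[str] = []
    for ind, d, svl in parsed:
        if ind not in by_id:
            order.append(ind)
            by_id[ind] = []
        by_id[ind].append((d, svl))
    for ind in order:
        rows = sorted(by_id[ind], key=lambda r: r[0])
        dates = [d for d, _ in rows]
        if len(set(dates)) != len(dates):
            raise ValidationError(f"individual {ind!r}: duplicate same-day capture")
        first = dates[0]
        occasions = tuple(
            CaptureOccasion(
                time_offset_years=(d - first).days / DAYS_PER_YEAR, svl_mm=svl
            )
            for d, svl in rows
        )
        histories.append(
            AdultCaptureHistory(
                individual_id=ind, first_capture_date=first, occasions=occasions
            )
        )
    return histories


def write_larval_csv(records: Iterable[LarvalRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "wetland_id": r.wetland_id,
                "capture_date": r.capture_date.isoformat(),
                "pond_fill_date": r.pond_fill_date.isoformat(),
                "svl_mm": repr(r.svl_mm),
            }
            for r in records
        ],
        columns=_LARVAL_COLS,
    ).to_csv(path, index=False)


def write_metamorph_csv(records: Iterable[MetamorphRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "wetland_id": r.wetland_id,
                "cohort_year": r.cohort_year,
                "svl_mm": repr(r.svl_mm),
            }
            for r in records
        ],
        columns=_META_COLS,
    ).to_csv(path, index=False)


def write_adult_captures_csv(histories: Iterable[AdultCaptureHistory], path) -> None:
    rows = []
    for h in histories:
        for occ in h.occasions:
            d = h.first_capture_date + pd.Timedelta(
                days=round(occ.time_offset_years * DAYS_PER_YEAR)
            )
            rows.append(
                {
                    "individual_id": h.individual_id,
                    "capture_date": d.date().isoformat()
                    if hasattr(d, "date")
                    else d.isoformat(),
                    "svl_mm": repr(occ.svl_mm),
                }
            )
    pd.DataFrame(rows, columns=_ADULT_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


def _stream_stats(values: list[float]) -> dict:
    if not values:
        return {"min": None, "max": None, "mean": None}
    arr = np.asarray(values, dtype=float)
    return {"min": float(arr.min()), "max": float(arr.max()), "mean": float(arr.mean())}


def validate_dataset(ds: Dataset) -> dict:
    """Report-only summary: per-stream counts, SVL summaries, violations."""
    violations: list[str] = []
    if not (ds.larvae or ds.metamorphs or ds.adults):
        violations.append("all streams empty")
    adult_svls = [o.svl_mm for h in ds.adults for o in h.occasions]
    return {
        "n_larvae": len(ds.larvae),
        "n_metamorphs": len(ds.metamorphs),
        "n_adults": len(ds.adults),
        "n_adults_recaptured": sum(1 for h in ds.adults if h.n_occasions >= 2),
        "svl": {
            "larvae": _stream_stats([r.svl_mm for r in ds.larvae]),
            "metamorphs": _stream_stats([r.svl_mm for r in ds.metamorphs]),
            "adults": _stream_stats(adult_svls),
        },
        "violations": violations,
    }
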
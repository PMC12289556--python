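"""Reading, validation, normalization and summarization of ICD-10 claims tables.

A *claim* is one billing record from a healthcare encounter: an opaque patient
identifier, a service date, one primary plus zero or more secondary ICD-10
diagnosis codes, and record-level demographics (age, sex).  Everything
downstream — patient-year aggregation, co-occurrence counting, association
networks — consumes the canonical :class:`ClaimsTable` defined here.

ICD-10 codes circulate in two dialects: dotted (``J45.909``) and undotted
(``J45909``).  :func:`normalize_icd10` reconciles them to the undotted
uppercase form, which is the canonical code string throughout the package.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
import re
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ICD10_PATTERN",
    "normalize_icd10",
    "ClaimRecord",
    "ClaimsTable",
    "ClaimsDialect",
    "LoadReport",
    "CohortSummary",
    "parse_claims",
    "write_claims",
    "summarize_cohort",
    "sex_percentages",
    "round_half_up",
]

#: Normalized ICD-10 shape: one letter, two digits, then 0-4 alphanumerics.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")

#: Oldest age retained verbatim; anything above is top-coded (de-identified
#: claims extracts cap reported age at 90).
AGE_CAP = 90

_SEXES = ("F", "M", "U")


def normalize_icd10(raw: str) -> str:
    """Normalize a free-text ICD-10 code to canonical undotted uppercase form.

    Strips surrounding whitespace, uppercases, and removes a single embedded
    dot (``"E78.5"`` → ``"E785"``).  Idempotent: normalizing an already
    normalized code returns it unchanged.

    Raises
    ------
    ValueError
        If ``raw`` is empty after trimming or the result does not match the
        ICD-10 shape (one letter, two digits, up to four more alphanumerics).
    """
    if raw is None:
        raise ValueError("ICD-10 code is missing")
    code = str(raw).strip().upper().replace(".", "", 1)
    if not code:
        raise ValueError("ICD-10 code is empty")
    if not ICD10_PATTERN.match(code):
        raise ValueError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclasses.dataclass(frozen=True)
class ClaimRecord:
    """One claim: patient, date, ordered diagnoses (first = primary), demographics."""

    patient_id: str
    service_date: dt.date
    diagnoses: tuple[str, ...]
    age: int | None = None
    sex: str = "U"

    def __post_init__(self) -> None:
        if not self.diagnoses:
            raise ValueError("claim must carry at least one diagnosis code")
        for code in self.diagnoses:
            if not ICD10_PATTERN.match(code):
                raise ValueError(f"unnormalized diagnosis code: {code!r}")
        if self.age is not None and not (0 <= self.age <= AGE_CAP):
            raise ValueError(f"age out of range [0, {AGE_CAP}]: {self.age}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}: {self.sex!r}")


class ClaimsTable:
    """Validated collection of claims backed by a pandas DataFrame.

    Columns: ``patient_id`` (str), ``service_date`` (datetime64),
    ``dx`` (tuple of normalized codes, first = primary), ``age``
    (nullable int), ``sex`` ({F, M, U}).  ``span`` is the (first, last)
    calendar year covered; every record's year falls within it.
    """

    COLUMNS = ("patient_id", "service_date", "dx", "age", "sex")

    def __init__(self, frame: pd.DataFrame, span: tuple[int, int] | None = None):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"claims frame lacks columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        frame["service_date"] = pd.to_datetime(frame["service_date"])
        years = frame["service_date"].dt.year
        if span is None:
            if len(frame) == 0:
                raise ValueError("cannot infer span from an empty claims table")
            span = (int(years.min()), int(years.max()))
        else:
            span = (int(span[0]), int(span[1]))
            if len(frame) and not years.between(span[0], span[1]).all():
                bad = int((~years.between(span[0], span[1])).sum())
                raise ValueError(f"{bad} record(s) fall outside span {span}")
        self.frame = frame
        self.span = span

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClaimsTable):
            return NotImplemented
        return self.span == other.span and self.frame.equals(other.frame)

    def records(self) -> Iterator[ClaimRecord]:
        """Iterate over rows as :class:`ClaimRecord` objects."""
        for row in self.frame.itertuples(index=False):
            age = None if pd.isna(row.age) else int(row.age)
            yield ClaimRecord(
                patient_id=str(row.patient_id),
                service_date=row.service_date.date(),
                diagnoses=tuple(row.dx),
                age=age,
                sex=str(row.sex),
            )

    @classmethod
    def from_records(
        cls, records: Iterable[ClaimRecord], span: tuple[int, int] | None = None
    ) -> "ClaimsTable":
        rows = [
            (r.patient_id, pd.Timestamp(r.service_date), tuple(r.diagnoses), r.age, r.sex)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        frame["age"] = frame["age"].astype("Int64")
        return cls(frame, span=span)


@dataclasses.dataclass(frozen=True)
class ClaimsDialect:
    """Column-name mapping for delimited claims files.

    ``diagnosis_columns`` lists the diagnosis columns in order; the first is
    the primary slot, the rest secondary.  ``date_format`` is ``"iso"``
    (YYYY-MM-DD, default) or ``"us"`` (MM/DD/YYYY) — an explicit switch so
    parsing stays deterministic.
    """

    patient_id: str = "patient_id"
    service_date: str = "service_date"
    diagnosis_columns: tuple[str, ...] = ("dx1", "dx2", "dx3", "dx4")
    age: str | None = "age"
    sex: str | None = "sex"
    sep: str = ","
    date_format: str = "iso"

    @property
    def strftime(self) -> str:
        if self.date_format == "iso":
            return "%Y-%m-%d"
        if self.date_format == "us":
            return "%m/%d/%Y"
        raise ValueError(f"unknown date format: {self.date_format!r}")


DEFAULT_DIALECT = ClaimsDialect()


@dataclasses.dataclass
class LoadReport:
    """Per-load accounting of accepted and rejected rows."""

    n_rows: int = 0
    n_loaded: int = 0
    dropped_bad_date: int = 0
    dropped_no_valid_code: int = 0
    dropped_bad_age: int = 0
    dropped_out_of_span: int = 0
    malformed_codes: int = 0

    @property
    def dropped(self) -> int:
        return (
            self.dropped_bad_date
            + self.dropped_no_valid_code
            + self.dropped_bad_age
            + self.dropped_out_of_span
        )

    def log_lines(self) -> list[str]:
        return [
            f"claims rows read: {self.n_rows}",
            f"claims rows loaded: {self.n_loaded}",
            f"rows dropped (unparseable date): {self.dropped_bad_date}",
            f"rows dropped (no valid diagnosis code): {self.dropped_no_valid_code}",
            f"rows dropped (invalid age): {self.dropped_bad_age}",
            f"rows dropped (outside study span): {self.dropped_out_of_span}",
            f"individual malformed codes skipped: {self.malformed_codes}",
        ]


def parse_claims(
    source: str | IO[str],
    dialect: ClaimsDialect = DEFAULT_DIALECT,
    span: tuple[int, int] | None = None,
) -> tuple[ClaimsTable, LoadReport]:
    """Read a delimited claims file into a validated :class:`ClaimsTable`.

    Rows with an unparseable service date, or whose diagnosis cells are all
    blank or malformed, are dropped and counted in the :class:`LoadReport`;
    blank secondary cells and individually malformed codes are skipped.  Ages
    above 90 are top-coded to 90; negative or non-numeric ages drop the row.
    Sex values other than F/M map to U (unspecified or other).

    Raises
    ------
    ValueError
        If the file is empty or a required column (patient id, service date,
        primary diagnosis) is missing from the header.
    """
    try:
        raw = pd.read_csv(source, sep=dialect.sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError("claims file is empty") from None
    required = [dialect.patient_id, dialect.service_date, dialect.diagnosis_columns[0]]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"claims file lacks required column(s): {missing}")
    dx_cols = [c for c in dialect.diagnosis_columns if c in raw.columns]

    report = LoadReport(n_rows=len(raw))
    rows: list[tuple] = []
    for row in raw.itertuples(index=False):
        row = row._asdict()
        date = pd.to_datetime(
            row[dialect.service_date].strip(), format=dialect.strftime, errors="coerce"
        )
        if pd.isna(date):
            report.dropped_bad_date += 1
            continue
        codes: list[str] = []
        for col in dx_cols:
            cell = row[col].strip()
            if not cell:
                continue
            try:
                codes.append(normalize_icd10(cell))
            except ValueError:
                report.malformed_codes += 1
        if not codes:
            report.dropped_no_valid_code += 1
            continue
        age: int | None = None
        if dialect.age is not None and dialect.age in row:
            cell = row[dialect.age].strip()
            if cell:
                try:
                    age = int(float(cell))
                except ValueError:
                    report.dropped_bad_age += 1
                    continue
                if age < 0:
                    report.dropped_bad_age += 1
                    continue
                age = min(age, AGE_CAP)
        sex = "U"
        if dialect.sex is not None and dialect.sex in row:
            cell = row[dialect.sex].strip().upper()
            sex = cell if cell in ("F", "M") else "U"
        if span is not None and not (span[0] <= date.year <= span[1]):
            report.dropped_out_of_span += 1
            continue
        rows.append((str(row[dialect.patient_id]).strip(), date, tuple(codes), age, sex))

    if not rows:
        raise ValueError("no valid claims rows after filtering")
    frame = pd.DataFrame(rows, columns=list(ClaimsTable.COLUMNS))
    frame["age"] = frame["age"].astype("Int64")
    table = ClaimsTable(frame, span=span)
    report.n_loaded = len(table)
    return table, report


def write_claims(
    table: ClaimsTable, target: str | IO[str], dialect: ClaimsDialect = DEFAULT_DIALECT
) -> None:
    """Write a claims table as delimited text in the given dialect.

    Emits as many diagnosis columns as the widest record needs (at least the
    dialect's count), so ``parse_claims(write_claims(t))`` round-trips.
    """
    width = max(
        len(dialect.diagnosis_columns),
        int(table.frame["dx"].map(len).max()) if len(table) else 1,
    )
    dx_cols = list(dialect.diagnosis_columns[:width])
    while len(dx_cols) < width:
        dx_cols.append(f"dx{len(dx_cols) + 1}")

    out = pd.DataFrame()
    out[dialect.patient_id] = table.frame["patient_id"]
    out[dialect.service_date] = table.frame["service_date"].dt.strftime(dialect.strftime)
    for i, col in enumerate(dx_cols):
        out[col] = table.frame["dx"].map(lambda dx: dx[i] if i < len(dx) else "")
    if dialect.age is not None:
        out[dialect.age] = table.frame["age"].map(
            lambda a: "" if pd.isna(a) else str(int(a))
        )
    if dialect.sex is not None:
        out[dialect.sex] = table.frame["sex"]
    out.to_csv(target, sep=dialect.sep, index=False)


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 0.05 → 0.1 at 1 digit."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def sex_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of records per sex category, rounded half-up to one decimal.

    Computed as 100·count/total before rounding, the convention used when
    reporting cohort demographics (e.g. 47,231,052 female of 82,270,481
    records → 57.4).
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total record count must be positive")
    out = {}
    for key, count in counts.items():
        pct = Decimal(count) * 100 / Decimal(total)
        out[key] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Record-level demographic summary of a claims table.

    Quartiles use the median-of-halves convention: the lower (upper) quartile
    is the median of the observations below (above) the overall median, the
    median itself being excluded when the count is odd.
    """

    n_records: int
    age_mean: float
    age_sd: float
    age_median: float
    age_q25: float
    age_q75: float
    counts_by_sex: dict[str, int]
    pct_by_sex: dict[str, float]


def _median_of_halves(sorted_ages: np.ndarray) -> tuple[float, float, float]:
    n = len(sorted_ages)
    med = float(np.median(sorted_ages))
    half = n // 2
    lower = sorted_ages[:half]
    upper = sorted_ages[n - half :]
    if half == 0:
        return med, med, med
    return float(np.median(lower)), med, float(np.median(upper))


def summarize_cohort(table: ClaimsTable) -> CohortSummary:
    """Summarize demographics at the record level (one unit per claim).

    Record-level, not patient-level: a patient with many claims contributes
    once per claim, matching how claims-volume demographics are reported.

    Raises
    ------
    ValueError
        If the table is empty or carries no age data.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty claims table")
    ages = table.frame["age"].dropna().astype(int).to_numpy()
    if ages.size == 0:
        raise ValueError("claims table carries no age data")
    ages = np.sort(ages)
    q25, med, q75 = _median_of_halves(ages)

    counts = {s: int((table.frame["sex"] == s).sum()) for s in _SEXES}
    return CohortSummary(
        n_records=len(table),
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if ages.size > 1 else 0.0,
        age_median=med,
        age_q25=q25,
        age_q75=q75,
        counts_by_sex=counts,
        pct_by_sex=sex_percentages(counts),
    )
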
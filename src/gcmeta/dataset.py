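"""Study-table data model, validation and TSV/CSV input/output.

A *study table* is an ordered collection of case-control studies, each
carrying genotype counts (CC / CT / TT) for its case and control arms at a
biallelic SNP.  The bundled seven-study table covers the GAK rs1564282
variant in Chinese Parkinson's-disease case-control cohorts and drives the
package's worked example.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = (
    "study_id",
    "population",
    "case_cc",
    "case_ct",
    "case_tt",
    "control_cc",
    "control_ct",
    "control_tt",
)

Dialect = Literal["tsv", "csv"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm (case or control) of one study.

    ``cc`` homozygous reference, ``ct`` heterozygous, ``tt`` homozygous
    effect allele.  All counts are non-negative integers and the arm must
    contain at least one individual.
    """

    cc: int
    ct: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("cc", "ct", "tt"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(f"genotype count {name}={value!r} is not an integer")
            if value < 0:
                raise ValidationError(f"genotype count {name}={value} is negative")
        if self.total < 1:
            raise ValidationError("arm has zero individuals")

    @property
    def total(self) -> int:
        return self.cc + self.ct + self.tt

    @property
    def effect_allele_count(self) -> int:
        """Number of effect (T) alleles carried by the arm."""
        return self.ct + 2 * self.tt

    @property
    def reference_allele_count(self) -> int:
        """Number of reference (C) alleles carried by the arm."""
        return 2 * self.cc + self.ct


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: identifier, population label, two arms."""

    study_id: str
    population: str
    case: GenotypeCounts
    control: GenotypeCounts

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be a non-empty string")


@dataclass(frozen=True)
class StudyTable:
    """Ordered, id-unique collection of studies."""

    studies: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise ValidationError("no studies")
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise ValidationError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    @property
    def k(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    def __len__(self) -> int:
        return self.k

    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    def drop(self, study_id: str) -> "StudyTable":
        """Return a new table without the named study."""
        if study_id not in self.study_ids():
            raise ValidationError(f"unknown study_id {study_id!r}")
        return StudyTable(tuple(s for s in self.studies if s.study_id != study_id))

    @property
    def n_cases(self) -> int:
        return sum(s.case.total for s in self.studies)

    @property
    def n_controls(self) -> int:
        return sum(s.control.total for s in self.studies)


def _parse_count(raw: str, study_id: str, column: str) -> int:
    """Parse an integer cell, tolerating thousands separators and whitespace."""
    text = raw.strip().replace(",", "").replace(" ", "")
    if not text:
        raise ValidationError(f"study {study_id!r}: empty cell in column {column!r}")
    try:
        value = int(text)
    except ValueError as exc:
        raise ValidationError(
            f"study {study_id!r}: non-integer count {raw!r} in column {column!r}"
        ) from exc
    if value < 0:
        raise ValidationError(
            f"study {study_id!r}: negative count {value} in column {column!r}"
        )
    return value


def _delimiter(dialect: Dialect) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def _infer_dialect(path: Path) -> Dialect:
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_study_table(path: str | Path, dialect: Dialect | None = None) -> StudyTable:
    """Read a study table from a TSV or CSV file.

    Column order is free; the header must name all eight required columns.
    When ``dialect`` is omitted it is inferred from the file extension
    (``.csv`` means comma-separated, anything else tab-separated).
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(dialect))
        header = reader.fieldnames or []
        for column in REQUIRED_COLUMNS:
            if column not in header:
                raise FormatError(f"missing required column {column!r}")
        rows = list(reader)
    if not rows:
        raise FormatError("no studies: file contains a header but no data rows")
    return table_from_rows(rows)


def table_from_rows(rows: Iterable[dict[str, str]]) -> StudyTable:
    """Build a validated StudyTable from parsed header->cell mappings."""
    studies = []
    for row in rows:
        study_id = (row.get("study_id") or "").strip()
        if not study_id:
            raise ValidationError("row with empty study_id")
        arms = {}
        for arm in ("case", "control"):
            counts = {
                g: _parse_count(row[f"{arm}_{g}"] or "", study_id, f"{arm}_{g}")
                for g in ("cc", "ct", "tt")
            }
            arms[arm] = GenotypeCounts(**counts)
        studies.append(
            StudyRecord(
                study_id=study_id,
                population=(row.get("population") or "").strip(),
                case=arms["case"],
                control=arms["control"],
            )
        )
    return StudyTable(tuple(studies))


def write_study_table(table: StudyTable, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write a study table; ``read_study_table`` round-trips it exactly."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(dialect))
        writer.writerow(REQUIRED_COLUMNS)
        for s in table:
            writer.writerow(
                [
                    s.study_id,
                    s.population,
                    s.case.cc,
                    s.case.ct,
                    s.case.tt,
                    s.control.cc,
                    s.control.ct,
                    s.control.tt,
                ]
            )


def bundled_table1() -> StudyTable:
    """The seven GAK rs1564282 Chinese case-control studies (4,055 cases,
    3,826 controls) that the package's worked example pools."""
    resource = importlib.resources.files("gcmeta.data") / "table1_rs1564282.tsv"
    with importlib.resources.as_file(resource) as path:
        return read_study_table(path, dialect="tsv")
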
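"""Report tables and the PT→SOC dictionary.

This module is the single source of counting conventions for the whole
package:

* **reports** are the unit of demographic tables and of all 2×2
  contingency cells (a report contributes once per PT, however often the
  PT was coded);
* **event occurrences** — (report, PT) pairs for the drug of interest as
  primary suspect — are the unit of SOC and top-PT tables and of their
  percentage denominators.

Reports live in a delimited text table with header
``report_id,drug,role,sex,age_group,region,year,pts`` where ``pts`` is a
``;``-separated list inside the cell.  The PT dictionary is a two-column
``pt,soc`` table standing in for a MedDRA-style PT → primary-SOC mapping.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "AdeReport",
    "ReportSet",
    "PtDictionary",
    "ReportFormatError",
    "ReportValidationError",
    "DictionaryConflictError",
    "normalize_term",
    "read_reports",
    "write_reports",
    "read_pt_dictionary",
    "write_pt_dictionary",
    "event_occurrences",
    "REPORT_COLUMNS",
    "SEXES",
    "AGE_GROUPS",
    "REGIONS",
    "ROLES",
]

REPORT_COLUMNS = ("report_id", "drug", "role", "sex", "age_group", "region", "year", "pts")

ROLES = ("primary_suspect", "other")
SEXES = ("female", "male", "unknown")
AGE_GROUPS = ("lt18", "a18_44", "a45_64", "a65_74", "ge75", "unknown")
REGIONS = ("africa", "americas", "asia", "europe", "unknown")

# Ingestion alias tables: raw cell value (case-folded) -> canonical level.
_SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "": "unknown", "na": "unknown", "n/a": "unknown", "unknown": "unknown", "u": "unknown",
}
_AGE_ALIASES = {
    "lt18": "lt18", "<18": "lt18", "0-17": "lt18",
    "a18_44": "a18_44", "18-44": "a18_44",
    "a45_64": "a45_64", "45-64": "a45_64",
    "a65_74": "a65_74", "65-74": "a65_74",
    "ge75": "ge75", ">=75": "ge75", "75+": "ge75", "≥75": "ge75",
    "": "unknown", "na": "unknown", "unknown": "unknown",
}
_REGION_ALIASES = {
    "africa": "africa",
    "americas": "americas", "america": "americas",
    "asia": "asia",
    "europe": "europe",
    "": "unknown", "na": "unknown", "unknown": "unknown",
}
_ROLE_ALIASES = {
    "primary_suspect": "primary_suspect", "ps": "primary_suspect",
    "primary suspect": "primary_suspect",
    "other": "other", "concomitant": "other",
}

_WS_RUN = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Canonical matching key for a PT or SOC string.

    Trims, collapses internal whitespace runs and case-folds.  Display
    forms keep the dictionary's casing; this key is used only for lookup
    and comparison (reporting systems print case variants of the same PT).
    """
    return _WS_RUN.sub(" ", term.strip()).casefold()


class ReportFormatError(ValueError):
    """Structural problem with a report or dictionary file (bad header, bad delimiter)."""


class ReportValidationError(ValueError):
    """Row-level content violates the report invariants."""


class DictionaryConflictError(ValueError):
    """A PT is mapped to more than one SOC."""


@dataclass(frozen=True)
class AdeReport:
    """One spontaneous adverse-event report.

    ``pts`` is a frozen *set* of preferred terms: a PT repeated within one
    report counts once everywhere downstream.  ``year`` is a calendar year
    or ``None`` for unknown; every categorical field carries ``unknown``
    as a first-class level, never a missing cell.
    """

    report_id: str
    drug: str
    role: str = "primary_suspect"
    sex: str = "unknown"
    age_group: str = "unknown"
    region: str = "unknown"
    year: int | None = None
    pts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ReportValidationError("report_id must be non-empty")
        if self.role not in ROLES:
            raise ReportValidationError(f"role {self.role!r} not in {ROLES}")
        if self.sex not in SEXES:
            raise ReportValidationError(f"sex {self.sex!r} not in {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ReportValidationError(f"age_group {self.age_group!r} not in {AGE_GROUPS}")
        if self.region not in REGIONS:
            raise ReportValidationError(f"region {self.region!r} not in {REGIONS}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ReportValidationError(f"implausible year {self.year}")
        if not self.pts:
            raise ReportValidationError("pts must be a non-empty set")
        object.__setattr__(self, "pts", frozenset(self.pts))


@dataclass
class ReportSet:
    """A labelled extract of one reporting system (one database source)."""

    source_label: str
    reports: list[AdeReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: list[str] = []
        for r in self.reports:
            if r.report_id in seen:
                dupes.append(r.report_id)
            seen.add(r.report_id)
        if dupes:
            raise ReportValidationError(
                f"duplicate report_id(s) in {self.source_label!r}: {sorted(set(dupes))}"
            )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdeReport]:
        return iter(self.reports)

    def drug_reports(self, drug: str, role: str = "primary_suspect") -> list[AdeReport]:
        """Reports naming ``drug`` (case-insensitive) in the given role."""
        key = normalize_term(drug)
        return [r for r in self.reports if normalize_term(r.drug) == key and r.role == role]


@dataclass
class PtDictionary:
    """PT → primary SOC mapping (one SOC per PT).

    Lookup is whitespace/case-insensitive; display forms retain the
    casing of the dictionary entry.
    """

    entries: dict[str, str]
    version_label: str = "mock"
    _index: dict[str, tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, tuple[str, str]] = {}
        for pt, soc in self.entries.items():
            key = normalize_term(pt)
            if key in index and normalize_term(index[key][1]) != normalize_term(soc):
                raise DictionaryConflictError(
                    f"PT {pt!r} mapped to both {index[key][1]!r} and {soc!r}"
                )
            index[key] = (pt, soc)
        self._index = index

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._index

    def soc(self, pt: str, default: str | None = None) -> str | None:
        """Primary SOC for ``pt``, or ``default`` when unmapped."""
        hit = self._index.get(normalize_term(pt))
        return hit[1] if hit is not None else default

    def display_pt(self, pt: str) -> str:
        """Dictionary-cased display form of ``pt`` (input form if unmapped)."""
        hit = self._index.get(normalize_term(pt))
        return hit[0] if hit is not None else pt


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_delimiter(sample: str, forced: str | None) -> str:
    if forced:
        return forced
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") > first.count(",") else ","


def _alias(value: str, table: Mapping[str, str], column: str, row_no: int) -> str:
    key = normalize_term(value)
    if key not in table:
        raise ReportValidationError(f"row {row_no}: unrecognized {column} value {value!r}")
    return table[key]


def _parse_year(value: str, row_no: int) -> int | None:
    v = value.strip()
    if normalize_term(v) in ("", "na", "n/a", "unknown"):
        return None
    try:
        return int(v)
    except ValueError:
        raise ReportValidationError(f"row {row_no}: year {value!r} is not an integer") from None


def read_reports(
    path: str | Path,
    delimiter: str | None = None,
    source_label: str | None = None,
    strict: bool = False,
) -> ReportSet:
    """Read a report table, validating every row.

    Rows that violate the report invariants are rejected with
    row-numbered diagnostics (logged; raised when ``strict``).  Duplicate
    ``report_id`` values are always an error.  The delimiter is sniffed
    from the header unless forced.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text, delimiter)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    header = tuple(reader.fieldnames or ())
    missing = [c for c in REPORT_COLUMNS if c not in header]
    if missing:
        raise ReportFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    reports: list[AdeReport] = []
    seen_ids: set[str] = set()
    dupes: list[str] = []
    rejected: list[str] = []
    for row_no, row in enumerate(reader, start=2):  # header is line 1
        try:
            rid = (row["report_id"] or "").strip()
            if rid in seen_ids:
                dupes.append(rid)
                continue
            pts = frozenset(
                p.strip() for p in (row["pts"] or "").split(";") if p.strip()
            )
            rec = AdeReport(
                report_id=rid,
                drug=(row["drug"] or "").strip(),
                role=_alias(row["role"] or "primary_suspect", _ROLE_ALIASES, "role", row_no),
                sex=_alias(row["sex"] or "", _SEX_ALIASES, "sex", row_no),
                age_group=_alias(row["age_group"] or "", _AGE_ALIASES, "age_group", row_no),
                region=_alias(row["region"] or "", _REGION_ALIASES, "region", row_no),
                year=_parse_year(row["year"] or "", row_no),
                pts=pts,
            )
        except ReportValidationError as exc:
            msg = f"row {row_no}: {exc}" if not str(exc).startswith("row ") else str(exc)
            rejected.append(msg)
            if strict:
                raise ReportValidationError(f"{path}: {msg}") from None
            continue
        seen_ids.add(rid)
        reports.append(rec)

    if dupes:
        raise ReportValidationError(
            f"{path}: duplicate report_id(s): {sorted(set(dupes))}"
        )
    for msg in rejected:
        logger.warning("%s: rejected %s", path, msg)
    logger.info("%s: accepted %d rows, rejected %d", path, len(reports), len(rejected))
    result = ReportSet(source_label=source_label or path.stem, reports=reports)
    result.n_rejected = len(rejected)  # type: ignore[attr-defined]
    result.rejected_rows = rejected  # type: ignore[attr-defined]
    return result


def write_reports(reports: ReportSet, path: str | Path, delimiter: str = ",") -> None:
    """Write a report table in the canonical dialect (sorted PT cells)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.report_id,
                    r.drug,
                    r.role,
                    r.sex,
                    r.age_group,
                    r.region,
                    "unknown" if r.year is None else str(r.year),
                    ";".join(sorted(r.pts)),
                ]
            )


def read_pt_dictionary(path: str | Path, version_label: str | None = None) -> PtDictionary:
    """Read a two-column ``pt,soc`` dictionary.

    Duplicate identical rows collapse silently; the same PT under two
    different SOCs is a conflict error naming the PT.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    by_key: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        fields = [f.strip().lower() for f in (reader.fieldnames or [])]
        if fields[:2] != ["pt", "soc"]:
            raise ReportFormatError(f"{path}: expected header 'pt,soc', got {reader.fieldnames}")
        for row in reader:
            pt = (row["pt"] or "").strip()
            soc = (row["soc"] or "").strip()
            if not pt or not soc:
                raise ReportFormatError(f"{path}: empty pt or soc cell")
            key = normalize_term(pt)
            if key in by_key and normalize_term(by_key[key]) != normalize_term(soc):
                raise DictionaryConflictError(
                    f"{path}: PT {pt!r} mapped to both {by_key[key]!r} and {soc!r}"
                )
            if key not in by_key:
                entries[pt] = soc
                by_key[key] = soc
    return PtDictionary(entries=entries, version_label=version_label or path.stem)


def write_pt_dictionary(dictionary: PtDictionary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["pt", "soc"])
        for pt, soc in sorted(dictionary.entries.items(), key=lambda kv: normalize_term(kv[0])):
            writer.writerow([pt, soc])


def event_occurrences(
    report_set: ReportSet, drug: str, role: str = "primary_suspect"
) -> list[tuple[str, str]]:
    """All (report_id, PT) pairs for ``drug`` in the given role.

    The length of this list is the package's definition of the "number of
    reported cases of ADE" (event count) used as the denominator of SOC
    and top-PT percentage tables.
    """
    out: list[tuple[str, str]] = []
    for r in report_set.drug_reports(drug, role):
        out.extend((r.report_id, pt) for pt in sorted(r.pts))
    return out
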
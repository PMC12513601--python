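"""Replay of published aggregate tables.

A public pharmacovigilance analysis prints only aggregates: the
demographic breakdown, the system-organ-class distribution and the
top-30 preferred terms of each database extract.  This module loads
those published count tables (shipped as CSV fixtures for one worked
study: a potassium-binder extract from FAERS and from VigiAccess) and
rebuilds the descriptive layer from counts alone, so published
percentages can be reproduced and cross-checked without report-level
data.

For pipeline stages that genuinely need report-level input, a
*synthetic* replay report set is provided: the published top-30 PT
counts are kept exactly and the remaining event mass (the published
totals run over 546 resp. 594 distinct PTs) is filled with a
deterministic tail of synthetic background terms whose per-PT counts
stay strictly below the published rank-30 count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .descriptives import (
    CategoryBreakdown,
    SocDistribution,
    TopPtTable,
    breakdown_from_counts,
    soc_distribution_from_counts,
    top_pt_table_from_counts,
)
from .reports import AdeReport, PtDictionary, ReportSet, read_pt_dictionary

__all__ = [
    "PublishedSource",
    "SOURCES",
    "load_source",
    "mock_dictionary",
    "published_top_pt_table",
    "published_soc_distribution",
    "published_demographics",
    "replay_report_set",
]


@dataclass(frozen=True)
class PublishedSource:
    """Published aggregate facts of one database extract."""

    name: str
    drug: str
    n_reports: int
    total_events: int
    n_distinct_pts: int
    top_pt_file: str
    soc_file: str
    demographics_file: str


# The two worked extracts: sodium zirconium cyclosilicate (a potassium
# binder) as primary-suspect drug in FAERS (2004Q1–2024Q3) and in
# VigiAccess (to 2025-02-05), as published.
SOURCES: dict[str, PublishedSource] = {
    "faers": PublishedSource(
        name="FAERS",
        drug="Sodium zirconium cyclosilicate",
        n_reports=1384,
        total_events=2246,
        n_distinct_pts=546,
        top_pt_file="faers_top30_pts.csv",
        soc_file="faers_soc_counts.csv",
        demographics_file="faers_demographics.csv",
    ),
    "vigiaccess": PublishedSource(
        name="VigiAccess",
        drug="Sodium zirconium cyclosilicate",
        n_reports=1518,
        total_events=2555,
        n_distinct_pts=594,
        top_pt_file="vigiaccess_top30_pts.csv",
        soc_file="vigiaccess_soc_counts.csv",
        demographics_file="vigiaccess_demographics.csv",
    ),
}


def _data_path(filename: str):
    return resources.files("pvsignal.data").joinpath(filename)


def _read_rows(filename: str) -> list[dict[str, str]]:
    with _data_path(filename).open(encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def load_source(source: str) -> PublishedSource:
    try:
        return SOURCES[source.lower()]
    except KeyError:
        raise KeyError(f"unknown source {source!r}; expected one of {sorted(SOURCES)}") from None


def mock_dictionary() -> PtDictionary:
    """The bundled mock PT → SOC dictionary (synthetic stand-in for a
    licensed MedDRA-style terminology)."""
    with resources.as_file(_data_path("pt_soc_dictionary.csv")) as path:
        return read_pt_dictionary(path, version_label="pvsignal-mock-1.0")


def published_top_pt_table(source: str) -> TopPtTable:
    """The published top-30 PT table with percentages over the full
    published event total."""
    src = load_source(source)
    counts = [(row["pt"], int(row["count"])) for row in _read_rows(src.top_pt_file)]
    return top_pt_table_from_counts(counts, total_events=src.total_events)


def published_soc_distribution(source: str) -> SocDistribution:
    src = load_source(source)
    rows = [
        (row["soc"], int(row["n_pts"]), int(row["count"]))
        for row in _read_rows(src.soc_file)
    ]
    return soc_distribution_from_counts(rows, total_events=src.total_events)


def published_demographics(source: str) -> dict[str, CategoryBreakdown]:
    """Published demographic breakdowns, percentages over published
    report totals (which the published year rows do not always
    reconcile with — they are replayed as printed)."""
    src = load_source(source)
    by_cat: dict[str, list[tuple[str, int]]] = {}
    for row in _read_rows(src.demographics_file):
        by_cat.setdefault(row["category"], []).append((row["level"], int(row["count"])))
    return {
        cat: breakdown_from_counts(cat, levels, total=src.n_reports)
        for cat, levels in by_cat.items()
    }


def _synthetic_tail(source: PublishedSource, top_counts: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Deterministic synthetic per-PT counts for the event mass outside
    the published top 30, respecting the published distinct-PT and
    event totals."""
    n_tail_pts = source.n_distinct_pts - len(top_counts)
    tail_events = source.total_events - sum(c for _, c in top_counts)
    min_top_count = min(c for _, c in top_counts)
    # spread as evenly as possible: counts of floor/ceil of the mean
    base = tail_events // n_tail_pts
    extra = tail_events - base * n_tail_pts  # this many PTs get base+1
    if base + 1 >= min_top_count:
        raise ValueError("synthetic tail would intrude into the published top-30")
    counts = []
    for i in range(n_tail_pts):
        c = base + 1 if i < extra else base
        if c > 0:
            counts.append((f"Synthetic background term {i + 1:03d}", c))
    return counts


def replay_report_set(source: str) -> ReportSet:
    """Report-level stand-in reproducing the published per-PT event counts.

    One single-PT report per event occurrence, so event counting and PT
    ranking replay the published table exactly; demographics of these
    synthetic reports are all unknown and report counts do *not* match
    the published report total (use :func:`published_demographics` for
    the demographic layer).
    """
    src = load_source(source)
    top = [(row["pt"], int(row["count"])) for row in _read_rows(src.top_pt_file)]
    all_counts = top + _synthetic_tail(src, top)
    reports = []
    rid = 0
    for pt, count in all_counts:
        for _ in range(count):
            rid += 1
            reports.append(
                AdeReport(
                    report_id=f"{src.name}-replay-{rid:05d}",
                    drug=src.drug,
                    role="primary_suspect",
                    pts=frozenset({pt}),
                )
            )
    return ReportSet(source_label=f"{src.name}-replay", reports=reports)
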
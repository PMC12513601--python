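"""Descriptive layer: demographic breakdowns, SOC distributions, top-PT
rankings and cross-source overlap.

Counting conventions (fixed package-wide, see :mod:`pvsignal.reports`):
demographic tables count *reports*; SOC and PT tables count *event
occurrences* (report, PT pairs) and take percentages of the event total.
Display percentages round half-up to two decimals, as spontaneous
reporting summaries conventionally print them; full precision is kept
internally.

Every table also has a ``*_from_counts`` replay constructor so that a
published, pre-aggregated count table can be reproduced without
report-level data.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .reports import (
    AGE_GROUPS,
    REGIONS,
    SEXES,
    PtDictionary,
    ReportSet,
    event_occurrences,
    normalize_term,
)

__all__ = [
    "CategoryBreakdown",
    "SocDistribution",
    "TopPtTable",
    "OverlapResult",
    "demographic_table",
    "soc_table",
    "top_pts",
    "overlap",
    "breakdown_from_counts",
    "soc_distribution_from_counts",
    "top_pt_table_from_counts",
    "round_half_up",
    "UNMAPPED_SOC",
    "CATEGORIES",
]

UNMAPPED_SOC = "UNMAPPED"

CATEGORIES = ("sex", "age_group", "region", "year")

_LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "region": REGIONS,
}

DISPLAY_LABELS: dict[str, dict[str, str]] = {
    "sex": {"female": "Female", "male": "Male", "unknown": "Unknown"},
    "age_group": {
        "lt18": "<18",
        "a18_44": "18-44",
        "a45_64": "45-64",
        "a65_74": "65-74",
        "ge75": ">=75",
        "unknown": "Unknown",
    },
    "region": {
        "africa": "Africa",
        "americas": "Americas",
        "asia": "Asia",
        "europe": "Europe",
        "unknown": "Unknown",
    },
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero in decimal, the convention of printed
    pharmacovigilance tables (banker's rounding would print 0.125 → 0.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryBreakdown:
    """Counts and percentages of one demographic category over reports."""

    category: str
    rows: tuple[tuple[str, int, float], ...]  # (level, count, exact percent)
    total: int

    def to_frame(self) -> pd.DataFrame:
        labels = DISPLAY_LABELS.get(self.category, {})
        return pd.DataFrame(
            [
                (labels.get(level, level), n, round_half_up(pct))
                for level, n, pct in self.rows
            ],
            columns=["level", "count", "percent"],
        )

    def percent_of(self, level: str) -> float:
        for lv, _, pct in self.rows:
            if lv == level:
                return round_half_up(pct)
        raise KeyError(level)


@dataclass(frozen=True)
class SocDistribution:
    """Event counts per system organ class, sorted by count descending."""

    rows: tuple[tuple[str, int, int, float], ...]  # (soc, n_distinct_pts, events, percent)
    total_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(soc, k, n, round_half_up(pct)) for soc, k, n, pct in self.rows],
            columns=["soc", "n_distinct_pts", "event_count", "percent"],
        )

    def percent_of(self, soc: str) -> float:
        key = normalize_term(soc)
        for name, _, _, pct in self.rows:
            if normalize_term(name) == key:
                return round_half_up(pct)
        raise KeyError(soc)


@dataclass(frozen=True)
class TopPtTable:
    """Top-N preferred terms by event count."""

    rows: tuple[tuple[int, str, int, float], ...]  # (rank, pt, events, percent)
    total_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, pt, n, round_half_up(pct)) for r, pt, n, pct in self.rows],
            columns=["rank", "pt", "event_count", "percent"],
        )

    def pts(self) -> list[str]:
        return [pt for _, pt, _, _ in self.rows]

    def percent_of(self, pt: str) -> float:
        key = normalize_term(pt)
        for _, name, _, pct in self.rows:
            if normalize_term(name) == key:
                return round_half_up(pct)
        raise KeyError(pt)


@dataclass(frozen=True)
class OverlapResult:
    """Set partition of two top-PT lists after case-normalization."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


# ---------------------------------------------------------------------------
# report-level operations


def demographic_table(report_set: ReportSet) -> list[CategoryBreakdown]:
    """One breakdown per demographic category, reports as the unit.

    Levels appear in the conventional order with unknown last; unknown
    rows stay in the denominator (percentages within a category sum
    to 100).
    """
    total = len(report_set)
    out: list[CategoryBreakdown] = []
    for category in CATEGORIES:
        counts: Counter[str] = Counter()
        for r in report_set:
            if category == "year":
                counts["unknown" if r.year is None else str(r.year)] += 1
            else:
                counts[getattr(r, category)] += 1
        if category == "year":
            levels = sorted((lv for lv in counts if lv != "unknown"), key=int)
            if "unknown" in counts:
                levels.append("unknown")
        else:
            levels = [lv for lv in _LEVEL_ORDER[category]]
        rows = tuple(
            (lv, counts.get(lv, 0), 100.0 * counts.get(lv, 0) / total if total else 0.0)
            for lv in levels
        )
        out.append(CategoryBreakdown(category=category, rows=rows, total=total))
    return out


def soc_table(report_set: ReportSet, dictionary: PtDictionary, drug: str) -> SocDistribution:
    """SOC distribution of event occurrences for ``drug`` (primary suspect).

    PTs that the dictionary cannot resolve are collected under the
    flagged ``UNMAPPED`` organ class rather than dropped, so event totals
    are conserved.
    """
    occurrences = event_occurrences(report_set, drug)
    events_by_soc: Counter[str] = Counter()
    pts_by_soc: defaultdict[str, set[str]] = defaultdict(set)
    for _, pt in occurrences:
        soc = dictionary.soc(pt, UNMAPPED_SOC)
        events_by_soc[soc] += 1
        pts_by_soc[soc].add(normalize_term(pt))
    total = len(occurrences)
    ordered = sorted(events_by_soc.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = tuple(
        (soc, len(pts_by_soc[soc]), n, 100.0 * n / total if total else 0.0)
        for soc, n in ordered
    )
    return SocDistribution(rows=rows, total_events=total)


def top_pts(report_set: ReportSet, drug: str, n: int = 30) -> TopPtTable:
    """Top ``n`` PTs by event count; ties break alphabetically.

    Percentages are taken against the *total* event count of the drug,
    not the sum within the table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    occurrences = event_occurrences(report_set, drug)
    display: dict[str, str] = {}
    counts: Counter[str] = Counter()
    for _, pt in occurrences:
        key = normalize_term(pt)
        counts[key] += 1
        prev = display.get(key)
        display[key] = pt if prev is None or pt < prev else prev
    total = len(occurrences)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], display[kv[0]]))[:n]
    rows = tuple(
        (rank, display[key], cnt, 100.0 * cnt / total if total else 0.0)
        for rank, (key, cnt) in enumerate(ordered, start=1)
    )
    return TopPtTable(rows=rows, total_events=total)


def overlap(table_a: TopPtTable, table_b: TopPtTable) -> OverlapResult:
    """Partition the union of two top-PT lists into shared / A-only /
    B-only after case-normalization (the Venn-diagram sets)."""
    a = {normalize_term(pt) for pt in table_a.pts()}
    b = {normalize_term(pt) for pt in table_b.pts()}
    return OverlapResult(
        shared=frozenset(a & b), only_a=frozenset(a - b), only_b=frozenset(b - a)
    )


# ---------------------------------------------------------------------------
# replay constructors: rebuild tables from published aggregate counts


def breakdown_from_counts(
    category: str, counts: Sequence[tuple[str, int]], total: int | None = None
) -> CategoryBreakdown:
    """Rebuild a demographic breakdown from (level, count) pairs."""
    tot = total if total is not None else sum(c for _, c in counts)
    rows = tuple((lv, c, 100.0 * c / tot if tot else 0.0) for lv, c in counts)
    return CategoryBreakdown(category=category, rows=rows, total=tot)


def soc_distribution_from_counts(
    counts: Sequence[tuple[str, int, int]], total_events: int | None = None
) -> SocDistribution:
    """Rebuild a SOC distribution from (soc, n_distinct_pts, events) rows."""
    tot = total_events if total_events is not None else sum(n for _, _, n in counts)
    ordered = sorted(counts, key=lambda row: (-row[2], row[0]))
    rows = tuple(
        (soc, k, n, 100.0 * n / tot if tot else 0.0) for soc, k, n in ordered
    )
    return SocDistribution(rows=rows, total_events=tot)


def top_pt_table_from_counts(
    counts: Sequence[tuple[str, int]], total_events: int, n: int | None = None
) -> TopPtTable:
    """Rebuild a top-PT table from (pt, count) pairs.

    ``total_events`` must be the full event count of the source (the
    published denominator), which generally exceeds the sum within the
    top-N table.
    """
    ordered = sorted(counts, key=lambda kv: (-kv[1], kv[0]))
    if n is not None:
        ordered = ordered[:n]
    rows = tuple(
        (rank, pt, cnt, 100.0 * cnt / total_events if total_events else 0.0)
        for rank, (pt, cnt) in enumerate(ordered, start=1)
    )
    return TopPtTable(rows=rows, total_events=total_events)
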
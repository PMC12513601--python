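"""Stratified (subgroup) disproportionality screening.

The report universe is partitioned by a demographic level *before*
contingency construction, so both the drug-of-interest arm and the
comparator arm of each stratum contain only same-stratum reports.  The
cells of the stratum tables therefore sum exactly to the pooled table's
cells (partition conservation), and a "stratum-specific signal" is a PT
that is a combined positive in exactly one stratum — a labelling rule,
not an interaction test.

Unknown values form their own stratum: an unknown-sex report belongs to
neither the male nor the female screen, but is never dropped from the
pooled analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .descriptives import CATEGORIES
from .reports import PtDictionary, ReportSet, normalize_term
from .screening import ScreeningCriteria, ScreeningResults, SignalStats, screen

__all__ = ["StratifiedScreenResult", "screen_by"]


@dataclass
class StratifiedScreenResult:
    """Per-stratum screens plus a cross-stratum positivity comparison."""

    stratifier: str
    strata: Mapping[str, ScreeningResults]
    drug: str

    def levels(self) -> list[str]:
        return list(self.strata.keys())

    def comparison(self) -> pd.DataFrame:
        """Presence matrix: one row per PT screened anywhere, one boolean
        column per stratum (combined positivity), plus ``n_positive``."""
        pts: dict[str, str] = {}
        for res in self.strata.values():
            for s in res.stats:
                pts.setdefault(normalize_term(s.pt), s.pt)
        rows = []
        for key in sorted(pts):
            row: dict[str, object] = {"pt": pts[key]}
            n_pos = 0
            for level, res in self.strata.items():
                try:
                    pos = res[pts[key]].combined_positive
                except KeyError:
                    pos = False
                row[level] = pos
                n_pos += int(pos)
            row["n_positive"] = n_pos
            rows.append(row)
        return pd.DataFrame(rows, columns=["pt", *self.strata.keys(), "n_positive"])

    def specific_signals(self, level: str) -> list[SignalStats]:
        """Signals combined-positive in ``level`` and in no other stratum."""
        out = []
        for s in self.strata[level].positive():
            alone = all(
                not _is_positive(other_res, s.pt)
                for other_level, other_res in self.strata.items()
                if other_level != level
            )
            if alone:
                out.append(s)
        return out

    def summary(self) -> str:
        lines = [f"Stratified screen by {self.stratifier} — drug {self.drug}"]
        for level, res in self.strata.items():
            lines.append(
                f"  {level}: {res.n_reports} reports "
                f"({res.n_drug_reports} drug-of-interest), "
                f"{len(res.positive())} positive signals"
            )
        return "\n".join(lines)


def _is_positive(res: ScreeningResults, pt: str) -> bool:
    try:
        return res[pt].combined_positive
    except KeyError:
        return False


def _level_of(report, stratifier: str) -> str:
    if stratifier == "year":
        return "unknown" if report.year is None else str(report.year)
    return getattr(report, stratifier)


def screen_by(
    report_set: ReportSet,
    dictionary: PtDictionary,
    drug: str,
    criteria: ScreeningCriteria | None = None,
    stratifier: str = "sex",
) -> StratifiedScreenResult:
    """Screen within each level of a demographic category.

    The partition happens before contingency construction: stratum
    comparator counts (b, d) only include same-stratum reports.
    """
    if stratifier not in CATEGORIES:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {CATEGORIES}")
    criteria = criteria or ScreeningCriteria()

    buckets: dict[str, list] = {}
    for r in report_set:
        buckets.setdefault(_level_of(r, stratifier), []).append(r)

    def _order(level: str):
        return (level == "unknown", level)

    strata: dict[str, ScreeningResults] = {}
    for level in sorted(buckets, key=_order):
        subset = ReportSet(
            source_label=f"{report_set.source_label}[{stratifier}={level}]",
            reports=buckets[level],
        )
        stats = screen(subset, dictionary, drug, criteria)
        strata[level] = ScreeningResults(
            stats=stats,
            criteria=criteria,
            drug=drug,
            source_label=subset.source_label,
            n_reports=len(subset),
            n_drug_reports=len(subset.drug_reports(drug)),
        )
    return StratifiedScreenResult(stratifier=stratifier, strata=strata, drug=drug)
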
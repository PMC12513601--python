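"""Disproportionality screening: 2×2 contingency tables, ROR/PRR
statistics and signal positivity.

For one (drug, event) pair over a universe of reports the 2×2 table is

=====================  ================  ===============
..                     drug of interest  all other drugs
event of interest          a                  b
all other events           c                  d
=====================  ================  ===============

with report-level counting: each report falls in exactly one cell, and a
report contains an event once however often it was coded.  The screening
statistics are the classical ones of spontaneous-report signal
detection:

* reporting odds ratio  ``ROR = ad/bc`` with Wald 95% CI
  ``exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d))``;
* proportional reporting ratio  ``PRR = a(c+d) / (c(a+b))``;
* uncorrected Pearson chi-square
  ``χ² = (ad − bc)²(a+b+c+d) / ((a+b)(c+d)(a+c)(b+d))``  (no Yates
  continuity correction).

A PT is an ROR-positive signal when a ≥ 3 and the CI lower bound
exceeds 1; PRR-positive when a ≥ 3, PRR ≥ 2 and χ² ≥ 4; and a
*positive signal* when it meets both.  Degenerate tables (zero cells)
yield flagged non-finite statistics, never exceptions, and are never
positive.  No multiple-testing adjustment is applied (a known
limitation of threshold-based screening; see the package docs).

The model/results pair follows the fit-and-inspect idiom::

    model = DisproportionalityModel(reports, dictionary, drug="DRUG-X")
    res = model.fit()            # ScreeningResults
    res.summary()                # text table of positive signals
    res.to_frame()               # full per-PT statistics
    res_sex = model.fit(stratify_by="sex")
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .reports import PtDictionary, ReportSet, normalize_term
from .descriptives import UNMAPPED_SOC, round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .subgroups import StratifiedScreenResult

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "ScreeningCriteria",
    "contingency",
    "ror_stats",
    "prr_stats",
    "screen",
    "DisproportionalityModel",
    "ScreeningResults",
]


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d report counts for one (drug, event) pair."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0:
                raise ValueError(f"cell {cell} is negative: {v}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_continuity(self, k: float) -> "ContingencyTable":
        """Haldane–Anscombe style correction: add ``k`` to every cell when
        any cell is zero.  Off by default everywhere in this package."""
        if k and min(self.a, self.b, self.c, self.d) == 0:
            return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)
        return self

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class ScreeningCriteria:
    """Positivity thresholds of threshold-based SRS screening."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ci_z: float = 1.96
    continuity: float = 0.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")
        for name in ("ror_ci_low_gt", "prr_min", "chi2_min", "ci_z", "continuity"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SignalStats:
    """Per-PT screening statistics with positivity flags."""

    pt: str
    soc: str
    a: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ror_positive: bool
    prr_positive: bool

    @property
    def combined_positive(self) -> bool:
        return self.ror_positive and self.prr_positive


def ror_stats(table: ContingencyTable, z: float = 1.96) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald CI.

    Zero-cell policy (no correction applied here): ``b=0`` or ``c=0``
    makes the ROR infinite, ``a·d = 0`` with finite denominator makes it
    0, both → NaN; the CI is NaN unless all four cells are positive.
    """
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        ror = float("nan") if num == 0 else float("inf")
    else:
        ror = num / den
    if min(table.a, table.b, table.c, table.d) > 0:
        se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
        log_ror = math.log(ror)
        lo, hi = math.exp(log_ror - z * se), math.exp(log_ror + z * se)
    else:
        lo = hi = float("nan")
    return ror, lo, hi


def prr_stats(table: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and the uncorrected Pearson χ².

    Zero denominators yield NaN (flagged undefined), never an exception.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    prr_den = c * (a + b)
    prr = a * (c + d) / prr_den if prr_den > 0 else float("nan")
    chi_den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = (a * d - b * c) ** 2 * table.n / chi_den if chi_den > 0 else float("nan")
    return prr, chi2


def _in_doi_arm(report, drug_key: str) -> bool:
    return report.role == "primary_suspect" and normalize_term(report.drug) == drug_key


def contingency(report_set: ReportSet, drug: str, pt: str) -> ContingencyTable:
    """Build the 2×2 table for one (drug, PT) pair over the whole set.

    The drug-of-interest arm is reports naming the drug as primary
    suspect; every other report (other drugs, or non-suspect roles) is
    the comparator arm.
    """
    drug_key = normalize_term(drug)
    pt_key = normalize_term(pt)
    a = b = c = d = 0
    for r in report_set:
        has_pt = any(normalize_term(p) == pt_key for p in r.pts)
        if _in_doi_arm(r, drug_key):
            a, c = (a + 1, c) if has_pt else (a, c + 1)
        else:
            b, d = (b + 1, d) if has_pt else (b, d + 1)
    return ContingencyTable(a, b, c, d)


def _evaluate(
    pt: str,
    soc: str,
    table: ContingencyTable,
    criteria: ScreeningCriteria,
) -> SignalStats:
    a_raw = int(table.a)
    t = table.with_continuity(criteria.continuity)
    ror, lo, hi = ror_stats(t, criteria.ci_z)
    prr, chi2 = prr_stats(t)
    meets_a = a_raw >= criteria.min_a
    ror_pos = meets_a and math.isfinite(lo) and lo > criteria.ror_ci_low_gt
    prr_pos = (
        meets_a
        and math.isfinite(prr)
        and prr >= criteria.prr_min
        and math.isfinite(chi2)
        and chi2 >= criteria.chi2_min
    )
    return SignalStats(
        pt=pt, soc=soc, a=a_raw, ror=ror, ror_ci_low=lo, ror_ci_high=hi,
        prr=prr, chi2=chi2, ror_positive=ror_pos, prr_positive=prr_pos,
    )


def _sort_key(s: SignalStats) -> tuple:
    # combined positives first, strongest ROR first; NaN sinks to the bottom
    ror = s.ror if math.isfinite(s.ror) else (math.inf if s.ror == math.inf else -math.inf)
    return (not s.combined_positive, -ror, s.pt)


def screen(
    report_set: ReportSet,
    dictionary: PtDictionary,
    drug: str,
    criteria: ScreeningCriteria | None = None,
) -> list["SignalStats"]:
    """Screen every PT observed with the drug of interest.

    Returns one :class:`SignalStats` per PT, combined positives first
    (sorted by ROR descending), then the remainder.
    """
    criteria = criteria or ScreeningCriteria()
    drug_key = normalize_term(drug)

    n_doi = n_other = 0
    a_counts: dict[str, int] = {}
    b_counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for r in report_set:
        keys = {normalize_term(p): p for p in r.pts}
        if _in_doi_arm(r, drug_key):
            n_doi += 1
            for key, raw in keys.items():
                a_counts[key] = a_counts.get(key, 0) + 1
                prev = display.get(key)
                display[key] = raw if prev is None or raw < prev else prev
        else:
            n_other += 1
            for key in keys:
                b_counts[key] = b_counts.get(key, 0) + 1

    stats = []
    for key, a in a_counts.items():
        b = b_counts.get(key, 0)
        table = ContingencyTable(a, b, n_doi - a, n_other - b)
        pt_disp = dictionary.display_pt(display[key])
        soc = dictionary.soc(pt_disp, UNMAPPED_SOC)
        stats.append(_evaluate(pt_disp, soc, table, criteria))
    stats.sort(key=_sort_key)
    return stats


class ScreeningResults:
    """Results of one disproportionality screen.

    Attributes
    ----------
    stats : list of SignalStats, combined positives first.
    criteria : the thresholds used.
    n_reports, n_drug_reports : universe and drug-arm sizes.
    """

    def __init__(
        self,
        stats: Sequence[SignalStats],
        criteria: ScreeningCriteria,
        drug: str,
        source_label: str,
        n_reports: int,
        n_drug_reports: int,
    ) -> None:
        self.stats = list(stats)
        self.criteria = criteria
        self.drug = drug
        self.source_label = source_label
        self.n_reports = n_reports
        self.n_drug_reports = n_drug_reports

    def __len__(self) -> int:
        return len(self.stats)

    def __iter__(self):
        return iter(self.stats)

    def positive(self) -> list[SignalStats]:
        """Combined positive signals (both ROR and PRR criteria met)."""
        return [s for s in self.stats if s.combined_positive]

    def __getitem__(self, pt: str) -> SignalStats:
        key = normalize_term(pt)
        for s in self.stats:
            if normalize_term(s.pt) == key:
                return s
        raise KeyError(pt)

    def to_frame(self) -> pd.DataFrame:
        """Full per-PT statistics as a DataFrame (one row per screened PT)."""
        return pd.DataFrame(
            [
                {
                    "pt": s.pt,
                    "soc": s.soc,
                    "a": s.a,
                    "ror": s.ror,
                    "ror_ci_low": s.ror_ci_low,
                    "ror_ci_high": s.ror_ci_high,
                    "prr": s.prr,
                    "chi2": s.chi2,
                    "ror_positive": s.ror_positive,
                    "prr_positive": s.prr_positive,
                    "combined_positive": s.combined_positive,
                }
                for s in self.stats
            ]
        )

    def forest_frame(self, positives_only: bool = True) -> pd.DataFrame:
        """Forest-plot-ready table: pt, ror, ci_low, ci_high."""
        rows = self.positive() if positives_only else self.stats
        return pd.DataFrame(
            [
                {"pt": s.pt, "ror": s.ror, "ci_low": s.ror_ci_low, "ci_high": s.ror_ci_high}
                for s in rows
            ]
        )

    def plot_forest(self, ax=None, positives_only: bool = True):
        """Forest plot of ROR point estimates with 95% CIs (log x-axis)."""
        import matplotlib.pyplot as plt

        frame = self.forest_frame(positives_only).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * max(len(frame), 4) + 1))
        y = np.arange(len(frame))
        ax.errorbar(
            frame["ror"], y,
            xerr=[frame["ror"] - frame["ci_low"], frame["ci_high"] - frame["ror"]],
            fmt="o", capsize=2, lw=1,
        )
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(frame["pt"])
        ax.set_xscale("log")
        ax.set_xlabel("ROR (95% CI)")
        ax.set_title(f"Positive signals: {self.drug} ({self.source_label})")
        return ax

    def summary(self) -> str:
        """Human-readable table of the positive signals, strongest first."""
        lines = [
            f"Disproportionality screen: {self.drug} in {self.source_label}",
            f"universe {self.n_reports} reports ({self.n_drug_reports} drug-of-interest); "
            f"{len(self.stats)} PTs screened, {len(self.positive())} positive signals",
            f"criteria: a>={self.criteria.min_a}, ROR CI low>{self.criteria.ror_ci_low_gt}, "
            f"PRR>={self.criteria.prr_min}, chi2>={self.criteria.chi2_min}",
            "",
            f"{'PT':<36} {'a':>5} {'ROR':>10} {'95% CI':>22} {'PRR':>8} {'chi2':>9}",
        ]
        for s in self.positive():
            ci = f"[{round_half_up(s.ror_ci_low, 3):.3f}, {round_half_up(s.ror_ci_high, 3):.3f}]"
            lines.append(
                f"{s.pt:<36} {s.a:>5d} {round_half_up(s.ror, 3):>10.3f} {ci:>22} "
                f"{round_half_up(s.prr, 3):>8.3f} {round_half_up(s.chi2, 3):>9.3f}"
            )
        return "\n".join(lines)


class DisproportionalityModel:
    """Disproportionality screening model for one drug in one report set.

    Parameters
    ----------
    reports : ReportSet
        The report universe (drug of interest plus background drugs).
    dictionary : PtDictionary
        PT → SOC mapping used to annotate and group signals.
    drug : str
        Name of the drug of interest (matched case-insensitively against
        primary-suspect drug names).
    """

    def __init__(self, reports: ReportSet, dictionary: PtDictionary, drug: str) -> None:
        self.reports = reports
        self.dictionary = dictionary
        self.drug = drug

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        dictionary: PtDictionary,
        drug: str,
        source_label: str = "dataframe",
    ) -> "DisproportionalityModel":
        """Build the model from a canonical report-table DataFrame
        (columns as in the report CSV; ``pts`` either a ``;``-joined
        string or an iterable of PTs)."""
        from .reports import AdeReport

        reports = []
        for _, row in frame.iterrows():
            pts = row["pts"]
            if isinstance(pts, str):
                pts = frozenset(p.strip() for p in pts.split(";") if p.strip())
            else:
                pts = frozenset(pts)
            year = row.get("year")
            if isinstance(year, str):
                year = None if year.strip().lower() in ("", "unknown", "na") else int(year)
            elif year is not None and not (isinstance(year, float) and math.isnan(year)):
                year = int(year)
            else:
                year = None
            reports.append(
                AdeReport(
                    report_id=str(row["report_id"]),
                    drug=str(row["drug"]),
                    role=str(row.get("role", "primary_suspect")),
                    sex=str(row.get("sex", "unknown")),
                    age_group=str(row.get("age_group", "unknown")),
                    region=str(row.get("region", "unknown")),
                    year=year,
                    pts=pts,
                )
            )
        return cls(ReportSet(source_label=source_label, reports=reports), dictionary, drug)

    def fit(
        self,
        criteria: ScreeningCriteria | None = None,
        stratify_by: str | None = None,
    ):
        """Run the screen.

        Returns :class:`ScreeningResults`, or a
        :class:`~pvsignal.subgroups.StratifiedScreenResult` when
        ``stratify_by`` names a demographic category.
        """
        criteria = criteria or ScreeningCriteria()
        if stratify_by is not None:
            from .subgroups import screen_by

            return screen_by(self.reports, self.dictionary, self.drug, criteria, stratify_by)
        stats = screen(self.reports, self.dictionary, self.drug, criteria)
        return ScreeningResults(
            stats=stats,
            criteria=criteria,
            drug=self.drug,
            source_label=self.reports.source_label,
            n_reports=len(self.reports),
            n_drug_reports=len(self.reports.drug_reports(self.drug)),
        )
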
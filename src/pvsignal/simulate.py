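"""Synthetic spontaneous-reporting-system (SRS) generator.

Generates report sets with *known ground truth* so that every stage of
the pipeline — descriptive tables, disproportionality screening,
subgroup screening — can be tested without access to a live
pharmacovigilance database.

The generative model is deliberately the simplest one under which the
disproportionality null and alternative are exact:

* each report names one suspect drug, drawn from a categorical
  distribution over the drug of interest and a background of other drugs;
* each preferred term (PT) in the catalog is included in the report
  independently with its baseline probability, multiplied by a per-PT
  rate ratio ρ when the report's drug is the drug of interest
  (capped at 1);
* demographics (sex, age group, region, reporting year) are drawn
  independently of everything else, each with an explicit "unknown" mass;
* reports that draw fewer than ``min_pts_per_report`` PTs are redrawn,
  because a spontaneous report with no event does not exist.

Because inclusion is independent Bernoulli, the true report-level odds
ratio of any PT is available in closed form (including the correction
for the minimum-PT resampling), which is what the calibration and
coverage tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .reports import AdeReport, PtDictionary, ReportSet

__all__ = [
    "PtSpec",
    "SimConfig",
    "GroundTruth",
    "SimConfigError",
    "simulate",
    "two_source_pair",
    "default_config",
    "default_pt_catalog",
    "catalog_dictionary",
]

_PROB_TOL = 1e-9


class SimConfigError(ValueError):
    """A SimConfig violates its invariants (checked before any sampling)."""


@dataclass(frozen=True)
class PtSpec:
    """One catalog entry: a PT, its primary SOC and its per-report
    baseline inclusion probability under any background drug."""

    pt: str
    soc: str
    baseline_prob: float


@dataclass
class SimConfig:
    """Full generative specification of one synthetic reporting system."""

    n_reports: int
    drug_of_interest: str
    n_background_drugs: int
    drug_weights: Sequence[float]  # [drug_of_interest, bg_1, ..., bg_k]
    pt_catalog: Sequence[PtSpec]
    effect_multipliers: Mapping[str, float] = field(default_factory=dict)
    min_pts_per_report: int = 1
    demographics: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0
    source_label: str = "synthetic"

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise SimConfigError("n_reports must be positive")
        if self.n_background_drugs <= 0:
            raise SimConfigError("n_background_drugs must be positive")
        if self.min_pts_per_report <= 0:
            raise SimConfigError("min_pts_per_report must be positive")
        if len(self.drug_weights) != self.n_background_drugs + 1:
            raise SimConfigError(
                f"drug_weights must have length n_background_drugs+1 "
                f"({self.n_background_drugs + 1}), got {len(self.drug_weights)}"
            )
        w = np.asarray(self.drug_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > _PROB_TOL:
            raise SimConfigError("drug_weights must be non-negative and sum to 1")
        if not self.pt_catalog:
            raise SimConfigError("pt_catalog must be non-empty")
        names = [s.pt for s in self.pt_catalog]
        if len(set(names)) != len(names):
            raise SimConfigError("pt_catalog contains duplicate PTs")
        for spec in self.pt_catalog:
            if not (0.0 <= spec.baseline_prob <= 1.0):
                raise SimConfigError(f"baseline_prob for {spec.pt!r} outside [0, 1]")
        catalog = set(names)
        for pt, rho in self.effect_multipliers.items():
            if pt not in catalog:
                raise SimConfigError(f"effect multiplier for unknown PT {pt!r}")
            if rho < 0:
                raise SimConfigError(f"effect multiplier for {pt!r} must be >= 0")
        for category, dist in self.demographics.items():
            p = np.asarray(list(dist.values()), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
                raise SimConfigError(
                    f"demographic distribution {category!r} must be non-negative and sum to 1"
                )
        # A report must be able to reach min_pts_per_report in either arm.
        for arm_probs in (self.background_probs(), self.doi_probs()):
            if int((np.asarray(arm_probs) > 0).sum()) < self.min_pts_per_report:
                raise SimConfigError(
                    "fewer PTs with positive probability than min_pts_per_report"
                )

    # -- derived probability vectors ------------------------------------

    def pt_names(self) -> list[str]:
        return [s.pt for s in self.pt_catalog]

    def background_probs(self) -> np.ndarray:
        return np.array([s.baseline_prob for s in self.pt_catalog], dtype=float)

    def doi_probs(self) -> np.ndarray:
        """Inclusion probabilities under the drug of interest: min(1, ρ·baseline)."""
        p = self.background_probs().copy()
        for i, spec in enumerate(self.pt_catalog):
            rho = self.effect_multipliers.get(spec.pt, 1.0)
            p[i] = min(1.0, rho * spec.baseline_prob)
        return p

    def drug_names(self) -> list[str]:
        return [self.drug_of_interest] + [
            f"BG-DRUG-{i + 1:03d}" for i in range(self.n_background_drugs)
        ]


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative quantities for one SimConfig, used as oracles."""

    rate_ratios: Mapping[str, float]
    background_probs: Mapping[str, float]
    doi_probs: Mapping[str, float]
    min_pts_per_report: int

    @property
    def signal_pts(self) -> frozenset[str]:
        return frozenset(pt for pt, rho in self.rate_ratios.items() if rho != 1.0)

    def conditional_prob(self, pt: str, arm: str = "doi") -> float:
        """P(report includes ``pt`` | report survived min-PT resampling).

        Resampling of reports with fewer than ``min_pts_per_report`` PTs
        conditions the Bernoulli vector on K ≥ m; this returns the exact
        conditional marginal p·P(K₋ᵢ ≥ m−1)/P(K ≥ m) via a
        Poisson-binomial recursion.
        """
        probs = self.doi_probs if arm == "doi" else self.background_probs
        p_vec = np.array(list(probs.values()), dtype=float)
        p_i = probs[pt]
        others = np.array([v for k, v in probs.items() if k != pt], dtype=float)
        m = self.min_pts_per_report
        denom = 1.0 - _p_fewer_than(p_vec, m)
        if denom <= 0:
            return float("nan")
        num = p_i * (1.0 - _p_fewer_than(others, m - 1))
        return num / denom

    def true_report_odds_ratio(self, pt: str) -> float:
        """Exact report-level odds ratio of ``pt`` between the
        drug-of-interest arm and the pooled background arm."""
        q1 = self.conditional_prob(pt, "doi")
        q0 = self.conditional_prob(pt, "background")
        if q0 in (0.0, 1.0) or q1 in (0.0, 1.0):
            return float("inf") if q1 > q0 else 0.0
        return (q1 / (1 - q1)) / (q0 / (1 - q0))


def _p_fewer_than(probs: np.ndarray, m: int) -> float:
    """P(sum of independent Bernoulli(probs) < m), exact, O(len·m)."""
    if m <= 0:
        return 0.0
    dp = np.zeros(m)
    dp[0] = 1.0
    for p in probs:
        dp[1:] = dp[1:] * (1 - p) + dp[:-1] * p
        dp[0] *= 1 - p
    return float(dp.sum())


def ground_truth(config: SimConfig) -> GroundTruth:
    names = config.pt_names()
    bg = config.background_probs()
    doi = config.doi_probs()
    return GroundTruth(
        rate_ratios={s.pt: config.effect_multipliers.get(s.pt, 1.0) for s in config.pt_catalog},
        background_probs=dict(zip(names, bg.tolist())),
        doi_probs=dict(zip(names, doi.tolist())),
        min_pts_per_report=config.min_pts_per_report,
    )


_MAX_RESAMPLE_ROUNDS = 10_000


def simulate(config: SimConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw one synthetic reporting system.

    Identical configs (including seed) produce bit-identical report sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = config.drug_names()
    drug_idx = rng.choice(len(drug_names), size=n, p=np.asarray(config.drug_weights, float))
    is_doi = drug_idx == 0

    p_bg = config.background_probs()
    p_doi = config.doi_probs()
    probs = np.where(is_doi[:, None], p_doi[None, :], p_bg[None, :])
    include = rng.random(probs.shape) < probs

    # Redraw reports below the minimum PT count: an SRS report without an
    # event does not exist, so the observed universe is conditioned on K>=m.
    short = include.sum(axis=1) < config.min_pts_per_report
    rounds = 0
    while short.any():
        rounds += 1
        if rounds > _MAX_RESAMPLE_ROUNDS:
            raise SimConfigError("resampling failed to reach min_pts_per_report")
        rows = np.flatnonzero(short)
        include[rows] = rng.random((rows.size, probs.shape[1])) < probs[rows]
        short[rows] = include[rows].sum(axis=1) < config.min_pts_per_report

    demo = {cat: _draw_categorical(rng, dist, n) for cat, dist in _demographics(config).items()}

    pt_names = np.array(config.pt_names(), dtype=object)
    width = len(str(n))
    reports = []
    for i in range(n):
        year_level = demo["year"][i]
        reports.append(
            AdeReport(
                report_id=f"{config.source_label}-{i + 1:0{width}d}",
                drug=drug_names[drug_idx[i]],
                role="primary_suspect",
                sex=demo["sex"][i],
                age_group=demo["age_group"][i],
                region=demo["region"][i],
                year=None if year_level == "unknown" else int(year_level),
                pts=frozenset(pt_names[include[i]]),
            )
        )
    return ReportSet(source_label=config.source_label, reports=reports), ground_truth(config)


def _draw_categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> list[str]:
    levels = list(dist.keys())
    idx = rng.choice(len(levels), size=n, p=np.asarray(list(dist.values()), float))
    return [levels[i] for i in idx]


def _demographics(config: SimConfig) -> dict[str, dict[str, float]]:
    demo = {k: dict(v) for k, v in config.demographics.items()}
    demo.setdefault("sex", dict(DEFAULT_DEMOGRAPHICS["sex"]))
    demo.setdefault("age_group", dict(DEFAULT_DEMOGRAPHICS["age_group"]))
    demo.setdefault("region", dict(DEFAULT_DEMOGRAPHICS["region"]))
    demo.setdefault("year", dict(DEFAULT_DEMOGRAPHICS["year"]))
    return demo


def two_source_pair(
    config: SimConfig,
    n_reports_b: int | None = None,
    seed_b: int | None = None,
    effect_multipliers_b: Mapping[str, float] | None = None,
    source_labels: tuple[str, str] = ("source-A", "source-B"),
) -> tuple[ReportSet, ReportSet]:
    """Two draws sharing one PT catalog, emulating two reporting systems.

    The second source may differ in size, seed and effect multipliers;
    by default it is an independent draw (seed+1) from the same system.
    """
    config_a = replace(config, source_label=source_labels[0])
    config_b = replace(
        config,
        source_label=source_labels[1],
        n_reports=n_reports_b if n_reports_b is not None else config.n_reports,
        seed=seed_b if seed_b is not None else config.seed + 1,
        effect_multipliers=(
            dict(effect_multipliers_b)
            if effect_multipliers_b is not None
            else dict(config.effect_multipliers)
        ),
    )
    set_a, _ = simulate(config_a)
    set_b, _ = simulate(config_b)
    return set_a, set_b


# ---------------------------------------------------------------------------
# Default study conditions
#
# Demographic masses follow the marginal structure of a real hyperkalemia
# drug's FAERS extract: male-dominated reporting, a large unknown-age mass,
# reports mostly from the Americas, and counts rising over recent years.

DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.2746, "male": 0.4819, "unknown": 0.2435},
    "age_group": {
        "lt18": 0.0007,
        "a18_44": 0.0188,
        "a45_64": 0.0715,
        "a65_74": 0.0997,
        "ge75": 0.2341,
        "unknown": 0.5752,
    },
    "region": {
        "africa": 0.0007,
        "americas": 0.7890,
        "asia": 0.1756,
        "europe": 0.0347,
        "unknown": 0.0000,
    },
    "year": {
        "2018": 0.0043,
        "2019": 0.0650,
        "2020": 0.0795,
        "2021": 0.1156,
        "2022": 0.1908,
        "2023": 0.2775,
        "2024": 0.2673,
        "unknown": 0.0000,
    },
}


def default_pt_catalog() -> list[PtSpec]:
    """Default catalog: clinically plausible event terms with heterogeneous
    baseline frequencies, spanning the organ classes a potassium-binder
    extract touches, plus low-frequency background terms."""
    entries = [
        ("Death", "General disorders and administration site conditions", 0.08),
        ("Drug ineffective", "General disorders and administration site conditions", 0.05),
        ("Oedema", "General disorders and administration site conditions", 0.02),
        ("Oedema peripheral", "General disorders and administration site conditions", 0.02),
        ("Fatigue", "General disorders and administration site conditions", 0.04),
        ("Blood potassium increased", "Investigations", 0.01),
        ("Blood potassium abnormal", "Investigations", 0.004),
        ("Blood potassium decreased", "Investigations", 0.006),
        ("Blood sodium increased", "Investigations", 0.003),
        ("Weight increased", "Investigations", 0.015),
        ("Blood pressure increased", "Investigations", 0.02),
        ("Constipation", "Gastrointestinal disorders", 0.025),
        ("Diarrhoea", "Gastrointestinal disorders", 0.035),
        ("Nausea", "Gastrointestinal disorders", 0.04),
        ("Vomiting", "Gastrointestinal disorders", 0.03),
        ("Abdominal discomfort", "Gastrointestinal disorders", 0.015),
        ("Dysphagia", "Gastrointestinal disorders", 0.008),
        ("Ileus", "Gastrointestinal disorders", 0.002),
        ("Cardiac failure", "Cardiac disorders", 0.012),
        ("Cardiac failure congestive", "Cardiac disorders", 0.008),
        ("Myocardial infarction", "Cardiac disorders", 0.01),
        ("Hypokalaemia", "Metabolism and nutrition disorders", 0.006),
        ("Hyperkalaemia", "Metabolism and nutrition disorders", 0.006),
        ("Hypernatraemia", "Metabolism and nutrition disorders", 0.002),
        ("Fluid overload", "Metabolism and nutrition disorders", 0.003),
        ("Renal failure", "Renal and urinary disorders", 0.012),
        ("Renal disorder", "Renal and urinary disorders", 0.008),
        ("Cerebrovascular accident", "Nervous system disorders", 0.008),
        ("Dizziness", "Nervous system disorders", 0.025),
        ("Headache", "Nervous system disorders", 0.03),
        ("Pneumonia", "Infections and infestations", 0.012),
        ("Rash", "Skin and subcutaneous tissue disorders", 0.02),
        ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.02),
        ("Off label use", "Injury, poisoning and procedural complications", 0.02),
        ("Product dose omission issue", "Injury, poisoning and procedural complications", 0.012),
        ("Intentional product misuse", "Injury, poisoning and procedural complications", 0.006),
        ("Product use issue", "Product issues", 0.012),
        ("Fall", "Injury, poisoning and procedural complications", 0.015),
        ("Insomnia", "Psychiatric disorders", 0.012),
        ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.015),
    ]
    return [PtSpec(pt, soc, p) for pt, soc, p in entries]


def catalog_dictionary(catalog: Sequence[PtSpec], version_label: str = "catalog") -> PtDictionary:
    """PT dictionary covering exactly the catalog (lookup is total on
    every PT the generator can emit)."""
    return PtDictionary(
        entries={s.pt: s.soc for s in catalog}, version_label=version_label
    )


def default_config(
    n_reports: int = 5000,
    seed: int = 0,
    drug_of_interest: str = "DRUG-X",
    doi_weight: float = 0.10,
    n_background_drugs: int = 40,
    effect_multipliers: Mapping[str, float] | None = None,
    **overrides,
) -> SimConfig:
    """Study-condition default: a mid-sized system where the drug of
    interest carries elevated reporting of potassium/sodium laboratory
    terms and oedema-related terms over a broad drug background."""
    if effect_multipliers is None:
        effect_multipliers = {
            "Blood potassium increased": 8.0,
            "Blood potassium abnormal": 10.0,
            "Blood sodium increased": 6.0,
            "Hypernatraemia": 5.0,
            "Oedema": 3.0,
            "Cardiac failure congestive": 2.5,
        }
    bg = np.full(n_background_drugs, (1.0 - doi_weight) / n_background_drugs)
    return SimConfig(
        n_reports=n_reports,
        drug_of_interest=drug_of_interest,
        n_background_drugs=n_background_drugs,
        drug_weights=[doi_weight, *bg.tolist()],
        pt_catalog=default_pt_catalog(),
        effect_multipliers=dict(effect_multipliers),
        demographics={k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()},
        seed=seed,
        **overrides,
    )
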
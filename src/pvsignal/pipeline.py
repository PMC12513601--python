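"""End-to-end pipeline: validated run configuration, orchestration of
every analysis stage, and a machine-readable run manifest.

A run takes one or two report tables (or a seeded generative
specification standing in for them), a PT dictionary, and a drug of
interest, and writes the full analysis bundle as CSV artifacts:
demographic tables, SOC tables, top-N PT tables, cross-source overlap,
pooled screening and stratified screening, plus ``manifest.json``
recording versions, a config hash, row-count accounting and timing.
Reruns on identical inputs and config produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .descriptives import demographic_table, overlap, soc_table, top_pts
from .replay import mock_dictionary
from .reports import PtDictionary, ReportSet, read_pt_dictionary, read_reports, write_reports
from .screening import DisproportionalityModel, ScreeningCriteria
from .simulate import default_config, ground_truth, simulate, two_source_pair

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "PipelineStageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """A run configuration violates its schema (fail-closed)."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_TOP_KEYS = {
    "drug", "dictionary", "reports", "simulate", "criteria",
    "top_n", "stratify", "output_dir", "seed", "log_level",
}
_CRITERIA_KEYS = {"min_a", "ror_ci_low_gt", "prr_min", "chi2_min", "ci_z", "continuity"}
_SIM_KEYS = {
    "n_reports", "doi_weight", "n_background_drugs", "effect_multipliers",
    "two_source", "n_reports_b",
}
_STRATIFIERS = {"sex", "age_group", "region", "year"}


@dataclass
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    drug: str
    output_dir: Path
    dictionary: str = "bundled"
    reports: list[str] = field(default_factory=list)
    simulate: dict[str, Any] | None = None
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    top_n: int = 30
    stratify: list[str] = field(default_factory=lambda: ["sex"])
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            "drug": self.drug,
            "dictionary": self.dictionary,
            "reports": list(self.reports),
            "simulate": self.simulate,
            "criteria": asdict(self.criteria),
            "top_n": self.top_n,
            "stratify": list(self.stratify),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are errors (fail-closed); criteria default to the
    conventional screening thresholds (a≥3; ROR CI low >1; PRR≥2, χ²≥4,
    z=1.96); top-N defaults to 30.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))
    if "drug" not in raw or not str(raw["drug"]).strip():
        raise ConfigError(f"{path}: 'drug' is required")
    if "output_dir" not in raw:
        raise ConfigError(f"{path}: 'output_dir' is required")

    reports = raw.get("reports") or []
    if isinstance(reports, str):
        reports = [reports]
    sim = raw.get("simulate")
    if bool(reports) == bool(sim):
        raise ConfigError(f"{path}: exactly one of 'reports' and 'simulate' must be given")
    if len(reports) > 2:
        raise ConfigError(f"{path}: at most two report sources are supported")
    if sim is not None:
        _check_keys(sim, _SIM_KEYS, f"{path}:simulate")

    crit_raw = raw.get("criteria") or {}
    _check_keys(crit_raw, _CRITERIA_KEYS, f"{path}:criteria")
    try:
        criteria = ScreeningCriteria(**crit_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}:criteria: {exc}") from None

    top_n = int(raw.get("top_n", 30))
    if top_n < 1:
        raise ConfigError(f"{path}: top_n must be >= 1")
    stratify = raw.get("stratify", ["sex"])
    if isinstance(stratify, str):
        stratify = [stratify]
    bad = set(stratify) - _STRATIFIERS
    if bad:
        raise ConfigError(f"{path}: unknown stratifier(s): {', '.join(sorted(bad))}")

    dictionary = str(raw.get("dictionary", "bundled"))
    if dictionary != "bundled" and not Path(dictionary).exists():
        raise ConfigError(f"{path}: dictionary file not found: {dictionary}")
    for rp in reports:
        if not Path(rp).exists():
            raise ConfigError(f"{path}: report file not found: {rp}")

    return RunConfig(
        drug=str(raw["drug"]),
        output_dir=Path(raw["output_dir"]),
        dictionary=dictionary,
        reports=[str(r) for r in reports],
        simulate=dict(sim) if sim is not None else None,
        criteria=criteria,
        top_n=top_n,
        stratify=list(stratify),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _load_dictionary(config: RunConfig) -> PtDictionary:
    if config.dictionary == "bundled":
        return mock_dictionary()
    return read_pt_dictionary(config.dictionary)


class _ArtifactWriter:
    """Writes artifacts through a .partial temporary so interrupted runs
    are visibly incomplete."""

    def __init__(self, out_dir: Path) -> None:
        self.out_dir = out_dir
        self.artifacts: list[str] = []

    def write_frame(self, name: str, frame) -> None:
        final = self.out_dir / name
        partial = self.out_dir / f"{name}.partial"
        frame.to_csv(partial, index=False, lineterminator="\n")
        partial.replace(final)
        self.artifacts.append(name)

    def write_text(self, name: str, text: str) -> None:
        final = self.out_dir / name
        partial = self.out_dir / f"{name}.partial"
        partial.write_text(text, encoding="utf-8")
        partial.replace(final)
        self.artifacts.append(name)


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — annotate with stage name
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorate


@_stage("inputs")
def _acquire_inputs(config: RunConfig, writer: _ArtifactWriter) -> tuple[list[ReportSet], dict]:
    accounting: dict[str, Any] = {}
    sets: list[ReportSet] = []
    if config.simulate is not None:
        sim = dict(config.simulate)
        two_source = bool(sim.pop("two_source", False))
        n_reports_b = sim.pop("n_reports_b", None)
        effect = sim.pop("effect_multipliers", None)
        base = default_config(
            n_reports=int(sim.pop("n_reports", 5000)),
            seed=config.seed,
            drug_of_interest=config.drug,
            doi_weight=float(sim.pop("doi_weight", 0.10)),
            n_background_drugs=int(sim.pop("n_background_drugs", 40)),
            effect_multipliers=effect,
        )
        if two_source:
            set_a, set_b = two_source_pair(
                base, n_reports_b=int(n_reports_b) if n_reports_b else None
            )
            sets = [set_a, set_b]
        else:
            set_a, _ = simulate(base)
            sets = [set_a]
        truth = ground_truth(base)
        writer.write_text(
            "ground_truth.json",
            json.dumps(
                {
                    "rate_ratios": dict(truth.rate_ratios),
                    "signal_pts": sorted(truth.signal_pts),
                    "seed": config.seed,
                },
                indent=2,
                sort_keys=True,
            ),
        )
        for s in sets:
            path = writer.out_dir / f"reports_{s.source_label}.csv"
            write_reports(s, path)
            writer.artifacts.append(path.name)
            accounting[s.source_label] = {"accepted": len(s), "rejected": 0}
    else:
        for rp in config.reports:
            s = read_reports(rp)
            sets.append(s)
            accounting[s.source_label] = {
                "accepted": len(s),
                "rejected": getattr(s, "n_rejected", 0),
            }
    return sets, accounting


@_stage("descriptives")
def _run_descriptives(config: RunConfig, writer: _ArtifactWriter, sets, dictionary) -> None:
    for s in sets:
        label = s.source_label
        demo = demographic_table(s)
        frames = []
        for breakdown in demo:
            f = breakdown.to_frame()
            f.insert(0, "category", breakdown.category)
            frames.append(f)
        import pandas as pd

        writer.write_frame(f"demographics_{label}.csv", pd.concat(frames, ignore_index=True))
        writer.write_frame(f"soc_{label}.csv", soc_table(s, dictionary, config.drug).to_frame())
        writer.write_frame(
            f"top{config.top_n}_pts_{label}.csv", top_pts(s, config.drug, config.top_n).to_frame()
        )


@_stage("overlap")
def _run_overlap(config: RunConfig, writer: _ArtifactWriter, sets) -> None:
    if len(sets) != 2:
        return
    import pandas as pd

    table_a = top_pts(sets[0], config.drug, config.top_n)
    table_b = top_pts(sets[1], config.drug, config.top_n)
    result = overlap(table_a, table_b)
    rows = (
        [("shared", pt) for pt in sorted(result.shared)]
        + [("only_" + sets[0].source_label, pt) for pt in sorted(result.only_a)]
        + [("only_" + sets[1].source_label, pt) for pt in sorted(result.only_b)]
    )
    writer.write_frame("overlap.csv", pd.DataFrame(rows, columns=["partition", "pt"]))


@_stage("screening")
def _run_screening(config: RunConfig, writer: _ArtifactWriter, sets, dictionary) -> dict:
    counts = {}
    for s in sets:
        label = s.source_label
        model = DisproportionalityModel(s, dictionary, config.drug)
        res = model.fit(criteria=config.criteria)
        writer.write_frame(f"screening_{label}.csv", res.to_frame())
        writer.write_frame(f"forest_{label}.csv", res.forest_frame())
        counts[label] = {"pts_screened": len(res), "positive_signals": len(res.positive())}
        for stratifier in config.stratify:
            strat = model.fit(criteria=config.criteria, stratify_by=stratifier)
            for level, level_res in strat.strata.items():
                writer.write_frame(
                    f"screening_{label}_{stratifier}_{level}.csv", level_res.to_frame()
                )
            writer.write_frame(f"{stratifier}_comparison_{label}.csv", strat.comparison())
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis bundle; returns the run manifest dict
    (also written as ``manifest.json``)."""
    t0 = time.perf_counter()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _ArtifactWriter(out_dir)
    dictionary = _load_dictionary(config)

    sets, accounting = _acquire_inputs(config, writer)
    _run_descriptives(config, writer, sets, dictionary)
    _run_overlap(config, writer, sets)
    screen_counts = _run_screening(config, writer, sets, dictionary)

    manifest = {
        "tool": "pvsignal",
        "version": __version__,
        "dictionary_version": dictionary.version_label,
        "config_hash": config.config_hash(),
        "drug": config.drug,
        "seed": config.seed,
        "sources": accounting,
        "screening": screen_counts,
        "artifacts": sorted(writer.artifacts),
        "elapsed_seconds": round(time.perf_counter() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info("pipeline complete: %d artifacts in %s", len(writer.artifacts), out_dir)
    return manifest
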
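"""End-to-end orchestration: simulate -> label -> score -> derive -> evaluate -> impute.

A :class:`RunConfig` names the stages to execute and their options; ``run``
writes every artifact (cohort CSVs, score YAMLs, JSON reports, the audit
trail) under one run directory together with a manifest recording the
config, the master seed and a SHA-256 per artifact, so two runs with the
same config and seed produce identical manifests.

The ``table2_cohort_a``/``table2_cohort_b`` presets skip simulation and
evaluate the published validation counts directly (expanded into labelled
vectors), which reproduces every printed sensitivity/specificity/odds-ratio
cell without patient-level data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import derivation, evaluation, imputation, outcomes, scores
from .reference_counts import MORTALITY_TABLES, SEPSIS_TABLES, expand_confusion

__all__ = ["RunConfig", "run", "table2_report"]

log = logging.getLogger("sepscore")

DEFAULT_SCORES = ("news2", "sews", "shews", "retts")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    stages: list = field(default_factory=lambda: ["simulate", "score", "evaluate"])
    preset: str | None = "cohort_a"  # cohort preset, table2_* fixture, or None
    input_path: str | None = None  # cohort CSV instead of simulation
    sim_config: dict | None = None  # inline SimConfig overrides
    with_missingness: bool = False
    score_set: list = field(default_factory=lambda: list(DEFAULT_SCORES))
    reference_score: str = "news2"
    subgroup_infected: bool = True
    derivation_options: dict = field(default_factory=dict)
    imputation_options: dict = field(default_factory=dict)
    output_dir: str = "runs"
    name: str = "run"
    seed: int = 0

    _ORDER = ("simulate", "score", "derive", "evaluate", "impute")

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in self._ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        order = [self._ORDER.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must respect the order simulate<score<derive<evaluate<impute")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def table2_report(cohort_key: str) -> dict:
    """Sens/spec/OR cells recomputed from the published count fixtures."""
    out: dict = {}
    for score, counts in SEPSIS_TABLES[cohort_key].items():
        pred, truth = expand_confusion(*counts)
        ct = evaluation.confusion(pred, truth)
        sens, spec = evaluation.sensitivity_specificity(ct)
        out[score] = {
            "counts": {"tp": ct.tp, "fn": ct.fn, "fp": ct.fp, "tn": ct.tn},
            "sensitivity_pct": sens.as_percent(),
            "specificity_pct": spec.as_percent(),
        }
    for score, cells in MORTALITY_TABLES[cohort_key].items():
        orr = evaluation.odds_ratio(*cells)
        out.setdefault(score, {})["mortality_or"] = [
            round(orr.estimate, 1),
            round(orr.ci_low, 1),
            round(orr.ci_high, 1),
        ]
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    Artifacts land in ``<output_dir>/<name>/``; a failing stage raises with
    the stage named, keeping partial outputs on disk.
    """
    config.validate()
    outdir = Path(config.output_dir) / config.name
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    artifacts: list[Path] = []
    df: pd.DataFrame | None = None

    if config.preset and config.preset.startswith("table2_"):
        key = config.preset.removeprefix("table2_")
        report["table2"] = table2_report(key)
        _finish(outdir, config, report, artifacts)
        return report

    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                if config.preset:
                    sim = cohort_mod.load_preset(config.preset)
                else:
                    sim = cohort_mod.SimConfig()
                for k, v in (config.sim_config or {}).items():
                    setattr(sim, k, v)
                ch = cohort_mod.generate_cohort(sim, seed=config.seed)
                if config.with_missingness:
                    ch = cohort_mod.inject_missingness(ch, sim, seed=config.seed)
                df = ch.df
                path = outdir / "cohort.csv"
                cohort_mod.write_cohort(ch, path)
                artifacts.append(path)
                report["simulate"] = {"n": len(df), "preset": config.preset}
            elif stage == "score":
                if df is None:
                    df = cohort_mod.read_cohort(config.input_path).df
                for name in config.score_set:
                    df = scores.score_cohort(df, name)
                lab = outcomes.label_cohort(df)
                df["sepsis"] = lab["sepsis"].to_numpy()
                path = outdir / "scored.csv"
                df.to_csv(path, index=False)
                artifacts.append(path)
                report["score"] = {"scores": list(config.score_set)}
            elif stage == "derive":
                if df is None:
                    df = cohort_mod.read_cohort(config.input_path).df
                y = outcomes.label_cohort(df)["sepsis"].to_numpy()
                opts = dict(config.derivation_options)
                opts.setdefault("random_state", config.seed)
                derived = derivation.derive_score(df, y, **opts)
                spath = outdir / "derived_score.yaml"
                derived.definition.to_yaml(spath)
                apath = outdir / "derivation_audit.json"
                audit = {
                    "points": derived.points,
                    "scale": derived.scale,
                    "cutoff": derived.definition.cutoff,
                    "stage1": derived.stage1.as_frame().to_dict(orient="list"),
                    "stage2": derived.stage2.as_frame().to_dict(orient="list"),
                }
                apath.write_text(json.dumps(_jsonable(audit), indent=2, sort_keys=True))
                artifacts += [spath, apath]
                report["derive"] = {"cutoff": derived.definition.cutoff, "points": derived.points}
            elif stage == "evaluate":
                if df is None:
                    df = pd.read_csv(config.input_path)
                subgroups = {}
                if config.subgroup_infected and "infected" in df.columns:
                    subgroups["infected"] = df["infected"].astype(bool).to_numpy()
                rep = evaluation.evaluate_scores(
                    df,
                    config.score_set,
                    outcome_col="sepsis",
                    reference=config.reference_score,
                    subgroups=subgroups,
                )
                frame = evaluation.report_to_frame(rep)
                tpath = outdir / "evaluation.tsv"
                frame.to_csv(tpath, sep="\t", index=False)
                artifacts.append(tpath)
                report["evaluate"] = json.loads(
                    json.dumps(_jsonable(rep), default=str)
                )
            elif stage == "impute":
                if df is None:
                    df = cohort_mod.read_cohort(config.input_path).df
                opts = dict(config.imputation_options)
                opts.setdefault("seed", config.seed)
                res = imputation.pmm_impute(df, **opts)
                pooled = {}
                for name in config.score_set:
                    if name == "retts":
                        continue
                    pooled[name] = imputation.pooled_evaluation(res, name)
                dpath = outdir / "imputation_diagnostics.json"
                dpath.write_text(
                    json.dumps(_jsonable({"chain_means": res.chain_means,
                                          "methods": res.methods}), indent=2, sort_keys=True)
                )
                artifacts.append(dpath)
                report["impute"] = {
                    "m": res.m,
                    "variables": list(res.variables),
                    "pooled_auc": _jsonable(pooled),
                }
        except Exception as exc:
            report["failed_stage"] = stage
            _finish(outdir, config, report, artifacts)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finish(outdir, config, report, artifacts)
    return report


def _finish(outdir: Path, config: RunConfig, report: dict, artifacts: list[Path]) -> None:
    rpath = outdir / "report.json"
    rpath.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True, default=str))
    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts + [rpath]))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
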
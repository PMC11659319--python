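"""End-to-end pipeline runner.

Stages (any subset, in fixed order): ``simulate`` -> ``features`` ->
``score`` -> ``associate`` -> ``sweep`` -> ``crossval`` -> ``report``.
Outputs are CSVs in the run directory plus a machine-readable manifest
(versions, seed, per-file SHA-256 digests, stage timings) and a
human-readable markdown report with the association, sweep and CV tables.
Logging goes to standard error; analysis output only to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import compare_age_groups, run_association_suite
from .crossval import ALLOWED_K, CVConfig, cv_sweep
from .io import load_source_data, read_cohort, write_cohort
from .roc import SweepConfig, chance_band, run_sweep
from .schema import COMPOSITE_COLUMN, ParameterError, PipelineError
from .scoring import build_cognitive_scores
from .synthetic import default_params, generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "score", "associate", "sweep", "crossval", "report")
SWEEP_PREDICTORS = ("wave_v_latency", "wave_v_amplitude")


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str | Path = "abrcog_run"
    cohort_path: str | Path | None = None  # existing cohort CSV
    source_data_path: str | Path | None = None  # deposited workbook
    column_map_path: str | Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_participants: int | None = None  # None => study-sized default cohort
    cv_k: tuple[int, ...] = (2,)
    chance_replicates: int = 1000
    allow_any_k: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ParameterError(f"unknown stages {unknown}; allowed: {ALL_STAGES}")
        for k in self.cv_k:
            if k not in ALLOWED_K and not self.allow_any_k:
                raise ParameterError(
                    f"cv_k={k} outside the study set {ALLOWED_K}; set allow_any_k to override"
                )
        if self.cohort_path is None and self.source_data_path is None and "simulate" not in self.stages:
            raise ParameterError("no input: provide cohort_path, source_data_path or the simulate stage")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        for key in ("stages", "cv_k"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    python: str = platform.python_version()
    stages: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # relative path -> sha256
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest as a dict.

    A stage failure raises :class:`PipelineError` naming the stage; partial
    outputs stay on disk next to a ``FAILED`` marker.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    outputs: dict[str, Path] = {}
    results: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:
            manifest.failed_stage = name
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            _write_manifest(manifest, outputs, outdir)
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest.stages.append(name)
        manifest.timings_s[name] = round(time.perf_counter() - t0, 4)
        logger.info("stage %s: done in %.2fs", name, manifest.timings_s[name])

    state: dict = {}

    def stage_simulate():
        if config.source_data_path is not None:
            state["cohort"] = load_source_data(
                config.source_data_path, config.column_map_path
            )
        elif config.cohort_path is not None:
            state["cohort"] = read_cohort(config.cohort_path)
        else:
            params = default_params(n_total=config.n_participants, seed=config.seed)
            state["cohort"], _ = generate_cohort(params)
        outputs["cohort.csv"] = write_cohort(state["cohort"], outdir / "cohort.csv")
        manifest.record_counts["cohort"] = len(state["cohort"])

    def stage_score():
        if "cohort" not in state:
            state["cohort"] = read_cohort(config.cohort_path) if config.cohort_path else None
            if state["cohort"] is None:
                raise PipelineError("score stage needs a cohort (run simulate or pass cohort_path)")
        scored = build_cognitive_scores(state["cohort"])
        state["scored"] = scored
        outputs["scored_cohort.csv"] = write_cohort(scored, outdir / "scored_cohort.csv")
        manifest.record_counts["scored"] = len(scored)

    def stage_associate():
        scored = state["scored"]
        suite = run_association_suite(scored)
        state["associations"] = suite
        path = outdir / "associations.csv"
        suite.to_csv(path, index=False)
        outputs["associations.csv"] = path
        groups = compare_age_groups(scored, COMPOSITE_COLUMN)
        path = outdir / "age_group_comparison.json"
        path.write_text(json.dumps(groups, indent=2, default=float))
        outputs["age_group_comparison.json"] = path
        manifest.record_counts["association_models"] = len(suite)

    def stage_sweep():
        scored = state["scored"]
        state["sweeps"] = {}
        for predictor in SWEEP_PREDICTORS:
            for adjust in (False, True):
                cfg = SweepConfig.for_predictor(
                    predictor, adjust_age=adjust, seed=config.seed,
                    chance_replicates=config.chance_replicates,
                )
                curve = run_sweep(scored, cfg)
                tag = f"{predictor}_{'adj' if adjust else 'raw'}"
                state["sweeps"][tag] = curve
                path = outdir / f"sweep_{tag}.csv"
                curve.table.to_csv(path, index=False)
                outputs[path.name] = path
        band = chance_band(
            scored,
            SweepConfig.for_predictor(
                SWEEP_PREDICTORS[0], seed=config.seed,
                chance_replicates=config.chance_replicates,
            ),
        )
        state["chance_band"] = band
        path = outdir / "chance_band.csv"
        pd.DataFrame(
            {"replicate": np.arange(band.replicate_means.size), "mean_auc": band.replicate_means}
        ).to_csv(path, index=False)
        outputs["chance_band.csv"] = path

    def stage_crossval():
        scored = state["scored"]
        state["cv"] = {}
        for k in config.cv_k:
            for predictor in SWEEP_PREDICTORS:
                for adjust in (False, True):
                    cfg = CVConfig(
                        k=k, predictor=predictor,
                        orientation=SweepConfig.for_predictor(predictor).orientation,
                        adjust_age=adjust, seed=config.seed,
                        allow_any_k=config.allow_any_k,
                    )
                    result = cv_sweep(scored, cfg)
                    tag = f"{predictor}_{'adj' if adjust else 'raw'}_k{k}"
                    state["cv"][tag] = result
                    path = outdir / f"crossval_{tag}.csv"
                    result.table.to_csv(path, index=False)
                    outputs[path.name] = path

    def stage_report():
        path = outdir / "report.md"
        path.write_text(_render_report(state, manifest))
        outputs["report.md"] = path

    stage_fns = {
        "simulate": stage_simulate,
        "score": stage_score,
        "associate": stage_associate,
        "sweep": stage_sweep,
        "crossval": stage_crossval,
        "report": stage_report,
    }
    for name in ALL_STAGES:
        if name in config.stages:
            run_stage(name, stage_fns[name])

    results = _write_manifest(manifest, outputs, outdir)
    return results


def _write_manifest(manifest: RunManifest, outputs: dict[str, Path], outdir: Path) -> dict:
    manifest.outputs = {name: _digest(p) for name, p in sorted(outputs.items())}
    (outdir / "manifest.json").write_text(manifest.to_json())
    return json.loads(manifest.to_json())


def _fmt_auc_summary(summary: dict) -> str:
    return (
        f"mean {summary['mean_auc']:.3f} ± {summary['sd_auc']:.3f} "
        f"(range {summary['min_auc']:.3f}–{summary['max_auc']:.3f}, "
        f"peak at percentile {summary['argmax_percentile']})"
    )


def _render_report(state: dict, manifest: RunManifest) -> str:
    lines = ["# ABR–cognition analysis report", ""]
    lines.append(f"- package version: {manifest.version}, seed: {manifest.seed}")
    if "cohort" in state:
        lines.append(f"- participants: {len(state['cohort'])}")
    lines.append("")
    if "associations" in state:
        lines.append("## Association models (full sample, composite outcome)")
        lines.append("")
        suite = state["associations"]
        sub = suite[(suite["outcome"] == COMPOSITE_COLUMN) & (suite["subgroup"] == "full")]
        lines.append(sub.to_markdown(index=False, floatfmt=".4f"))
        lines.append("")
    if "sweeps" in state:
        lines.append("## Percentile ROC sweeps")
        lines.append("")
        for tag, curve in state["sweeps"].items():
            lines.append(f"- **{tag}**: {_fmt_auc_summary(curve.summary)}")
        if "chance_band" in state:
            band = state["chance_band"]
            lines.append(
                f"- **chance band**: mean {band.mean:.3f}, "
                f"sd between replicates {band.sd_between_replicates:.3f}, "
                f"sd across percentiles {band.sd_across_percentiles:.3f}"
            )
        lines.append("")
    if "cv" in state:
        lines.append("## Cross-validated LDA sweeps")
        lines.append("")
        for tag, result in state["cv"].items():
            s = result.summary
            lines.append(
                f"- **{tag}**: mean AUC {s['mean_auc']:.3f} ± {s['sd_auc']:.3f} "
                f"({s['n_missing_percentiles']} missing percentiles)"
            )
        lines.append("")
    return "\n".join(lines)


def reproduction_run(
    source_data_path: str | Path,
    outdir: str | Path,
    column_map_path: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Convenience wrapper: full pipeline on the deposited source data."""
    config = PipelineConfig(
        outdir=outdir,
        source_data_path=source_data_path,
        column_map_path=column_map_path,
        seed=seed,
    )
    return run_pipeline(config)
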
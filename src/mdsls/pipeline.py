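"""End-to-end orchestration: simulate -> screen -> select -> fit -> score
-> probability -> flag, reproducible from (config, seed)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import flags as flags_mod
from . import probability as prob_mod
from .registry import build_default_registry
from .score import fit_score_model, score_cohort, evaluate
from .selection import CriticalParameterSelector
from .synth import (analysis_parameters, default_cohort_spec, generate_cohort,
                    read_cohort_csv, write_cohort_csv)

logger = logging.getLogger("mdsls")


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline knobs; every default equals the published design."""

    seed: int = 0
    cohort_path: str | None = None  # None -> simulate
    n_mds: int = 101
    n_healthy: int = 88
    effect_d: float = 1.5
    top_k: int = 12
    cos2_threshold: float = 0.6
    n_iterations: int = 10_000
    learn_size: int = 130
    flag_overrides: dict = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    screening: pd.DataFrame
    lists: "object"
    model: "object"
    scores: pd.DataFrame
    curve: "object"
    flag_reports: pd.DataFrame
    flag_summary: dict
    performance: "object"


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full score-construction pipeline.

    When ``out_dir`` is given, every artifact (cohort, screening table,
    selection lists, model document, probability curve, flag report, run
    manifest) is written there; file headers carry the config digest.
    """
    registry = build_default_registry()

    if config.cohort_path:
        cohort = _stage("load")(read_cohort_csv, config.cohort_path)
    else:
        spec = default_cohort_spec(registry, effect_d=config.effect_d,
                                   n_mds=config.n_mds,
                                   n_healthy=config.n_healthy,
                                   seed=config.seed)
        cohort = _stage("simulate")(generate_cohort, spec)
    params = analysis_parameters(cohort, registry)
    logger.info("analyzing %d parameters over %d subjects",
                len(params), len(cohort))

    selector = CriticalParameterSelector(k=config.top_k,
                                         cos2_threshold=config.cos2_threshold)
    _stage("select")(selector.fit, cohort[params], cohort["group"])
    selected = selector.selected_parameters_
    logger.info("selected %d critical parameters: %s", len(selected), selected)

    model = _stage("fit")(fit_score_model, cohort, selected,
                          n_iterations=config.n_iterations,
                          learn_size=config.learn_size, seed=config.seed)
    scores = _stage("score")(score_cohort, cohort, model)
    performance = evaluate(cohort, model)

    curve = _stage("probability")(
        prob_mod.fit_probability_curve,
        scores["mds_ls"].to_numpy(), scores["group"].to_numpy())

    rules = flags_mod.default_flag_rules()
    for label, (name, cmp_, thr) in config.flag_overrides.items():
        rules.append(flags_mod.FlagRule(name, cmp_, thr, label))
    reports = []
    flaggable = all(r.parameter_name in cohort.columns for r in rules)
    if flaggable:
        for (_, row), mds_ls in zip(cohort.iterrows(), scores["mds_ls"]):
            reports.append(_stage("flag")(
                flags_mod.apply_flags, row, rules, mds_ls))
    flag_frame = flags_mod.reports_to_frame(reports)
    summary = flags_mod.cohort_flag_summary(reports)

    result = PipelineResult(cohort=cohort, screening=selector.screening_,
                            lists=selector.lists_, model=model,
                            scores=scores, curve=curve,
                            flag_reports=flag_frame, flag_summary=summary,
                            performance=performance)
    if out_dir is not None:
        _write_bundle(result, config, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig,
                  out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    write_cohort_csv(result.cohort, out_dir / "cohort.csv")
    result.screening.to_csv(out_dir / "screening.csv", index=False)
    result.lists.membership_table().to_csv(
        out_dir / "selection_lists.csv", index=False)
    result.model.save(out_dir / "score_model.json")
    with open(out_dir / "probability_curve.json", "w") as fh:
        json.dump(result.curve.to_document(), fh, indent=2)
    result.scores.to_csv(out_dir / "scores.csv", index=False)
    result.flag_reports.to_csv(out_dir / "flag_report.csv", index=False)
    perf = result.performance
    manifest = {
        "config": asdict(config),
        "config_digest": digest,
        "n_parameters_analyzed": int(len(result.screening)),
        "selected_parameters": list(result.lists.intersection),
        "mean_efficiency": float(result.model.efficiencies_.mean()),
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "ppv": perf.ppv,
        "npv": perf.npv,
        "flag_summary": result.flag_summary,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
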
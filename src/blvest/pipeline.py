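"""End-to-end orchestration: simulate -> window/featurize -> cross-validate
-> evaluate -> report.

Stages persist their outputs under a run directory (features as CSV,
cross-validation predictions per model variant, report tables, and a JSON
manifest of seeds and configuration), so each stage can be re-run from
the previous stage's files.  Everything derives from one master seed:
identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SimConfig, SubjectRecord, generate_cohort, reference_blv
from .evaluate import (
    compare_hct_vs_model,
    render_report,
    summarize_errors,
    summarize_hct_comparison,
)
from .features import extract_cohort_features
from .models import CVResult, ModelSpec, loao_cv, rank_features

__all__ = ["RunConfig", "run_all", "simulate_stage", "extract_stage", "evaluate_stage", "report_stage"]

log = logging.getLogger("blvest")


@dataclass
class RunConfig:
    """Fully serializable description of one end-to-end run."""

    n_subjects: int = 40
    seed: int = 0
    window_s: float = 60.0
    hop_s: float = 30.0
    modalities: tuple[str, ...] = ("PPG", "ABP", "PPG&ABP")
    normalizations: tuple[str, ...] = ("person", "group")
    methods: tuple[str, ...] = ("RF", "LASSO")
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "blvest_run"
    save_signals: bool = False
    make_plots: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (d.pop("sim", {}) or {}).items()
        })
        for key in ("modalities", "normalizations", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sim=sim, **d)


def _variant_name(method: str, modality: str, normalization: str) -> str:
    mod = modality.replace("&", "_").lower()
    return f"{method.lower()}_{mod}_{normalization}"


def simulate_stage(config: RunConfig, out_dir: Path) -> list[SubjectRecord]:
    t0 = time.time()
    cohort = generate_cohort(config.n_subjects, config.sim, config.seed)
    log.info("simulated %d subjects in %.1f s", len(cohort), time.time() - t0)
    if config.save_signals:
        from .windows import write_record

        for rec in cohort:
            write_record(rec, out_dir / "cohort" / rec.subject_id)
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "weight_kg": [r.weight for r in cohort],
            "ebv_ml": [r.ebv for r in cohort],
            "baseline_s": [r.baseline_duration for r in cohort],
            "duration_s": [r.duration for r in cohort],
            "final_blv_ml": [reference_blv(r.duration, r.bleed_schedule) for r in cohort],
        }
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out_dir / "subjects.csv", index=False, float_format="%.6g")
    return cohort


def extract_stage(config: RunConfig, cohort: list[SubjectRecord], out_dir: Path) -> pd.DataFrame:
    t0 = time.time()
    feats = extract_cohort_features(cohort, config.window_s, config.hop_s)
    log.info(
        "featurized %d windows (%d dropped for artifacts, %d unusable) in %.1f s",
        len(feats),
        feats.attrs.get("n_dropped_artifact", 0),
        feats.attrs.get("n_dropped_unusable", 0),
        time.time() - t0,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    feats.to_csv(out_dir / "features.csv", index=False, float_format="%.8g")
    return feats


def evaluate_stage(config: RunConfig, feats: pd.DataFrame, out_dir: Path) -> dict[str, CVResult]:
    results: dict[str, CVResult] = {}
    for method in config.methods:
        for modality in config.modalities:
            for norm in config.normalizations:
                name = _variant_name(method, modality, norm)
                t0 = time.time()
                spec = ModelSpec(method=method, modality=modality, normalization=norm, seed=config.seed)
                cv = loao_cv(spec, feats)
                results[name] = cv
                cv.predictions.to_csv(
                    out_dir / f"cv_{name}.csv", index=False, float_format="%.6g"
                )
                log.info("variant %s: %d predictions in %.1f s", name, len(cv.predictions), time.time() - t0)
    return results


def report_stage(
    config: RunConfig,
    cohort: list[SubjectRecord],
    results: dict[str, CVResult],
    out_dir: Path,
) -> list[Path]:
    ebv = {r.subject_id: r.ebv for r in cohort}
    severity = {name: summarize_errors(cv, ebv) for name, cv in results.items()}

    hct_summary = None
    ref_name = _variant_name("RF", "PPG&ABP", "person")
    ref_cv = results.get(ref_name) or next(iter(results.values()))
    hct_table = compare_hct_vs_model(ref_cv, cohort, window_s=config.window_s)
    if len(hct_table):
        hct_summary = summarize_hct_comparison(hct_table)

    def _rank_table(method: str) -> pd.DataFrame | None:
        parts = []
        for name, cv in results.items():
            if cv.spec.method != method:
                continue
            r = rank_features(cv)[["feature", "rank"]].rename(columns={"rank": name})
            parts.append(r.set_index("feature"))
        if not parts:
            return None
        return pd.concat(parts, axis=1).reset_index()

    return render_report(
        out_dir,
        severity_tables=severity,
        hct_table=hct_summary,
        lasso_ranks=_rank_table("LASSO"),
        rf_ranks=_rank_table("RF"),
        cv_results=results,
        make_plots=config.make_plots,
    )


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Produces the cohort summary, the feature matrix, per-variant
    cross-validation predictions for every modality x normalization under
    each requested method, the severity/HCT/ranking tables, and a
    manifest recording the configuration and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = simulate_stage(config, out_dir)
    feats = extract_stage(config, cohort, out_dir)
    results = evaluate_stage(config, feats, out_dir)
    report_stage(config, cohort, results, out_dir)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "variants": sorted(results.keys()),
        "n_windows": int(len(feats)),
        "elapsed_s": round(time.time() - t0, 1),
        "config": dataclasses.asdict(config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    config.to_yaml(out_dir / "run_config.yaml")
    return out_dir
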
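"""End-to-end orchestration: simulate -> score -> recalibrate -> validate
-> eligibility -> disparity -> report.

Each stage reads/writes delimited-text artifacts under one output
directory, so stages are individually invocable and composable; the files
are the only inter-stage contract.  All randomness flows from one root
seed, expanded deterministically per stage, and a run manifest records the
configuration, input checksums and per-stage record counts.  Re-running
with the same configuration and seed reproduces every output
byte-identically (wall-clock timestamps go to the log, not to outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    OVERALL,
    RISK_BASED,
    USPSTF_2013,
    USPSTF_2021,
    AnalysisConfig,
    GroupCountsTable,
    load_packaged_counts,
    read_cohort,
    read_group_counts,
    write_cohort,
)
from .disparity import (
    disparity_table,
    ei_results_frame,
    performance_frame,
    performance_table,
)
from .eligibility import (
    USPSTF_2013_RULE,
    USPSTF_2021_RULE,
    eligible_mask,
    match_threshold,
    risk_criterion,
)
from .recalibration import crossfit_predictions, fit_race_recalibration
from .risk_models import (
    load_coefficients,
    packaged_model_path,
    save_coefficients,
    score_cohort,
)
from .synthetic_cohort import SyntheticSpec, generate_cohort
from .validation_metrics import grouped_validation

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "simulate",
    "score",
    "recalibrate",
    "validate",
    "eligibility",
    "disparity",
    "report",
)


class PipelineError(RuntimeError):
    pass


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise PipelineError("pipeline config must be a mapping")
    return doc


def _resolve_model(name_or_path: str):
    if name_or_path in ("original", "race3l"):
        path = packaged_model_path(name_or_path)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise PipelineError(f"coefficient file not found: {path}")
    return load_coefficients(path), path


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    ``config`` is a mapping (or path to a YAML file) with optional
    per-stage sections; ``out_dir`` and ``seed`` override the config.
    """
    t0 = time.time()
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = dict(config)
    out = Path(out_dir if out_dir is not None else config.get("output_dir", "lungscreen_out"))
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(seed if seed is not None else config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": root_seed,
        "config": _jsonable(config),
        "stages": stages,
        "input_checksums": {},
        "record_counts": {},
    }

    cohort = None
    base_model = None
    base_model_path = None
    scores = None
    recal = None
    crossfit = None
    risks_for_eligibility = None
    counts: GroupCountsTable | None = None
    masks: dict[str, np.ndarray] = {}
    ei_results = None
    perf_results = None

    # --- simulate (or load) ------------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    if "simulate" in stages:
        spec = SyntheticSpec(
            n=int(sim_cfg.get("n", 20000)),
            seed=stage_seed(root_seed, "simulate"),
            target_incidence=float(sim_cfg.get("target_incidence", 0.014)),
        )
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort.csv")
        manifest["record_counts"]["simulate"] = len(cohort)
        logger.info("simulated %d records", len(cohort))
    elif "cohort_file" in config:
        cohort_path = Path(config["cohort_file"])
        cohort, rejects = read_cohort(cohort_path, schema=config.get("schema"))
        manifest["input_checksums"][cohort_path.name] = _sha256(cohort_path)
        manifest["record_counts"]["read_cohort"] = len(cohort)
        manifest["record_counts"]["rejected_rows"] = len(rejects)
        if len(rejects):
            rejects.to_csv(out / "rejected_rows.csv", index=False)

    def need_cohort(stage: str):
        if cohort is None:
            raise PipelineError(f"stage {stage!r} needs a cohort (simulate or cohort_file)")

    # --- score --------------------------------------------------------------
    if "score" in stages:
        need_cohort("score")
        base_model, base_model_path = _resolve_model(
            str(config.get("score", {}).get("model", "original"))
        )
        manifest["input_checksums"][base_model_path.name] = _sha256(base_model_path)
        scores = score_cohort(cohort, base_model)
        scores.to_csv(out / "scores.csv", index=False)
        manifest["record_counts"]["score"] = len(scores)

    # --- recalibrate ---------------------------------------------------------
    if "recalibrate" in stages:
        need_cohort("recalibrate")
        if base_model is None:
            base_model, base_model_path = _resolve_model("original")
            manifest["input_checksums"][base_model_path.name] = _sha256(base_model_path)
        recal = fit_race_recalibration(cohort, base_model)
        save_coefficients(recal.updated_model, out / "recalibrated_model.yaml")
        est = pd.DataFrame(
            [
                {"parameter": k, "estimate": v[0], "se": v[1]}
                for k, v in recal.estimates.items()
            ]
        )
        est.to_csv(out / "recalibration_estimates.csv", index=False)
        manifest["record_counts"]["recalibrate"] = len(cohort)
        manifest["recalibration"] = {
            "converged": recal.converged,
            "n_iterations": recal.n_iterations,
            "log_likelihood": recal.log_likelihood,
            "separated": list(recal.separated),
        }

    # --- validate (10-fold CV of the recalibration) --------------------------
    if "validate" in stages:
        need_cohort("validate")
        if base_model is None:
            base_model, _ = _resolve_model("original")
        val_cfg = dict(config.get("validate", {}))
        folds = int(val_cfg.get("folds", 10))
        crossfit = crossfit_predictions(
            cohort, base_model, folds=folds, seed=stage_seed(root_seed, "validate")
        )
        crossfit.to_csv(out / "crossfit_scores.csv", index=False)
        reports = grouped_validation(
            cohort,
            crossfit["risk"].to_numpy(),
            bins=int(val_cfg.get("bins", 10)),
            n_boot=int(val_cfg.get("bootstrap_reps", 2000)),
            seed=stage_seed(root_seed, "validate_boot"),
        )
        rows, cal_rows = [], []
        for r in reports:
            rows.append(
                {
                    "group": r.group, "n": r.n, "events": r.events,
                    "auc": r.auc, "auc_ci_lo": r.auc_ci[0], "auc_ci_hi": r.auc_ci[1],
                    "brier": r.brier, "calibration_slope": r.calibration_slope,
                }
            )
            d = r.calibration_deciles.copy()
            d.insert(0, "group", r.group)
            cal_rows.append(d)
        pd.DataFrame(rows).to_csv(out / "validation.csv", index=False)
        pd.concat(cal_rows, ignore_index=True).to_csv(
            out / "calibration_bins.csv", index=False
        )
        manifest["record_counts"]["validate"] = len(crossfit)

    # --- eligibility ----------------------------------------------------------
    if "eligibility" in stages:
        need_cohort("eligibility")
        elig_cfg = dict(config.get("eligibility", {}))
        model_for_risk = recal.updated_model if recal is not None else base_model
        if model_for_risk is None:
            model_for_risk, _ = _resolve_model("original")
        risk_scores = score_cohort(cohort, model_for_risk)["risk"].to_numpy()
        risks_for_eligibility = risk_scores

        criteria = [USPSTF_2021_RULE, USPSTF_2013_RULE]
        thresholds = list(elig_cfg.get("risk_thresholds", [0.013]))
        if elig_cfg.get("match_threshold_to"):
            target_rule = {
                USPSTF_2021: USPSTF_2021_RULE,
                USPSTF_2013: USPSTF_2013_RULE,
            }[elig_cfg["match_threshold_to"]]
            target_count = int(eligible_mask(cohort, target_rule).sum())
            t = match_threshold(
                risk_scores, cohort["age"].to_numpy(), target_count
            )
            thresholds = [t] + [x for x in thresholds if x != t]
            manifest["matched_threshold"] = t
        risk_crits = [risk_criterion(t, model_name=model_for_risk.model_name) for t in thresholds]
        criteria += risk_crits

        per_record = pd.DataFrame({"id": cohort["id"].to_numpy()})
        for crit in criteria:
            r = risk_scores if crit.kind == "risk_threshold" else None
            m = eligible_mask(cohort, crit, r)
            masks[crit.name] = m
            per_record[crit.name] = m.astype(int)
        per_record.to_csv(out / "eligibility_records.csv", index=False)

        from .eligibility import eligibility_summary

        counts = eligibility_summary(
            cohort, criteria, {c.name: risk_scores for c in risk_crits}
        )
        counts.write(out / "group_counts.csv")
        manifest["record_counts"]["eligibility"] = len(per_record)

    # --- disparity -------------------------------------------------------------
    if "disparity" in stages:
        disp_cfg = dict(config.get("disparity", {}))
        acfg = AnalysisConfig(
            reference_group=disp_cfg.get("reference_group", "white"),
            rng_seed=root_seed,
        )
        if disp_cfg.get("counts_file") == "packaged":
            counts = load_packaged_counts()
        elif disp_cfg.get("counts_file"):
            cpath = Path(disp_cfg["counts_file"])
            counts = read_group_counts(cpath)
            manifest["input_checksums"][cpath.name] = _sha256(cpath)
        if counts is None:
            raise PipelineError(
                "disparity stage needs group counts (eligibility stage or counts_file)"
            )
        ei_results = disparity_table(counts, acfg)
        ei_results_frame(ei_results).to_csv(out / "ei_results.csv", index=False)
        manifest["record_counts"]["disparity"] = len(ei_results)
        if cohort is not None and masks:
            perf_results = performance_table(cohort, masks)
            performance_frame(perf_results).to_csv(out / "performance.csv", index=False)

    # --- report -----------------------------------------------------------------
    if "report" in stages:
        _write_report(out, manifest, ei_results, perf_results)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.1f s -> %s", time.time() - t0, out)
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(out: Path, manifest, ei_results, perf_results) -> None:
    lines = ["# Screening eligibility and disparity report", ""]
    lines.append(f"Seed: {manifest['seed']}; stages: {', '.join(manifest['stages'])}.")
    lines.append("")
    if ei_results:
        lines.append("## Eligibility-incidence (E-I) ratios")
        lines.append("")
        lines.append(
            "| criterion | group | eligible | cases | E-I ratio | % diff vs ref | p | significant |"
        )
        lines.append("|---|---|---|---|---|---|---|---|")
        for r in ei_results:
            pct = (
                f"{r.percent_difference_vs_reference:+.1f}"
                if r.percent_difference_vs_reference is not None
                else ""
            )
            p = f"{r.p_value:.3g}" if r.p_value is not None else ""
            sig = "" if r.significant_after_bonferroni is None else (
                "yes" if r.significant_after_bonferroni else "no"
            )
            lines.append(
                f"| {r.criterion} | {r.group} | {r.eligible} | {r.incident_cases} "
                f"| {r.ei_ratio_rounded:.1f} | {pct} | {p} | {sig} |"
            )
        lines.append("")
    if perf_results:
        lines.append("## Screening performance")
        lines.append("")
        lines.append("| criterion | group | sensitivity % | specificity % | NNS |")
        lines.append("|---|---|---|---|---|")
        for r in perf_results:
            nns = f"{r.nns_rounded}" if r.nns_rounded >= 0 else "inf"
            lines.append(
                f"| {r.criterion} | {r.group} | {r.sensitivity:.1f} "
                f"| {r.specificity:.1f} | {nns} |"
            )
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
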
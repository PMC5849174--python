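"""End-to-end pipeline orchestration.

A single YAML/JSON config drives the whole workflow: load or simulate two
cohorts -> sample/SNP QC on the training cohort -> per-SNP association
(unadjusted and age-adjusted) -> LD matrix -> PRS models (model1/2/3 x two
weight sources) -> scoring and quartile/trend/AUC evaluation on the
independent evaluation cohort.  Every stage writes its table to the output
directory and a run manifest records config hash, seed, input digests and
per-stage row counts, so any number in the final report is recomputable
from logged intermediates.

Weights always come from the training cohort; evaluating on the training
cohort itself is refused unless the config sets
``prs.allow_same_cohort: true``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from polyrisk import association, ld, prs, qc, synthetic_data
from polyrisk.association import association_frame, associate_all
from polyrisk.genotype_io import (
    GenotypeMatrix,
    PhenotypeTable,
    join_cohort,
    read_genotypes,
    read_manifest,
    read_phenotypes,
)
from polyrisk.qc import QcConfig, qc_report_frame

__all__ = ["validate_config", "run_pipeline", "load_config", "PipelineResult"]

logger = logging.getLogger("polyrisk.pipeline")

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "": {"seed": int, "simulate": dict, "inputs": dict, "qc": dict, "association": dict,
         "ld": dict, "prs": dict},
    "simulate": {"preset": str, "all_null": bool, "n_cases_1": int, "n_controls_1": int,
                 "n_cases_2": int, "n_controls_2": int, "block_r2": float,
                 "missing_rate": float, "prevalence": float, "age_risk_slope": float},
    "qc": {"call_rate_threshold": float, "maf_threshold": float,
           "hwe_p_threshold": float, "hwe_method": str},
    "association": {"alpha": float},
    "ld": {"threshold": float},
    "prs": {"missing_policy": str, "cutpoint_source": str, "allow_same_cohort": bool},
    "inputs": {"train": dict, "eval": dict, "manifest": str},
}
_COHORT_KEYS = {"genotypes": str, "dialect": str, "phenotypes": str, "status_dialect": str}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def validate_config(config: Mapping[str, Any] | str | Path) -> list[str]:
    """Schema-check a config; returns a list of violations (empty = ok).

    Unknown keys are rejected so typos never pass silently.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    v: list[str] = []

    def check_section(section: Mapping, schema: Mapping, prefix: str) -> None:
        for key, val in section.items():
            if key not in schema:
                v.append(f"unknown key {prefix}{key}")
                continue
            want = schema[key]
            if want is float:
                ok = isinstance(val, (int, float)) and not isinstance(val, bool)
            elif want is int:
                ok = isinstance(val, int) and not isinstance(val, bool)
            else:
                ok = isinstance(val, want)
            if not ok:
                v.append(f"{prefix}{key}: expected {getattr(want, '__name__', want)}")

    check_section(config, _SCHEMA[""], "")
    if "seed" not in config:
        v.append("missing required key: seed")
    has_sim = isinstance(config.get("simulate"), dict)
    has_inp = isinstance(config.get("inputs"), dict)
    if has_sim == has_inp:
        v.append("exactly one of 'simulate' or 'inputs' must be given")
    for name in ("simulate", "qc", "association", "ld", "prs", "inputs"):
        if isinstance(config.get(name), dict):
            check_section(config[name], _SCHEMA[name], f"{name}.")
    if has_inp:
        inputs = config["inputs"]
        if "manifest" not in inputs:
            v.append("inputs.manifest is required")
        for side in ("train", "eval"):
            sub = inputs.get(side)
            if not isinstance(sub, dict):
                v.append(f"inputs.{side} is required")
                continue
            check_section(sub, _COHORT_KEYS, f"inputs.{side}.")
            for req in ("genotypes", "phenotypes"):
                if req not in sub:
                    v.append(f"inputs.{side}.{req} is required")
    qc_cfg = config.get("qc", {})
    for key in ("call_rate_threshold", "maf_threshold", "hwe_p_threshold"):
        val = qc_cfg.get(key)
        if isinstance(val, (int, float)) and not 0 <= val <= 1:
            v.append(f"qc.{key}={val} outside [0, 1]")
    ld_t = config.get("ld", {}).get("threshold")
    if isinstance(ld_t, (int, float)) and not 0 <= ld_t <= 1:
        v.append(f"ld.threshold={ld_t} outside [0, 1]")
    for key, allowed in (
        ("missing_policy", {"impute_control_freq", "renormalize"}),
        ("cutpoint_source", {"controls", "combined"}),
    ):
        val = config.get("prs", {}).get(key)
        if isinstance(val, str) and val not in allowed:
            v.append(f"prs.{key}={val!r} not in {sorted(allowed)}")
    return v


@dataclasses.dataclass
class PipelineResult:
    """In-memory results of a full run (everything is also on disk)."""

    out_dir: Path
    qc_results: list[qc.SnpQcResult]
    assoc_unadj: list[association.AssocResult]
    assoc_adj: list[association.AssocResult]
    evaluations: dict[str, prs.PrsEvaluation]
    skipped_models: dict[str, str]
    manifest: dict


def _digest(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_cohorts(config: Mapping) -> tuple[GenotypeMatrix, PhenotypeTable,
                                            GenotypeMatrix, PhenotypeTable, dict]:
    digests: dict[str, str] = {}
    if "simulate" in config:
        sim = dict(config["simulate"])
        preset = sim.pop("preset", "paper_like")
        if preset != "paper_like":
            raise ValueError(f"unknown simulation preset {preset!r}")
        sim_cfg = synthetic_data.paper_like_panel(seed=config["seed"], **sim)
        c1, c2 = synthetic_data.simulate_cohort(sim_cfg)
        digests["sim_config"] = _digest(dataclasses.asdict(sim_cfg))
        return c1.gm, c1.phen, c2.gm, c2.phen, digests
    inputs = config["inputs"]
    manifest = read_manifest(inputs["manifest"])
    digests["manifest"] = _file_digest(Path(inputs["manifest"]))
    out = []
    for side in ("train", "eval"):
        sub = inputs[side]
        gm = read_genotypes(sub["genotypes"], sub.get("dialect", "tsv"), manifest)
        phen = read_phenotypes(sub["phenotypes"], sub.get("status_dialect", "case_control"))
        gm, phen, report = join_cohort(gm, phen)
        if report.genotype_only or report.phenotype_only:
            logger.info(
                "%s cohort join: %d joined, %d genotype-only, %d phenotype-only",
                side, report.n_joined, len(report.genotype_only), len(report.phenotype_only),
            )
        digests[f"{side}_genotypes"] = _file_digest(Path(sub["genotypes"]))
        digests[f"{side}_phenotypes"] = _file_digest(Path(sub["phenotypes"]))
        out += [gm, phen]
    return out[0], out[1], out[2], out[3], digests


def _evaluation_report(evaluations: dict[str, prs.PrsEvaluation],
                       skipped: dict[str, str], settings: dict) -> dict:
    report: dict[str, Any] = {"settings": settings, "models": {}}
    for name, ev in sorted(evaluations.items()):
        rows = []
        for r in ev.quartiles.rows:
            rows.append(
                {
                    "quartile": r.quartile,
                    "n_controls": r.n_controls,
                    "n_cases": r.n_cases,
                    "or": None if r.quartile == 1 else r.or_,
                    "ci95": list(r.ci95) if r.ci95 else None,
                    "p": r.p,
                    "flagged": r.flagged,
                }
            )
        report["models"][name] = {
            "n_snps": ev.model.n_snps,
            "weight_source": ev.model.weight_source,
            "quartiles": rows,
            "cutpoints": list(ev.quartiles.cutpoints),
            "trend": {"or": ev.trend.or_, "ci95": list(ev.trend.ci95), "p": ev.trend.p},
            "auc": {"value": ev.auc.auc, "ci95": list(ev.auc.ci95)},
        }
    report["skipped_models"] = dict(sorted(skipped.items()))
    return report


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> PipelineResult:
    """Execute the full workflow under ``config``, writing to ``out_dir``."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gm_train, phen_train, gm_eval, phen_eval, digests = _load_cohorts(config)
    if not config.get("prs", {}).get("allow_same_cohort", False):
        overlap = set(gm_train.sample_ids) & set(gm_eval.sample_ids)
        if overlap:
            raise ValueError(
                f"training and evaluation cohorts share {len(overlap)} samples; "
                "set prs.allow_same_cohort to evaluate in-sample"
            )
    counts = {"train_samples_in": gm_train.n_samples, "eval_samples_in": gm_eval.n_samples,
              "snps_in": gm_train.n_snps}

    qc_cfg = QcConfig(**config.get("qc", {}))
    gm_train, dropped = qc.apply_sample_filter(gm_train, qc_cfg)
    phen_train = phen_train.aligned_to(gm_train.sample_ids)
    gm_eval, dropped_eval = qc.apply_sample_filter(gm_eval, qc_cfg)
    phen_eval = phen_eval.aligned_to(gm_eval.sample_ids)
    logger.info("sample QC: dropped %d train / %d eval samples", len(dropped), len(dropped_eval))
    gm_train, qc_results = qc.apply_snp_filters(gm_train, phen_train, qc_cfg)
    qc_report_frame(qc_results).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    gm_eval = gm_eval.subset(snp_ids=[s for s in gm_train.snp_ids if s in gm_eval.snp_ids])
    counts.update(train_samples_qc=gm_train.n_samples, eval_samples_qc=gm_eval.n_samples,
                  snps_qc=gm_train.n_snps)
    logger.info("SNP QC: %d of %d SNPs pass", gm_train.n_snps, counts["snps_in"])

    assoc_unadj = associate_all(gm_train, phen_train, adjust_age=False)
    assoc_adj = associate_all(gm_train, phen_train, adjust_age=True)
    association_frame(assoc_unadj).to_csv(out / "assoc_unadjusted.tsv", sep="\t", index=False)
    association_frame(assoc_adj).to_csv(out / "assoc_adjusted.tsv", sep="\t", index=False)

    ld_mat = ld.ld_matrix(gm_train)
    pd.DataFrame(ld_mat.r2, index=ld_mat.snp_ids, columns=ld_mat.snp_ids).to_csv(
        out / "ld_matrix.tsv", sep="\t"
    )

    alpha = config.get("association", {}).get("alpha", 0.05)
    ld_threshold = config.get("ld", {}).get("threshold", 0.5)
    prs_cfg = config.get("prs", {})
    policy = prs_cfg.get("missing_policy", "impute_control_freq")

    evaluations: dict[str, prs.PrsEvaluation] = {}
    skipped: dict[str, str] = {}
    score_rows = []
    for source in ("unadjusted", "age_adjusted"):
        for rule in ("model1", "model2", "model3"):
            key = f"{rule}_{source}"
            try:
                model = prs.build_model(
                    assoc_unadj, assoc_adj, ld_mat, gm_train, phen_train,
                    rule, source, alpha=alpha, ld_threshold=ld_threshold,
                )
                evaluations[key] = prs.evaluate_model(
                    gm_eval, phen_eval, model, policy,
                    cutpoint_source=prs_cfg.get("cutpoint_source", "controls"),
                )
            except (prs.EmptyModelError, ValueError, RuntimeError) as exc:
                skipped[key] = str(exc)
                logger.warning("model %s skipped: %s", key, exc)
                continue
            for sid, sc in zip(gm_eval.sample_ids, evaluations[key].scores):
                score_rows.append({"sample_id": sid, "model": key, "prs": sc})
    pd.DataFrame(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)

    settings = {
        "alpha": alpha,
        "ld_threshold": ld_threshold,
        "missing_policy": policy,
        "cutpoint_source": prs_cfg.get("cutpoint_source", "controls"),
        "qc": dataclasses.asdict(qc_cfg),
    }
    report = _evaluation_report(evaluations, skipped, settings)
    (out / "evaluation.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config_hash": _digest(dict(config)),
        "seed": config["seed"],
        "inputs": digests,
        "package_version": __import__("polyrisk").__version__,
        "stage_counts": counts,
        "models_evaluated": sorted(evaluations),
        "models_skipped": sorted(skipped),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(out, qc_results, assoc_unadj, assoc_adj, evaluations, skipped, manifest)
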
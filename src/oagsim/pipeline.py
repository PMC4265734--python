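"""End-to-end analysis pipeline: baseline table, per-SNP association tables,
joint model with collinearity diagnostics, Bonferroni flagging, and the
optional subset-ensemble importance ranking.

Human-readable reports round to the conventional display precision (OR and
frequencies shown, p to 3 decimals); machine outputs (JSON lines, manifest)
keep full precision so every report is regenerable from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (DegenerateTableError, allele_count_table,
                          allelic_test, additive_logistic, baseline_comparison,
                          bonferroni_threshold, joint_multivariate_model, vif)
from .ensemble import VariablePanel, rank_variables, run_ensemble
from .io import read_cohort
from .params import CLINICAL_COVARIATES


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    cohort_path: str
    output_dir: str
    snp_ids: list[str] = field(default_factory=list)  # empty -> all genotype columns
    joint_snp_ids: list[str] | None = None            # SNPs entering the joint model
    covariates: list[str] = field(default_factory=lambda: list(CLINICAL_COVARIATES))
    alpha_family: float = 0.05
    n_snps_tested: int | None = None                  # defaults to len(snp_ids)
    run_nn: bool = False
    nn_reps: int = 3
    nn_subset_cap: int | None = None
    nn_age_matched: bool = False
    nn_tolerance_years: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _fmt_p(p: float) -> str:
    return "NA" if not np.isfinite(p) else f"{p:.3f}"


def _result_row(r) -> dict:
    return {"beta": r.beta, "se": r.se, "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Writes, under ``output_dir``: ``table_baseline.tsv``,
    ``table_association.tsv`` (univariate + adjusted per SNP),
    ``table_joint_model.tsv``, ``results.jsonl`` (full precision),
    optionally ``table_importance.tsv`` / ``runs.tsv``, and
    ``manifest.json``.  A stage failure aborts with the stage name; outputs
    written before the failure are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_cohort"
    machine: list[dict] = []
    try:
        cohort = read_cohort(config.cohort_path)
        snp_ids = config.snp_ids or [c for c in cohort.columns
                                     if c not in ("pid", "status") + CLINICAL_COVARIATES]
        m = config.n_snps_tested or len(snp_ids)
        threshold = bonferroni_threshold(config.alpha_family, m)

        stage = "baseline_comparison"
        base = baseline_comparison(cohort)
        base_disp = base.copy()
        base_disp["p_value"] = base["p_value"].map(_fmt_p)
        base_disp.to_csv(out / "table_baseline.tsv", sep="\t", index=False)
        machine.extend({"stage": "baseline", **row} for row in base.to_dict("records"))

        stage = "association"
        rows = []
        for snp in snp_ids:
            cases = cohort.loc[cohort["status"] == 1, snp]
            ctrls = cohort.loc[cohort["status"] == 0, snp]
            table = allele_count_table(cases, ctrls)
            try:
                uni = allelic_test(table, snp)
            except DegenerateTableError:
                uni = None
            adj = additive_logistic(cohort, snp, config.covariates)
            rows.append({
                "snp_id": snp,
                "freq_cases": round(table.case_freq, 3),
                "freq_controls": round(table.control_freq, 3),
                "uni_p": _fmt_p(uni.p_value) if uni else "NA",
                "uni_or_ci": (f"{uni.odds_ratio:.2f} ({uni.ci_low:.2f}-{uni.ci_high:.2f})"
                              if uni else "NA"),
                "adj_p": _fmt_p(adj.p_value),
                "adj_or_ci": f"{adj.odds_ratio:.2f} ({adj.ci_low:.2f}-{adj.ci_high:.2f})",
                "significant": bool(adj.p_value < threshold),
            })
            machine.append({"stage": "association", "snp_id": snp,
                            "allelic": _result_row(uni) if uni else None,
                            "additive_adjusted": _result_row(adj)})
        pd.DataFrame(rows).to_csv(out / "table_association.tsv", sep="\t", index=False)

        stage = "joint_model"
        joint_snps = config.joint_snp_ids if config.joint_snp_ids is not None else snp_ids
        results, intercept = joint_multivariate_model(cohort, joint_snps, config.covariates)
        vifs = {v.variable: v.vif for v in
                vif(cohort, config.covariates + list(joint_snps))}
        jrows = [{"variable": (r.snp_id or term), "beta": round(r.beta, 3),
                  "se": round(r.se, 3), "p": _fmt_p(r.p_value),
                  "or_ci": f"{r.odds_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})",
                  "vif": round(vifs[term], 2)}
                 for term, r in zip(config.covariates + list(joint_snps), results)]
        jrows.append({"variable": "constant", "beta": round(intercept, 3),
                      "se": "", "p": "", "or_ci": "", "vif": ""})
        pd.DataFrame(jrows).to_csv(out / "table_joint_model.tsv", sep="\t", index=False)
        machine.append({"stage": "joint_model", "intercept": intercept,
                        "terms": {(r.snp_id or t): _result_row(r)
                                  for t, r in zip(config.covariates + list(joint_snps),
                                                  results)},
                        "vif": vifs})

        importance_file = None
        if config.run_nn:
            stage = "subset_nn"
            panel = VariablePanel(clinical=tuple(config.covariates),
                                  snps=tuple(snp_ids))
            runs = run_ensemble(cohort[cohort["status"] == 1],
                                cohort[cohort["status"] == 0], panel,
                                reps=config.nn_reps,
                                age_matched=config.nn_age_matched,
                                tolerance_years=config.nn_tolerance_years,
                                master_seed=config.seed,
                                subset_cap=config.nn_subset_cap)
            runs.to_csv(out / "runs.tsv", sep="\t", index=False)
            imp = rank_variables(runs, panel, config.nn_age_matched)
            imp.to_csv(out / "table_importance.tsv", sep="\t", index=False)
            importance_file = "table_importance.tsv"
            machine.append({"stage": "subset_nn",
                            "importance": imp.to_dict("records")})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "results.jsonl", "w") as fh:
        for rec in machine:
            fh.write(json.dumps(rec) + "\n")

    manifest = {
        "oagsim_version": __version__,
        "seed": config.seed,
        "cohort_path": str(config.cohort_path),
        "n_snps_tested": m,
        "snp_ids": list(snp_ids),
        "bonferroni_threshold": threshold,
        "bonferroni_threshold_display": f"{threshold:.3f}",
        "alpha_family": config.alpha_family,
        "stages": ["baseline", "association", "joint_model"]
                  + (["subset_nn"] if config.run_nn else []),
        "outputs": ["table_baseline.tsv", "table_association.tsv",
                    "table_joint_model.tsv", "results.jsonl"]
                   + (["runs.tsv", importance_file] if importance_file else []),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
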
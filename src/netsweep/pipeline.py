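"""End-to-end orchestration: simulate -> connect -> metrics -> compare ->
clinical -> report.

Every stage persists its artifacts under the configured output directory
so each number in the final report can be recomputed from intermediates.
A single master seed drives all stages through named
``numpy.random.SeedSequence`` children (simulate / metrics / compare /
clinical, in that order), so stages are independently rerunnable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netsweep import __version__
from netsweep.clinical import (
    forward_lr_logistic,
    label_responders,
    partial_correlation,
    roc_analysis,
)
from netsweep.connectivity import compute_fc_matrix, link_weight_distribution
from netsweep.graphs import SparsityGrid, binarize_at_sparsity, \
    degree_distribution
from netsweep.inference import (
    cohort_auc_table,
    compare_distributions,
    compare_group_metrics,
)
from netsweep.io import (
    check_cohort_alignment,
    read_clinical_csv,
    read_timeseries_dir,
    write_clinical_csv,
    write_connectivity_csv,
    write_json,
    write_timeseries_tsv,
)
from netsweep.metrics import metrics_for_subject
from netsweep.synthetic import CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("netsweep")

_STAGE_NAMES = ("simulate", "metrics", "compare", "clinical")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str = "netsweep_out"
    input_dir: str | None = None  # None -> simulate a cohort
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    sparsity_min: float = 0.10
    sparsity_max: float = 0.34
    sparsity_step: float = 0.01
    n_nulls: int = 100
    n_perm: int = 10_000
    alpha: float = 0.05
    entry_p: float = 0.05
    removal_p: float = 0.10
    modularity_runs: int = 10
    degree_distribution_sparsity: float = 0.22  # sweep midpoint
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_min < self.sparsity_max < 1:
            raise ValueError("need 0 < sparsity_min < sparsity_max < 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_nulls < 0 or self.modularity_runs < 1:
            raise ValueError("n_nulls must be >= 0, modularity_runs >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")

    def grid(self) -> SparsityGrid:
        return SparsityGrid.from_range(self.sparsity_min, self.sparsity_max,
                                       self.sparsity_step)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return dict(zip(_STAGE_NAMES, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "software": {"name": "netsweep", "version": __version__},
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    failure_marker = out / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()
    try:
        # ---- stage 1: cohort ------------------------------------------
        if config.input_dir is None:
            spec = CohortSpec(seed=_seed_int(seeds["simulate"]),
                              **config.cohort)
            log.info("simulate: generating %d+%d subjects",
                     spec.n_responders, spec.n_nonresponders)
            cohort = simulate_cohort(spec)
            time_series, clinical = cohort.time_series, cohort.clinical
            ts_dir = out / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for ts in time_series:
                write_timeseries_tsv(ts, ts_dir / f"{ts.subject_id}.tsv")
        else:
            log.info("loading cohort from %s", config.input_dir)
            time_series = read_timeseries_dir(
                Path(config.input_dir) / "timeseries")
            clinical = read_clinical_csv(
                Path(config.input_dir) / "clinical.csv")
            check_cohort_alignment(time_series, clinical)
            clinical = label_responders(clinical)
        write_clinical_csv(clinical, out / "clinical.csv")
        report["stages"]["cohort"] = {"n_subjects": len(time_series)}

        # ---- stage 2: connectivity ------------------------------------
        fc_dir = out / "connectivity"
        fc_dir.mkdir(exist_ok=True)
        fcs = []
        for ts in time_series:
            fc = compute_fc_matrix(ts)
            write_connectivity_csv(fc, fc_dir / f"{fc.subject_id}.csv")
            fcs.append(fc)
        report["stages"]["connectivity"] = {
            "n_matrices": len(fcs), "n_rois": fcs[0].n_rois}

        # ---- stage 3: metrics -----------------------------------------
        grid = config.grid()
        subj_seeds = seeds["metrics"].spawn(len(fcs))
        curve_sets = []
        for fc, child in zip(fcs, subj_seeds):
            log.info("metrics: %s", fc.subject_id)
            curve_sets.append(metrics_for_subject(
                fc, grid, n_nulls=config.n_nulls, seed=_seed_int(child),
                n_runs=config.modularity_runs))
        tidy = pd.concat([cs.to_tidy() for cs in curve_sets],
                         ignore_index=True)
        tidy.to_csv(out / "metric_curves.csv", index=False)
        auc_table = cohort_auc_table(curve_sets)
        auc_table.to_csv(out / "metric_auc.csv", index=False)
        report["stages"]["metrics"] = {
            "n_thresholds": len(grid), "n_subjects": len(curve_sets)}

        # ---- stage 4: group comparison --------------------------------
        grouping = clinical.set_index("subject_id")["group"]
        comparison = compare_group_metrics(
            auc_table, grouping, n_perm=config.n_perm,
            seed=_seed_int(seeds["compare"]), alpha=config.alpha)
        comparison.to_csv(out / "group_comparison.csv", index=False)
        glob_rows = comparison[comparison["scope"] == "global"]
        node_rows = comparison[comparison["scope"] == "node"]
        # degree and link-weight distribution tests
        mid_s = config.degree_distribution_sparsity
        by_group: dict[str, dict[str, list]] = {
            g: {"degree": [], "weights": []} for g in grouping.unique()}
        for fc in fcs:
            g = grouping[fc.subject_id]
            by_group[g]["degree"].extend(
                degree_distribution(binarize_at_sparsity(fc, mid_s)))
            by_group[g]["weights"].extend(link_weight_distribution(fc))
        ga, gb = sorted(by_group)
        dist_tests = {
            kind: dataclasses.asdict(compare_distributions(
                np.asarray(by_group[ga][kind]),
                np.asarray(by_group[gb][kind])))
            for kind in ("degree", "weights")
        }
        write_json(dist_tests, out / "distribution_tests.json")
        report["stages"]["compare"] = {
            "n_global": int(len(glob_rows)),
            "n_nodal": int(len(node_rows)),
            "n_significant_global": int(glob_rows["significant"].sum()),
            "n_significant_nodal_fdr":
                int((node_rows["p_fdr"] < config.alpha).sum()),
            "distribution_tests": dist_tests,
        }

        # ---- stage 5: clinical models ---------------------------------
        clin = label_responders(clinical) \
            if "responder" not in clinical else clinical
        clin = clin.set_index("subject_id").loc[
            [cs.subject_id for cs in curve_sets]]
        covariates = pd.DataFrame({
            "age": clin["age"].to_numpy(dtype=float),
            "sex": (clin["sex"] == "female").astype(float).to_numpy(),
        })
        delta_hamd = (clin["hamd17_pre"] - clin["hamd17_post"]) \
            .to_numpy(dtype=float)
        # feature matrix of candidate predictors = significant metrics
        sig_global = glob_rows.loc[glob_rows["significant"], "metric"]
        sig_nodal = node_rows.loc[node_rows["p_fdr"] < config.alpha,
                                  ["metric", "node_label"]]
        features = {}
        wide = auc_table.pivot_table(
            index="subject_id", columns=["scope", "metric", "node_label"],
            values="auc", sort=False).loc[clin.index]
        for m in sig_global:
            features[m] = wide[("global", m, "")].to_numpy()
        for _, row in sig_nodal.iterrows():
            features[f"{row['metric']}[{row['node_label']}]"] = \
                wide[("node", row["metric"], row["node_label"])].to_numpy()
        # z-score candidates: AUC metrics live on tiny scales, so per-SD
        # odds ratios are the readable reporting unit
        feature_df = pd.DataFrame(features, index=clin.index)
        feature_df = (feature_df - feature_df.mean()) / \
            feature_df.std(ddof=0).replace(0.0, 1.0)
        # partial correlations of every candidate with symptom change
        corr_rows = []
        for name, vals in feature_df.items():
            pc = partial_correlation(vals.to_numpy(), delta_hamd, covariates)
            corr_rows.append({"predictor": name, "outcome": "delta_hamd17",
                              "r_partial": pc.r_partial, "p": pc.p,
                              "df": pc.df})
        corr_table = pd.DataFrame(
            corr_rows, columns=["predictor", "outcome", "r_partial", "p",
                                "df"])
        corr_table.to_csv(out / "partial_correlations.csv", index=False)
        labels = clin["responder"].to_numpy()
        model_summary: dict = {"selected_predictors": [], "note": ""}
        roc_summaries = {}
        if feature_df.shape[1] > 0:
            model = forward_lr_logistic(
                feature_df, labels, entry_p=config.entry_p,
                removal_p=config.removal_p)
            model_summary = {
                "selected_predictors": model.selected_predictors,
                "coefficients": model.coefficients,
                "odds_ratios": {k: {"OR": v[0], "ci_low": v[1],
                                    "ci_high": v[2]}
                                for k, v in model.odds_ratios.items()},
                "p_values": model.p_values,
                "log_likelihood": model.log_likelihood,
                "selection_trace": model.selection_trace,
            }
            pd.DataFrame([
                {"predictor": k, "coefficient": model.coefficients[k],
                 "OR": model.odds_ratios[k][0],
                 "ci_low": model.odds_ratios[k][1],
                 "ci_high": model.odds_ratios[k][2],
                 "p": model.p_values[k]}
                for k in model.selected_predictors
            ]).to_csv(out / "logistic_model.csv", index=False)
            # ROC for the joint model and for each selected predictor
            if model.selected_predictors:
                roc = roc_analysis(model.predict_proba(feature_df), labels)
                roc_summaries["joint_model"] = _roc_summary(roc)
                _write_roc(roc, out / "roc_joint_model.csv")
            for name in model.selected_predictors:
                # orient each predictor by its marginal group direction so
                # the univariate ROC reads as discrimination (AUC >= 0.5)
                vals = feature_df[name].to_numpy()
                sign = np.sign(vals[labels].mean()
                               - vals[~labels].mean()) or 1.0
                roc = roc_analysis(sign * vals, labels)
                roc_summaries[name] = _roc_summary(roc)
                _write_roc(roc, out / f"roc_{_safe(name)}.csv")
        else:
            model_summary["note"] = ("no metrics passed the group "
                                     "comparison; logistic stage skipped")
        write_json(model_summary, out / "logistic_model.json")
        report["stages"]["clinical"] = {
            "n_candidates": int(feature_df.shape[1]),
            "model": model_summary,
            "roc": roc_summaries,
            "n_correlations": int(len(corr_table)),
        }

        # ---- report ----------------------------------------------------
        report["global_comparison"] = glob_rows.drop(columns=["scope"]) \
            .to_dict(orient="records")
        report["nodal_significant"] = node_rows.loc[
            node_rows["p_fdr"] < config.alpha].drop(columns=["scope"]) \
            .to_dict(orient="records")
        report["correlations"] = corr_table.to_dict(orient="records")
        write_json(report, out / "report.json")
        (out / "report.txt").write_text(_format_report(report, glob_rows))
    except Exception:
        failure_marker.write_text("pipeline failed; see logs\n")
        raise
    return report


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def _roc_summary(roc) -> dict:
    return {"auc": roc.auc, "sensitivity": roc.operating_point[0],
            "specificity": roc.operating_point[1]}


def _write_roc(roc, path) -> None:
    pd.DataFrame({
        "threshold": roc.thresholds,
        "sensitivity": roc.sensitivities,
        "specificity": roc.specificities,
    }).to_csv(path, index=False)


def _format_report(report: dict, glob_rows: pd.DataFrame) -> str:
    lines = [
        f"netsweep {report['software']['version']} run report "
        f"(seed={report['seed']})",
        "",
        "Global topological metrics (AUC over sparsity sweep)",
        "-" * 64,
    ]
    mean_cols = [c for c in glob_rows.columns if c.startswith("mean_")]
    for _, r in glob_rows.iterrows():
        means = "  ".join(
            f"{c[5:]}: {r[c]:.4f} ± {r['sd_' + c[5:]]:.4f}"
            for c in mean_cols)
        star = " *" if r["significant"] else ""
        lines.append(f"{r['metric']:<14} {means}  p={r['p_raw']:.4f}{star}")
    lines.append("")
    clin = report["stages"].get("clinical", {})
    model = clin.get("model", {})
    lines.append(f"Selected predictors: "
                 f"{model.get('selected_predictors') or 'none'}")
    for name, s in clin.get("roc", {}).items():
        lines.append(
            f"  ROC[{name}]: AUC={s['auc']:.3f} "
            f"sens={s['sensitivity']:.3f} spec={s['specificity']:.3f}")
    lines.append("")
    return "\n".join(lines)
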
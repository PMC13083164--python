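"""One-command orchestration of the full analysis.

Stages: simulate/load -> per-rater metrics & agreement -> nested CV over the
four methods -> paired comparisons -> calibration & decision-curve analysis
on pooled outer predictions -> age-heterogeneity analysis.  Every artifact
is listed in a manifest with its SHA-256 hash; a run is fully reproducible
from (config, seed) because the single pipeline seed fans out into fixed
stage-specific child seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from .age import SplineConfig, cutpoint_scan, fit_interaction
from .calibration import calibration_report, decision_curve
from .dataset import PredictionDataset, load_predictions, write_predictions
from .ensemble import SearchConfig
from .metrics import auc as roc_auc
from .metrics import classification_metrics, confusion
from .nested_cv import CVConfig, compare_methods, format_cell, run_nested_cv, summarize
from .simulate import GeneratorConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)

_MOD = 2**31

DCA_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.5001, 0.05), 10).tolist())


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AgeConfig:
    min_n: int = 10
    B: int = 1000
    df: int = 4


@dataclass
class PipelineConfig:
    generator: GeneratorConfig | None = None
    input_path: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    dca_thresholds: tuple = DCA_THRESHOLDS
    calibration_bins: int = 10
    age: AgeConfig = field(default_factory=AgeConfig)
    out_dir: str = "results"
    seed: int = 0

    def validate(self):
        if (self.generator is None) == (self.input_path is None):
            raise ValueError("exactly one of generator / input_path must be set")


def _child(seed, salt):
    return (seed * 7919 + salt) % _MOD


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, sep: str):
    df.to_csv(path, sep=sep, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    manifest_path = out / "manifest.json"

    def emit(name):
        artifacts.append(name)

    stage = "data"
    try:
        if config.generator is not None:
            dataset = generate_cohort(config.generator, seed=_child(config.seed, 1))
        else:
            dataset = load_predictions(config.input_path)
        write_predictions(dataset, out / "predictions.csv")
        emit("predictions.csv")
        logger.info("data stage: %d patients, %d raters, %d tasks",
                    dataset.n_patients, len(dataset.models), len(dataset.tasks))

        stage = "per_rater_metrics"
        rows = []
        rdf, P, models = dataset.matrix()
        y = rdf["label"].to_numpy()
        for t in dataset.tasks:
            m_task = (rdf["task"] == t).to_numpy()
            for j, m in enumerate(models):
                cm = confusion(P[m_task, j], y[m_task])
                b = classification_metrics(cm)
                try:
                    a = roc_auc(P[m_task, j].astype(float), y[m_task])
                except ValueError:
                    a = None
                rows.append({"model": m, "task": t, "accuracy": b.accuracy,
                             "sensitivity": b.sensitivity, "specificity": b.specificity,
                             "precision": b.precision, "f1": b.f1, "auc": a})
        _write_df(pd.DataFrame(rows), out / "model_metrics.tsv", "\t")
        emit("model_metrics.tsv")

        rep_tasks = [t for t, c in dataset.replicate_counts().items() if c >= 2]
        krows = []
        for m in dataset.models:
            table = agr.binary_replicate_table(dataset, m)
            if len(table):
                res = agr.fleiss_kappa(table)
                krows.append({"model": m, "kappa": res.kappa,
                              "observed_agreement": res.mean_observed_agreement,
                              "expected_agreement": res.expected_agreement})
        if krows:
            _write_df(pd.DataFrame(krows), out / "fleiss_kappa.tsv", "\t")
            emit("fleiss_kappa.tsv")

        corr = agr.model_correlation(dataset)
        cdf = pd.DataFrame(corr.rho, columns=corr.models)
        cdf.insert(0, "model", corr.models)
        _write_df(cdf, out / "correlation.tsv", "\t")
        emit("correlation.tsv")
        link_doc = {
            "clustered_models": corr.clustered_models,
            "excluded": corr.excluded,
            "linkage": corr.linkage_matrix.tolist() if corr.linkage_matrix is not None else None,
        }
        (out / "linkage.json").write_text(json.dumps(link_doc, sort_keys=True, indent=2))
        emit("linkage.json")

        stage = "nested_cv"
        outcome = run_nested_cv(dataset, config=config.cv, search=config.search)
        _write_df(outcome.records, out / "cv_records.csv", ",")
        emit("cv_records.csv")
        summary = summarize(outcome)
        tab = summary["metrics"].copy()
        tab["cell"] = [
            format_cell(r["mean"], r["sd"], r["ci_low"], r["ci_high"])
            for _, r in tab.iterrows()
        ]
        _write_df(tab, out / "cv_summary.tsv", "\t")
        emit("cv_summary.tsv")
        sel_doc = {
            "baseline_frequency": summary["baseline_frequency"],
            "member_frequency": summary["member_frequency"],
            "records": outcome.selection,
        }
        (out / "selection.json").write_text(json.dumps(sel_doc, sort_keys=True, indent=2))
        emit("selection.json")

        stage = "comparisons"
        comps = compare_methods(outcome, b_boot=1000, seed=_child(config.seed, 2))
        _write_df(pd.DataFrame([c.__dict__ for c in comps]), out / "comparisons.tsv", "\t")
        emit("comparisons.tsv")

        stage = "calibration_dca"
        preds = outcome.predictions
        cal_rows, nb_cols = [], {}
        thresholds = np.asarray(config.dca_thresholds)
        for method in outcome.methods:
            sub = preds[preds["method"] == method]
            rep = calibration_report(sub["prob"], sub["y"], config.calibration_bins)
            cal_rows.append({"method": method, "brier": rep.brier, "ece": rep.ece,
                             "mce": rep.mce})
            nb = decision_curve(sub["prob"], sub["y"], thresholds)
            nb_cols[method] = nb.net_benefit
            nb_all, nb_none = nb.treat_all, nb.treat_none
        _write_df(pd.DataFrame(cal_rows), out / "calibration.tsv", "\t")
        emit("calibration.tsv")
        nb_df = pd.DataFrame({"threshold": thresholds, **{f"nb_{m}": v for m, v in nb_cols.items()},
                              "nb_treat_all": nb_all, "nb_treat_none": nb_none})
        _write_df(nb_df, out / "net_benefit.tsv", "\t")
        emit("net_benefit.tsv")

        stage = "age_analysis"
        target = "advanced_grouped" if "advanced_grouped" in outcome.methods else outcome.methods[0]
        sub = preds[preds["method"] == target]
        per_pat = sub.groupby("patient_id").agg(prob=("prob", "mean"), y=("y", "first"))
        pat = dataset.canonical_patients().set_index("patient_id")
        per_pat["age"] = pat.loc[per_pat.index, "age"]
        cps = cutpoint_scan(per_pat["prob"], per_pat["y"], per_pat["age"],
                            min_n=config.age.min_n, B=config.age.B,
                            seed=_child(config.seed, 3))
        if cps:
            _write_df(pd.DataFrame([c.__dict__ for c in cps]), out / "cutpoints.tsv", "\t")
        else:
            (out / "cutpoints.tsv").write_text("cutpoint\n")
        emit("cutpoints.tsv")
        try:
            it = fit_interaction(per_pat["prob"], per_pat["age"], per_pat["y"],
                                 SplineConfig(df=config.age.df))
            doc = {
                "loglik_full": it.loglik_full, "loglik_reduced": it.loglik_reduced,
                "lrt_stat": it.lrt_stat, "lrt_df": it.lrt_df, "p": it.p,
                "coef_full": it.coef_full, "coef_reduced": it.coef_reduced,
                "score_at_half": it.score_at_half,
            }
            (out / "interaction.json").write_text(json.dumps(doc, sort_keys=True, indent=2))
            emit("interaction.json")
            crows = []
            for label, (grid, pq) in it.curves.items():
                for g, p in zip(grid, pq):
                    crows.append({"age_percentile": label, "score": g, "prob": p})
            _write_df(pd.DataFrame(crows), out / "probability_curves.tsv", "\t")
            emit("probability_curves.tsv")
        except ValueError as exc:
            logger.warning("interaction model skipped: %s", exc)

        stage = "report"
        report = render_report(out)
        (out / "report.md").write_text(report)
        emit("report.md")
    except Exception as exc:  # halt with stage name and partial manifest
        partial = _manifest_doc(out, artifacts, config.seed, failed_stage=stage)
        manifest_path.write_text(json.dumps(partial, sort_keys=True, indent=2))
        raise PipelineError(stage, exc) from exc

    doc = _manifest_doc(out, artifacts, config.seed)
    manifest_path.write_text(json.dumps(doc, sort_keys=True, indent=2))
    return doc


def _manifest_doc(out: Path, artifacts, seed, failed_stage=None):
    doc = {
        "seed": seed,
        "artifacts": {
            name: {"sha256": _sha256(out / name), "bytes": (out / name).stat().st_size}
            for name in artifacts
        },
    }
    if failed_stage is not None:
        doc["failed_stage"] = failed_stage
    return doc


def render_report(out_dir) -> str:
    """Markdown summary in the mean ± sd [low, high] house style."""
    out = Path(out_dir)
    lines = ["# Analysis report", ""]
    missing = []

    summary_path = out / "cv_summary.tsv"
    if summary_path.exists():
        tab = pd.read_csv(summary_path, sep="\t")
        lines.append("## Nested cross-validated performance")
        lines.append("")
        lines.append("| method | metric | value |")
        lines.append("|---|---|---|")
        for _, r in tab.iterrows():
            lines.append(f"| {r['method']} | {r['metric']} | {r['cell']} |")
        lines.append("")
    else:
        missing.append("nested CV summary")

    sel_path = out / "selection.json"
    if sel_path.exists():
        sel = json.loads(sel_path.read_text())
        lines.append("## Selection frequencies")
        lines.append("")
        for method, freqs in sorted(sel.get("baseline_frequency", {}).items()):
            top = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            fmt = ", ".join(f"{m} ({100*f:.1f}%)" for m, f in top)
            lines.append(f"- {method} baseline: {fmt}")
        for method, freqs in sorted(sel.get("member_frequency", {}).items()):
            top = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:1]
            for combo, f in top:
                lines.append(f"- {method} most frequent members: {combo} ({100*f:.1f}%)")
        lines.append("")
    else:
        missing.append("selection frequencies")

    cp_path = out / "cutpoints.tsv"
    lines.append("## Age heterogeneity")
    lines.append("")
    if cp_path.exists():
        cps = pd.read_csv(cp_path, sep="\t")
        if len(cps) and "p_holm" in cps.columns:
            sig = cps[cps["p_holm"] < 0.05]
            if len(sig):
                pts = ", ".join(str(int(c)) for c in sig["cutpoint"])
                lines.append(f"Holm-significant age cut-points: {pts}.")
            else:
                lines.append("No Holm-significant age cut-points.")
        else:
            lines.append("No eligible cut-points.")
    else:
        missing.append("cut-point scan")
    it_path = out / "interaction.json"
    if it_path.exists():
        it = json.loads(it_path.read_text())
        lines.append(
            f"Age x score interaction LRT: stat {it['lrt_stat']:.3f}, "
            f"df {it['lrt_df']}, p = {it['p']:.5f}."
        )
    else:
        missing.append("interaction test")
    lines.append("")

    if missing:
        lines.append("## Missing sections")
        lines.append("")
        for m in missing:
            lines.append(f"- {m}")
        lines.append("")
    return "\n".join(lines)
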
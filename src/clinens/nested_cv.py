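"""Nested repeated stratified cross-validation.

The outer loop (default 5 folds, many repeats) estimates generalization
performance; every act of selection — baseline rater, ensemble members,
balance parameter beta, decision threshold tau, calibration family — happens
inside the inner loop on outer-training patients only, so outer-test metrics
are free of selection optimism.  Folds are stratified on the patient-level
outcome; all rows (tasks) of a patient move together, which keeps the
patient the unit of independence.

Per-patient outer predictions and calibrated probabilities are retained so
methods can be compared by paired patient-level bootstrap (F1) and McNemar's
test (accuracy), with Holm step-down adjustment within each metric family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import calibration_report, fit_calibrator, select_calibrator
from .dataset import PredictionDataset
from .ensemble import (
    SearchConfig,
    TrainingSlice,
    best_single_model,
    decide,
    make_slice,
    select_advanced_ensemble,
    select_standard_ensemble,
)
from .folds import make_folds
from .metrics import auc as roc_auc
from .metrics import classification_metrics, confusion
from .stats import bootstrap_two_sided_p, holm, mcnemar_p

logger = logging.getLogger(__name__)

_MOD = 2**31

METHODS = ("best_single", "standard", "advanced_global", "advanced_grouped")
METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc",
                  "brier", "ece", "mce")


@dataclass
class CVConfig:
    outer_folds: int = 5
    repeats: int = 200
    inner_folds: int = 3
    seed: int = 0
    objective: str = "f1"
    n_bins: int = 10

    def validate(self):
        if self.outer_folds < 2 or self.inner_folds < 2 or self.repeats < 1:
            raise ValueError("outer_folds >= 2, inner_folds >= 2, repeats >= 1 required")


@dataclass
class CVOutcome:
    records: pd.DataFrame          # one row per (repeat, fold, method)
    predictions: pd.DataFrame      # one row per (repeat, patient, task, method)
    selection: list                # dict per fitted spec / chosen model
    audit: list                    # per-iteration train/test patient sets
    config: CVConfig
    methods: tuple


def _child_seed(seed, r, f, salt=0):
    return (seed + 100003 * r + 101 * f + salt) % _MOD


def _fit_and_score(method, train_sl, test_sl, groups, search, inner_folds, seed):
    """Fit one method on the training slice, score the test slice.

    Returns (pred, score, selection_records).
    """
    if method == "best_single":
        name = best_single_model(train_sl, inner_folds, seed, search.objective)
        col = train_sl.model_names.index(name)
        pred = test_sl.P[:, col].astype(int)
        score = pred.astype(float)
        score_train = train_sl.P[:, col].astype(float)
        sel = [{"method": method, "model": name}]
        return pred, score, score_train, sel
    if method == "majority_class":
        maj = int(round(train_sl.y.mean()))
        pred = np.full(test_sl.n_rows, maj, dtype=int)
        score = np.full(test_sl.n_rows, float(train_sl.y.mean()))
        score_train = np.full(train_sl.n_rows, float(train_sl.y.mean()))
        return pred, score, score_train, [{"method": method, "majority": maj}]
    if method == "standard":
        spec = select_standard_ensemble(train_sl, search, inner_folds, seed)
        score = spec.score(test_sl.P, test_sl.model_names)
        pred = decide(score, spec.threshold)
        score_train = spec.score(train_sl.P, train_sl.model_names)
        sel = [{"method": method, "strategy": spec.strategy, "members": list(spec.members),
                "tau": spec.threshold}]
        return pred, score, score_train, sel
    if method == "advanced_global":
        spec = select_advanced_ensemble(train_sl, search, "GLOBAL", inner_folds, seed)
        score = spec.score(test_sl.P, test_sl.model_names)
        pred = decide(score, spec.threshold)
        score_train = spec.score(train_sl.P, train_sl.model_names)
        sel = [{"method": method, "scope": "GLOBAL", "baseline": spec.members[0],
                "members": list(spec.members), "beta": spec.beta, "tau": spec.threshold}]
        return pred, score, score_train, sel
    if method == "advanced_grouped":
        pred = np.empty(test_sl.n_rows, dtype=int)
        score = np.empty(test_sl.n_rows, dtype=float)
        score_train = np.empty(train_sl.n_rows, dtype=float)
        sel = []
        for g in groups:
            try:
                spec = select_advanced_ensemble(train_sl, search, g, inner_folds, seed)
            except ValueError as exc:
                logger.warning("group %s degenerate (%s); falling back to global fit", g, exc)
                spec = select_advanced_ensemble(train_sl, search, "GLOBAL", inner_folds, seed)
            m_test = test_sl.group == g
            m_train = train_sl.group == g
            if m_test.any():
                s = spec.score(test_sl.P[m_test], test_sl.model_names)
                score[m_test] = s
                pred[m_test] = decide(s, spec.threshold)
            if m_train.any():
                score_train[m_train] = spec.score(train_sl.P[m_train], train_sl.model_names)
            sel.append({"method": method, "scope": g, "baseline": spec.members[0],
                        "members": list(spec.members), "beta": spec.beta,
                        "tau": spec.threshold})
        return pred, score, score_train, sel
    raise ValueError(f"unknown method {method!r}")


def run_nested_cv(
    dataset: PredictionDataset,
    methods=METHODS,
    config: CVConfig | None = None,
    search: SearchConfig | None = None,
) -> CVOutcome:
    """Run the full nested evaluation over the requested methods."""
    config = config or CVConfig()
    config.validate()
    search = search or SearchConfig(objective=config.objective)
    methods = tuple(methods)
    if not methods:
        raise ValueError("method set must not be empty")
    if len(dataset.models) < 3:
        raise ValueError("need at least 3 raters")

    sl = make_slice(dataset)
    groups = sorted(set(dataset.task_groups.values()))
    patients = dataset.canonical_patients()
    pat_ids = patients["patient_id"].to_numpy()
    pat_labels = patients["label"].to_numpy().astype(int)
    pat_pos = {p: i for i, p in enumerate(pat_ids)}
    row_pat = np.array([pat_pos[p] for p in sl.patient_id])

    folds = make_folds(pat_labels, config.outer_folds, config.repeats, config.seed)

    records = []
    sel_records = []
    audit = []
    pred_blocks = {m: [] for m in methods}
    n_undefined_auc = 0

    for r in range(config.repeats):
        assign = folds[r]
        for f in range(config.outer_folds):
            test_pat_mask = assign == f
            test_rows = test_pat_mask[row_pat]
            train_rows = ~test_rows
            train_sl = sl.subset(train_rows)
            test_sl = sl.subset(test_rows)
            y_test = test_sl.y
            seed_sel = _child_seed(config.seed, r, f)
            audit.append(
                {
                    "repeat": r,
                    "fold": f,
                    "train_patients": sorted(set(train_sl.patient_id)),
                    "test_patients": sorted(set(test_sl.patient_id)),
                }
            )
            for method in methods:
                pred, score, score_train, sel = _fit_and_score(
                    method, train_sl, test_sl, groups, search, config.inner_folds, seed_sel
                )
                # calibration is fitted on outer-train scores only
                kind = select_calibrator(
                    score_train, train_sl.y, config.inner_folds, _child_seed(config.seed, r, f, 17)
                )
                cal = fit_calibrator(kind, score_train, train_sl.y)
                probs = cal.predict(score)

                cm = confusion(pred, y_test)
                bundle = classification_metrics(cm)
                try:
                    auc_val = roc_auc(score, y_test)
                except ValueError:
                    auc_val = None
                    n_undefined_auc += 1
                cal_rep = calibration_report(probs, y_test, config.n_bins)
                rec = {
                    "repeat": r,
                    "fold": f,
                    "method": method,
                    "accuracy": bundle.accuracy,
                    "sensitivity": bundle.sensitivity,
                    "specificity": bundle.specificity,
                    "precision": bundle.precision,
                    "f1": bundle.f1,
                    "auc": auc_val,
                    "brier": cal_rep.brier,
                    "ece": cal_rep.ece,
                    "mce": cal_rep.mce,
                }
                records.append(rec)
                for s in sel:
                    sel_records.append({"repeat": r, "fold": f, "calibrator": kind, **s})
                pred_blocks[method].append(
                    pd.DataFrame(
                        {
                            "repeat": r,
                            "fold": f,
                            "method": method,
                            "patient_id": test_sl.patient_id,
                            "task": test_sl.task,
                            "group": test_sl.group,
                            "y": y_test,
                            "pred": pred,
                            "score": score,
                            "prob": probs,
                        }
                    )
                )
    if n_undefined_auc:
        logger.info("%d outer iterations had single-class test folds (AUC undefined)", n_undefined_auc)
    predictions = pd.concat(
        [pd.concat(pred_blocks[m], ignore_index=True) for m in methods], ignore_index=True
    )
    rec_df = pd.DataFrame(records)
    return CVOutcome(
        records=rec_df,
        predictions=predictions,
        selection=sel_records,
        audit=audit,
        config=config,
        methods=methods,
    )


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    method_a: str
    method_b: str
    delta_f1: float
    f1_p: float
    f1_p_holm: float
    acc_p: float
    acc_p_holm: float
    b_discordant: int
    c_discordant: int
    b_boot: int


def _patient_counts(sub: pd.DataFrame, pat_order):
    """Per-patient (tp, fp, fn, correct, total) pooled over rows."""
    y = sub["y"].to_numpy()
    p = sub["pred"].to_numpy()
    df = pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "tp": (p == 1) & (y == 1),
            "fp": (p == 1) & (y == 0),
            "fn": (p == 0) & (y == 1),
        }
    )
    agg = df.groupby("patient_id").sum().reindex(pat_order, fill_value=0)
    return agg[["tp", "fp", "fn"]].to_numpy(dtype=float)


def compare_methods(outcome: CVOutcome, b_boot: int = 1000, seed: int = 0) -> list:
    """All pairwise method comparisons: paired bootstrap F1 + McNemar accuracy.

    The bootstrap resamples patients (keeping every pooled outer-test row of
    a resampled patient, across repeats) so within-patient correlation is
    respected; p-values carry the (count+1)/(B+1) plus-one correction.
    McNemar uses pooled per-row predictions at matched (repeat, fold);
    the exact binomial form is used when b + c < 25.  Holm step-down is
    applied within each metric family across all pairs.
    """
    preds = outcome.predictions
    methods = list(outcome.methods)
    pairs = list(itertools.combinations(methods, 2))
    pat_order = sorted(preds["patient_id"].unique())
    n_pat = len(pat_order)
    rng = np.random.default_rng(seed % _MOD)
    W = rng.multinomial(n_pat, np.full(n_pat, 1.0 / n_pat), size=b_boot).astype(float)

    counts = {m: _patient_counts(preds[preds["method"] == m], pat_order) for m in methods}
    aligned = {
        m: preds[preds["method"] == m].sort_values(
            ["repeat", "fold", "patient_id", "task"], kind="mergesort"
        ) for m in methods
    }

    raw_f1, raw_acc, meta = [], [], []
    for a, b in pairs:
        ca, cb = counts[a], counts[b]
        def boot_f1(c):
            tp = W @ c[:, 0]
            fp = W @ c[:, 1]
            fn = W @ c[:, 2]
            denom = 2 * tp + fp + fn
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(denom > 0, 2 * tp / denom, np.nan)
        delta = boot_f1(ca) - boot_f1(cb)
        delta = delta[~np.isnan(delta)]
        p_f1 = bootstrap_two_sided_p(delta) if len(delta) else 1.0

        pa = aligned[a]["pred"].to_numpy()
        pb = aligned[b]["pred"].to_numpy()
        yy = aligned[a]["y"].to_numpy()
        ok_a, ok_b = pa == yy, pb == yy
        bd = int((ok_a & ~ok_b).sum())
        cd = int((~ok_a & ok_b).sum())
        p_acc = mcnemar_p(bd, cd)

        def point_f1(c):
            tp, fp, fn = c.sum(axis=0)
            d = 2 * tp + fp + fn
            return 2 * tp / d if d > 0 else np.nan

        raw_f1.append(p_f1)
        raw_acc.append(p_acc)
        meta.append((a, b, float(point_f1(ca) - point_f1(cb)), bd, cd))

    adj_f1 = holm(raw_f1)
    adj_acc = holm(raw_acc)
    out = []
    for i, (a, b, d, bd, cd) in enumerate(meta):
        out.append(
            ComparisonResult(
                method_a=a, method_b=b, delta_f1=d,
                f1_p=raw_f1[i], f1_p_holm=float(adj_f1[i]),
                acc_p=raw_acc[i], acc_p_holm=float(adj_acc[i]),
                b_discordant=bd, c_discordant=cd, b_boot=b_boot,
            )
        )
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def format_cell(mean, sd, lo, hi) -> str:
    return f"{mean:.3f} ± {sd:.3f} [{lo:.3f}, {hi:.3f}]"


def summarize(outcome: CVOutcome) -> dict:
    """Per-method metric aggregates and selection frequencies.

    Aggregates are mean, sd and the percentile [2.5%, 97.5%] interval over
    outer iterations; undefined (None) metric cells are excluded from the
    aggregation of their metric only.
    """
    rec = outcome.records.copy()
    rows = []
    for method in outcome.methods:
        sub = rec[rec["method"] == method]
        for metric in METRIC_COLUMNS:
            vals = pd.to_numeric(sub[metric], errors="coerce").dropna().to_numpy()
            if len(vals) == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "ci_low": float(np.percentile(vals, 2.5)),
                    "ci_high": float(np.percentile(vals, 97.5)),
                    "n_iterations": int(len(vals)),
                }
            )
    table = pd.DataFrame(rows)

    sel = pd.DataFrame(outcome.selection)
    baseline_freq, member_freq = {}, {}
    if len(sel):
        for method in outcome.methods:
            sub = sel[sel["method"] == method]
            if "baseline" in sub.columns:
                base = sub["baseline"].dropna()
                if len(base):
                    baseline_freq[method] = (base.value_counts(normalize=True)).to_dict()
            if "model" in sub.columns:
                base = sub["model"].dropna() if "model" in sub else []
                if len(base):
                    baseline_freq[method] = (base.value_counts(normalize=True)).to_dict()
            if "members" in sub.columns:
                combos = sub["members"].dropna().map(lambda ms: "+".join(sorted(ms)))
                if len(combos):
                    member_freq[method] = combos.value_counts(normalize=True).to_dict()
    return {"metrics": table, "baseline_frequency": baseline_freq, "member_frequency": member_freq}
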
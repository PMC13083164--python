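"""Voting-score aggregation and ensemble construction.

Three construction strategies are provided, all selected strictly on
training data via an inner cross-validation loop:

* **standard** — the better of four classical benchmarks (majority voting,
  top-N voting with N in {3, 5, 7}, replicate-consistency ("confidence")
  weighting, and F1-weighted voting), each thresholded at 0.5.
* **advanced global** — a baseline rater chosen by F1 plus two raters added
  greedily to maximize J(m | S) = f1_hat(m) + beta * div(m, S), where
  f1_hat is the min-max-normalized training F1 and div(m, S) is the mean
  pairwise disagreement rate between m and the current members; beta is
  grid-searched and the decision threshold tau is searched over
  0.30..1.00 in steps of 0.05 by inner-CV objective.
* **advanced grouped** — the same construction fitted separately per task
  group, so each clinical-input modality gets its own member set and
  threshold.

The ensemble's continuous output is the weighted, normalized voting score
sum(w_i * pred_i) / sum(w_i); the binary decision is score >= tau.
Tie-breaking is fully specified (higher objective, then smaller beta,
smaller tau, lexicographic member names) so selection is reproducible.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import PredictionDataset
from .folds import make_folds

logger = logging.getLogger(__name__)

TAU_GRID = tuple(np.round(np.arange(0.30, 1.0001, 0.05), 10).tolist())
BETA_GRID = (0.5, 1.0, 1.5, 2.0)
STANDARD_TIE_ORDER = ("majority", "top_n_voting", "weighted", "confidence")


@dataclass
class SearchConfig:
    beta_grid: tuple = BETA_GRID
    tau_grid: tuple = TAU_GRID
    standard_candidates: tuple = STANDARD_TIE_ORDER
    objective: str = "f1"
    top_n_options: tuple = (3, 5, 7)
    ensemble_size: int = 3
    exhaustive: bool = False


@dataclass
class EnsembleSpec:
    """A fitted ensemble: members, weights, threshold, provenance."""

    members: tuple
    weights: tuple
    threshold: float
    group: str = "GLOBAL"
    beta: float | None = None
    strategy: str = "advanced"
    calibrator_kind: str | None = None

    def score(self, P: np.ndarray, model_names) -> np.ndarray:
        cols = [list(model_names).index(m) for m in self.members]
        return vote_score(P[:, cols], self.weights)

    def predict(self, P: np.ndarray, model_names) -> np.ndarray:
        return decide(self.score(P, model_names), self.threshold)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleSpec":
        d = json.loads(text)
        d["members"] = tuple(d["members"])
        d["weights"] = tuple(d["weights"])
        return cls(**d)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def vote_score(member_predictions, weights) -> np.ndarray:
    """Weighted normalized vote: sum(w_i * pred_i) / sum(w_i).

    ``member_predictions`` is (n_members,) for a single case or
    (n_cases, n_members).
    """
    P = np.asarray(member_predictions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    if P.ndim == 1:
        return float(P @ w / w.sum())
    return P @ w / w.sum()


def decide(scores, tau: float) -> np.ndarray:
    """Binary decision: 1 iff score >= tau (inclusive at the boundary)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    s = np.asarray(scores, dtype=float)
    return (s >= tau).astype(int)


# ---------------------------------------------------------------------------
# training slices
# ---------------------------------------------------------------------------

@dataclass
class TrainingSlice:
    """Matrix view of a dataset (or subset) for selection and evaluation."""

    P: np.ndarray          # (rows, models) replicate-1 predictions
    y: np.ndarray          # (rows,) labels
    patient_id: np.ndarray  # (rows,)
    task: np.ndarray        # (rows,)
    group: np.ndarray       # (rows,) group label per row
    age: np.ndarray         # (rows,)
    model_names: tuple
    consistency: np.ndarray  # per-model replicate unanimity rate

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def subset(self, row_mask) -> "TrainingSlice":
        m = np.asarray(row_mask)
        return TrainingSlice(
            P=self.P[m],
            y=self.y[m],
            patient_id=self.patient_id[m],
            task=self.task[m],
            group=self.group[m],
            age=self.age[m],
            model_names=self.model_names,
            consistency=self.consistency,
        )

    def patient_table(self):
        """Unique patients of the slice with their labels, in sorted order."""
        upat, idx = np.unique(self.patient_id, return_index=True)
        return upat, self.y[idx]


def make_slice(dataset: PredictionDataset, tasks=None) -> TrainingSlice:
    rows, P, models = dataset.matrix(tasks=tasks)
    consistency = replicate_consistency(dataset, models)
    return TrainingSlice(
        P=P,
        y=rows["label"].to_numpy().astype(int),
        patient_id=rows["patient_id"].to_numpy(),
        task=rows["task"].to_numpy(),
        group=rows["group"].to_numpy(),
        age=rows["age"].to_numpy(),
        model_names=tuple(models),
        consistency=consistency,
    )


def replicate_consistency(dataset: PredictionDataset, models=None) -> np.ndarray:
    """Fraction of (patient, task) cases with unanimous replicates per rater.

    Cases queried once count as unanimous, so single-replicate raters get 1.
    """
    models = list(models) if models is not None else dataset.models
    preds = dataset.predictions
    g = preds.groupby(["model", "patient_id", "task"])["prediction"].nunique() == 1
    per_model = g.groupby(level="model").mean()
    return np.array([float(per_model.get(m, 1.0)) for m in models])


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _objective_by_tau(scores, y, taus, objective):
    """Objective value at each threshold; NaN where undefined (0/0)."""
    pred = scores[:, None] >= np.asarray(taus)[None, :]
    yb = y.astype(bool)[:, None]
    tp = (pred & yb).sum(axis=0).astype(float)
    fp = (pred & ~yb).sum(axis=0).astype(float)
    fn = ((~pred) & yb).sum(axis=0).astype(float)
    tn = ((~pred) & ~yb).sum(axis=0).astype(float)
    if objective == "f1":
        denom = 2 * tp + fp + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, 2 * tp / denom, np.nan)
        return out
    if objective == "accuracy":
        return (tp + tn) / len(y)
    raise ValueError(f"unknown objective {objective!r}")


def _objective_cols(P, y, objective):
    """Objective per model column for binary predictions (tau irrelevant)."""
    yb = y.astype(bool)[:, None]
    pred = P.astype(bool)
    tp = (pred & yb).sum(axis=0).astype(float)
    fp = (pred & ~yb).sum(axis=0).astype(float)
    fn = ((~pred) & yb).sum(axis=0).astype(float)
    tn = ((~pred) & ~yb).sum(axis=0).astype(float)
    if objective == "f1":
        denom = 2 * tp + fp + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, 2 * tp / denom, np.nan)
    if objective == "accuracy":
        return (tp + tn) / len(y)
    raise ValueError(f"unknown objective {objective!r}")


def f1_per_model(P, y) -> np.ndarray:
    return _objective_cols(P, y, "f1")


def disagreement_matrix(P) -> np.ndarray:
    """Pairwise disagreement rate (fraction of rows with differing votes)."""
    Pf = P.astype(float)
    n = Pf.shape[0]
    agree = Pf.T @ Pf + (1 - Pf).T @ (1 - Pf)
    return 1.0 - agree / n


# ---------------------------------------------------------------------------
# inner folds
# ---------------------------------------------------------------------------

def _inner_fold_masks(sl: TrainingSlice, inner_folds: int, seed: int):
    """Patient-level stratified fold masks over slice rows.

    Returns a list of (train_mask, val_mask).  Falls back to apparent
    (train == validation) evaluation when a class is too small to split,
    which is logged.
    """
    upat, ulab = sl.patient_table()
    k = min(inner_folds, int(ulab.sum()), int((1 - ulab).sum()))
    if k < 2:
        logger.warning("inner split impossible (a class has < 2 patients); using apparent evaluation")
        full = np.ones(sl.n_rows, dtype=bool)
        return [(full, full)]
    assign = make_folds(ulab, k, 1, seed)[0]
    fold_of_patient = dict(zip(upat, assign))
    row_fold = np.array([fold_of_patient[p] for p in sl.patient_id])
    return [(row_fold != f, row_fold == f) for f in range(k)]


# ---------------------------------------------------------------------------
# standard ensemble benchmark
# ---------------------------------------------------------------------------

def _top_n_cols(obj, names, n):
    order = sorted(range(len(names)), key=lambda i: (-np.nan_to_num(obj[i]), names[i]))
    return order[:n]


def select_standard_ensemble(
    train: TrainingSlice, config: SearchConfig | None = None,
    inner_folds: int = 3, seed: int = 0,
) -> EnsembleSpec:
    """Pick the best classical voting benchmark by inner-CV mean objective.

    Candidates: majority (all raters, tau 0.5), top-N voting (equal weights
    over the N best-F1 raters, N in {3,5,7}, tau 0.5), confidence-based
    (weights = replicate consistency), and weighted (weights proportional to
    training F1).  Ties follow the fixed order majority > top_n_voting >
    weighted > confidence; smaller N wins within top-N.
    """
    config = config or SearchConfig()
    if len(set(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    names = train.model_names
    folds = _inner_fold_masks(train, inner_folds, seed)

    scores_per_cand = {}
    for cand in config.standard_candidates:
        if cand == "top_n_voting":
            for n in config.top_n_options:
                scores_per_cand[("top_n_voting", n)] = []
        else:
            scores_per_cand[(cand, None)] = []

    n_models = train.P.shape[1]
    for tr_mask, val_mask in folds:
        y_val = train.y[val_mask]
        if len(set(y_val)) < 2 and config.objective != "f1":
            logger.info("degenerate inner fold skipped")
            continue
        f1_tr = _objective_cols(train.P[tr_mask], train.y[tr_mask], "f1")
        P_val = train.P[val_mask]
        for key in scores_per_cand:
            cand, n = key
            if cand == "majority":
                s = P_val.mean(axis=1)
            elif cand == "top_n_voting":
                cols = _top_n_cols(f1_tr, names, min(n, n_models))
                s = P_val[:, cols].mean(axis=1)
            elif cand == "weighted":
                w = np.clip(np.nan_to_num(f1_tr), 0, None)
                if w.sum() <= 0:
                    w = np.ones(n_models)
                s = P_val @ w / w.sum()
            elif cand == "confidence":
                w = train.consistency.copy()
                if w.sum() <= 0:
                    w = np.ones(n_models)
                s = P_val @ w / w.sum()
            else:
                raise ValueError(f"unknown standard candidate {cand!r}")
            obj = _objective_by_tau(s, y_val, [0.5], config.objective)[0]
            scores_per_cand[key].append(obj)

    means = {}
    for key, vals in scores_per_cand.items():
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            raise ValueError("all inner folds degenerate for the objective")
        means[key] = float(np.mean(vals))

    def sort_key(key):
        cand, n = key
        return (-means[key], STANDARD_TIE_ORDER.index(cand), n if n is not None else 0)

    winner, win_n = sorted(means, key=sort_key)[0]

    f1_full = _objective_cols(train.P, train.y, "f1")
    if winner == "majority":
        members, weights = names, tuple([1.0] * n_models)
    elif winner == "top_n_voting":
        cols = _top_n_cols(f1_full, names, min(win_n, n_models))
        members = tuple(names[i] for i in cols)
        weights = tuple([1.0] * len(members))
    elif winner == "weighted":
        w = np.clip(np.nan_to_num(f1_full), 0, None)
        if w.sum() <= 0:
            w = np.ones(n_models)
        members, weights = names, tuple(w.tolist())
    else:  # confidence
        w = train.consistency.copy()
        if w.sum() <= 0:
            w = np.ones(n_models)
        members, weights = names, tuple(w.tolist())
    return EnsembleSpec(
        members=tuple(members),
        weights=weights,
        threshold=0.5,
        group="GLOBAL",
        beta=None,
        strategy=f"standard:{winner}" + (f"{win_n}" if winner == "top_n_voting" else ""),
    )


# ---------------------------------------------------------------------------
# advanced (diversity-regularized) ensemble
# ---------------------------------------------------------------------------

def _greedy_members(f1_hat, D, names, baseline_col, beta, size):
    members = [baseline_col]
    remaining = [i for i in range(len(names)) if i != baseline_col]
    while len(members) < size and remaining:
        div = D[np.ix_(remaining, members)].mean(axis=1)
        J = f1_hat[remaining] + beta * div
        order = sorted(range(len(remaining)), key=lambda i: (-J[i], names[remaining[i]]))
        members.append(remaining.pop(order[0]))
    return tuple(members)


def _exhaustive_members(f1_hat, D, names, baseline_col, beta, size):
    others = [i for i in range(len(names)) if i != baseline_col]
    best = None
    for combo in itertools.combinations(others, size - 1):
        full = (baseline_col,) + combo
        pairs = list(itertools.combinations(full, 2))
        div = np.mean([D[i, j] for i, j in pairs])
        J = sum(f1_hat[i] for i in combo) + beta * div
        key = (-J, tuple(sorted(names[i] for i in full)))
        if best is None or key < best[0]:
            best = (key, full)
    return best[1]


def select_advanced_ensemble(
    train: TrainingSlice, config: SearchConfig | None = None,
    scope: str = "GLOBAL", inner_folds: int = 3, seed: int = 0,
) -> EnsembleSpec:
    """Diversity-regularized ensemble: F1 baseline + two complementary raters.

    ``scope`` other than "GLOBAL" restricts training rows to that task
    group.  Ties across (beta, tau, member set) candidates are broken by
    smaller beta, then smaller tau, then lexicographic member names.
    """
    config = config or SearchConfig()
    sl = train if scope == "GLOBAL" else train.subset(train.group == scope)
    if sl.P.shape[1] < config.ensemble_size:
        raise ValueError(
            f"need at least {config.ensemble_size} raters, got {sl.P.shape[1]}"
        )
    if len(set(sl.y)) < 2:
        raise ValueError("training data must contain both classes")
    names = sl.model_names
    f1_full = np.nan_to_num(_objective_cols(sl.P, sl.y, "f1"))
    baseline_col = sorted(range(len(names)), key=lambda i: (-f1_full[i], names[i]))[0]
    span = f1_full.max() - f1_full.min()
    f1_hat = (f1_full - f1_full.min()) / span if span > 0 else np.zeros_like(f1_full)
    D = disagreement_matrix(sl.P)

    pick = _exhaustive_members if config.exhaustive else _greedy_members
    member_sets = {}  # tuple(cols) -> smallest beta proposing it
    for beta in sorted(config.beta_grid):
        cols = pick(f1_hat, D, names, baseline_col, beta, config.ensemble_size)
        member_sets.setdefault(cols, beta)

    folds = _inner_fold_masks(sl, inner_folds, seed)
    taus = np.asarray(config.tau_grid)
    best = None
    for cols, beta in member_sets.items():
        scores = sl.P[:, list(cols)].mean(axis=1)
        per_fold = []
        for tr_mask, val_mask in folds:
            obj = _objective_by_tau(scores[val_mask], sl.y[val_mask], taus, config.objective)
            per_fold.append(obj)
        stacked = np.vstack(per_fold)
        with np.errstate(invalid="ignore"):
            mean_obj = np.nanmean(stacked, axis=0)
        mean_obj = np.where(np.isnan(mean_obj), -np.inf, mean_obj)
        ti = int(np.argmax(mean_obj))  # argmax returns smallest tau on ties
        key = (
            -mean_obj[ti],
            beta,
            taus[ti],
            tuple(sorted(names[i] for i in cols)),
        )
        if best is None or key < best[0]:
            best = (key, cols, beta, float(taus[ti]))

    _, cols, beta, tau = best
    return EnsembleSpec(
        members=tuple(names[i] for i in cols),
        weights=tuple([1.0] * len(cols)),
        threshold=tau,
        group=scope,
        beta=beta,
        strategy="advanced",
    )


def best_single_model(
    train: TrainingSlice, inner_folds: int = 3, seed: int = 0, objective: str = "f1"
) -> str:
    """The single rater with the best inner-CV mean objective (ties: name)."""
    folds = _inner_fold_masks(train, inner_folds, seed)
    per_fold = []
    for _tr, val_mask in folds:
        per_fold.append(_objective_cols(train.P[val_mask], train.y[val_mask], objective))
    with np.errstate(invalid="ignore"):
        mean_obj = np.nanmean(np.vstack(per_fold), axis=0)
    mean_obj = np.nan_to_num(mean_obj, nan=-np.inf)
    names = train.model_names
    order = sorted(range(len(names)), key=lambda i: (-mean_obj[i], names[i]))
    return names[order[0]]
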
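"""Probability calibration and clinical-utility measures.

Voting scores in [0, 1] are mapped to calibrated probabilities by Platt
scaling (a two-parameter logistic map fitted with smoothed targets, which
keeps the likelihood bounded on separable data) or isotonic regression
(pool-adjacent-violators).  Which family to use is chosen by inner-loop
cross-validated Brier score, with ties going to the smoother Platt map.

Probabilistic quality is summarized by the Brier score and by expected /
maximum calibration error over equal-width bins; clinical utility by
decision-curve net benefit NB(t) = TP/n - FP/n * t / (1 - t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.isotonic import IsotonicRegression

from .folds import make_folds


@dataclass
class Calibrator:
    """A fitted score -> probability map.

    ``kind`` is one of platt / isotonic / identity.  Platt stores (a, b) of
    sigma(a*s + b); isotonic stores its breakpoints and fitted values.
    """

    kind: str
    a: float | None = None
    b: float | None = None
    x_thresholds: np.ndarray | None = None
    y_thresholds: np.ndarray | None = None

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if self.kind == "identity":
            return np.clip(s, 0.0, 1.0)
        if self.kind == "platt":
            return expit(self.a * s + self.b)
        if self.kind == "isotonic":
            return np.interp(s, self.x_thresholds, self.y_thresholds)
        raise ValueError(f"unknown calibrator kind {self.kind!r}")


def _check_two_classes(labels):
    y = np.asarray(labels).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required to fit a calibrator")
    return y


def fit_platt(scores, labels, max_iter: int = 200) -> Calibrator:
    """Platt scaling with smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2).

    Newton optimization of the regularized cross-entropy, following the
    numerically stable formulation of Lin, Lin & Weng.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_two_classes(labels)
    if len(s) < 4:
        raise ValueError("need at least 4 points to fit Platt scaling")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    a, b = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    sigma = 1e-12

    def nll(a, b):
        f = a * s + b
        return float(np.sum(np.logaddexp(0.0, f) - t * f))

    current = nll(a, b)
    for _ in range(max_iter):
        f = a * s + b
        p = expit(f)
        d1 = p - t
        d2 = np.clip(p * (1 - p), 1e-12, None)
        g = np.array([np.sum(d1 * s), np.sum(d1)])
        if np.abs(g).max() < 1e-10:
            break
        H = np.array(
            [
                [np.sum(d2 * s * s) + sigma, np.sum(d2 * s)],
                [np.sum(d2 * s), np.sum(d2) + sigma],
            ]
        )
        step = np.linalg.solve(H, g)
        stepsize = 1.0
        for _ in range(30):
            na, nb = a - stepsize * step[0], b - stepsize * step[1]
            cand = nll(na, nb)
            if cand < current + 1e-12:
                a, b, current = na, nb, cand
                break
            stepsize /= 2.0
        else:
            break
    return Calibrator(kind="platt", a=float(a), b=float(b))


def fit_isotonic(scores, labels) -> Calibrator:
    """Isotonic (PAV) calibration; out-of-range scores clamp to end values."""
    s = np.asarray(scores, dtype=float)
    y = _check_two_classes(labels)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip")
    iso.fit(s, y)
    return Calibrator(
        kind="isotonic",
        x_thresholds=np.asarray(iso.X_thresholds_, dtype=float),
        y_thresholds=np.asarray(iso.y_thresholds_, dtype=float),
    )


def fit_calibrator(kind: str, scores, labels) -> Calibrator:
    if kind == "platt":
        return fit_platt(scores, labels)
    if kind == "isotonic":
        return fit_isotonic(scores, labels)
    if kind == "identity":
        return Calibrator(kind="identity")
    raise ValueError(f"unknown calibrator kind {kind!r}")


def brier(probs, labels) -> float:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    return float(np.mean((p - y) ** 2))


@dataclass
class CalibrationReport:
    brier: float
    ece: float
    mce: float
    bin_table: list  # (count, mean predicted, observed frequency) per non-empty bin


def calibration_report(probs, labels, n_bins: int = 10) -> CalibrationReport:
    """Brier, ECE and MCE over equal-width probability bins (empty bins dropped)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0,1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    table = []
    ece = 0.0
    mce = 0.0
    n = len(p)
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        conf = float(p[m].mean())
        acc = float(y[m].mean())
        gap = abs(acc - conf)
        ece += (m.sum() / n) * gap
        mce = max(mce, gap)
        table.append((int(m.sum()), conf, acc))
    return CalibrationReport(brier=brier(p, y), ece=float(ece), mce=float(mce), bin_table=table)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(probs, labels, thresholds) -> NetBenefitCurve:
    """Decision-curve net benefit with treat-all / treat-none references.

    Positivity at threshold t is p >= t; NB(t) = TP/n - FP/n * t/(1-t).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    t = np.asarray(thresholds, dtype=float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly within (0, 1)")
    n = len(y)
    prev = y.mean()
    nb = np.empty(len(t))
    for i, ti in enumerate(t):
        pos = p >= ti
        tp = (pos & (y == 1)).sum() / n
        fp = (pos & (y == 0)).sum() / n
        nb[i] = tp - fp * ti / (1.0 - ti)
    treat_all = prev - (1.0 - prev) * t / (1.0 - t)
    return NetBenefitCurve(
        thresholds=t, net_benefit=nb, treat_all=treat_all, treat_none=np.zeros(len(t))
    )


def select_calibrator(scores, labels, inner_folds: int = 3, seed: int = 0) -> str:
    """Pick platt vs isotonic by inner-CV mean Brier score (ties -> platt)."""
    s = np.asarray(scores, dtype=float)
    y = _check_two_classes(labels)
    k = min(inner_folds, int(y.sum()), int(len(y) - y.sum()))
    if k < 2:
        return "platt"
    assign = make_folds(y, k, 1, seed)[0]
    losses = {"platt": [], "isotonic": []}
    for f in range(k):
        tr, va = assign != f, assign == f
        if y[tr].sum() in (0, tr.sum()):
            continue
        for kind in losses:
            try:
                cal = fit_calibrator(kind, s[tr], y[tr])
            except ValueError:
                continue
            losses[kind].append(brier(cal.predict(s[va]), y[va]))
    mean = {k2: np.mean(v) if v else np.inf for k2, v in losses.items()}
    if mean["isotonic"] < mean["platt"]:
        return "isotonic"
    return "platt"
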
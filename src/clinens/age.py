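"""Age-heterogeneity analysis of rater/ensemble scores.

Two complementary views of whether discrimination depends on patient age:

* a scan over integer age cut-points (each side holding at least ``min_n``
  patients) comparing subgroup ROC-AUCs by stratified bootstrap, with
  Holm-Bonferroni adjustment across the scanned cut-points; and
* a logistic model in which continuous age enters through a restricted
  cubic spline (default df = 4, knots at Harrell's quantiles) and the
  age x score interaction is tested by a likelihood-ratio test against the
  nested main-effects model.

Bootstrap p-values are two-sided Monte-Carlo values floored at 1/(B+1); a
raw exceedance count of zero is flagged so reports can render the
conventional "p < 1/(B+1)" marker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .metrics import auc, auc_rows
from .stats import holm

logger = logging.getLogger(__name__)

_MOD = 2**31

#: Harrell's default knot quantiles by knot count (k knots -> k-1 df)
HARRELL_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.5, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineConfig:
    df: int = 4
    knot_quantiles: tuple | None = None  # default: Harrell quantiles for df+1 knots

    def quantiles(self) -> tuple:
        if self.knot_quantiles is not None:
            return tuple(self.knot_quantiles)
        k = self.df + 1
        if k in HARRELL_QUANTILES:
            return HARRELL_QUANTILES[k]
        return tuple(np.linspace(0.05, 0.95, k))


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    n_young: int
    n_old: int
    delta_auc: float
    ci: tuple
    p_raw: float
    p_holm: float
    below_floor: bool  # zero raw exceedances: render as "p < 1/(B+1)"
    B: int


@dataclass
class InteractionTest:
    loglik_full: float
    loglik_reduced: float
    lrt_stat: float
    lrt_df: int
    p: float
    coef_full: dict
    coef_reduced: dict
    curves: dict  # age percentile label -> (score grid, predicted probability)
    score_at_half: dict  # age percentile label -> smallest score with p >= 0.5


# ---------------------------------------------------------------------------
# cut-point scan
# ---------------------------------------------------------------------------

def candidate_cutpoints(ages, min_n: int = 10) -> list:
    """Integer-year cut-points c with #(age < c) >= min_n and #(age >= c) >= min_n."""
    a = np.asarray(ages, dtype=float)
    if len(a) == 0:
        raise ValueError("ages must be non-empty")
    out = []
    for c in range(int(np.floor(a.min())) + 1, int(np.ceil(a.max())) + 1):
        if (a < c).sum() >= min_n and (a >= c).sum() >= min_n:
            out.append(c)
    return out


def _stratified_boot_auc(scores, labels, B, rng):
    """Bootstrap AUC replicates resampling within each label stratum."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    s_pos, s_neg = s[y == 1], s[y == 0]
    n1, n0 = len(s_pos), len(s_neg)
    S = np.concatenate(
        [
            s_pos[rng.integers(0, n1, size=(B, n1))],
            s_neg[rng.integers(0, n0, size=(B, n0))],
        ],
        axis=1,
    )
    yy = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    return auc_rows(S, yy)


def cutpoint_scan(
    scores, labels, ages, min_n: int = 10, B: int = 1000, seed: int = 0
) -> list:
    """Bootstrap ΔAUC = AUC(young) − AUC(old) at every eligible cut-point.

    Patients are resampled within each (subgroup, label) stratum, so both
    classes stay present in every replicate.  Confidence intervals are
    percentile 2.5/97.5; the Holm adjustment spans all scanned cut-points.
    Cut-points where a subgroup lacks a class are skipped (logged).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    a = np.asarray(ages, dtype=float)
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates give unstable intervals", stacklevel=2)
    rng = np.random.default_rng(seed % _MOD)
    results = []
    for c in candidate_cutpoints(a, min_n):
        young = a < c
        ok = all(
            len(set(y[m])) == 2 for m in (young, ~young)
        )
        if not ok:
            logger.info("cut-point %s skipped: a subgroup has a single class", c)
            continue
        d_point = auc(s[young], y[young]) - auc(s[~young], y[~young])
        d_boot = _stratified_boot_auc(s[young], y[young], B, rng) - _stratified_boot_auc(
            s[~young], y[~young], B, rng
        )
        lo, hi = np.percentile(d_boot, [2.5, 97.5])
        frac = 2.0 * min(float((d_boot <= 0).mean()), float((d_boot >= 0).mean()))
        below = frac == 0.0
        p_raw = min(1.0, max(frac, 1.0 / (B + 1)))
        results.append(
            CutpointResult(
                cutpoint=float(c),
                n_young=int(young.sum()),
                n_old=int((~young).sum()),
                delta_auc=float(d_point),
                ci=(float(lo), float(hi)),
                p_raw=p_raw,
                p_holm=np.nan,  # filled below
                below_floor=below,
                B=B,
            )
        )
    if results:
        adj = holm([r.p_raw for r in results])
        results = [
            CutpointResult(
                cutpoint=r.cutpoint, n_young=r.n_young, n_old=r.n_old,
                delta_auc=r.delta_auc, ci=r.ci, p_raw=r.p_raw,
                p_holm=float(adj[i]), below_floor=r.below_floor, B=r.B,
            )
            for i, r in enumerate(results)
        ]
    return results


# ---------------------------------------------------------------------------
# restricted cubic spline interaction
# ---------------------------------------------------------------------------

def rcs_knots(ages, config: SplineConfig) -> np.ndarray:
    a = np.asarray(ages, dtype=float)
    if len(np.unique(a)) < config.df + 1:
        raise ValueError("need at least df+1 distinct values to place knots")
    knots = np.quantile(a, config.quantiles())
    if not np.all(np.diff(knots) > 0):
        raise ValueError(f"degenerate (tied) knots {knots.tolist()}")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    For k knots the basis has k-1 columns: the identity plus k-2 nonlinear
    terms, each constructed so the function is linear beyond the boundary
    knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[k - 2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


class ConvergenceError(RuntimeError):
    def __init__(self, message, deviance=None):
        super().__init__(message)
        self.deviance = deviance


def _logistic_irls(X, y, ridge: float = 1e-8, max_iter: int = 100, tol: float = 1e-10):
    """Ridge-stabilized IRLS for logistic regression with step-halving.

    Returns (beta, loglik).  The tiny ridge keeps the normal equations
    solvable under near-separation; a diverging coefficient norm is reported
    as an error rather than silently returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    current = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        g = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular IRLS system: {exc}", deviance=-2 * current)
        stepsize = 1.0
        improved = False
        for _ in range(30):
            cand = beta + stepsize * step
            ll = loglik(cand)
            if ll >= current - 1e-12:
                beta, current = cand, ll
                improved = True
                break
            stepsize /= 2.0
        if not improved or np.abs(stepsize * step).max() < tol:
            break
        if np.linalg.norm(beta) > 1e8:
            raise ConvergenceError("perfect separation (diverging coefficients)",
                                   deviance=-2 * current)
    return beta, current


def fit_interaction(scores, ages, labels, config: SplineConfig | None = None) -> InteractionTest:
    """Likelihood-ratio test for an age x score interaction.

    Reduced model: logit P(y=1) = a + g*score + spline(age).
    Full model adds score x spline(age) terms (df columns), so the LRT has
    df degrees of freedom.  Probability curves and the smallest score whose
    predicted probability reaches 0.5 are reported at the 25th/50th/75th age
    percentiles.
    """
    config = config or SplineConfig()
    s = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    knots = rcs_knots(a, config)
    S_age = rcs_basis(a, knots)
    one = np.ones(len(y))
    X_red = np.column_stack([one, s, S_age])
    X_full = np.column_stack([X_red, s[:, None] * S_age])
    if len(y) < 10 * X_full.shape[1]:
        warnings.warn(
            f"n={len(y)} below 10x parameter count ({X_full.shape[1]})", stacklevel=2
        )
    beta_red, ll_red = _logistic_irls(X_red, y)
    beta_full, ll_full = _logistic_irls(X_full, y)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    df = S_age.shape[1]
    p = float(chi2.sf(stat, df))

    spline_names = ["age"] + [f"age_s{j}" for j in range(1, S_age.shape[1])]
    red_names = ["intercept", "score"] + spline_names
    full_names = red_names + [f"score:{nm}" for nm in spline_names]

    grid = np.linspace(0.0, 1.0, 101)
    curves, score_at_half = {}, {}
    for q, label in ((25, "p25"), (50, "p50"), (75, "p75")):
        age_q = float(np.percentile(a, q))
        Sq = rcs_basis(np.full(len(grid), age_q), knots)
        Xq = np.column_stack([np.ones(len(grid)), grid, Sq, grid[:, None] * Sq])
        pq = expit(Xq @ beta_full)
        curves[label] = (grid, pq)
        above = np.where(pq >= 0.5)[0]
        score_at_half[label] = float(grid[above[0]]) if len(above) else None
    return InteractionTest(
        loglik_full=ll_full,
        loglik_reduced=ll_red,
        lrt_stat=stat,
        lrt_df=df,
        p=p,
        coef_full=dict(zip(full_names, beta_full.tolist())),
        coef_reduced=dict(zip(red_names, beta_red.tolist())),
        curves=curves,
        score_at_half=score_at_half,
    )
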
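"""Inter- and intra-rater agreement: Fleiss' kappa, Spearman correlation
matrices and hierarchical clustering of raters.

Fleiss' kappa quantifies chance-corrected agreement among a fixed number of
ratings per item — here, repeat queries of the same rater on the same case.
Rater similarity uses Spearman correlation of flattened (patient, task)
prediction vectors, clustered with average linkage on the distance 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr


@dataclass(frozen=True)
class AgreementResult:
    kappa: float | None
    mean_observed_agreement: float
    expected_agreement: float


def fleiss_kappa(ratings) -> AgreementResult:
    """Fleiss' kappa from an items x categories count table.

    Every item must carry the same number n >= 2 of ratings.  Unanimity on
    every item yields kappa = 1; a degenerate table where expected agreement
    is 1 but observed is not (impossible for count tables) would yield the
    undefined marker ``None``.
    """
    T = np.asarray(ratings, dtype=float)
    if T.ndim != 2:
        raise ValueError("ratings must be a 2-D items x categories table")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    n_per_item = T.sum(axis=1)
    if len(np.unique(n_per_item)) != 1:
        raise ValueError("unequal rating counts per item")
    n = float(n_per_item[0])
    if n < 2:
        raise ValueError("need at least 2 ratings per item")
    N = T.shape[0]
    P_i = ((T**2).sum(axis=1) - n) / (n * (n - 1))
    P_bar = float(P_i.mean())
    p_j = T.sum(axis=0) / (N * n)
    P_e = float((p_j**2).sum())
    if 1.0 - P_bar < 1e-15:
        kappa = 1.0
    elif 1.0 - P_e < 1e-15:
        kappa = None
    else:
        kappa = (P_bar - P_e) / (1.0 - P_e)
    return AgreementResult(kappa=kappa, mean_observed_agreement=P_bar, expected_agreement=P_e)


def binary_replicate_table(dataset, model: str, tasks=None) -> np.ndarray:
    """Items x 2 count table of replicate answers for one rater.

    Items are (patient, task) pairs restricted to tasks carrying more than
    one replicate (optionally further restricted to ``tasks``).
    """
    preds = dataset.predictions
    sub = preds[preds["model"] == model]
    if tasks is not None:
        sub = sub[sub["task"].isin(tasks)]
    counts = sub.groupby(["patient_id", "task"])["replicate"].max()
    keep = counts[counts >= 2].index
    sub = sub.set_index(["patient_id", "task"]).loc[keep].reset_index()
    g = sub.groupby(["patient_id", "task"])["prediction"]
    ones = g.sum()
    total = g.count()
    table = np.column_stack([(total - ones).to_numpy(), ones.to_numpy()])
    return table.astype(int)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlation of raters plus an average-linkage tree.

    ``rho`` is symmetric with unit diagonal; entries involving a
    constant-prediction rater are NaN and that rater is excluded from the
    clustering (``excluded``).  ``linkage_matrix`` follows the SciPy linkage
    convention over ``clustered_models``.
    """

    models: list
    rho: np.ndarray
    linkage_matrix: np.ndarray | None
    clustered_models: list
    excluded: list

    def cut(self, n_clusters: int) -> dict:
        """Flat cluster labels for the clustered raters."""
        from scipy.cluster.hierarchy import fcluster

        if self.linkage_matrix is None:
            raise ValueError("no clustering available")
        labels = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.clustered_models, labels.tolist()))


def model_correlation(dataset, tasks=None) -> CorrelationMatrix:
    """Spearman correlation matrix over raters, with hierarchical clustering.

    Each rater's replicate-1 predictions over (patient, task in subset) are
    flattened to one vector; pairwise midrank Spearman rho is computed and
    raters are merged by average linkage on 1 - rho.
    """
    rows, P, models = dataset.matrix(tasks=tasks)
    if P.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    const = np.ptp(P, axis=0) == 0
    rho = np.full((len(models), len(models)), np.nan)
    keep = np.where(~const)[0]
    if len(keep) >= 2:
        sub_rho = spearmanr(P[:, keep]).statistic
        sub_rho = np.atleast_2d(sub_rho)
        if sub_rho.shape == (1, 1):  # spearmanr collapses the 2-rater case
            c = float(spearmanr(P[:, keep[0]], P[:, keep[1]]).statistic)
            sub_rho = np.array([[1.0, c], [c, 1.0]])
        rho[np.ix_(keep, keep)] = sub_rho
    np.fill_diagonal(rho, 1.0)

    excluded = [models[i] for i in np.where(const)[0]]
    clustered = [models[i] for i in keep]
    link = None
    if len(keep) >= 2:
        d = 1.0 - rho[np.ix_(keep, keep)]
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        link = linkage(squareform(d, checks=False), method="average")
    return CorrelationMatrix(
        models=models,
        rho=rho,
        linkage_matrix=link,
        clustered_models=clustered,
        excluded=excluded,
    )
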
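"""Population structure: PCA, k-means with BIC model choice, and DAPC.

Follows the find.clusters / DAPC workflow: genotypes are mean-imputed and
PC-transformed, the number of clusters K is chosen by the BIC of the best
k-means solution per K (BIC = n*log(WSS/n) + K*log(n)), and a linear
discriminant analysis on a cross-validated number of retained PCs yields
per-individual membership probabilities. Cross-validation withholds whole
sampling locations (20% by default), not random individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterSolution", "DAPCResult", "impute_and_pca",
           "select_k_bic", "dapc_assign"]


def impute_and_pca(g: GenotypeMatrix | np.ndarray,
                   n_components: int | None = None):
    """Mean-impute missing dosages per SNP, center, and PCA via SVD.

    Returns (scores, explained_variance) where scores are the principal
    component projections (orthogonal columns) and explained_variance the
    per-axis variances, non-increasing. ``n_components`` beyond the matrix
    rank is reduced with a warning.
    """
    x = g.dosages.copy() if isinstance(g, GenotypeMatrix) else np.array(g, dtype=float)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components is None:
        n_components = rank
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; reduced", n_components, rank)
        n_components = rank
    scores = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / max(x.shape[0] - 1, 1)
    return scores, explained


@dataclass
class ClusterSolution:
    """k-means clustering over a K range with the BIC curve."""

    k: int
    assignments: np.ndarray                 # 1-based hard labels at the chosen K
    bic: pd.Series                          # BIC per candidate K
    labels_per_k: dict = field(default_factory=dict)
    probabilities: np.ndarray | None = None
    n_pcs: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.assignments.min() < 1 or self.assignments.max() > self.k:
            raise ValueError("assignments must lie in 1..K")


def select_k_bic(scores: np.ndarray, k_range=range(1, 11), n_starts: int = 10,
                 seed: int = 0) -> ClusterSolution:
    """Choose K by the BIC of the best of ``n_starts`` k-means runs per K.

    BIC = n*log(WSS/n) + K*log(n), the find.clusters convention. Returns the
    full BIC curve and the argmin solution.
    """
    n = scores.shape[0]
    k_range = [k for k in k_range if 1 <= k <= max(n // 2, 1)]
    if not k_range:
        raise ValueError("empty K range after clipping to [1, n/2]")
    bics, labels = {}, {}
    for k in k_range:
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels[k] = np.ones(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            lab = km.fit_predict(scores)
            wss = float(km.inertia_)
            labels[k] = lab + 1
        bics[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
    bic = pd.Series(bics).sort_index()
    best = int(bic.idxmin())
    return ClusterSolution(k=best, assignments=labels[best], bic=bic,
                           labels_per_k=labels)


@dataclass
class DAPCResult:
    n_pcs: int
    assignments: np.ndarray          # 1-based predicted cluster
    probabilities: np.ndarray        # rows sum to 1
    cv_table: pd.DataFrame           # held-out success per candidate n_pc
    lda: LinearDiscriminantAnalysis = None


def dapc_assign(scores: np.ndarray, groups: np.ndarray,
                locations: np.ndarray, n_pc_grid=None,
                holdout_frac: float = 0.2, n_rep: int = 10,
                seed: int = 0) -> DAPCResult:
    """Discriminant analysis of principal components with location-holdout CV.

    ``groups`` are 1-based prior cluster labels (e.g. from
    :func:`select_k_bic`); ``locations`` are sampling-location labels used
    to withhold whole locations (20% by default) when cross-validating the
    number of retained PCs. Membership probabilities come from the fitted
    LDA posterior.
    """
    groups = np.asarray(groups)
    locations = np.asarray(locations)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    max_pc = min(scores.shape[1], scores.shape[0] - len(uniq) - 1)
    if n_pc_grid is None:
        n_pc_grid = sorted({max(1, int(round(f * max_pc)))
                            for f in (0.1, 0.25, 0.5, 0.75, 1.0)})
    rng = np.random.default_rng(seed)
    loc_ids = np.unique(locations)
    n_hold = max(1, int(round(holdout_frac * len(loc_ids))))
    rows = []
    for n_pc in n_pc_grid:
        succ = []
        for _ in range(n_rep):
            held = rng.choice(loc_ids, size=n_hold, replace=False)
            test = np.isin(locations, held)
            train = ~test
            if len(np.unique(groups[train])) < 2 or not test.any():
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(scores[train, :n_pc], groups[train])
            known = np.isin(groups[test], lda.classes_)
            if not known.any():
                continue
            succ.append(float((lda.predict(scores[test, :n_pc])[known]
                               == groups[test][known]).mean()))
        rows.append({"n_pc": n_pc, "success": np.mean(succ) if succ else np.nan})
    cv = pd.DataFrame(rows)
    best = int(cv.loc[cv["success"].idxmax(), "n_pc"])
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores[:, :best], groups)
    proba = lda.predict_proba(scores[:, :best])
    pred = lda.predict(scores[:, :best])
    return DAPCResult(n_pcs=best, assignments=pred, probabilities=proba,
                      cv_table=cv, lda=lda)
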
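"""Random-forest turnover functions and R2-weighted predictor importance.

Each candidate SNP's population allele frequencies are fit with an
ensemble of regression trees on the environmental predictors; SNPs with
positive out-of-bag R2 are retained. Predictor importance is the mean
R2-weighted permutation importance over retained SNPs; for predictors
correlated above a threshold the permutation is conditional (the
predictor is shuffled within quantile bins of its strongest correlate) so
shared signal is not double-counted. Split improvements are pooled along
each gradient, standardized by the data density, and accumulated into a
monotone cumulative turnover function whose plateau equals the
predictor's importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

__all__ = ["TurnoverModel", "fit_turnover", "cumulative_turnover"]


@dataclass
class TurnoverModel:
    importance: pd.Series               # per-predictor R2-weighted importance
    snp_r2: pd.Series                   # out-of-bag R2 per SNP
    retained: list                      # SNPs with positive out-of-bag R2
    splits: dict                        # predictor -> (thresholds, improvements)
    env_ranges: dict                    # predictor -> (min, max)
    env_values: pd.DataFrame = field(repr=False, default=None)
    n_trees: int = 2000
    corr_threshold: float = 0.7
    seed: int = 0


def _conditional_permutation(x: np.ndarray, j: int, partner: int | None,
                             rng, n_bins: int = 4) -> np.ndarray:
    """Permute column j, within quantile bins of the partner column if given."""
    out = x.copy()
    if partner is None:
        out[:, j] = rng.permutation(out[:, j])
        return out
    q = np.quantile(x[:, partner], np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.digitize(x[:, partner], q)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        out[idx, j] = out[rng.permutation(idx), j]
    return out


def fit_turnover(freqs: pd.DataFrame, env: pd.DataFrame, n_trees: int = 2000,
                 corr_threshold: float = 0.7, seed: int = 0,
                 min_samples_leaf: int = 2) -> TurnoverModel:
    """Fit per-SNP regression-tree ensembles and aggregate importances.

    ``freqs`` is populations x SNPs (candidate-locus allele frequencies),
    ``env`` populations x predictors; at least 15 populations are required
    for out-of-bag estimates to be meaningful. Determinism is guaranteed
    for a fixed seed.
    """
    if len(freqs) < 15:
        raise ValueError("turnover model needs at least 15 populations")
    if list(freqs.index) != list(env.index):
        raise ValueError("frequency and environment tables must align")
    x = env.to_numpy(dtype=float)
    predictors = list(env.columns)
    p = len(predictors)
    corr = np.corrcoef(x, rowvar=False) if p > 1 else np.ones((1, 1))
    partner = []
    for j in range(p):
        others = [(abs(corr[j, k]), k) for k in range(p) if k != j]
        best = max(others, default=(0.0, None))
        partner.append(best[1] if best[0] > corr_threshold else None)

    rng = np.random.default_rng(seed)
    snp_r2, retained = {}, []
    imp_sum = np.zeros(p)
    splits: dict = {name: ([], []) for name in predictors}
    for s, snp in enumerate(freqs.columns):
        y = freqs[snp].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            snp_r2[snp] = 0.0
            continue
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   max_features=max(1, p // 3),
                                   min_samples_leaf=min_samples_leaf,
                                   oob_score=True, bootstrap=True,
                                   random_state=int(rng.integers(2 ** 31)),
                                   n_jobs=1)
        rf.fit(x, y)
        r2 = float(rf.oob_score_)
        snp_r2[snp] = r2
        if r2 <= 0:
            continue
        retained.append(snp)
        # permutation importance (conditional for correlated predictors)
        base = float(1 - ((y - rf.predict(x)) ** 2).sum()
                     / max(((y - y.mean()) ** 2).sum(), 1e-300))
        rel = np.zeros(p)
        for j in range(p):
            drops = []
            for _ in range(3):
                xp = _conditional_permutation(x, j, partner[j], rng)
                r2p = float(1 - ((y - rf.predict(xp)) ** 2).sum()
                            / max(((y - y.mean()) ** 2).sum(), 1e-300))
                drops.append(base - r2p)
            rel[j] = max(np.mean(drops), 0.0)
        if rel.sum() > 0:
            rel = rel / rel.sum()
        imp_sum += r2 * rel
        # harvest split improvements, weighted by this SNP's share
        total_ss = max(((y - y.mean()) ** 2).sum(), 1e-300)
        for est in rf.estimators_:
            t = est.tree_
            internal = t.children_left != -1
            for node in np.flatnonzero(internal):
                f = t.feature[node]
                nl, nr = t.children_left[node], t.children_right[node]
                gain = (t.weighted_n_node_samples[node] * t.impurity[node]
                        - t.weighted_n_node_samples[nl] * t.impurity[nl]
                        - t.weighted_n_node_samples[nr] * t.impurity[nr])
                splits[predictors[f]][0].append(float(t.threshold[node]))
                splits[predictors[f]][1].append(
                    r2 * float(gain) / (total_ss * n_trees))
    if not retained:
        logger.warning("fit_turnover: no SNP with positive out-of-bag R2; "
                       "empty model")
    n_ret = max(len(retained), 1)
    importance = pd.Series(imp_sum / n_ret, index=predictors)
    split_arrays = {name: (np.array(th), np.array(im))
                    for name, (th, im) in splits.items()}
    ranges = {name: (float(env[name].min()), float(env[name].max()))
              for name in predictors}
    return TurnoverModel(importance=importance, snp_r2=pd.Series(snp_r2),
                         retained=retained, splits=split_arrays,
                         env_ranges=ranges, env_values=env.copy(),
                         n_trees=n_trees, corr_threshold=corr_threshold,
                         seed=seed)


def cumulative_turnover(model: TurnoverModel, predictor: str,
                        n_bins: int = 40) -> pd.DataFrame:
    """Cumulative turnover step function along one predictor's gradient.

    Split improvements are binned at their threshold positions over the
    observed range, standardized by the data density along the gradient
    (binned-count convention), cumulatively summed, and rescaled so the
    terminal value equals the predictor's R2-weighted importance. A
    zero-importance predictor yields the identically-zero function.
    """
    if predictor not in model.importance.index:
        raise KeyError(f"unknown predictor {predictor!r}")
    lo, hi = model.env_ranges[predictor]
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    importance = float(model.importance[predictor])
    th, im = model.splits[predictor]
    if importance <= 0 or len(th) == 0:
        return pd.DataFrame({"threshold": centers,
                             "cumulative": np.zeros(n_bins)})
    binned, _ = np.histogram(th, bins=edges, weights=im)
    density, _ = np.histogram(model.env_values[predictor], bins=edges)
    density = density / max(density.sum(), 1)
    standardized = np.where(density > 0, binned / np.maximum(density, 1e-12), 0.0)
    cum = np.cumsum(standardized)
    if cum[-1] > 0:
        cum = cum * (importance / cum[-1])
    return pd.DataFrame({"threshold": centers, "cumulative": cum})
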
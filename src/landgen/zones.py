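"""Seed transfer zone delineation and future-climate projection.

Sampling locations are clustered on GDM-predicted genetic dissimilarity
(Ward linkage; cluster count chosen by silhouette, with perMANOVA R2
reported per candidate k). Every suitable raster cell is then assigned to
the cluster of the sampling location with minimum combined cost,

    C_p(cell) = w_res * ACD'_p(cell) + w_env * ED'_p(cell)

where ACD_p is the accumulated least-cost distance from location p over
the habitat conductance surface, ED_p the Euclidean distance from p in
GDM-transformed environmental space, and both components are min-max
normalized to [0, 1] over all (location, cell) values before the weighted
combination (default weights 0.6 / 0.4). Cells below the habitat
probability clip (default 0.2) are nodata. The identical algorithm on
future-projected habitat and transformed predictors shifts the zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .raster import RasterLayer
from .resistance import (PairwiseMatrix, TransitionGraph,
                         accumulated_cost_surface, build_transition)

logger = logging.getLogger(__name__)

__all__ = ["ZoneSolution", "ZoneRaster", "cluster_populations",
           "permanova_r2", "assign_zones", "project_future_zones",
           "change_summary", "zone_concordance"]


@dataclass
class ZoneSolution:
    """Ward clustering of locations with per-k quality statistics."""

    linkage: np.ndarray
    k: int
    labels: np.ndarray                    # 1-based cluster per location at k
    labels_per_k: dict
    silhouette: pd.Series                 # mean silhouette width per k
    permanova: pd.DataFrame               # R2 (and p) per k
    population_ids: list
    w_resistance: float = 0.6
    w_environment: float = 0.4
    clip_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not np.isclose(self.w_resistance + self.w_environment, 1.0):
            raise ValueError("cost weights must sum to 1")
        if self.k < 2:
            raise ValueError("need at least two clusters")
        if not 0.0 <= self.clip_threshold <= 1.0:
            raise ValueError("clip threshold must lie in [0, 1]")


def permanova_r2(d: PairwiseMatrix, labels, n_perm: int = 999,
                 seed: int = 0) -> tuple[float, float]:
    """perMANOVA R2 = SS_among/SS_total from the distance partition, with a
    permutation p-value on the pseudo-F statistic."""
    labels = np.asarray(labels)
    arr = d.array
    n = arr.shape[0]
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("perMANOVA needs at least two groups")

    def ss_parts(lab):
        d2 = arr ** 2
        iu = np.triu_indices(n, 1)
        ss_total = d2[iu].sum() / n
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss_total, ss_within

    ss_total, ss_within = ss_parts(labels)
    r2 = 1.0 - ss_within / ss_total
    k = len(groups)
    f_obs = (r2 / (k - 1)) / ((1 - r2) / (n - k)) if r2 < 1 else np.inf
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        lab = rng.permutation(labels)
        sst, ssw = ss_parts(lab)
        r2p = 1.0 - ssw / sst
        fp = (r2p / (k - 1)) / ((1 - r2p) / (n - k)) if r2p < 1 else np.inf
        count += fp >= f_obs
    p = (1.0 + count) / (n_perm + 1.0)
    return float(r2), float(p)


def cluster_populations(dissim: PairwiseMatrix, k_range=range(2, 9),
                        chosen_k: int | None = None,
                        w_resistance: float = 0.6, w_environment: float = 0.4,
                        clip_threshold: float = 0.2, n_perm: int = 199,
                        seed: int = 0) -> ZoneSolution:
    """Ward-linkage clustering of GDM-predicted dissimilarities.

    For each candidate k the mean silhouette width (computed directly on
    the dissimilarity matrix) and perMANOVA R2 are evaluated; the returned
    k maximizes the silhouette unless ``chosen_k`` overrides it. k values
    outside [2, n-1] are clipped.
    """
    n = len(dissim.ids)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("no valid k in range")
    z = linkage(dissim.condensed(), method="ward")
    sil, r2s, labels = {}, {}, {}
    for k in k_range:
        lab = fcluster(z, k, criterion="maxclust")
        labels[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
            r2s[k] = {"R2": np.nan, "p": np.nan}
            continue
        sil[k] = float(silhouette_score(dissim.array, lab, metric="precomputed"))
        r2, p = permanova_r2(dissim, lab, n_perm=n_perm, seed=seed)
        r2s[k] = {"R2": r2, "p": p}
    sil = pd.Series(sil).sort_index()
    perm = pd.DataFrame(r2s).T.sort_index()
    k = int(chosen_k) if chosen_k is not None else int(sil.idxmax())
    if k not in labels:
        labels[k] = fcluster(z, k, criterion="maxclust")
    return ZoneSolution(linkage=z, k=k, labels=labels[k], labels_per_k=labels,
                        silhouette=sil, permanova=perm,
                        population_ids=dissim.ids,
                        w_resistance=w_resistance, w_environment=w_environment,
                        clip_threshold=clip_threshold)


@dataclass
class ZoneRaster:
    """Integer zone labels per cell; 0 encodes nodata/unsuitable."""

    raster: RasterLayer
    legend: dict                      # zone label -> list of member populations
    n_unreachable: int = 0
    ties: int = 0

    @property
    def labels(self) -> np.ndarray:
        return self.raster.values

    def zone_areas(self) -> pd.Series:
        vals = self.raster.values
        out = {int(z): int((vals == z).sum()) for z in np.unique(vals[vals > 0])}
        return pd.Series(out, dtype=int)


def _combined_costs(solution: ZoneSolution, habitat: RasterLayer,
                    transformed: list[RasterLayer],
                    populations: pd.DataFrame,
                    graph: TransitionGraph | None = None) -> np.ndarray:
    """Stacked combined cost surfaces, one slab per population."""
    if graph is None:
        graph = build_transition(habitat)
    n_pop = len(populations)
    shape = habitat.shape
    acd = np.full((n_pop,) + shape, np.nan)
    ed = np.full((n_pop,) + shape, np.nan)
    tvals = np.stack([t.values for t in transformed])      # (p, r, c)
    for i, (_, row) in enumerate(populations.iterrows()):
        r, c = int(row["row"]), int(row["col"])
        acd[i] = accumulated_cost_surface(graph, (r, c)).values
        origin = tvals[:, r, c]
        ed[i] = np.sqrt(((tvals - origin[:, None, None]) ** 2).sum(axis=0))

    def minmax(a):
        finite = np.isfinite(a)
        lo, hi = a[finite].min(), a[finite].max()
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    return solution.w_resistance * minmax(acd) + solution.w_environment * minmax(ed)


def assign_zones(solution: ZoneSolution, habitat: RasterLayer,
                 transformed: list[RasterLayer],
                 populations: pd.DataFrame,
                 graph: TransitionGraph | None = None) -> ZoneRaster:
    """Assign every suitable cell to the zone of its minimum-cost location.

    Suitability requires habitat probability at or above the solution's
    clip threshold; cells unreachable from every location along the
    conductance graph become nodata and are counted. Cost ties resolve to
    the lowest population index and are logged.
    """
    if habitat.shape != transformed[0].shape:
        raise ValueError("habitat and transformed stack must be aligned")
    cost = _combined_costs(solution, habitat, transformed, populations, graph)
    suitable = np.nan_to_num(habitat.values, nan=-1.0) >= solution.clip_threshold
    reachable = np.isfinite(cost).any(axis=0)
    out = np.zeros(habitat.shape, dtype=float)
    assign_mask = suitable & reachable
    cost_masked = np.where(np.isfinite(cost), cost, np.inf)
    best = np.argmin(cost_masked, axis=0)  # ties -> lowest index (argmin rule)
    n_ties = int(((cost_masked == cost_masked.min(axis=0)).sum(axis=0) > 1)
                 [assign_mask].sum())
    if n_ties:
        logger.info("assign_zones: %d tied cells resolved to the lowest "
                    "population index", n_ties)
    pop_cluster = np.asarray(solution.labels)
    out[assign_mask] = pop_cluster[best[assign_mask]]
    n_unreach = int((suitable & ~reachable).sum())
    if n_unreach:
        logger.warning("assign_zones: %d suitable cells unreachable from every "
                       "population", n_unreach)
    legend = {int(z): [solution.population_ids[i]
                       for i in np.flatnonzero(pop_cluster == z)]
              for z in np.unique(pop_cluster)}
    zr = habitat.copy_with(out, name="seed_zones")
    zr.nodata = 0
    return ZoneRaster(raster=zr, legend=legend, n_unreachable=n_unreach,
                      ties=n_ties)


def project_future_zones(solution: ZoneSolution, future_habitat: RasterLayer,
                         future_transformed: list[RasterLayer],
                         populations: pd.DataFrame,
                         graph: TransitionGraph | None = None) -> ZoneRaster:
    """Re-run the assignment on future-projected habitat and predictors."""
    if future_habitat.shape != future_transformed[0].shape:
        raise ValueError("future inputs must be aligned with each other")
    return assign_zones(solution, future_habitat, future_transformed,
                        populations, graph)


def change_summary(current: ZoneRaster, future: ZoneRaster
                   ) -> tuple[RasterLayer, pd.Series]:
    """Cell-by-cell comparison raster: 1 same, 2 changed, 3 lost, 4 gained.

    ``same + changed + lost`` partitions the current suitable cells.
    """
    cur = current.raster.values
    fut = future.raster.values
    out = np.zeros(cur.shape)
    out[(cur > 0) & (fut == cur)] = 1
    out[(cur > 0) & (fut > 0) & (fut != cur)] = 2
    out[(cur > 0) & (fut == 0)] = 3
    out[(cur == 0) & (fut > 0)] = 4
    counts = pd.Series({"same": int((out == 1).sum()),
                        "changed": int((out == 2).sum()),
                        "lost": int((out == 3).sum()),
                        "gained": int((out == 4).sum())})
    layer = current.raster.copy_with(out, name="zone_change")
    return layer, counts


def zone_concordance(zones: ZoneRaster, populations: pd.DataFrame,
                     ancestry_labels) -> float:
    """Adjusted Rand index between zone membership of the sampling locations
    and an independent ancestry-cluster partition."""
    rows = populations["row"].to_numpy(int)
    cols = populations["col"].to_numpy(int)
    zone_at_pop = zones.raster.values[rows, cols].astype(int)
    return float(adjusted_rand_score(np.asarray(ancestry_labels), zone_at_pop))
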
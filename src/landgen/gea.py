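"""RDA-based genotype-environment association scan.

Redundancy analysis regresses the (mean-imputed, centered) individual
dosage matrix on standardized environmental predictors and
eigen-decomposes the fitted values; loci whose loadings on a significant
constrained axis fall more than 3 standard deviations from the mean are
flagged as potentially adaptive. Predictors are screened for
multicollinearity (VIF < 10) before fitting, and candidates from external
scan methods can be merged with per-method provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["vif_screen", "RDAModel", "rda_fit", "significant_axes",
           "detect_outliers", "ScanResult", "CandidateSet", "merge_candidates"]


def vif_screen(env: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor until all VIF < threshold.

    VIF_j = 1/(1 - R2_j) from regressing predictor j on the remaining
    predictors (with intercept). Perfectly collinear predictors have
    infinite VIF and are dropped first. Returns (retained predictors,
    history table with the VIF at each drop decision).
    """
    if env.shape[1] < 2:
        raise ValueError("VIF screen needs at least two predictors")
    x = env.copy()
    history = []

    def vifs(frame: pd.DataFrame) -> pd.Series:
        arr = frame.to_numpy(dtype=float)
        arr = (arr - arr.mean(axis=0)) / np.maximum(arr.std(axis=0), 1e-300)
        out = {}
        for j, name in enumerate(frame.columns):
            others = np.delete(arr, j, axis=1)
            design = np.column_stack([np.ones(len(arr)), others])
            coef, *_ = np.linalg.lstsq(design, arr[:, j], rcond=None)
            resid = arr[:, j] - design @ coef
            ss_res = float(resid @ resid)
            ss_tot = float(arr[:, j] @ arr[:, j])
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    while x.shape[1] >= 2:
        v = vifs(x)
        history.append(v)
        if v.max() < threshold:
            break
        worst = v.idxmax()
        if np.isinf(v[worst]):
            logger.warning("vif_screen: %r perfectly collinear, dropped", worst)
        x = x.drop(columns=[worst])
    hist = pd.DataFrame(history).reset_index(drop=True)
    return x, hist


@dataclass
class RDAModel:
    """Fitted redundancy analysis.

    ``site_scores`` are the constrained-axis projections of individuals,
    ``loadings`` the per-locus axis loadings, ``eigenvalues`` the constrained
    eigenvalues (non-increasing). The variance decomposition
    constrained + residual = total holds by construction.
    """

    site_scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    n_axes: int
    total_variance: float
    constrained_variance: float
    response: np.ndarray = field(repr=False)        # centered, imputed Y
    hat: np.ndarray = field(repr=False)             # projection onto predictors
    predictors: pd.DataFrame = field(repr=False, default=None)

    @property
    def residual_variance(self) -> float:
        return self.total_variance - self.constrained_variance

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "proportion": self.proportion_explained,
        }, index=[f"RDA{i+1}" for i in range(self.n_axes)])


def rda_fit(dosages: np.ndarray, env: pd.DataFrame,
            scale: bool = True) -> RDAModel:
    """Fit the constrained ordination of dosages on environmental predictors.

    Missing dosages are mean-imputed per SNP and columns centered;
    ``scale=True`` (default) also standardizes each SNP to unit variance
    (correlation-scale RDA). Dosage variance depends on allele frequency,
    so without scaling the pooled loading distribution across loci is a
    variance mixture with heavy tails and the downstream 3-SD outlier rule
    over-flags neutral loci. Predictors are standardized. Eigenvalues come
    from the SVD of the fitted values.
    """
    y = np.array(dosages, dtype=float)
    col_mean = np.nanmean(y, axis=0)
    nan_mask = np.isnan(y)
    y[nan_mask] = np.take(np.where(np.isnan(col_mean), 0.0, col_mean),
                          np.nonzero(nan_mask)[1])
    y = y - y.mean(axis=0)
    if scale:
        sd = y.std(axis=0)
        sd[sd == 0] = 1.0
        y = y / sd
    x = env.to_numpy(dtype=float)
    if y.shape[0] <= x.shape[1]:
        raise ValueError("need more individuals than predictors")
    x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-300)
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])).sum())
    if rank < x.shape[1]:
        logger.warning("rda_fit: predictor matrix rank-deficient (%d < %d)",
                       rank, x.shape[1])
    q = q[:, :rank]
    # svd of the projected response (rank x L) carries the fitted values
    qty = q.T @ y
    u1, s, vt = np.linalg.svd(qty, full_matrices=False)
    n = y.shape[0]
    n_axes = rank
    eig = (s[:n_axes] ** 2) / (n - 1)
    total = float((y ** 2).sum()) / (n - 1)
    constrained = float((qty ** 2).sum()) / (n - 1)
    return RDAModel(site_scores=(q @ u1)[:, :n_axes] * s[:n_axes],
                    loadings=vt[:n_axes].T,
                    eigenvalues=eig, n_axes=n_axes,
                    total_variance=total, constrained_variance=constrained,
                    response=y, hat=q, predictors=env)


def significant_axes(rda: RDAModel, n_perm: int = 199, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Permutation test per constrained axis.

    Sequential conditional test: for axis k the previously fitted axes
    are removed from the response, the residuals are row-permuted, the
    reduced ordination refit, and the axis eigenvalue compared with its
    permuted distribution; p = (1 + #{perm >= obs}) / (n_perm + 1). The
    conditioning keeps later-axis tests calibrated when earlier axes carry
    strong signal. Axes with p <= alpha are flagged significant.
    """
    rng = np.random.default_rng(seed)
    n = rda.response.shape[0]
    q = rda.hat
    p_out = np.ones(rda.n_axes)
    for k in range(rda.n_axes):
        if k == 0:
            yk = rda.response
            qk = q
        else:
            z = rda.site_scores[:, :k]
            z = z / np.linalg.norm(z, axis=0)
            yk = rda.response - z @ (z.T @ rda.response)
            qk, _ = np.linalg.qr(q - z @ (z.T @ q))
            keep = (np.abs(np.diag(np.linalg.qr(q - z @ (z.T @ q),
                                                mode="r"))) > 1e-10)
            qk = qk[:, keep]
        obs = np.linalg.svd(qk.T @ yk, compute_uv=False)[0] ** 2 / (n - 1)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            lam = np.linalg.svd(qk.T @ yk[perm],
                                compute_uv=False)[0] ** 2 / (n - 1)
            count += lam >= obs
        p_out[k] = (1.0 + count) / (n_perm + 1.0)
    p = p_out
    return pd.DataFrame({"axis": np.arange(1, rda.n_axes + 1),
                         "eigenvalue": rda.eigenvalues, "p": p,
                         "significant": p <= alpha})


@dataclass
class ScanResult:
    outliers: pd.DataFrame          # locus, axis, z, env_variable
    loadings_z: np.ndarray
    axis_table: pd.DataFrame
    vif: pd.DataFrame | None = None
    locus_ids: list | None = None

    @property
    def outlier_indices(self) -> np.ndarray:
        return self.outliers["locus"].to_numpy()


def detect_outliers(rda: RDAModel, axis_table: pd.DataFrame,
                    sd_threshold: float = 3.0,
                    locus_ids=None) -> ScanResult:
    """Flag loci with |loading z-score| > ``sd_threshold`` on a significant axis.

    Loadings are standardized per axis, so flags are invariant to axis sign
    and scale. Each outlier is annotated with the environmental variable
    whose values across individuals correlate most strongly (in absolute
    value) with its dosage column.
    """
    sig = axis_table.loc[axis_table["significant"], "axis"].to_numpy()
    if len(sig) == 0:
        raise ValueError("no significant axes; nothing to scan")
    z = (rda.loadings - rda.loadings.mean(axis=0)) / rda.loadings.std(axis=0)
    if locus_ids is None:
        locus_ids = np.arange(rda.loadings.shape[0])
    locus_ids = np.asarray(locus_ids)
    env = rda.predictors
    env_arr = env.to_numpy(dtype=float)
    env_arr = (env_arr - env_arr.mean(axis=0)) / np.maximum(env_arr.std(axis=0), 1e-300)
    rows = []
    for ax in sig:
        za = z[:, ax - 1]
        for idx in np.flatnonzero(np.abs(za) > sd_threshold):
            snp = rda.response[:, idx]
            cors = env_arr.T @ snp / (np.linalg.norm(snp) + 1e-300) / np.sqrt(len(snp))
            best = env.columns[int(np.argmax(np.abs(cors)))]
            rows.append({"locus": locus_ids[idx], "axis": int(ax),
                         "z": float(za[idx]), "env_variable": best})
    out = pd.DataFrame(rows, columns=["locus", "axis", "z", "env_variable"])
    out = out.sort_values(["locus", "axis"]).drop_duplicates("locus").reset_index(drop=True)
    return ScanResult(outliers=out, loadings_z=z, axis_table=axis_table,
                      locus_ids=list(locus_ids))


@dataclass
class CandidateSet:
    """Union of candidate loci across scan methods with provenance."""

    table: pd.DataFrame             # locus, methods (list of tags)
    counts: dict
    overlap: pd.DataFrame

    @property
    def loci(self) -> list:
        return list(self.table["locus"])


def merge_candidates(scan: ScanResult, **external_lists) -> CandidateSet:
    """Union the RDA outliers with externally supplied candidate lists.

    Keyword arguments name each external method (e.g. ``bayescenv=[...]``).
    Locus IDs must exist in the scanned dataset; unknown IDs are rejected.
    """
    known = set(scan.locus_ids)
    methods = {"rda": list(scan.outliers["locus"])}
    for name, loci in external_lists.items():
        bad = [l for l in loci if l not in known]
        if bad:
            raise ValueError(f"unknown locus IDs in {name!r}: {bad[:5]}")
        methods[name] = list(loci)
    all_loci = sorted({l for loci in methods.values() for l in loci},
                      key=lambda v: str(v))
    rows = [{"locus": l,
             "methods": [m for m, loci in methods.items() if l in set(loci)]}
            for l in all_loci]
    names = list(methods)
    overlap = pd.DataFrame(
        [[len(set(methods[a]) & set(methods[b])) for b in names] for a in names],
        index=names, columns=names)
    counts = {m: len(loci) for m, loci in methods.items()}
    counts["union"] = len(all_loci)
    return CandidateSet(table=pd.DataFrame(rows, columns=["locus", "methods"]),
                        counts=counts, overlap=overlap)
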
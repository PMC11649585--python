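"""Generalized dissimilarity modeling of allele-frequency turnover.

GDM regresses pairwise compositional dissimilarity d in [0, 1] on
between-site differences of monotone I-spline transforms of each
predictor, through a negative-exponential link:

    d_hat = 1 - exp(-eta),
    eta   = alpha + sum_j sum_k beta_jk * |I_jk(x1_j) - I_jk(x2_j)|

with alpha >= 0 and all beta_jk >= 0, so predicted dissimilarity is
monotone in every predictor difference and bounded in [0, 1). Pairwise
matrix predictors (geographic distance, habitat resistance) enter through
I-splines evaluated on the raw pairwise distance. Fitting is iteratively
reweighted least squares with an inner non-negative least-squares solve
and binomial-type deviance; the fitted transform per predictor,
f_j(x) = sum_k beta_jk I_jk(x), maps rasters into "genetic turnover"
units, and the genomic offset at a cell is the predicted dissimilarity
between its current and future transformed values (intercept excluded, so
an unchanged climate gives exactly zero offset).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .raster import RasterLayer
from .resistance import PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = ["ISplineBasis", "SitePairTable", "assemble_site_pairs",
           "GDMResults", "fit_gdm", "transform_predictors", "genomic_offset",
           "compare_models", "predict_matrix"]

_EPS = 1e-10


class ISplineBasis:
    """Monotone I-spline basis (integrated M-splines) for one predictor.

    With the default three knots at (min, median, max) and order 2 this
    gives three basis functions, each non-decreasing from 0 at/below the
    first knot to 1 at/above the last. Evaluation clamps x to the knot
    range (with a debug log), matching the convention that turnover
    saturates beyond the observed gradient.
    """

    def __init__(self, knots, order: int = 2):
        knots = np.asarray(knots, dtype=float).copy()
        if np.any(np.diff(knots) < 0):
            raise ValueError("knots must be sorted")
        if len(knots) < 2:
            raise ValueError("need at least two knots")
        # enforce a minimum relative gap so no basis density degenerates
        min_gap = 1e-9 * max(knots[-1] - knots[0], np.abs(knots).max(), 1.0)
        for i in range(1, len(knots)):
            if knots[i] - knots[i - 1] < min_gap:
                knots[i] = knots[i - 1] + min_gap
        self.knots = knots
        self.order = order
        # B-spline degree order-1; full knot vector pads each end
        t = np.r_[[knots[0]] * (order - 1), knots, [knots[-1]] * (order - 1)]
        self.n_basis = len(t) - order
        self._splines = []
        for i in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[i] = 1.0
            anti = BSpline(t, coef, order - 1).antiderivative()
            top = float(anti(knots[-1]))
            self._splines.append((anti, top))

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        clipped = np.clip(x, self.knots[0], self.knots[-1])
        if np.any(x != clipped):
            logger.debug("I-spline evaluation clamped %d values to knot range",
                         int((x != clipped).sum()))
        out = np.empty(clipped.shape + (self.n_basis,))
        for i, (anti, top) in enumerate(self._splines):
            out[..., i] = anti(clipped) / top
        return np.clip(out, 0.0, 1.0)  # guard float overshoot at the knots

    @classmethod
    def from_data(cls, x, n_knots: int = 3, order: int = 2) -> "ISplineBasis":
        qs = np.linspace(0, 1, n_knots)
        knots = np.quantile(np.asarray(x, dtype=float), qs)
        # degenerate (constant) predictors get a token span
        if knots[-1] <= knots[0]:
            knots = knots[0] + np.linspace(0, 1e-6, n_knots)
        return cls(knots, order=order)


@dataclass
class SitePairTable:
    """All site pairs: response dissimilarity, predictor values, distances."""

    data: pd.DataFrame                  # columns: distance, weights, s1_<p>, s2_<p>, m_<name>
    env_predictors: list
    matrix_predictors: list
    site_ids: list

    def __post_init__(self) -> None:
        d = self.data["distance"].to_numpy()
        if np.any((d < 0) | (d > 1)):
            raise ValueError("response dissimilarities must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def pair_index(self) -> np.ndarray:
        return self.data[["i", "j"]].to_numpy()


def assemble_site_pairs(freqs: pd.DataFrame, env: pd.DataFrame,
                        matrix_predictors: dict | None = None,
                        response: str = "braycurtis") -> SitePairTable:
    """Build the site-pair table from population allele frequencies.

    The response is the Bray-Curtis dissimilarity between population
    frequency vectors (default) or a pre-computed genetic
    :class:`PairwiseMatrix` passed directly as ``freqs``. Environmental
    predictors contribute their values at both sites; each matrix predictor
    contributes its pairwise distance.
    """
    matrix_predictors = matrix_predictors or {}
    if isinstance(freqs, PairwiseMatrix):
        ids = freqs.ids
        d = freqs.condensed()
    else:
        ids = list(freqs.index)
        arr = freqs.to_numpy(dtype=float)
        if response != "braycurtis":
            raise ValueError("response must be 'braycurtis' or a PairwiseMatrix")
        d = pdist(arr, metric="braycurtis")
    if list(env.index) != ids:
        raise ValueError("environmental table must align with population IDs")
    n = len(ids)
    ii, jj = np.triu_indices(n, 1)
    rows = {"i": ii, "j": jj, "distance": d, "weights": np.ones(len(d))}
    for col in env.columns:
        v = env[col].to_numpy(dtype=float)
        rows[f"s1_{col}"] = v[ii]
        rows[f"s2_{col}"] = v[jj]
    for name, m in matrix_predictors.items():
        if m.ids != ids:
            raise ValueError(f"matrix predictor {name!r} misaligned")
        rows[f"m_{name}"] = m.array[ii, jj]
    return SitePairTable(pd.DataFrame(rows), env_predictors=list(env.columns),
                         matrix_predictors=list(matrix_predictors), site_ids=ids)


def _design(pairs: SitePairTable, bases: dict) -> tuple[np.ndarray, list]:
    cols, names = [], []
    for p in pairs.env_predictors:
        basis = bases[p]
        i1 = basis(pairs.data[f"s1_{p}"].to_numpy())
        i2 = basis(pairs.data[f"s2_{p}"].to_numpy())
        block = np.abs(i1 - i2)
        for k in range(basis.n_basis):
            cols.append(block[:, k])
            names.append((p, k))
    for m in pairs.matrix_predictors:
        basis = bases[f"m_{m}"]
        block = basis(pairs.data[f"m_{m}"].to_numpy())
        for k in range(basis.n_basis):
            cols.append(block[:, k])
            names.append((f"m_{m}", k))
    x = np.column_stack(cols) if cols else np.empty((pairs.n_pairs, 0))
    return x, names


def _binomial_deviance(d, mu, w):
    d = np.clip(d, 0.0, 1.0)
    mu = np.clip(mu, _EPS, 1 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1 - d) * np.log((1 - d) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _irls_nnls(x, d, w, max_iter=100, tol=1e-6):
    """Fit eta = X@beta (incl. intercept col 0) with beta >= 0 by IRLS/NNLS."""
    design = np.column_stack([np.ones(len(d)), x])
    mu = np.clip(0.5 * (d + d.mean()), 0.01, 0.95)
    eta = -np.log1p(-mu)
    dev = _binomial_deviance(d, mu, w)
    beta = None
    trace = [dev]
    for it in range(max_iter):
        dmu = 1.0 - mu                     # d mu / d eta for mu = 1-exp(-eta)
        var = np.clip(mu * (1 - mu), _EPS, None)
        wk = w * dmu ** 2 / var
        z = eta + (d - mu) / np.clip(dmu, _EPS, None)
        z = np.clip(z, 0.0, None)          # eta is non-negative by construction
        sw = np.sqrt(wk)
        beta, _ = nnls(design * sw[:, None], z * sw)
        eta = design @ beta
        mu = -np.expm1(-eta)
        new_dev = _binomial_deviance(d, mu, w)
        trace.append(new_dev)
        if abs(dev - new_dev) <= tol * (abs(dev) + _EPS):
            dev = new_dev
            break
        dev = new_dev
    else:
        logger.warning("GDM IRLS did not converge in %d iterations; "
                       "deviance trace tail: %s", max_iter,
                       np.round(trace[-5:], 6).tolist())
    return beta, dev, trace


@dataclass
class GDMResults:
    """A fitted GDM: intercept, non-negative spline coefficients, deviances."""

    intercept: float
    coefficients: pd.Series            # index (predictor, basis_k)
    bases: dict
    env_predictors: list
    matrix_predictors: list
    null_deviance: float
    deviance: float
    converged: bool
    trace: list = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.intercept < -1e-12 or (self.coefficients < -1e-12).any():
            raise ValueError("GDM coefficients must be non-negative")

    @property
    def pct_deviance_explained(self) -> float:
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def spline_height(self, predictor: str) -> float:
        """Total turnover attributed to a predictor (sum of its coefficients)."""
        return float(self.coefficients.loc[predictor].sum())

    def not_selected(self) -> list:
        """Predictors whose coefficients are all (numerically) zero."""
        out = []
        for p in self.env_predictors + [f"m_{m}" for m in self.matrix_predictors]:
            if self.spline_height(p) <= 1e-9:
                out.append(p)
        return out

    def transform_values(self, predictor: str, x) -> np.ndarray:
        """f_j(x) = sum_k beta_jk I_jk(x) for one predictor."""
        basis = self.bases[predictor]
        coefs = self.coefficients.loc[predictor].to_numpy()
        return basis(np.asarray(x, dtype=float)) @ coefs

    def linear_predictor(self, pairs: SitePairTable) -> np.ndarray:
        x, names = _design(pairs, self.bases)
        beta = np.array([self.coefficients.loc[n] for n in names])
        return self.intercept + x @ beta

    def predict(self, pairs: SitePairTable) -> np.ndarray:
        """Predicted dissimilarities for a site-pair table."""
        return -np.expm1(-self.linear_predictor(pairs))

    def summary(self) -> str:
        lines = [f"GDM: {len(self.env_predictors)} environmental + "
                 f"{len(self.matrix_predictors)} matrix predictors",
                 f"intercept           {self.intercept:.4f}",
                 f"null deviance       {self.null_deviance:.4f}",
                 f"deviance            {self.deviance:.4f}",
                 f"% deviance explained {self.pct_deviance_explained:.2f}"]
        for p in self.env_predictors + [f"m_{m}" for m in self.matrix_predictors]:
            h = self.spline_height(p)
            tag = "  (not selected)" if h <= 1e-9 else ""
            lines.append(f"  spline height {p:<20s} {h:.4f}{tag}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        out = {
            "intercept": self.intercept,
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "pct_deviance_explained": self.pct_deviance_explained,
            "predictors": {},
        }
        for p, basis in self.bases.items():
            out["predictors"][p] = {
                "knots": basis.knots.tolist(),
                "coefficients": self.coefficients.loc[p].tolist(),
            }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


def fit_gdm(pairs: SitePairTable, n_knots: int = 3,
            max_iter: int = 100, tol: float = 1e-6) -> GDMResults:
    """Fit the GDM to a site-pair table.

    I-spline knots default to (min, median, max) of each predictor's
    observed values (pooled over both sites; matrix predictors use the
    pairwise distances). Requires at least twice as many pairs as
    coefficients.
    """
    bases = {}
    for p in pairs.env_predictors:
        pooled = np.r_[pairs.data[f"s1_{p}"], pairs.data[f"s2_{p}"]]
        bases[p] = ISplineBasis.from_data(pooled, n_knots=n_knots)
    for m in pairs.matrix_predictors:
        bases[f"m_{m}"] = ISplineBasis.from_data(
            np.r_[0.0, pairs.data[f"m_{m}"].to_numpy()], n_knots=n_knots)
    x, names = _design(pairs, bases)
    if pairs.n_pairs < 2 * (x.shape[1] + 1):
        raise ValueError("need at least 2x more site pairs than coefficients")
    d = pairs.data["distance"].to_numpy(dtype=float)
    w = pairs.data["weights"].to_numpy(dtype=float)
    beta, dev, trace = _irls_nnls(x, d, w, max_iter=max_iter, tol=tol)
    # null model: intercept only
    _, null_dev, _ = _irls_nnls(np.empty((len(d), 0)), d, w,
                                max_iter=max_iter, tol=tol)
    coefs = pd.Series(beta[1:], index=pd.MultiIndex.from_tuples(
        names, names=["predictor", "basis"]))
    converged = len(trace) <= max_iter
    return GDMResults(intercept=float(beta[0]), coefficients=coefs,
                      bases=bases, env_predictors=pairs.env_predictors,
                      matrix_predictors=pairs.matrix_predictors,
                      null_deviance=null_dev, deviance=dev,
                      converged=converged, trace=trace)


def transform_predictors(model: GDMResults,
                         env_stack: list[RasterLayer]) -> list[RasterLayer]:
    """Map environmental rasters into GDM turnover units, f_j(x) per cell.

    Each output layer is monotone in its input and spans [0, spline height].
    Nodata propagates. Matrix predictors have no raster and are skipped.
    """
    by_name = {layer.name: layer for layer in env_stack}
    out = []
    for p in model.env_predictors:
        if p not in by_name:
            raise ValueError(f"no raster supplied for predictor {p!r}")
        layer = by_name[p]
        vals = np.full(layer.shape, np.nan)
        m = layer.mask
        vals[m] = model.transform_values(p, layer.values[m])
        out.append(layer.copy_with(vals, name=f"gdm_{p}"))
    return out


def genomic_offset(model: GDMResults, current: list[RasterLayer],
                   future: list[RasterLayer]) -> RasterLayer:
    """Predicted dissimilarity between current and future climate per cell.

    offset = 1 - exp(-sum_j |f_j(x_future) - f_j(x_current)|); the intercept
    is excluded so an unchanged climate gives exactly zero. Values lie in
    [0, 1); nodata propagates.
    """
    cur = {l.name: l for l in current}
    fut = {l.name: l for l in future}
    ref = current[0]
    acc = np.zeros(ref.shape)
    valid = np.ones(ref.shape, dtype=bool)
    for p in model.env_predictors:
        if p not in cur or p not in fut:
            raise ValueError(f"predictor {p!r} missing from a stack")
        if cur[p].shape != ref.shape or fut[p].shape != ref.shape:
            raise ValueError("current/future stacks must be aligned")
        m = cur[p].mask & fut[p].mask
        valid &= m
        diff = np.zeros(ref.shape)
        diff[m] = np.abs(model.transform_values(p, fut[p].values[m])
                         - model.transform_values(p, cur[p].values[m]))
        acc += diff
    vals = np.where(valid, -np.expm1(-acc), np.nan)
    return ref.copy_with(vals, name="genomic_offset")


def predict_matrix(model: GDMResults, pairs: SitePairTable) -> PairwiseMatrix:
    """Predicted dissimilarities folded back into a pairwise matrix."""
    pred = model.predict(pairs)
    n = len(pairs.site_ids)
    out = np.zeros((n, n))
    ij = pairs.pair_index
    out[ij[:, 0], ij[:, 1]] = pred
    out[ij[:, 1], ij[:, 0]] = pred
    return PairwiseMatrix.from_array(out, ids=pairs.site_ids, kind="gdm_predicted")


def compare_models(pairs: SitePairTable, predictor_subsets: dict) -> pd.DataFrame:
    """Refit the GDM for each named predictor configuration.

    ``predictor_subsets`` maps model name -> (env predictor list, matrix
    predictor list). Returns one row per model with % deviance explained
    and the best model flagged.
    """
    rows = []
    for name, (envs, mats) in predictor_subsets.items():
        cols = ["i", "j", "distance", "weights"]
        cols += [f"s1_{p}" for p in envs] + [f"s2_{p}" for p in envs]
        cols += [f"m_{m}" for m in mats]
        sub = SitePairTable(pairs.data[cols].copy(), env_predictors=list(envs),
                            matrix_predictors=list(mats),
                            site_ids=pairs.site_ids)
        fit = fit_gdm(sub)
        rows.append({"model": name,
                     "pct_deviance_explained": fit.pct_deviance_explained,
                     "not_selected": fit.not_selected()})
    table = pd.DataFrame(rows).set_index("model")
    table["best"] = table["pct_deviance_explained"] == table["pct_deviance_explained"].max()
    return table
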
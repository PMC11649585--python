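"""Mantel and partial Mantel tests, and the IBD/IBR/IBE causal-model battery.

Genetic divergence among populations can arise from geographic separation
alone (isolation by distance, IBD), from dispersal limits through
unsuitable habitat (isolation by resistance, IBR), or from divergent
selection along environmental gradients (isolation by environment, IBE).
The battery contrasts simple and partial Mantel correlations of a genetic
distance matrix against geographic, habitat-resistance, and environmental
distance matrices, evaluated primarily on the strength of r rather than
permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resistance import PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = ["MantelResult", "mantel", "partial_mantel", "causal_table"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    labels: tuple
    conditioned_on: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r out of [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p out of (0, 1]")


def _aligned_arrays(*mats: PairwiseMatrix) -> list[np.ndarray]:
    ids = mats[0].ids
    out = []
    for m in mats:
        if m.ids != ids:
            raise ValueError("matrices must share locations in the same order")
        out.append(m.array)
    return out


def _tri(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def mantel(a: PairwiseMatrix, b: PairwiseMatrix, n_perm: int = 999,
           seed: int = 0, tail: str = "upper") -> MantelResult:
    """Mantel test: Pearson r over upper-triangle entries with a joint
    row/column permutation null.

    p = (1 + #{permuted r >= observed}) / (n_perm + 1) for the default
    one-tailed upper test; ``tail='two-sided'`` compares |r|.
    """
    A, B = _aligned_arrays(a, b)
    va, vb = _tri(A), _tri(B)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = _tri(A[np.ix_(perm, perm)])
        r_p = float(np.corrcoef(vp, vb)[0, 1])
        if tail == "upper":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm,
                        labels=(a.kind, b.kind))


def _residual_matrix(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the upper triangle of A regressed on that of C,
    folded back into symmetric matrix form."""
    va, vc = _tri(A), _tri(C)
    beta = np.polyfit(vc, va, 1)
    resid = va - np.polyval(beta, vc)
    n = A.shape[0]
    out = np.zeros_like(A)
    out[np.triu_indices(n, 1)] = resid
    return out + out.T


def partial_mantel(a: PairwiseMatrix, b: PairwiseMatrix, c: PairwiseMatrix,
                   n_perm: int = 999, seed: int = 0,
                   tail: str = "upper") -> MantelResult:
    """Partial Mantel: correlation of A and B after removing C from both.

    The statistic is the Pearson correlation of the residuals of A-on-C and
    B-on-C over the vectorized upper triangle; the null permutes the
    residualized A matrix by joint row/column relabeling. When C is
    (near-)collinear with B the result is flagged degenerate.
    """
    A, B, C = _aligned_arrays(a, b, c)
    va, vb, vc = _tri(A), _tri(B), _tri(C)
    if min(va.std(), vb.std(), vc.std()) == 0:
        raise ValueError("partial Mantel undefined for a constant matrix")
    r_bc = float(np.corrcoef(vb, vc)[0, 1])
    degenerate = abs(r_bc) > 0.999 or abs(float(np.corrcoef(va, vc)[0, 1])) > 0.999
    if degenerate:
        logger.warning("partial_mantel: conditioning matrix nearly collinear "
                       "with a tested matrix; r reported with degeneracy flag")
    RA = _residual_matrix(A, C)
    rb = _tri(_residual_matrix(B, C))
    ra = _tri(RA)
    # residuals that are pure float noise (A or B affine in C) are degenerate
    if ra.std() <= 1e-9 * va.std() or rb.std() <= 1e-9 * vb.std():
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm,
                            labels=(a.kind, b.kind), conditioned_on=c.kind,
                            degenerate=True)
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _tri(RA[np.ix_(perm, perm)])
        r_p = float(np.corrcoef(rp, rb)[0, 1])
        if tail == "upper":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm,
                        labels=(a.kind, b.kind), conditioned_on=c.kind,
                        degenerate=degenerate)


_TESTS = [
    ("IBD", "Genetic x Geographic", "geo", None),
    ("IBD", "Genetic x Geographic (- Habitat resistance)", "geo", "res"),
    ("IBD", "Genetic x Geographic (- Environment)", "geo", "env"),
    ("IBR", "Genetic x Habitat resistance", "res", None),
    ("IBR", "Genetic x Habitat resistance (- Environment)", "res", "env"),
    ("IBR", "Genetic x Habitat resistance (- Geographic)", "res", "geo"),
    ("IBE", "Genetic x Environment", "env", None),
    ("IBE", "Genetic x Environment (- Habitat resistance)", "env", "res"),
    ("IBE", "Genetic x Environment (- Geographic)", "env", "geo"),
]


def causal_table(genetic_neutral: PairwiseMatrix,
                 genetic_adaptive: PairwiseMatrix,
                 geographic: PairwiseMatrix,
                 resistance: PairwiseMatrix,
                 environmental: PairwiseMatrix,
                 n_perm: int = 999, seed: int = 0,
                 r_positive: float = 0.1) -> tuple[pd.DataFrame, str]:
    """The nine-test Mantel battery for neutral and adaptive genetic distances.

    Verdict rule (r magnitudes, not p): IBR is supported when the partial
    r(genetic x resistance | geographic) stays at or above ``r_positive``
    while r(genetic x geographic | resistance) collapses to <= 0; IBD is the
    mirror image; IBE is supported when the adaptive-loci partials
    r(gen x environment | resistance) and (| geographic) both stay positive.
    """
    mats = {"geo": geographic, "res": resistance, "env": environmental}
    rows = []
    vals = {}
    for name, gen in (("neutral", genetic_neutral),
                      ("adaptive", genetic_adaptive)):
        for scen, label, target, cond in _TESTS:
            if cond is None:
                res = mantel(gen, mats[target], n_perm=n_perm, seed=seed)
            else:
                res = partial_mantel(gen, mats[target], mats[cond],
                                     n_perm=n_perm, seed=seed)
            vals[(name, target, cond)] = res.r
            rows.append({"scenario": scen, "test": label, "dataset": name,
                         "r": res.r, "p": res.p})
    table = (pd.DataFrame(rows)
             .pivot_table(index=["scenario", "test"], columns="dataset",
                          values=["r", "p"], sort=False))
    verdicts = []
    if (vals[("neutral", "res", "geo")] >= r_positive
            and vals[("neutral", "geo", "res")] <= 0):
        verdicts.append("IBR")
    elif (vals[("neutral", "geo", "res")] >= r_positive
            and vals[("neutral", "res", "geo")] <= 0):
        verdicts.append("IBD")
    if (vals[("adaptive", "env", "res")] >= r_positive
            and vals[("adaptive", "env", "geo")] >= r_positive):
        verdicts.append("IBE")
    verdict = "+".join(verdicts) if verdicts else "none supported"
    return table, verdict
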
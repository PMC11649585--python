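"""Genotype matrices: VCF input, quality filters, diversity and differentiation.

Dosages are alternate-allele counts (0/1/2) stored as floats with NaN for
missing calls. Filters follow a fixed, documented order: individuals by
missingness first, then SNPs by minor-allele count, excess mean depth, and
excess observed heterozygosity. Differentiation uses the Weir & Cockerham
(1984) variance-component estimator theta; molecular variance is
partitioned with a one-level AMOVA on squared Euclidean dosage distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .resistance import PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix", "FilterReport", "DiversityTable", "PairwiseFst",
    "AmovaResult", "read_vcf", "apply_quality_filters",
    "thin_one_snp_per_locus", "pop_allele_freqs", "diversity_stats",
    "pairwise_fst", "amova_phi_st", "wc_variance_components",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosages with metadata.

    ``dosages`` holds 0/1/2 with NaN for missing. ``snp_meta`` must carry
    ``locus`` (RAD-locus ID) and ``pos`` columns, optionally ``mean_depth``;
    ``ind_meta`` must carry ``sample`` and ``location``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    ind_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        d = self.dosages
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if d.shape != (len(self.ind_meta), len(self.snp_meta)):
            raise ValueError("dosage shape does not match metadata")
        if self.ind_meta["location"].isna().any():
            raise ValueError("every individual needs a location")
        if (self.snp_meta["locus"].astype(str) == "").any():
            raise ValueError("locus IDs must be non-empty")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def locations(self) -> pd.Series:
        return self.ind_meta["location"]

    def take_individuals(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx],
                              self.snp_meta.copy(),
                              self.ind_meta.iloc[idx].reset_index(drop=True))

    def take_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, idx],
                              self.snp_meta.iloc[idx].reset_index(drop=True),
                              self.ind_meta.copy())

    def by_location(self) -> dict:
        """Row indices of each sampling location, in first-seen order."""
        out: dict = {}
        for i, loc in enumerate(self.ind_meta["location"]):
            out.setdefault(loc, []).append(i)
        return {k: np.array(v) for k, v in out.items()}


@dataclass
class FilterReport:
    """Counts removed per rule, in application order."""

    steps: list = field(default_factory=list)  # (rule, n_removed)
    dropped_records: int = 0

    def as_dict(self) -> dict:
        return {"steps": [{"rule": r, "removed": int(n)} for r, n in self.steps],
                "dropped_records": int(self.dropped_records)}


def read_vcf(path, sample_locations) -> tuple[GenotypeMatrix, FilterReport]:
    """Read biallelic GT records from a VCF into a dosage matrix.

    ``sample_locations`` maps sample ID -> location ID (dict, Series, or a
    CSV path with columns sample, location); a sample without a mapping is
    fatal. Non-biallelic records are dropped and counted; half-calls become
    missing. Mean depth per SNP is taken from FORMAT DP when present, else
    INFO DP / n samples.
    """
    from cyvcf2 import VCF

    if isinstance(sample_locations, (str, bytes)) or hasattr(sample_locations, "__fspath__"):
        tbl = pd.read_csv(sample_locations)
        sample_locations = dict(zip(tbl["sample"], tbl["location"]))
    elif isinstance(sample_locations, pd.Series):
        sample_locations = sample_locations.to_dict()

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_map = [s for s in samples if s not in sample_locations]
    if missing_map:
        raise ValueError(f"no location mapping for samples: {missing_map[:5]}")

    rows, loci, positions, depths = [], [], [], []
    dropped = 0
    half_calls = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        g = np.array([gt[:2] for gt in v.genotypes], dtype=float)
        miss = (g < 0).any(axis=1)
        half_calls += int(((g < 0).sum(axis=1) == 1).sum())
        dos = g.sum(axis=1)
        dos[miss] = np.nan
        rows.append(dos)
        loci.append(v.CHROM)
        positions.append(v.POS)
        fmt_dp = v.format("DP") if "DP" in (v.FORMAT or []) else None
        if fmt_dp is not None:
            fdp = np.asarray(fmt_dp, dtype=float).ravel()
            depths.append(float(np.nanmean(np.where(fdp < 0, np.nan, fdp))))
        else:
            info_dp = v.INFO.get("DP")
            depths.append(float(info_dp) / len(samples) if info_dp is not None else np.nan)
    if dropped or half_calls:
        logger.warning("read_vcf: dropped %d non-biallelic records, "
                       "set %d half-calls missing", dropped, half_calls)
    dosages = np.array(rows) if rows else np.empty((0, len(samples)))
    snp_meta = pd.DataFrame({"locus": loci, "pos": positions})
    if np.isfinite(depths).any():
        snp_meta["mean_depth"] = depths
    ind_meta = pd.DataFrame({"sample": samples,
                             "location": [sample_locations[s] for s in samples]})
    g = GenotypeMatrix(dosages.T, snp_meta, ind_meta)
    report = FilterReport(dropped_records=dropped)
    return g, report


def apply_quality_filters(g: GenotypeMatrix, max_ind_missing: float = 0.30,
                          min_mac: int = 3, depth_quantile: float | None = 0.99,
                          max_obs_het: float | None = 0.7,
                          min_pop_call_rate: float | None = None,
                          ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard RAD-seq quality filters in a fixed order.

    Order: (1) individuals with more than ``max_ind_missing`` missing calls
    removed; (2) SNPs with minor-allele count below ``min_mac``; (3) SNPs
    whose mean depth exceeds the ``depth_quantile`` quantile of the retained
    set (requires depth metadata — pass ``depth_quantile=None`` for GT-only
    data); (4) SNPs with observed heterozygosity above ``max_obs_het``.
    ``min_pop_call_rate`` optionally requires that fraction of individuals
    genotyped in every location (off by default).
    """
    report = FilterReport()
    miss = np.isnan(g.dosages).mean(axis=1)
    keep_ind = miss <= max_ind_missing + 1e-12
    report.steps.append(("individual_missingness", int((~keep_ind).sum())))
    if not keep_ind.any():
        raise ValueError("individual_missingness filter removed all individuals")
    g = g.take_individuals(np.flatnonzero(keep_ind))

    d = g.dosages
    called = ~np.isnan(d)
    alt = np.nansum(d, axis=0)
    total = 2.0 * called.sum(axis=0)
    mac = np.minimum(alt, total - alt)
    keep = mac >= min_mac
    report.steps.append(("minor_allele_count", int((~keep).sum())))
    if not keep.any():
        raise ValueError("minor_allele_count filter removed all SNPs")
    g = g.take_snps(np.flatnonzero(keep))

    if depth_quantile is not None:
        if "mean_depth" not in g.snp_meta or g.snp_meta["mean_depth"].isna().all():
            raise ValueError("depth filter requested but no depth metadata present")
        depth = g.snp_meta["mean_depth"].to_numpy(dtype=float)
        cut = np.nanquantile(depth, depth_quantile)  # linear interpolation
        keep = ~(depth > cut)
        report.steps.append(("excess_depth", int((~keep).sum())))
        if not keep.any():
            raise ValueError("excess_depth filter removed all SNPs")
        g = g.take_snps(np.flatnonzero(keep))
    else:
        report.steps.append(("excess_depth", 0))

    if max_obs_het is not None:
        d = g.dosages
        het = np.nansum(d == 1, axis=0) / np.maximum((~np.isnan(d)).sum(axis=0), 1)
        keep = het <= max_obs_het
        report.steps.append(("excess_heterozygosity", int((~keep).sum())))
        if not keep.any():
            raise ValueError("excess_heterozygosity filter removed all SNPs")
        g = g.take_snps(np.flatnonzero(keep))

    if min_pop_call_rate is not None:
        d = g.dosages
        keep = np.ones(g.n_snps, dtype=bool)
        for loc, idx in g.by_location().items():
            rate = (~np.isnan(d[idx])).mean(axis=0)
            keep &= rate >= min_pop_call_rate
        report.steps.append(("pop_call_rate", int((~keep).sum())))
        if not keep.any():
            raise ValueError("pop_call_rate filter removed all SNPs")
        g = g.take_snps(np.flatnonzero(keep))
    return g, report


def thin_one_snp_per_locus(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep one uniformly random SNP per RAD locus (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    keep = []
    for _, idx in g.snp_meta.groupby("locus", sort=True).groups.items():
        idx = np.asarray(idx)
        keep.append(idx[rng.integers(len(idx))])
    return g.take_snps(np.sort(np.asarray(keep)))


def pop_allele_freqs(g: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-location frequency of the globally minor allele, plus called-allele n.

    The minor allele is defined once on the full (post-filter) matrix; cells
    with no called genotypes are NaN.
    """
    d = g.dosages
    called = ~np.isnan(d)
    global_alt = np.nansum(d, axis=0) / np.maximum(2.0 * called.sum(axis=0), 1)
    flip = global_alt > 0.5  # minor allele is REF there
    locs = g.by_location()
    freq = np.full((len(locs), g.n_snps), np.nan)
    n_called = np.zeros((len(locs), g.n_snps))
    for r, (loc, idx) in enumerate(locs.items()):
        sub = d[idx]
        n = (~np.isnan(sub)).sum(axis=0) * 2.0
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / np.where(n > 0, n, np.nan)
        p = np.where(flip, 1.0 - p, p)
        freq[r] = p
        n_called[r] = n
    if np.isnan(freq).any():
        logger.warning("pop_allele_freqs: %d location x SNP cells have no calls",
                       int(np.isnan(freq).sum()))
    ids = list(locs)
    cols = [f"snp_{i}" for i in range(g.n_snps)]
    return (pd.DataFrame(freq, index=ids, columns=cols),
            pd.DataFrame(n_called, index=ids, columns=cols))


def diversity_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-location H_o, unbiased H_e and nucleotide diversity over variant sites.

    H_o is the mean fraction of heterozygous calls; H_e is 2*p*q corrected by
    2n/(2n-1); pi is the mean pairwise allelic difference per site computed
    from allele counts. Locations with a single individual are skipped.
    """
    rows = []
    for loc, idx in g.by_location().items():
        if len(idx) < 2:
            logger.warning("diversity_stats: skipping location %r with 1 individual", loc)
            continue
        sub = g.dosages[idx]
        called = ~np.isnan(sub)
        n_dip = called.sum(axis=0).astype(float)
        use = n_dip >= 1
        ho = np.nansum(sub == 1, axis=0)[use] / n_dip[use]
        k = np.nansum(sub, axis=0)[use]           # alt allele copies
        two_n = 2.0 * n_dip[use]
        p = k / two_n
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = two_n / np.maximum(two_n - 1.0, 1.0)
            he = 2.0 * p * (1.0 - p) * corr
            pi = k * (two_n - k) / (two_n * (two_n - 1.0) / 2.0)
        rows.append({"location": loc, "n": len(idx),
                     "H_o": float(np.mean(ho)), "H_e": float(np.mean(he)),
                     "pi": float(np.mean(pi))})
    return pd.DataFrame(rows).set_index("location")


def wc_variance_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir & Cockerham (1984) per-locus components a, b, c.

    Parameters are per-population arrays over r populations at one locus:
    sample sizes in diploid individuals ``n``, alternate-allele frequencies
    ``p``, observed heterozygote proportions ``h``. Vectorized over loci if
    2-D arrays (r x L) are passed.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


@dataclass
class PairwiseFst:
    """Pairwise Weir-Cockerham theta with overall summaries."""

    matrix: PairwiseMatrix
    mean_pairwise: float
    overall_theta: float          # ratio-of-sums across all populations jointly
    per_locus: pd.DataFrame | None = None


def _pop_summaries(g: GenotypeMatrix):
    locs = g.by_location()
    n = np.zeros((len(locs), g.n_snps))
    p = np.full((len(locs), g.n_snps), np.nan)
    h = np.full((len(locs), g.n_snps), np.nan)
    for r, (loc, idx) in enumerate(locs.items()):
        sub = g.dosages[idx]
        called = ~np.isnan(sub)
        n[r] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[r] = np.nansum(sub, axis=0) / np.where(n[r] > 0, 2.0 * n[r], np.nan)
            h[r] = np.nansum(sub == 1, axis=0) / np.where(n[r] > 0, n[r], np.nan)
    return list(locs), n, p, h


def pairwise_fst(g: GenotypeMatrix) -> PairwiseFst:
    """Multi-locus Weir-Cockerham theta for every pair of locations.

    Per pair, theta = sum(a) / sum(a + b + c) over loci where both
    populations have at least two called individuals and the locus is
    polymorphic in the pair; negative values are retained. The overall mean
    is the average of pairwise values; an all-population ratio-of-sums theta
    is reported alongside.
    """
    ids, n, p, h = _pop_summaries(g)
    if len(ids) < 2:
        raise ValueError("pairwise_fst needs at least two locations")
    k = len(ids)
    theta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = (n[i] >= 2) & (n[j] >= 2)
            if not ok.any():
                theta[i, j] = theta[j, i] = np.nan
                continue
            a, b, c = wc_variance_components(
                np.vstack([n[i, ok], n[j, ok]]),
                np.vstack([p[i, ok], p[j, ok]]),
                np.vstack([h[i, ok], h[j, ok]]))
            denom = (a + b + c)
            poly = denom != 0
            theta[i, j] = theta[j, i] = (a[poly].sum() / denom[poly].sum()
                                         if poly.any() else np.nan)
    ok_all = (n >= 2).all(axis=0)
    a, b, c = wc_variance_components(n[:, ok_all], p[:, ok_all], h[:, ok_all])
    denom = a + b + c
    poly = denom != 0
    overall = float(a[poly].sum() / denom[poly].sum()) if poly.any() else np.nan
    tri = theta[np.triu_indices(k, 1)]
    return PairwiseFst(PairwiseMatrix.from_array(theta, ids=ids, kind="genetic"),
                       mean_pairwise=float(np.nanmean(tri)),
                       overall_theta=overall)


@dataclass
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int


def amova_phi_st(g: GenotypeMatrix) -> AmovaResult:
    """One-level AMOVA on squared Euclidean dosage distances.

    Missing dosages are excluded pairwise; each squared distance is rescaled
    to the full SNP count by the fraction of shared called loci. Negative
    variance components are floored at zero and logged.
    """
    locs = g.by_location()
    if len(locs) < 2:
        raise ValueError("amova needs at least two locations")
    d = g.dosages
    n_tot, L = d.shape
    # pairwise-deleted squared distances, rescaled to L loci
    d2 = np.zeros((n_tot, n_tot))
    for i in range(n_tot):
        diff = d[i] - d
        shared = ~np.isnan(diff)
        m = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d2[i] = np.nansum(diff ** 2, axis=1) * (L / np.maximum(m, 1))
    if np.allclose(d2, 0.0):
        raise ValueError("zero-variance input: all individuals identical")
    iu = np.triu_indices(n_tot, 1)
    ss_total = d2[iu].sum() / n_tot
    ss_within = 0.0
    sizes = []
    for loc, idx in locs.items():
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        sizes.append(len(idx))
    ss_among = ss_total - ss_within
    k = len(locs)
    df_a, df_w = k - 1, n_tot - k
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    sizes = np.array(sizes, dtype=float)
    n0 = (n_tot - (sizes ** 2).sum() / n_tot) / df_a
    sig_w = ms_w
    sig_a = (ms_a - ms_w) / n0
    if sig_a < 0:
        logger.warning("amova_phi_st: negative among-group component %.3g floored at 0",
                       sig_a)
        sig_a = 0.0
    phi = sig_a / (sig_a + sig_w)
    return AmovaResult(phi_st=float(phi), sigma2_among=float(sig_a),
                       sigma2_within=float(sig_w), pct_among=float(100 * phi),
                       ss_among=float(ss_among), ss_within=float(ss_within),
                       df_among=df_a, df_within=df_w)
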
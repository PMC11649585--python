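"""Synthetic landscapes, populations and genotypes with planted truth.

The generator emulates a desert-annual landscape-genomics design: smooth,
spatially autocorrelated environmental surfaces; a logistic habitat
suitability surface; sampling locations placed in suitable habitat; neutral
allele-frequency structure whose between-population covariance decays
exponentially with habitat-resistance distance (isolation by resistance);
and a small minority of adaptive loci whose logit frequencies follow linear
clines along chosen environmental layers. Genotypes are binomial draws of
two allele copies per diploid individual — a logit-normal frequency model,
deliberately non-genealogical (no coalescent, mutation or recombination).

Every source of randomness flows from one seeded generator and the seed is
recorded in all outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .genotypes import GenotypeMatrix
from .raster import RasterLayer
from .resistance import (PairwiseMatrix, build_transition,
                         environmental_distance_matrix,
                         geographic_distance_matrix, least_cost_matrix)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig", "SimTruth", "SimulatedDataset", "generate_environment",
    "generate_habitat", "place_populations", "simulate_allele_frequencies",
    "sample_genotypes", "simulate_dataset", "write_fixture",
    "lag1_autocorrelation", "patchy_habitat",
]


@dataclass
class SimConfig:
    """Study-design knobs for one simulated landscape.

    Defaults emulate the sampling design the package targets: ~60 locations
    of ~12 diploids each, 500 biallelic SNPs of which 4% carry logistic
    clines (slope ``beta`` per standardized environmental unit), neutral
    covariance decaying with habitat-resistance distance at scale ``phi``.
    """

    shape: tuple = (60, 60)
    cell_size: float = 1000.0
    n_env_layers: int = 4
    autocorr_range: float = 6.0        # smoothing kernel sd, in cells
    trend_weight: float = 1.0          # strength of the linear gradient component
    habitat_coefficients: tuple | None = None
    habitat_intercept: float = 0.5
    n_populations: int = 60
    n_individuals: int = 12
    min_spacing: float = 3.0           # cells
    min_habitat: float = 0.2
    n_neutral: int = 480
    n_adaptive: int = 20
    beta: float = 2.0                  # cline slope per adaptive locus
    adaptive_layers: tuple | None = None
    adaptive_noise_sd: float = 0.25
    phi: float = 60.0                  # covariance decay scale, resistance units
    sigma2: float = 1.0                # logit-scale neutral variance
    snps_per_locus: int = 1
    missing_rate: float = 0.0
    ploidy_draws: int = 2              # binomial sampling depth (diploid)
    distance_mode: str = "resistance"  # resistance | geographic | environmental
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ValueError("grid must be at least 8 x 8")
        for name in ("n_env_layers", "n_populations", "n_individuals",
                     "n_neutral", "snps_per_locus", "ploidy_draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_adaptive < 0:
            raise ValueError("n_adaptive must be non-negative")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.distance_mode not in ("resistance", "geographic", "environmental"):
            raise ValueError("unknown distance_mode")

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_adaptive

    def coefficients(self) -> np.ndarray:
        if self.habitat_coefficients is not None:
            c = np.asarray(self.habitat_coefficients, dtype=float)
            if len(c) != self.n_env_layers:
                raise ValueError("habitat coefficient count must match layer count")
            return c
        base = np.array([1.2, -0.8, 0.6, 0.0])
        c = np.zeros(self.n_env_layers)
        c[:min(4, self.n_env_layers)] = base[:min(4, self.n_env_layers)]
        return c


@dataclass
class SimTruth:
    """Planted truth of one simulation, for downstream recovery checks."""

    adaptive_indices: np.ndarray
    adaptive_layer: np.ndarray       # env layer index driving each adaptive locus
    beta: np.ndarray                 # cline slope per adaptive locus
    neutral_base_freqs: np.ndarray
    population_cells: np.ndarray     # (n_pops, 2) row/col
    seed: int

    def __post_init__(self) -> None:
        neutral = np.setdiff1d(np.arange(len(self.neutral_base_freqs)
                                         + len(self.adaptive_indices)),
                               self.adaptive_indices)
        if len(np.intersect1d(self.adaptive_indices, neutral)) != 0:
            raise ValueError("adaptive indices overlap neutral indices")

    def to_json(self, path) -> None:
        out = {
            "seed": int(self.seed),
            "adaptive_indices": self.adaptive_indices.tolist(),
            "adaptive_layer": self.adaptive_layer.tolist(),
            "beta": self.beta.tolist(),
            "neutral_base_freqs": np.round(self.neutral_base_freqs, 6).tolist(),
            "population_cells": self.population_cells.tolist(),
        }
        Path(path).write_text(json.dumps(out, indent=1))


def lag1_autocorrelation(values: np.ndarray) -> float:
    """Mean correlation between rook-adjacent cell pairs (a Moran-type lag-1
    autocorrelation estimator)."""
    v = np.asarray(values, dtype=float)
    pairs_a = np.concatenate([v[:, :-1].ravel(), v[:-1, :].ravel()])
    pairs_b = np.concatenate([v[:, 1:].ravel(), v[1:, :].ravel()])
    return float(np.corrcoef(pairs_a, pairs_b)[0, 1])


def generate_environment(config: SimConfig, rng=None) -> list[RasterLayer]:
    """Smooth correlated environmental layers, standardized over cells.

    Each layer is white noise smoothed with a Gaussian kernel of sd
    ``autocorr_range`` cells, plus a linear trend of random orientation
    weighted by ``trend_weight``, then standardized to zero mean and unit
    variance over cells.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows, cols = config.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    layers = []
    for k in range(config.n_env_layers):
        noise = rng.standard_normal((rows, cols))
        if config.autocorr_range > 0:
            smooth = gaussian_filter(noise, sigma=config.autocorr_range,
                                     mode="reflect")
            smooth /= max(smooth.std(), 1e-12)
        else:
            smooth = noise
        if config.trend_weight != 0:
            theta = rng.uniform(0, 2 * np.pi)
            trend = (np.cos(theta) * rr + np.sin(theta) * cc)
            trend = (trend - trend.mean()) / max(trend.std(), 1e-12)
            smooth = smooth + config.trend_weight * trend
        smooth = (smooth - smooth.mean()) / smooth.std()
        layers.append(RasterLayer(smooth, cell_size=config.cell_size,
                                  name=f"env_{k}",
                                  meta={"seed": config.seed}))
    return layers


def generate_habitat(env: list[RasterLayer], coefficients,
                     intercept: float = 0.0) -> RasterLayer:
    """Cellwise logistic habitat probability from the environmental stack."""
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != len(env):
        raise ValueError("coefficient count must match layer count")
    lin = np.full(env[0].shape, float(intercept))
    for c, layer in zip(coefficients, env):
        lin = lin + c * layer.values
    hab = expit(lin)
    return env[0].copy_with(hab, name="habitat")


def patchy_habitat(shape: tuple, blocks: tuple = (2, 2),
                   barrier_width: int = 2, high: float = 0.9,
                   low: float = 0.02, cell_size: float = 1000.0) -> RasterLayer:
    """Blocky habitat with thin low-conductance barriers between patches.

    A contrast scenario for cluster-recovery and corridor experiments: the
    grid is split into ``blocks`` rectangular patches of suitability
    ``high`` separated by barriers of suitability ``low``.
    """
    rows, cols = shape
    hab = np.full(shape, high)
    br, bc = blocks
    for k in range(1, br):
        r = int(round(k * rows / br))
        hab[max(0, r - barrier_width // 2):r + (barrier_width + 1) // 2, :] = low
    for k in range(1, bc):
        c = int(round(k * cols / bc))
        hab[:, max(0, c - barrier_width // 2):c + (barrier_width + 1) // 2] = low
    return RasterLayer(hab, cell_size=cell_size, name="habitat")


def block_gradient_environment(shape: tuple, seed: int,
                               n_layers: int = 4,
                               noise_sd: float = 0.6,
                               cell_size: float = 1000.0) -> list[RasterLayer]:
    """Environmental layers whose first two gradients parallel a 2x2 block
    division of the landscape.

    A contrast scenario for the gradients-parallel-structure situation:
    layer 0 steps east-west, layer 1 north-south, remaining layers are
    white noise; all standardized. Combined with :func:`patchy_habitat`
    at the same boundaries, adaptive clines then align with the neutral
    population blocks.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    def std(v):
        return (v - v.mean()) / v.std()

    layers = [
        std((cc > cols // 2).astype(float) * 2
            + noise_sd * rng.standard_normal(shape)),
        std((rr > rows // 2).astype(float) * 2
            + noise_sd * rng.standard_normal(shape)),
    ]
    while len(layers) < n_layers:
        layers.append(std(rng.standard_normal(shape)))
    return [RasterLayer(v, cell_size=cell_size, name=f"env_{i}")
            for i, v in enumerate(layers[:n_layers])]


def place_populations(habitat: RasterLayer, n: int, min_spacing: float,
                      seed: int, min_habitat: float = 0.2) -> pd.DataFrame:
    """Place ``n`` sampling locations in suitable habitat with a minimum
    pairwise spacing (in cells). Random but deterministic per seed."""
    rng = np.random.default_rng(seed)
    suitable = np.argwhere(np.nan_to_num(habitat.values, nan=-1.0) >= min_habitat)
    if len(suitable) == 0:
        raise ValueError("no cells meet the habitat threshold")
    order = rng.permutation(len(suitable))
    chosen: list[np.ndarray] = []
    for idx in order:
        cell = suitable[idx]
        if all(np.hypot(*(cell - c)) >= min_spacing for c in chosen):
            chosen.append(cell)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(
            f"cannot place {n} populations with spacing {min_spacing}: "
            f"max feasible n under this draw is {len(chosen)}")
    cells = np.array(chosen)
    x, y = habitat.xy_from_rowcol(cells[:, 0], cells[:, 1])
    return pd.DataFrame({
        "pop_id": [f"P{i:02d}" for i in range(n)],
        "row": cells[:, 0], "col": cells[:, 1],
        "x": x, "y": y,
    })


def simulate_allele_frequencies(populations: pd.DataFrame,
                                distances: PairwiseMatrix,
                                env_at_pops: pd.DataFrame,
                                config: SimConfig,
                                rng=None) -> tuple[np.ndarray, SimTruth]:
    """Draw per-population allele frequencies with planted structure.

    Neutral locus: logit frequencies are jointly Gaussian over populations
    with covariance sigma2 * exp(-D/phi) around a locus-specific base logit.
    Adaptive locus: logit p = logit(base) + beta * standardized env (layer
    assigned to that locus) + small independent noise.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    D = distances.array
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix has non-finite entries; "
                         "populations must be connected")
    k = D.shape[0]
    cov = config.sigma2 * np.exp(-D / config.phi)
    jitter = 0.0
    for _ in range(8):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(k))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 10
    else:
        raise np.linalg.LinAlgError("covariance not repairable by jitter")
    if jitter:
        logger.warning("covariance repaired with diagonal jitter %.1e", jitter)

    n_loci = config.n_loci
    base = rng.beta(0.8, 0.8, size=n_loci)
    base = np.clip(base, 0.05, 0.95)
    adaptive_idx = np.sort(rng.choice(n_loci, size=config.n_adaptive,
                                      replace=False))
    env_std = env_at_pops.to_numpy(dtype=float)
    env_std = (env_std - env_std.mean(axis=0)) / np.maximum(
        env_std.std(axis=0), 1e-12)
    if config.adaptive_layers is not None:
        layer_pool = np.asarray(config.adaptive_layers, dtype=int)
    else:
        layer_pool = np.arange(min(2, env_std.shape[1]))
    layers = layer_pool[np.arange(config.n_adaptive) % len(layer_pool)]

    logits = logit(base)[None, :] + chol @ rng.standard_normal((k, n_loci))
    for j, (loc_idx, layer) in enumerate(zip(adaptive_idx, layers)):
        logits[:, loc_idx] = (logit(base[loc_idx])
                              + config.beta * env_std[:, layer]
                              + config.adaptive_noise_sd * rng.standard_normal(k))
    freqs = expit(logits)
    neutral_mask = np.ones(n_loci, dtype=bool)
    neutral_mask[adaptive_idx] = False
    truth = SimTruth(adaptive_indices=adaptive_idx,
                     adaptive_layer=layers,
                     beta=np.full(config.n_adaptive, config.beta),
                     neutral_base_freqs=base[neutral_mask],
                     population_cells=populations[["row", "col"]].to_numpy(),
                     seed=config.seed)
    return freqs, truth


def sample_genotypes(freqs: np.ndarray, populations: pd.DataFrame,
                     config: SimConfig, rng=None) -> GenotypeMatrix:
    """Binomial genotype draws: dosage ~ Binomial(2, p of the population)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    k, L = freqs.shape
    n_ind = config.n_individuals
    dosages = np.empty((k * n_ind, L))
    samples, locations = [], []
    for p_idx in range(k):
        pop = populations["pop_id"].iloc[p_idx]
        dosages[p_idx * n_ind:(p_idx + 1) * n_ind] = rng.binomial(
            config.ploidy_draws, freqs[p_idx], size=(n_ind, L))
        samples += [f"{pop}_i{j:02d}" for j in range(n_ind)]
        locations += [pop] * n_ind
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    n_rad = int(np.ceil(L / config.snps_per_locus))
    locus_ids = [f"RAD{i // config.snps_per_locus:05d}" for i in range(L)]
    pos = [i % config.snps_per_locus + 1 for i in range(L)]
    snp_meta = pd.DataFrame({"locus": locus_ids, "pos": pos})
    ind_meta = pd.DataFrame({"sample": samples, "location": locations})
    logger.debug("sampled %d individuals x %d SNPs over %d RAD loci",
                 k * n_ind, L, n_rad)
    return GenotypeMatrix(dosages, snp_meta, ind_meta)


@dataclass
class SimulatedDataset:
    """Everything one simulation produced, bundled for the pipeline."""

    config: SimConfig
    env: list
    habitat: RasterLayer
    populations: pd.DataFrame
    distances: PairwiseMatrix      # the matrix that drove neutral covariance
    geographic: PairwiseMatrix
    env_at_pops: pd.DataFrame
    freqs: np.ndarray
    truth: SimTruth
    genotypes: GenotypeMatrix
    habitat_graph: object = None


def simulate_dataset(config: SimConfig,
                     habitat: RasterLayer | None = None,
                     env: list | None = None) -> SimulatedDataset:
    """Run the full generator: environment -> habitat -> populations ->
    resistance -> frequencies -> genotypes.

    ``habitat`` may be supplied (e.g. :func:`patchy_habitat`) to override
    the logistic surface, and ``env`` to override the generated layers —
    e.g. to build contrast scenarios where environmental gradients do or do
    not parallel the habitat structure.
    """
    rng = np.random.default_rng(config.seed)
    if env is None:
        env = generate_environment(config, rng)
    elif len(env) != config.n_env_layers:
        raise ValueError("env override must match n_env_layers")
    if habitat is None:
        habitat = generate_habitat(env, config.coefficients(),
                                   config.habitat_intercept)
    pops = place_populations(habitat, config.n_populations,
                             config.min_spacing, seed=config.seed + 10,
                             min_habitat=config.min_habitat)
    graph = build_transition(habitat)
    env_at_pops = pd.DataFrame(
        {layer.name: layer.values[pops["row"], pops["col"]] for layer in env},
        index=pops["pop_id"])
    geo = geographic_distance_matrix(pops)
    if config.distance_mode == "resistance":
        drive = least_cost_matrix(graph, pops)
    elif config.distance_mode == "geographic":
        # rescale so phi keeps the same meaning across modes
        arr = geo.array / max(config.cell_size, 1e-12)
        drive = PairwiseMatrix.from_array(arr, ids=geo.ids, kind="geographic")
    else:
        drive = environmental_distance_matrix(env_at_pops)
    freqs, truth = simulate_allele_frequencies(pops, drive, env_at_pops,
                                               config, rng)
    genotypes = sample_genotypes(freqs, pops, config, rng)
    return SimulatedDataset(config=config, env=env, habitat=habitat,
                            populations=pops, distances=drive, geographic=geo,
                            env_at_pops=env_at_pops, freqs=freqs, truth=truth,
                            genotypes=genotypes, habitat_graph=graph)


# --- fixture I/O ---------------------------------------------------------

def _gt_string(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]


def write_vcf(genotypes: GenotypeMatrix, path, seed: int | None = None) -> None:
    """Write a minimal VCF v4.2 with GT only; CHROM carries the RAD-locus ID."""
    lines = ["##fileformat=VCFv4.2",
             "##source=landgen-simulate" + (f" seed={seed}" if seed is not None else "")]
    for locus in pd.unique(genotypes.snp_meta["locus"]):
        lines.append(f"##contig=<ID={locus}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(genotypes.ind_meta["sample"])
    lines.append("\t".join(header))
    for j in range(genotypes.n_snps):
        meta = genotypes.snp_meta.iloc[j]
        gts = "\t".join(_gt_string(d) for d in genotypes.dosages[:, j])
        lines.append(f"{meta['locus']}\t{int(meta['pos'])}\tsnp_{j}\tA\tT\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture(dataset: SimulatedDataset, outdir) -> dict:
    """Write the simulated dataset as plain-text files.

    Outputs: ``genotypes.vcf`` (v4.2, GT only), ``coords.csv``,
    ``samples.csv`` (sample -> location), ``env_<k>.asc``, ``habitat.asc``,
    ``truth.json``. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    try:
        vcf_path = outdir / "genotypes.vcf"
        write_vcf(dataset.genotypes, vcf_path, seed=dataset.config.seed)
        paths["vcf"] = vcf_path
        coords = dataset.populations[["pop_id", "x", "y"]]
        coords.to_csv(outdir / "coords.csv", index=False)
        paths["coords"] = outdir / "coords.csv"
        dataset.genotypes.ind_meta.to_csv(outdir / "samples.csv", index=False)
        paths["samples"] = outdir / "samples.csv"
        for layer in dataset.env:
            p = outdir / f"{layer.name}.asc"
            layer.write_ascii(p)
            paths[layer.name] = p
        dataset.habitat.write_ascii(outdir / "habitat.asc")
        paths["habitat"] = outdir / "habitat.asc"
        dataset.truth.to_json(outdir / "truth.json")
        paths["truth"] = outdir / "truth.json"
    except OSError as exc:
        raise OSError(f"failed writing fixture under {outdir}: {exc}") from exc
    return paths
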
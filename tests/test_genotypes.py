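"""Genotype module: VCF semantics, filter order, diversity, theta, AMOVA."""

import numpy as np
import pandas as pd
import pytest

from landgen.genotypes import (GenotypeMatrix, amova_phi_st,
                               apply_quality_filters, diversity_stats,
                               pairwise_fst, pop_allele_freqs, read_vcf,
                               thin_one_snp_per_locus)


def make_g(dosages, locations, loci=None, depth=None):
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_snp = dosages.shape
    snp_meta = pd.DataFrame({
        "locus": loci if loci is not None else [f"L{i}" for i in range(n_snp)],
        "pos": np.arange(1, n_snp + 1)})
    if depth is not None:
        snp_meta["mean_depth"] = depth
    ind_meta = pd.DataFrame({"sample": [f"s{i}" for i in range(n_ind)],
                             "location": locations})
    return GenotypeMatrix(dosages, snp_meta, ind_meta)


class TestReadVcf:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=L1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
L1\t1\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t./.
L1\t2\tv2\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1
L1\t3\tv3\tA\tT\t.\t.\t.\tGT\t1/1\t0/1\t0/0
"""

    def test_gt_semantics_and_triallelic_drop(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        g, report = read_vcf(p, {"s1": "A", "s2": "A", "s3": "B"})
        assert report.dropped_records == 1
        assert g.n_snps == 2
        np.testing.assert_array_equal(
            np.nan_to_num(g.dosages, nan=-1.0),
            [[0, 2], [1, 1], [-1, 0]])

    def test_missing_location_fatal(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        with pytest.raises(ValueError, match="no location mapping"):
            read_vcf(p, {"s1": "A"})


class TestQualityFilters:
    def test_mac_boundary(self):
        # alt allele in exactly 2 copies -> removed; 3 copies -> kept
        d = np.zeros((10, 2))
        d[0, 0] = 2.0                      # MAC 2
        d[0, 1], d[1, 1] = 2.0, 1.0        # MAC 3
        g = make_g(d, ["A"] * 5 + ["B"] * 5)
        out, report = apply_quality_filters(g, depth_quantile=None,
                                            max_obs_het=None)
        assert out.n_snps == 1
        assert dict(report.steps)["minor_allele_count"] == 1

    def test_individual_missingness_boundary(self):
        # 30.0% missing retained ("no more than 30%"), above removed
        d = np.ones((3, 10))
        d[:, 0] += 1  # keep MAC high
        d[0, :3] = np.nan            # exactly 30%
        d[1, :4] = np.nan            # 40%
        g = make_g(d, ["A", "A", "B"])
        out, report = apply_quality_filters(g, min_mac=0, depth_quantile=None,
                                            max_obs_het=None)
        assert out.n_individuals == 2
        assert dict(report.steps)["individual_missingness"] == 1

    def test_depth_filter_hits_extreme_snp(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(30, 100)).astype(float)
        depth = np.full(100, 40.0) + rng.normal(0, 2, 100)
        depth[17] = 400.0
        g = make_g(d, ["A"] * 15 + ["B"] * 15, depth=depth)
        out, report = apply_quality_filters(g, min_mac=0, max_obs_het=None,
                                            depth_quantile=0.99)
        assert dict(report.steps)["excess_depth"] == 1
        assert 400.0 not in out.snp_meta["mean_depth"].to_numpy()

    def test_depth_requested_without_metadata(self):
        g = make_g(np.ones((4, 3)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="depth"):
            apply_quality_filters(g, depth_quantile=0.99)

    def test_order_is_individuals_then_snps(self):
        # the high-missingness individual is removed before MAC counting,
        # which flips one SNP below the MAC threshold
        d = np.zeros((4, 10))
        d[:, 1:] = 1.0
        d[3, 0] = 2.0            # only carrier of SNP0's alt
        d[3, 1:5] = np.nan       # 40% missing -> removed first
        g = make_g(d, ["A", "A", "B", "B"])
        out, report = apply_quality_filters(g, min_mac=2, depth_quantile=None,
                                            max_obs_het=None)
        steps = dict(report.steps)
        assert steps["individual_missingness"] == 1
        assert steps["minor_allele_count"] >= 1
        assert 1 not in out.snp_meta["pos"].tolist()  # SNP at pos 1 removed

    def test_all_removed_is_fatal(self):
        d = np.zeros((4, 2))  # every SNP monomorphic -> MAC 0
        g = make_g(d, ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="minor_allele_count"):
            apply_quality_filters(g, depth_quantile=None, max_obs_het=None)


class TestThinning:
    def test_identity_when_single_snp_loci(self):
        g = make_g(np.ones((4, 5)), ["A"] * 4)
        out = thin_one_snp_per_locus(g, seed=0)
        assert out.n_snps == 5

    def test_count_and_determinism(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (6, 300)).astype(float)
        loci = [f"L{i // 3}" for i in range(300)]
        g = make_g(d, ["A"] * 3 + ["B"] * 3, loci=loci)
        a = thin_one_snp_per_locus(g, seed=7)
        b = thin_one_snp_per_locus(g, seed=7)
        c = thin_one_snp_per_locus(g, seed=8)
        assert a.n_snps == 100
        assert a.snp_meta["pos"].tolist() == b.snp_meta["pos"].tolist()
        assert a.snp_meta["pos"].tolist() != c.snp_meta["pos"].tolist()


class TestAlleleFreqs:
    def test_matches_hand_computation(self):
        # 3 pops x 4 SNPs, hand-counted minor-allele frequencies
        d = np.array([
            [0, 2, 1, 0], [0, 2, 1, 0],        # pop A
            [2, 2, 0, 1], [0, 2, 2, 1],        # pop B
            [2, 0, 0, np.nan], [2, 2, 0, 2],   # pop C
        ], dtype=float)
        g = make_g(d, ["A", "A", "B", "B", "C", "C"])
        freq, n = pop_allele_freqs(g)
        # global alt freqs: snp0 6/12=0.5 (alt is minor by convention <=0.5),
        # snp1 10/12 -> minor is REF; snp2 4/12; snp3 4/10
        np.testing.assert_allclose(freq.loc["A"], [0.0, 0.0, 0.5, 0.0])
        np.testing.assert_allclose(freq.loc["B"], [0.5, 0.0, 0.5, 0.5])
        np.testing.assert_allclose(freq.loc["C"], [1.0, 0.5, 0.0, 1.0])
        assert n.loc["C"].tolist() == [4, 4, 4, 2]

    def test_all_missing_cell_flagged(self):
        d = np.array([[1, np.nan], [1, np.nan], [1, 1], [1, 1]])
        g = make_g(d, ["A", "A", "B", "B"])
        freq, _ = pop_allele_freqs(g)
        assert np.isnan(freq.loc["A"].iloc[1])


class TestDiversity:
    def test_two_diploid_closed_form(self):
        # genotypes 0 and 2 at one SNP: H_o = 0, unbiased H_e = 2/3, pi = 2/3
        g = make_g([[0.0], [2.0]], ["A", "A"])
        t = diversity_stats(g)
        assert t.loc["A", "H_o"] == 0.0
        np.testing.assert_allclose(t.loc["A", "H_e"], 2 / 3)
        np.testing.assert_allclose(t.loc["A", "pi"], 2 / 3)

    def test_monomorphic_contributes_zero(self):
        g = make_g([[0.0, 1.0], [0.0, 1.0], [0.0, 0.0]], ["A"] * 3)
        t = diversity_stats(g)
        g2 = make_g([[1.0], [1.0], [0.0]], ["A"] * 3)
        t2 = diversity_stats(g2)
        np.testing.assert_allclose(t.loc["A", "H_e"], t2.loc["A", "H_e"] / 2)

    def test_single_individual_location_skipped(self):
        g = make_g([[1.0], [1.0], [0.0]], ["A", "A", "B"])
        t = diversity_stats(g)
        assert "B" not in t.index


def wc_theta_oracle(counts1, counts2):
    """Literal transcription of the Weir & Cockerham (1984) estimator for
    two populations of diploids, from genotype counts per locus.

    ``counts1/2`` are lists of (n_hom_ref, n_het, n_hom_alt) per locus.
    Returns multi-locus theta as ratio of summed components.
    """
    num = den = 0.0
    r = 2
    for (c1, c2) in zip(counts1, counts2):
        n1 = sum(c1)
        n2 = sum(c2)
        p1 = (2 * c1[2] + c1[1]) / (2 * n1)
        p2 = (2 * c2[2] + c2[1]) / (2 * n2)
        h1 = c1[1] / n1
        h2 = c2[1] / n2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestPairwiseFst:
    def test_matches_literal_oracle_on_toy(self):
        # 2 pops x 2 loci with asymmetric genotype counts
        counts1 = [(3, 2, 1), (4, 1, 1)]
        counts2 = [(1, 1, 4), (2, 3, 1)]
        rows = []
        for c in (counts1, counts2):
            pop = []
            for locus in c:
                pop.append([0.0] * locus[0] + [1.0] * locus[1] + [2.0] * locus[2])
            rows.append(np.array(pop).T)
        d = np.vstack(rows)
        g = make_g(d, ["A"] * 6 + ["B"] * 6)
        res = pairwise_fst(g)
        expected = wc_theta_oracle(counts1, counts2)
        np.testing.assert_allclose(res.matrix.array[0, 1], expected, atol=1e-12)

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 200)
        d = rng.binomial(2, p, size=(30, 200)).astype(float)
        g = make_g(d, ["A"] * 15 + ["B"] * 15)
        assert abs(pairwise_fst(g).matrix.array[0, 1]) < 0.02

    def test_alternate_fixation_gives_one(self):
        d = np.r_[np.zeros((5, 20)), np.full((5, 20), 2.0)]
        g = make_g(d, ["A"] * 5 + ["B"] * 5)
        np.testing.assert_allclose(pairwise_fst(g).matrix.array[0, 1], 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        locs = ["A"] * 7 + ["B"] * 6 + ["C"] * 7
        g = make_g(d, locs)
        base = pairwise_fst(g).matrix.values
        perm_ind = rng.permutation(20)
        perm_snp = rng.permutation(50)
        g2 = make_g(d[np.ix_(perm_ind, perm_snp)],
                    [locs[i] for i in perm_ind])
        shuffled = pairwise_fst(g2).matrix.values
        pd.testing.assert_frame_equal(base, shuffled.loc[base.index, base.columns])


def amova_oracle(dosages, locations):
    """Explicit double-loop sums-of-squares partition on squared Euclidean
    dosage distances (complete data)."""
    n = len(dosages)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = np.sum((dosages[i] - dosages[j]) ** 2)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    groups = {}
    for i, loc in enumerate(locations):
        groups.setdefault(loc, []).append(i)
    ss_within = 0.0
    for idx in groups.values():
        ss_within += sum(d2[i, j] for a, i in enumerate(idx)
                         for j in idx[a + 1:]) / len(idx)
    k = len(groups)
    ms_a = (ss_total - ss_within) / (k - 1)
    ms_w = ss_within / (n - k)
    sizes = [len(v) for v in groups.values()]
    n0 = (n - sum(s ** 2 for s in sizes) / n) / (k - 1)
    sig_a = max((ms_a - ms_w) / n0, 0.0)
    return sig_a / (sig_a + ms_w)


class TestAmova:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(15, 30)).astype(float)
        d[5:10] += rng.integers(0, 2, size=(5, 30))
        d = np.clip(d, 0, 2)
        locs = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        g = make_g(d, locs)
        res = amova_phi_st(g)
        np.testing.assert_allclose(res.phi_st, amova_oracle(d, locs), atol=1e-12)

    def test_opposite_fixation_phi_one(self):
        d = np.r_[np.zeros((5, 10)), np.full((5, 10), 2.0)]
        g = make_g(d, ["A"] * 5 + ["B"] * 5)
        np.testing.assert_allclose(amova_phi_st(g).phi_st, 1.0)

    def test_identical_individuals_error(self):
        g = make_g(np.ones((6, 5)), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="zero-variance"):
            amova_phi_st(g)


class TestDivergenceMonotonicity:
    def test_theta_and_phi_track_divergence_knob(self):
        # theta and Phi_ST rise monotonically as phi (covariance range) shrinks
        from scipy.stats import spearmanr
        from landgen.synthetic import SimConfig, simulate_dataset
        phis = [8.0, 30.0, 120.0, 500.0]
        rho_theta, rho_phi = [], []
        for seed in range(10):
            thetas, phists = [], []
            for phi in phis:
                cfg = SimConfig(shape=(30, 30), n_populations=10,
                                n_individuals=8, n_neutral=120, n_adaptive=0,
                                phi=phi, seed=seed)
                ds = simulate_dataset(cfg)
                thetas.append(pairwise_fst(ds.genotypes).mean_pairwise)
                phists.append(amova_phi_st(ds.genotypes).phi_st)
            rho_theta.append(spearmanr(phis, thetas).statistic)
            rho_phi.append(spearmanr(phis, phists).statistic)
        assert np.mean(rho_theta) < -0.9
        assert np.mean(rho_phi) < -0.9
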
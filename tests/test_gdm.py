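"""GDM: I-spline basis, site pairs, fitting, transform, offset, comparison."""

import numpy as np
import pandas as pd
from scipy.integrate import quad

from landgen.gdm import (ISplineBasis, SitePairTable, assemble_site_pairs,
                         compare_models, fit_gdm, genomic_offset,
                         predict_matrix, transform_predictors)
from landgen.raster import RasterLayer
from landgen.resistance import PairwiseMatrix


def make_env(n_sites=60, n_pred=3, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"p{i}" for i in range(n_pred)]
    return pd.DataFrame(rng.uniform(0, 10, (n_sites, n_pred)),
                        index=[f"S{i}" for i in range(n_sites)], columns=names)


def synth_pairs(env, heights, alpha=0.1, seed=0):
    """Response generated exactly from known I-splines with the given
    per-predictor total heights (no noise)."""
    rng = np.random.default_rng(seed)
    bases = {p: ISplineBasis.from_data(env[p]) for p in env.columns}
    coefs = {}
    for p, h in zip(env.columns, heights):
        w = rng.uniform(0.2, 1.0, bases[p].n_basis)
        coefs[p] = h * w / w.sum()
    n = len(env)
    ii, jj = np.triu_indices(n, 1)
    eta = np.full(len(ii), alpha)
    for p in env.columns:
        iv = bases[p](env[p].to_numpy())
        eta += np.abs(iv[ii] - iv[jj]) @ coefs[p]
    d = 1 - np.exp(-eta)
    rows = {"i": ii, "j": jj, "distance": d, "weights": np.ones(len(ii))}
    for p in env.columns:
        rows[f"s1_{p}"] = env[p].to_numpy()[ii]
        rows[f"s2_{p}"] = env[p].to_numpy()[jj]
    pairs = SitePairTable(pd.DataFrame(rows), env_predictors=list(env.columns),
                          matrix_predictors=[], site_ids=list(env.index))
    return pairs, coefs


class TestISpline:
    def test_boundary_values(self):
        basis = ISplineBasis([0.0, 3.0, 10.0])
        np.testing.assert_allclose(basis(0.0), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis(10.0), 1.0, atol=1e-12)
        # clamping outside the knot range
        np.testing.assert_allclose(basis(-5.0), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis(20.0), 1.0, atol=1e-12)

    def test_monotone_non_decreasing(self):
        basis = ISplineBasis.from_data(np.random.default_rng(0).uniform(0, 5, 50))
        xs = np.linspace(-1, 6, 300)
        vals = basis(xs)
        assert np.all(np.diff(vals, axis=0) >= -1e-12)

    def test_matches_quadrature_of_m_spline(self):
        # I_i(x) equals the integral of its (normalized) M-spline density
        knots = [0.0, 2.0, 7.0]
        basis = ISplineBasis(knots)
        eps = 1e-6

        def density(i):
            return lambda t: (basis(np.array([t + eps]))[0, i]
                              - basis(np.array([t - eps]))[0, i]) / (2 * eps)

        for i in range(basis.n_basis):
            for x in (1.0, 3.5, 6.0):
                integral, _ = quad(density(i), 0.0, x, limit=200)
                np.testing.assert_allclose(basis(np.array([x]))[0, i],
                                           integral, atol=1e-6)


class TestSitePairs:
    def test_identical_frequencies_zero_distance(self):
        freqs = pd.DataFrame(np.tile([0.2, 0.4, 0.1], (3, 1)),
                             index=["a", "b", "c"])
        env = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        pairs = assemble_site_pairs(freqs, env)
        np.testing.assert_allclose(pairs.data["distance"], 0.0)

    def test_disjoint_frequencies_distance_one(self):
        freqs = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        env = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        pairs = assemble_site_pairs(freqs, env)
        np.testing.assert_allclose(pairs.data["distance"], 1.0)

    def test_pair_count(self):
        n = 12
        freqs = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (n, 5)),
                             index=[f"S{i}" for i in range(n)])
        env = pd.DataFrame({"x": np.arange(n, dtype=float)}, index=freqs.index)
        assert assemble_site_pairs(freqs, env).n_pairs == n * (n - 1) // 2


class TestFit:
    def test_noise_free_spline_recovery(self):
        env = make_env(60, 3, seed=1)
        pairs, coefs = synth_pairs(env, heights=[1.2, 0.6, 0.3], alpha=0.1)
        fit = fit_gdm(pairs)
        assert fit.pct_deviance_explained > 99.0
        for p, h in zip(env.columns, [1.2, 0.6, 0.3]):
            np.testing.assert_allclose(fit.spline_height(p), h, rtol=0.05)
        np.testing.assert_allclose(fit.intercept, 0.1, rtol=0.1)

    def test_inactive_predictor_not_selected(self):
        env = make_env(60, 3, seed=2)
        pairs, _ = synth_pairs(env, heights=[0.5, 1.0, 0.0], alpha=0.05)
        fit = fit_gdm(pairs)
        np.testing.assert_allclose(fit.spline_height("p0"), 0.5, rtol=0.10)
        np.testing.assert_allclose(fit.spline_height("p1"), 1.0, rtol=0.10)
        assert fit.spline_height("p2") < 0.05
        assert "p2" in fit.not_selected()

    def test_constant_response_intercept_only(self):
        env = make_env(30, 2, seed=3)
        pairs, _ = synth_pairs(env, heights=[0.0, 0.0], alpha=0.3)
        fit = fit_gdm(pairs)
        assert float(fit.coefficients.sum()) < 1e-6
        np.testing.assert_allclose(fit.intercept, 0.3, rtol=1e-3)

    def test_irrelevant_predictor_barely_changes_deviance(self):
        diffs = []
        for seed in range(10):
            env = make_env(30, 2, seed=seed)
            pairs, _ = synth_pairs(env, heights=[1.0, 0.4], alpha=0.1,
                                   seed=seed)
            base = fit_gdm(pairs).pct_deviance_explained
            env3 = env.copy()
            env3["noise"] = np.random.default_rng(100 + seed).uniform(0, 1, 30)
            pairs3, _ = synth_pairs(env3, heights=[1.0, 0.4, 0.0], alpha=0.1,
                                    seed=seed)
            diffs.append(abs(fit_gdm(pairs3).pct_deviance_explained - base))
        assert np.mean(diffs) < 1.0

    def test_predictions_bounded(self, ds_small):
        from landgen.genotypes import pop_allele_freqs
        freqs, _ = pop_allele_freqs(ds_small.genotypes)
        cand = freqs.iloc[:, sorted(ds_small.truth.adaptive_indices)]
        pairs = assemble_site_pairs(cand, ds_small.env_at_pops,
                                    {"res": ds_small.distances})
        fit = fit_gdm(pairs)
        pred = fit.predict(pairs)
        assert np.all((pred >= 0) & (pred < 1))

    def test_deviance_invariant_to_predictor_rescaling(self):
        env = make_env(40, 2, seed=4)
        pairs, _ = synth_pairs(env, heights=[0.8, 0.4], alpha=0.1)
        d1 = fit_gdm(pairs).pct_deviance_explained
        scaled = pairs.data.copy()
        scaled["s1_p0"] = scaled["s1_p0"] * 100 - 7
        scaled["s2_p0"] = scaled["s2_p0"] * 100 - 7
        pairs2 = SitePairTable(scaled, env_predictors=pairs.env_predictors,
                               matrix_predictors=[], site_ids=pairs.site_ids)
        d2 = fit_gdm(pairs2).pct_deviance_explained
        np.testing.assert_allclose(d1, d2, atol=1e-6)


class TestTransformAndOffset:
    def _fitted(self, seed=5):
        env = make_env(50, 2, seed=seed, names=["env_0", "env_1"])
        pairs, _ = synth_pairs(env, heights=[1.0, 0.0], alpha=0.1, seed=seed)
        return env, fit_gdm(pairs)

    def test_zero_coefficient_predictor_all_zero_layer(self):
        env, fit = self._fitted()
        rng = np.random.default_rng(0)
        stack = [RasterLayer(rng.uniform(0, 10, (8, 8)), name=n)
                 for n in ("env_0", "env_1")]
        out = transform_predictors(fit, stack)
        assert abs(out[1].values).max() < 1e-9

    def test_transformed_max_equals_height(self):
        env, fit = self._fitted()
        top = fit.bases["env_0"].knots[-1]
        np.testing.assert_allclose(fit.transform_values("env_0", top),
                                   fit.spline_height("env_0"), rtol=1e-10)

    def test_one_predictor_distance_identity(self):
        # with a single predictor, |f(x1)-f(x2)| equals eta - alpha
        env = make_env(30, 1, seed=6, names=["only"])
        pairs, _ = synth_pairs(env, heights=[0.9], alpha=0.2, seed=6)
        fit = fit_gdm(pairs)
        f = fit.transform_values("only", env["only"].to_numpy())
        ii, jj = np.triu_indices(30, 1)
        np.testing.assert_allclose(np.abs(f[ii] - f[jj]),
                                   fit.linear_predictor(pairs) - fit.intercept,
                                   atol=1e-10)

    def test_offset_zero_when_future_equals_current(self):
        env, fit = self._fitted()
        rng = np.random.default_rng(1)
        stack = [RasterLayer(rng.uniform(0, 10, (10, 10)), name=n)
                 for n in ("env_0", "env_1")]
        off = genomic_offset(fit, stack, stack)
        np.testing.assert_array_equal(off.values, 0.0)

    def test_offset_bounded_and_monotone(self):
        env, fit = self._fitted()
        rng = np.random.default_rng(2)
        cur = [RasterLayer(rng.uniform(2, 8, (10, 10)), name=n)
               for n in ("env_0", "env_1")]
        prev = None
        for shift in (0.5, 1.0, 2.0, 4.0):
            fut = [c.copy_with(c.values + shift) for c in cur]
            off = genomic_offset(fit, cur, fut).values
            assert np.all((off >= 0) & (off < 1))
            if prev is not None:
                assert np.all(off >= prev - 1e-12)
            prev = off

    def test_nodata_propagates(self):
        env, fit = self._fitted()
        vals = np.full((5, 5), 5.0)
        vals[2, 2] = np.nan
        cur = [RasterLayer(vals, name=n) for n in ("env_0", "env_1")]
        fut = [RasterLayer(vals + 1, name=n) for n in ("env_0", "env_1")]
        off = genomic_offset(fit, cur, fut)
        assert np.isnan(off.values[2, 2])
        assert np.isfinite(off.values[0, 0])


class TestCompareModels:
    def test_nested_deviance_monotone(self):
        env = make_env(40, 3, seed=7)
        pairs, _ = synth_pairs(env, heights=[1.0, 0.5, 0.2], alpha=0.1)
        table = compare_models(pairs, {
            "p0": (["p0"], []),
            "p0+p1": (["p0", "p1"], []),
            "full": (["p0", "p1", "p2"], []),
        })
        devs = table["pct_deviance_explained"]
        assert devs["p0"] <= devs["p0+p1"] + 1e-6
        assert devs["p0+p1"] <= devs["full"] + 1e-6
        assert table.loc["full", "best"]

    def test_duplicated_predictor_no_improvement(self):
        env = make_env(40, 1, seed=8, names=["a"])
        pairs, _ = synth_pairs(env, heights=[0.8], alpha=0.1)
        env2 = env.copy()
        env2["a_copy"] = env2["a"]
        pairs2, _ = synth_pairs(env2, heights=[0.8, 0.0], alpha=0.1)
        d1 = fit_gdm(pairs).pct_deviance_explained
        d2 = fit_gdm(pairs2).pct_deviance_explained
        assert abs(d2 - d1) < 0.5

    def test_resistance_model_beats_geography_on_ibr_truth(self):
        # response driven by resistance distance; geography only partially
        # correlated with it
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 25
            pts = rng.uniform(0, 10, (n, 2))
            geo = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            barrier = (pts[:, 0] > 5).astype(float)
            res = geo + 12.0 * np.abs(barrier[:, None] - barrier[None])
            d = 1 - np.exp(-(0.05 + res / res.max()))
            ii, jj = np.triu_indices(n, 1)
            env = pd.DataFrame({"e": rng.uniform(0, 1, n)},
                               index=[f"S{i}" for i in range(n)])
            rows = {"i": ii, "j": jj, "distance": d[ii, jj],
                    "weights": np.ones(len(ii)),
                    "s1_e": env["e"].to_numpy()[ii],
                    "s2_e": env["e"].to_numpy()[jj],
                    "m_res": res[ii, jj], "m_geo": geo[ii, jj]}
            pairs = SitePairTable(pd.DataFrame(rows), env_predictors=["e"],
                                  matrix_predictors=["res", "geo"],
                                  site_ids=list(env.index))
            table = compare_models(pairs, {
                "env+res": (["e"], ["res"]),
                "env+geo": (["e"], ["geo"]),
            })
            wins += (table.loc["env+res", "pct_deviance_explained"]
                     > table.loc["env+geo", "pct_deviance_explained"])
        assert wins >= 9

    def test_predict_matrix_round_trip(self):
        env = make_env(20, 2, seed=9)
        pairs, _ = synth_pairs(env, heights=[0.7, 0.3], alpha=0.1)
        fit = fit_gdm(pairs)
        m = predict_matrix(fit, pairs)
        assert isinstance(m, PairwiseMatrix)
        np.testing.assert_allclose(m.array[pairs.pair_index[:, 0],
                                           pairs.pair_index[:, 1]],
                                   fit.predict(pairs), atol=1e-12)
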
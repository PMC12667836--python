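"""Pseudobulk DE: aggregation, normalization, moderation, FDR, relatedness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from striatlas.diffexp import (
    adaptive_fdr,
    aggregate_pseudobulk,
    cosine_region_similarity,
    estimate_prior,
    fit_moderated,
    moderate_variance,
    normalize_and_weight,
    pairwise_relatedness,
    pseudobulk_de,
    tmm_factors,
)


class TestAggregation:
    def test_small_aggregates_excluded(self):
        Y = np.ones((34, 3))
        labels = ["A"] * 14 + ["B"] * 20
        animals = ["m1"] * 34
        pb = aggregate_pseudobulk(Y, labels, animals, ["g1", "g2", "g3"], min_cells=15)
        assert pb.meta["cell_type"].tolist() == ["B"]
        assert pb.excluded == [{"cell_type": "A", "animal_id": "m1", "n_cells": 14}]

    def test_sums_and_detection_rate(self):
        Y = np.array([[1, 2, 0], [0, 3, 5]])
        pb = aggregate_pseudobulk(Y, ["A", "A"], ["m1", "m1"], ["g1", "g2", "g3"],
                                  min_cells=2)
        assert pb.counts.iloc[0].tolist() == [1, 5, 5]
        assert pb.meta["detection_rate"].iloc[0] == pytest.approx(1.0)
        pb2 = aggregate_pseudobulk(np.array([[0, 1, 2], [0, 0, 0]]),
                                   ["A", "A"], ["m1", "m1"], ["g1", "g2", "g3"],
                                   min_cells=2)
        assert pb2.meta["detection_rate"].iloc[0] == pytest.approx(2 / 3)

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        Y = rng.poisson(3, size=(60, 8))
        labels = rng.choice(["A", "B"], 60)
        animals = rng.choice(["m1", "m2"], 60)
        pb = aggregate_pseudobulk(Y, labels, animals, [f"g{i}" for i in range(8)],
                                  min_cells=1)
        assert pb.counts.to_numpy().sum() == Y.sum()

    def test_no_surviving_aggregate_is_error(self):
        with pytest.raises(ValueError, match="aggregate"):
            aggregate_pseudobulk(np.ones((3, 2)), ["A"] * 3, ["m"] * 3, ["g1", "g2"])


class TestNormalization:
    def _pb(self, counts):
        genes = [f"g{i}" for i in range(counts.shape[1])]
        idx = [f"A|m{i}" for i in range(counts.shape[0])]
        meta = pd.DataFrame(
            {"cell_type": ["A", "A", "B", "B"][: counts.shape[0]],
             "animal_id": [f"m{i}" for i in range(counts.shape[0])],
             "n_cells": 20, "detection_rate": 1.0}, index=idx)
        from striatlas.diffexp import PseudobulkMatrix

        return PseudobulkMatrix(counts=pd.DataFrame(counts, index=idx, columns=genes),
                                meta=meta)

    def test_identical_samples_unit_factors_and_weights(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, 200).astype(float) + 1
        counts = np.tile(base, (4, 1))
        pb = self._pb(counts)
        norm = normalize_and_weight(pb)
        assert np.allclose(norm.norm_factors, 1.0, atol=1e-6)
        assert np.allclose(norm.sample_weights, 1.0, atol=1e-6)

    def test_uniformly_scaled_sample_factor(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, 300).astype(float) + 1
        counts = np.vstack([base, base, base, 2 * base])
        f = tmm_factors(pd.DataFrame(counts, columns=[f"g{i}" for i in range(300)]))
        # library size already absorbs the uniform doubling: TMM factor ~ 1
        assert np.allclose(f, 1.0, atol=0.02)
        # a composition change, by contrast, shifts the factor
        skew = base.copy()
        skew[:30] *= 8
        f2 = tmm_factors(pd.DataFrame(np.vstack([base, base, base, skew]),
                                      columns=[f"g{i}" for i in range(300)]))
        assert f2.iloc[3] < 0.95

    def test_weights_positive_finite(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=(4, 150)).astype(float)
        norm = normalize_and_weight(self._pb(counts), min_cpm=0.1)
        W = norm.weights.to_numpy()
        assert np.all(np.isfinite(W)) and np.all(W > 0)

    def test_all_zero_sample_rejected(self):
        counts = np.vstack([np.zeros(50), np.ones(50), np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_and_weight(self._pb(counts), min_cpm=0.0, min_samples=1)


class TestModeration:
    def test_posterior_variance_formula(self):
        out = moderate_variance(np.array([4.0]), np.array([4.0]), d0=4.0, s02=1.0)
        assert out[0] == pytest.approx(2.5, abs=1e-12)

    def test_prior_estimation_recovers_truth(self):
        rng = np.random.default_rng(1)
        d0t, s02t, d = 8.0, 2.0, 6
        sigma2 = d0t * s02t / rng.chisquare(d0t, 4000)
        s2 = sigma2 * rng.chisquare(d, 4000) / d
        d0e, s02e = estimate_prior(s2, np.full(4000, d))
        assert d0e == pytest.approx(d0t, rel=0.25)
        assert s02e == pytest.approx(s02t, rel=0.1)

    def _toy_norm(self, seed=0, n_types=2, reps=4, genes=60):
        rng = np.random.default_rng(seed)
        labels = np.repeat([f"t{i}" for i in range(n_types)], reps * 18)
        animals = np.tile(np.repeat([f"m{j}" for j in range(reps)], 18), n_types)
        Y = rng.poisson(5, size=(labels.size, genes))
        pb = aggregate_pseudobulk(Y, labels, animals, [f"g{i}" for i in range(genes)],
                                  min_cells=10)
        return normalize_and_weight(pb, min_cpm=0.1)

    def test_d0_zero_recovers_ordinary_weighted_t(self):
        norm = self._toy_norm()
        res0 = fit_moderated(norm, n_sv=0, d0_override=0.0)
        # recompute the ordinary WLS t for one gene by hand
        g = norm.logcpm.columns[0]
        t_tab = res0.table.query("gene == @g")
        Y = norm.logcpm.to_numpy()
        W = norm.weights.to_numpy() * norm.sample_weights.to_numpy()[:, None]
        types = sorted(norm.meta["cell_type"].unique())
        X = pd.get_dummies(pd.Categorical(norm.meta["cell_type"], categories=types)
                           ).to_numpy(float)
        j = list(norm.logcpm.columns).index(g)
        w = W[:, j]
        XtWXi = np.linalg.pinv((X * w[:, None]).T @ X)
        beta = XtWXi @ ((X * w[:, None]).T @ Y[:, j])
        r = Y[:, j] - X @ beta
        n, p = X.shape
        s2 = (w * r**2).sum() / (n - p)
        c = np.array([1.0, -1.0])
        t_hand = (c @ beta) / np.sqrt(s2 * c @ XtWXi @ c)
        assert t_tab.query("cell_type == 't0'")["t"].iloc[0] == pytest.approx(
            t_hand, abs=1e-10
        )

    def test_d0_infinite_recovers_pooled_z(self):
        norm = self._toy_norm(seed=1)
        res = fit_moderated(norm, n_sv=0, d0_override=np.inf)
        # with d0 = inf every gene uses the common s0^2 and the normal law
        g = norm.logcpm.columns[3]
        row = res.table.query("gene == @g and cell_type == 't0'").iloc[0]
        p_hand = 2 * stats.norm.sf(abs(row["t"]))
        assert row["p_value"] == pytest.approx(p_hand, abs=1e-10)

    def test_surrogate_variables_capped(self):
        norm = self._toy_norm(seed=2)
        res = fit_moderated(norm, n_sv="auto")
        assert 0 <= res.n_sv <= 5


class TestAdaptiveFDR:
    def test_all_ones_stay_ones(self):
        q = adaptive_fdr(np.ones(10), np.arange(10.0))
        assert np.allclose(q, 1.0)

    def test_bh_step_up_by_hand(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q = adaptive_fdr(p, covariate=None, fixed_pi0=1.0)
        assert np.allclose(q, 0.04, atol=1e-12)

    def test_constant_covariate_equals_scalar_q(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        qa = adaptive_fdr(p, np.full(500, 2.0))
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        grid = np.arange(0.05, 0.95, 0.05)
        pi0 = np.clip(np.mean([(p > l).mean() / (1 - l) for l in grid]), 0.01, 1)
        assert np.abs(qa - np.minimum(pi0 * bh, 1)).max() < 1e-10

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            adaptive_fdr(np.array([0.5, 1.5]), np.zeros(2))

    def test_covariate_informed_discoveries_with_fdr_control(self):
        from statsmodels.stats.multitest import multipletests

        fdrs, gains = [], 0
        for r in range(40):
            rng = np.random.default_rng(r)
            n = 1500
            x = rng.normal(0, 1, n)
            null = np.ones(n, bool)
            null[rng.choice(np.argsort(x)[-300:], 150, replace=False)] = False
            z = rng.normal(0, 1, n)
            z[~null] += 3.0
            p = 2 * stats.norm.sf(np.abs(z))
            q = adaptive_fdr(p, x)
            disc = q <= 0.05
            fdrs.append((disc & null).sum() / max(disc.sum(), 1))
            gains += disc.sum() >= (multipletests(p, method="fdr_bh")[1] <= 0.05).sum()
        assert np.mean(fdrs) <= 0.07
        assert gains >= 38


class TestRelatedness:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(200, 50))
        labels = ["A"] * 100 + ["B"] * 100
        rel = pairwise_relatedness(X, labels, [f"g{i}" for i in range(50)],
                                   mode="wilcoxon")
        assert rel.counts.loc["A", "B"] + rel.counts.loc["B", "A"] <= 3

    def test_planted_markers_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(300, 100)).astype(float)
        X[:150, :30] *= 4  # 30 four-fold markers up in A
        labels = ["A"] * 150 + ["B"] * 150
        rel = pairwise_relatedness(np.log1p(X), labels,
                                   [f"g{i}" for i in range(100)], mode="wilcoxon",
                                   min_log2fc=0.25)
        assert rel.counts.loc["A", "B"] == pytest.approx(30, abs=2)
        assert rel.counts.loc["B", "A"] <= 2

    def test_rank_sum_statistic_matches_enumeration(self):
        # U = #{(i,j): a_i > b_j} + 0.5 #ties, enumerated directly
        a = np.array([1.2, 3.4, 2.2, 5.0])
        b = np.array([0.5, 2.2, 4.1, 1.0])
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        u_scipy = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert u_scipy == pytest.approx(u_brute)

    def test_significance_direction_antisymmetric(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(4, size=(120, 40)).astype(float)
        X[:60, :10] *= 3
        labels = ["A"] * 60 + ["B"] * 60
        rel = pairwise_relatedness(np.log1p(X), labels,
                                   [f"g{i}" for i in range(40)], mode="wilcoxon")
        relT = pairwise_relatedness(np.log1p(X), ["B" if l == "A" else "A"
                                                  for l in labels],
                                    [f"g{i}" for i in range(40)], mode="wilcoxon")
        assert rel.counts.loc["A", "B"] == relT.counts.loc["B", "A"]

    def test_pseudobulk_mode_on_synthetic_types(self):
        rng = np.random.default_rng(3)
        n = 240
        labels = np.repeat(["A", "B"], n // 2)
        animals = np.tile(np.repeat(["m1", "m2", "m3"], n // 6), 2)
        mu = np.full(60, 5.0)
        Y = rng.poisson(mu, size=(n, 60)).astype(float)
        Y[labels == "A", :12] = rng.poisson(20, size=(n // 2, 12))
        rel = pairwise_relatedness(Y, labels, [f"g{i}" for i in range(60)],
                                   mode="moderated_t", animal_ids=animals,
                                   min_cells=10)
        assert rel.counts.loc["A", "B"] >= 10
        assert (np.diag(rel.counts) == 0).all()


class TestCosine:
    def test_unit_and_orthogonal_similarity(self):
        from sklearn.metrics.pairwise import cosine_similarity

        v = np.array([[1.0, 2, 3], [1.0, 2, 3], [3.0, -1.5, 0]])
        S = cosine_similarity(v)
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_region_similarity_matrix(self):
        rng = np.random.default_rng(4)
        base_a = rng.poisson(8, 40)
        base_b = rng.poisson(8, 40)
        Xa = rng.poisson(base_a, size=(60, 40))
        Xb = rng.poisson(base_b, size=(60, 40))
        X = np.vstack([Xa, Xb])
        regions = ["NAc"] * 60 + ["PUTv"] * 60
        M, order = cosine_region_similarity(X, regions, n_per_region=50, n_pcs=5, seed=0)
        assert set(order) == {"NAc", "PUTv"}
        assert M.loc["NAc", "NAc"] > M.loc["NAc", "PUTv"]
        assert M.loc["NAc", "PUTv"] == M.loc["PUTv", "NAc"]


def test_end_to_end_pseudobulk_de_finds_markers(demo_config, demo_panel):
    from striatlas import synth

    cells = synth.simulate_reference_cells(demo_panel, 120, demo_config)
    res = pseudobulk_de(
        cells.X,
        cells.obs["true_type"],
        np.tile(["m1", "m2", "m3"], cells.n_obs // 3 + 1)[: cells.n_obs],
        list(demo_panel.gene_ids),
        min_cells=10,
    )
    t = "D1-VS-RGS6"
    markers = demo_panel.marker_map[t]
    tab = res.table.query("cell_type == @t").set_index("gene")
    assert (tab.loc[markers, "adj_p_between"] < 0.05).all()
    assert (tab.loc[markers, "log2fc"] > 1).all()
    assert res.d0 > 0
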
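"""Spatial axes, Otsu boundaries, the RDD test, gradients, LOESS, and the LMM."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import shortest_path
from scipy.stats import spearmanr

from striatlas.spatialstats import (
    AxisSpec,
    abundance_gradient,
    embed_1d,
    lmm_fit,
    loess_smooth,
    log1p_norm,
    otsu_boundary,
    rdd_test,
    reference_correlation,
)


class TestEmbed:
    def test_axis_mode_is_identity(self):
        xy = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
        assert np.array_equal(embed_1d(xy, AxisSpec(mode="axis_x")), xy[:, 0])
        assert np.array_equal(embed_1d(xy, AxisSpec(mode="axis_y")), xy[:, 1])

    def test_line_gives_affine_arc_length(self):
        t = np.linspace(0, 1, 50)
        xy = np.column_stack([t * 100, t * 40])
        coord = embed_1d(xy, AxisSpec(mode="isomap_1d", n_neighbors=5))
        assert spearmanr(coord, t).statistic == pytest.approx(1.0)

    def test_quarter_circle_ordering_and_geodesics(self):
        th = np.linspace(0, np.pi / 2, 200)
        xy = 100 * np.column_stack([np.cos(th), np.sin(th)])
        spec = AxisSpec(mode="isomap_1d", n_neighbors=10)
        coord = embed_1d(xy, spec)
        assert abs(spearmanr(coord, th).statistic) == pytest.approx(1.0)
        # geodesic oracle: brute-force shortest paths on the same kNN graph
        from sklearn.neighbors import kneighbors_graph

        g = kneighbors_graph(xy, 10, mode="distance")
        g = g.maximum(g.T)
        d = shortest_path(g, directed=False)
        # the 1-D embedding must reproduce geodesic ordering from the ends
        ref = d[0]
        assert abs(spearmanr(coord, ref).statistic) == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_graph_is_reported(self):
        xy = np.vstack([np.random.default_rng(0).normal(0, 1, (20, 2)),
                        np.random.default_rng(1).normal(1000, 1, (20, 2))])
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_1d(xy, AxisSpec(mode="isomap_1d", n_neighbors=3))


class TestOtsu:
    def test_symmetric_bimodal_toy(self):
        assert otsu_boundary(np.array([0, 0, 0, 10, 10, 10.0])) == 5.0

    def test_binary_coords_single_interior_edge(self):
        b = otsu_boundary(np.array([0.0, 1.0] * 10))
        assert 0.0 < b < 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_boundary(np.full(5, 3.0))

    def test_equals_exhaustive_scan_on_random_mixtures(self):
        def brute_sigmas(x, n_bins=128):
            hist, edges = np.histogram(x, bins=n_bins)
            cent = 0.5 * (edges[:-1] + edges[1:])
            out = {}
            for k in range(1, n_bins):
                w0, w1 = hist[:k].sum(), hist[k:].sum()
                if w0 == 0 or w1 == 0:
                    continue
                m0 = (hist[:k] * cent[:k]).sum() / w0
                m1 = (hist[k:] * cent[k:]).sum() / w1
                out[edges[k]] = w0 * w1 * (m0 - m1) ** 2
            return out

        rng = np.random.default_rng(0)
        for _ in range(100):
            x = np.concatenate([rng.normal(0, 1, 120), rng.normal(6, 1, 80)])
            b = otsu_boundary(x)
            sig = brute_sigmas(x)
            best = max(sig.values())
            # the returned edge achieves the exhaustive-scan maximum
            assert sig[b] >= best * (1 - 1e-9)

    def test_well_separated_mixture_threshold_in_valley(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100)])
        assert 2.0 < otsu_boundary(x) < 4.0


class TestRDD:
    def test_noiseless_step_recovered_exactly(self):
        c = np.concatenate([np.linspace(-1, -0.01, 50), np.linspace(0.01, 1, 50)])
        e = np.where(c > 0, 5.0, 0.0)
        res = rdd_test(e, c, 0.0)
        assert res.jump_beta == pytest.approx(5.0, abs=1e-10)
        assert res.slope_beta == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 0.0

    def test_noiseless_gradient_has_zero_jump(self):
        c = np.linspace(-1, 1, 100)
        res = rdd_test(2 * c, c, 0.0)
        assert res.jump_beta == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 1.0

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(-1, 1, 400)
        e = 0.5 * (c > 0) + c + rng.normal(0, 1, 400)
        res = rdd_test(e, c, 0.0)
        X = np.column_stack([np.ones(400), (c > 0).astype(float), c])
        beta = np.linalg.solve(X.T @ X, X.T @ e)
        assert res.jump_beta == pytest.approx(beta[1], abs=1e-10)
        assert res.slope_beta == pytest.approx(beta[2], abs=1e-10)

    def test_affine_axis_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(-1, 1, 300)
        e = 1.0 * (c > 0) + 2 * c + rng.normal(0, 1, 300)
        r1 = rdd_test(e, c, 0.0)
        r2 = rdd_test(e, 10 * c + 3, 3.0)
        assert r2.jump_beta == pytest.approx(r1.jump_beta, rel=1e-9)
        assert r2.slope_beta == pytest.approx(r1.slope_beta / 10, rel=1e-9)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-6)

    def test_min_side_enforced(self):
        c = np.concatenate([np.full(5, -1.0), np.linspace(0.1, 1, 100)])
        with pytest.raises(ValueError, match="sides"):
            rdd_test(np.zeros(105), c, 0.0)


class TestReferenceCorrelation:
    def test_perfect_match_gives_unit_r2(self, toy_panel, toy_config):
        from striatlas import synth

        cells = synth.simulate_reference_cells(toy_panel, 300, toy_config)
        cells.obs["assigned_label"] = cells.obs["true_type"]
        out = reference_correlation(cells, toy_panel)
        assert (out["r2"].dropna() > 0.9).all()

    def test_hand_computed_pearson(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 6])
        r_hand = np.corrcoef(a, b)[0, 1]
        from scipy.stats import pearsonr

        assert pearsonr(a, b).statistic == pytest.approx(r_hand, abs=1e-12)


class TestGradient:
    def _obs(self, recs):
        return pd.DataFrame(recs)

    def test_even_split_unit_fold_change(self):
        obs = self._obs(
            [{"section_id": "s1", "rc_level_mm": 0.0, "assigned_label": t}
             for t in ["A"] * 50 + ["B"] * 50]
        )
        g = abundance_gradient(obs, group=["A", "B"], pair=("A", "B"))
        assert set(g.per_section["percent"]) == {50.0}
        assert g.fold_change["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_five_fold_change(self):
        obs = self._obs(
            [{"section_id": "s1", "rc_level_mm": 0.0, "assigned_label": t}
             for t in ["A"] * 10 + ["B"] * 50]
        )
        g = abundance_gradient(obs, group=["A", "B"], pair=("A", "B"))
        assert g.fold_change["fold_change"].iloc[0] == pytest.approx(5.0)

    def test_sem_across_sections(self):
        recs = []
        for sec, pct in zip("abc", (10, 20, 30)):
            recs += [{"section_id": sec, "rc_level_mm": 0.0, "assigned_label": "A"}] * pct
            recs += [{"section_id": sec, "rc_level_mm": 0.0, "assigned_label": "B"}] * (100 - pct)
        g = abundance_gradient(self._obs(recs), group=["A", "B"])
        sem = g.sem_by_level.query("cell_type == 'A'")["sem"].iloc[0]
        assert sem == pytest.approx(10 / np.sqrt(3), abs=1e-6)  # 5.7735

    def test_zero_count_pair_flagged(self):
        obs = self._obs(
            [{"section_id": "s1", "rc_level_mm": 0.0, "assigned_label": "B"}] * 20
        )
        g = abundance_gradient(obs, group=["A", "B"], pair=("A", "B"))
        assert any("undefined" in f for f in g.flags)


class TestLoess:
    def test_reproduces_linear_signal_exactly(self):
        x = np.linspace(0, 10, 25)
        y = 3 * x - 2
        for span in (0.3, 0.75, 1.0):
            assert np.allclose(loess_smooth(x, y, span=span), y, atol=1e-9)

    def test_constant_signal(self):
        x = np.arange(10.0)
        assert np.allclose(loess_smooth(x, np.full(10, 4.0)), 4.0)

    def test_matches_per_point_wls_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 10))
        y = np.sin(x) + rng.normal(0, 0.1, 10)
        span = 0.6
        x0 = x[4]
        fitted = loess_smooth(x, y, span=span, x_query=np.array([x0]))[0]
        k = int(np.ceil(span * 10))
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
        X = np.column_stack([np.ones(k), x[idx] - x0])
        beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y[idx]))
        assert fitted == pytest.approx(beta[0], abs=1e-10)


class TestLMM:
    def test_single_group_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        x = np.arange(12.0)
        y = 2 + 0.7 * x + rng.normal(0, 1, 12)
        fit = lmm_fit(y, x, np.repeat("g", 12))
        assert fit.beta == pytest.approx(np.polyfit(x, y, 1)[0], abs=1e-8)

    def test_zero_group_variance_hits_boundary(self):
        rng = np.random.default_rng(2)
        x = np.tile(np.arange(10.0), 3)
        g = np.repeat(list("abc"), 10)
        y = 1 + 0.5 * x + rng.normal(0, 1, 30)
        fit = lmm_fit(y, x, g)
        assert fit.random_intercept_sd <= 0.3
        ols = np.polyfit(x, y, 1)[0]
        assert fit.beta == pytest.approx(ols, abs=0.05)

    def test_matches_statsmodels_reml_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = np.tile(np.arange(10.0), 4)
        g = np.repeat(list("abcd"), 10)
        y = 1 + 1.44 * x + np.repeat(rng.normal(0, 1.5, 4), 10) + rng.normal(0, 1, 40)
        fit = lmm_fit(y, x, g)
        md = sm.MixedLM(y, sm.add_constant(x), groups=g).fit(reml=True)
        assert fit.beta == pytest.approx(np.asarray(md.params)[1], abs=1e-5)
        assert fit.se_beta == pytest.approx(np.asarray(md.bse)[1], abs=1e-4)
        assert fit.random_intercept_sd == pytest.approx(
            float(np.sqrt(np.asarray(md.cov_re)[0, 0])), abs=1e-3
        )

    def test_reml_at_optimum_not_below_boundary_model(self):
        rng = np.random.default_rng(6)
        x = np.tile(np.arange(8.0), 3)
        g = np.repeat(list("abc"), 8)
        y = 1 + x + np.repeat(rng.normal(0, 2, 3), 8) + rng.normal(0, 1, 24)
        from striatlas.spatialstats import _reml_profile

        fit = lmm_fit(y, x, g)
        X = np.column_stack([np.ones_like(x), x])
        groups_idx = [np.flatnonzero(g == k) for k in "abc"]
        crit0 = _reml_profile(0.0, y, X, groups_idx)[0]
        assert -0.5 * crit0 <= fit.reml_loglik + 1e-9


def test_log1p_norm_scales_to_median_depth():
    Y = np.array([[10, 0], [0, 40]])
    out = log1p_norm(Y)
    # depths 10 and 40, median 25: row 0 scaled by 2.5, row 1 by 0.625
    assert out[0, 0] == pytest.approx(np.log1p(25.0))
    assert out[1, 1] == pytest.approx(np.log1p(25.0))
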
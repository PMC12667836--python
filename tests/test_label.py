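"""Decomposition, doublet-mode classification, and two-round labeling."""

import numpy as np
import pytest

from striatlas import synth
from striatlas.label import (
    UNCLASSIFIED,
    PlatformFactors,
    assign_label,
    classify_mode,
    classify_modes,
    decompose_cell,
    decompose_cells,
    estimate_platform_factors,
    hierarchical_label,
    label_cells,
    poisson_mixture_loglik,
)


class TestPlatformFactors:
    def test_identical_pseudobulks_give_unit_factors(self):
        v = np.array([10.0, 20, 30, 40, 500.0])
        pf = estimate_platform_factors(v, v)
        assert np.allclose(pf.gamma, 1.0, atol=0.01)

    def test_doubled_reference_gene_halves_its_factor(self):
        s = np.full(50, 1000.0)
        r = np.full(50, 1000.0)
        r[7] *= 2
        pf = estimate_platform_factors(s, r)
        assert pf.gamma[7] == pytest.approx(0.5, abs=0.05)
        others = np.delete(pf.gamma, 7)
        assert np.allclose(others, 1.0, atol=0.06)

    def test_zero_in_reference_falls_back_to_one(self):
        s = np.array([10.0, 10, 10])
        r = np.array([10.0, 0, 10])
        pf = estimate_platform_factors(s, r)
        assert pf.gamma[1] == 1.0

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_platform_factors(np.zeros(3), np.ones(3))


class TestDecompose:
    def test_pure_singlet(self, toy_panel):
        y = np.round(500 * toy_panel.mu[0])
        w = decompose_cell(y, toy_panel)
        assert w[0] >= 0.99

    def test_symmetric_mix_disjoint_support(self):
        # two types with disjoint support: weights must split evenly
        mu = np.zeros((2, 10))
        mu[0, :5] = 0.2
        mu[1, 5:] = 0.2
        panel = synth.ReferencePanel(
            gene_ids=[f"g{i}" for i in range(10)], type_ids=["A", "B"], mu=mu,
            panel_mask=np.ones(10, bool),
            marker_map={"A": ["g0", "g1"], "B": ["g5", "g6"]},
        )
        y = np.round(200 * (0.5 * mu[0] + 0.5 * mu[1]))
        w = decompose_cell(y, panel)
        assert np.allclose(w, [0.5, 0.5], atol=0.02)

    @pytest.mark.parametrize("cell_seed", [1, 2, 3])
    def test_matches_exhaustive_grid_search(self, toy_panel, cell_seed):
        rng = np.random.default_rng(cell_seed)
        wtrue = rng.dirichlet(np.ones(3))
        y = rng.poisson(400 * wtrue @ toy_panel.mu)
        w = decompose_cell(y, toy_panel)
        best, bw = -np.inf, None
        N = y.sum()
        for a in range(101):
            for b in range(101 - a):
                ww = np.array([a, b, 100 - a - b]) / 100
                ll = poisson_mixture_loglik(y, ww, toy_panel.mu, N)
                if ll > best:
                    best, bw = ll, ww
        assert np.abs(w - bw).max() <= 0.02

    def test_weights_live_on_simplex(self, toy_panel, toy_config):
        cells = synth.simulate_reference_cells(toy_panel, 30, toy_config)
        W = decompose_cells(cells.X, toy_panel)
        assert np.all(W >= 0) and np.all(W <= 1)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-6)

    def test_likelihood_never_decreases(self, toy_panel, toy_config):
        cells = synth.simulate_reference_cells(toy_panel, 10, toy_config)
        decompose_cells(cells.X, toy_panel, check_ascent=True)  # asserts internally

    def test_platform_factors_respected(self, toy_panel):
        # counts generated under gamma-scaled profiles are recovered when the
        # same factors are supplied
        gamma = np.exp(np.linspace(-0.5, 0.5, toy_panel.n_genes))
        pf = PlatformFactors(gene_ids=list(toy_panel.gene_ids), gamma=gamma)
        prof = toy_panel.mu * gamma
        prof = prof / prof.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(0)
        y = rng.poisson(600 * prof[1])
        w = decompose_cell(y, toy_panel, pf)
        assert w[1] > 0.9

    def test_zero_count_cell_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="zero-count"):
            decompose_cell(np.zeros(20), toy_panel)


class TestClassify:
    def test_pure_singlet_mode(self, toy_panel):
        y = np.round(500 * toy_panel.mu[0])
        mode, _ = classify_mode(y, toy_panel)
        assert mode == "singlet"

    def test_balanced_mix_high_depth_is_certain_doublet(self, toy_panel):
        y = np.round(1000 * (0.5 * toy_panel.mu[0] + 0.5 * toy_panel.mu[1]))
        mode, _ = classify_mode(y, toy_panel)
        assert mode == "doublet_certain"

    def test_unrelated_uniform_counts_rejected(self, demo_panel):
        rng = np.random.default_rng(3)
        G = demo_panel.n_genes
        U = rng.integers(0, 2 * 500 // G + 2, size=(30, G))
        modes, _ = classify_modes(U, demo_panel)
        assert modes.count("rejected") >= 24

    def test_genuine_cells_not_rejected(self, demo_panel, demo_config):
        cells = synth.simulate_reference_cells(demo_panel, 25, demo_config)
        modes, _ = classify_modes(cells.X, demo_panel)
        assert modes.count("rejected") == 0


class TestAssign:
    def test_majority_weight_assigned(self):
        assert assign_label(np.array([0.62, 0.30, 0.08]), "singlet", ["a", "b", "c"]) == "a"

    def test_no_majority_is_unclassified(self):
        lab = assign_label(np.array([0.45, 0.40, 0.15]), "singlet", ["a", "b", "c"])
        assert lab == UNCLASSIFIED

    def test_exactly_half_is_unclassified(self):
        # the assignment rule is a strict inequality at 0.5
        lab = assign_label(np.array([0.5, 0.5]), "singlet", ["a", "b"])
        assert lab == UNCLASSIFIED

    def test_rejected_cells_excluded(self, toy_panel, toy_config):
        cells = synth.simulate_reference_cells(toy_panel, 5, toy_config)
        Y = cells.X.toarray()
        Y[0] = 0  # forces rejection before fitting
        res = label_cells(
            type(cells)(X=Y, obs=cells.obs, var=cells.var), toy_panel, classify=False
        )
        assert res["mode"].iloc[0] == "rejected"
        assert res["assigned_label"].iloc[0] is None

    def test_unclassified_rate_monotone_in_marker_fold(self):
        rates = []
        for fold in (10, 5, 3, 2, 1):
            cfg = synth.SimulationConfig(seed=11, n_types=6, n_genes=60,
                                         marker_fold=fold, library_size_mean=250)
            panel = synth.make_reference(cfg)
            cells = synth.simulate_reference_cells(panel, 150, cfg)
            W = decompose_cells(cells.X, panel)
            lab = [assign_label(w, "singlet", panel.type_ids) for w in W]
            rates.append(np.mean([l == UNCLASSIFIED for l in lab]))
        assert all(rates[i] <= rates[i + 1] + 0.01 for i in range(len(rates) - 1))


class TestHierarchical:
    def test_two_round_recovery(self, demo_config, demo_panel, class_and_subtype_panels):
        class_panel, subtype_panel = class_and_subtype_panels
        cells = synth.simulate_reference_cells(demo_panel, 100, demo_config)
        out, summary = hierarchical_label(cells, class_panel, subtype_panel)
        msn_truth = cells.obs["true_type"].isin(synth.DEMO_MSN_TYPES)
        sub = out.obs[msn_truth & (out.obs["label_round"] == "msn_subtype")]
        acc = (sub["assigned_label"] == sub["true_type"]).mean()
        assert acc >= 0.95
        assert summary["n_msn"] > 0

    def test_non_msn_cells_keep_round1_label(self, demo_config, demo_panel,
                                             class_and_subtype_panels):
        class_panel, subtype_panel = class_and_subtype_panels
        cells = synth.simulate_reference_cells(demo_panel, 60, demo_config)
        out, _ = hierarchical_label(cells, class_panel, subtype_panel)
        glia = out.obs[out.obs["major_class"].isin(["Astro", "Oligo"])]
        assert (glia["label_round"] == "major_class").all()
        assert (glia["assigned_label"] == glia["major_class"]).all()

    def test_all_glia_skips_round_two(self, demo_config, demo_panel,
                                      class_and_subtype_panels):
        class_panel, subtype_panel = class_and_subtype_panels
        cells = synth.simulate_reference_cells(demo_panel, 40, demo_config)
        keep = cells.obs["true_type"].isin(["Astro", "Oligo"]).to_numpy()
        with pytest.warns(UserWarning, match="skipped"):
            out, summary = hierarchical_label(cells[keep], class_panel, subtype_panel)
        assert summary["n_msn"] == 0
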
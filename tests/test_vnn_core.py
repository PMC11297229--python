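"""Network assembly and the masked forward pass."""

import numpy as np
import pytest

from visomix.annot_masks import ConnectivityMask
from visomix.synthdata import simulate_hierarchy
from visomix.vnn_core import (
    NetworkEngine,
    add_covariates,
    arctanh_activation,
    build_dense_equivalent,
    build_ge_network,
    build_locally_connected_baseline,
    build_me_ge_network,
    build_me_network,
    build_pathway_network,
    init_output_bias,
    init_state,
    masked_affine_forward,
)
from visomix.annot_masks import build_pathway_masks

from conftest import random_mask


def _gene_mask_fixture(n_cpgs=6, n_genes=3):
    """n_cpgs CpGs spread round-robin over n_genes genes."""
    edges = np.array([(i, i % n_genes) for i in range(n_cpgs)])
    return ConnectivityMask(
        [f"cg{i}" for i in range(n_cpgs)], [f"G{j}" for j in range(n_genes)], edges
    )


class TestMaskedAffineForward:
    def test_two_inputs_sum(self):
        mask = ConnectivityMask(["a", "b"], ["o"], np.array([[0, 0], [1, 0]]))
        out = masked_affine_forward(
            np.array([[3.0, 4.0]]), np.array([1.0, 1.0]), np.array([0.0]), mask, "linear"
        )
        assert out[0, 0] == pytest.approx(7.0)

    def test_relu_clamps_negative_preactivations(self):
        mask = ConnectivityMask(["a"], ["x", "y", "z"],
                                np.array([[0, 0], [0, 1], [0, 2]]))
        out = masked_affine_forward(
            np.array([[1.0]]), np.array([-2.0, 0.0, 5.0]), np.zeros(3), mask, "relu"
        )
        assert out.tolist() == [[0.0, 0.0, 5.0]]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_dense_matrix_with_explicit_zeros(self, seed):
        rng = np.random.default_rng(seed)
        n_in, n_out = int(rng.integers(2, 20)), int(rng.integers(1, 20))
        mask = random_mask(rng, [f"i{k}" for k in range(n_in)],
                           [f"o{k}" for k in range(n_out)], density=0.4)
        w = rng.standard_normal(mask.n_edges)
        b = rng.standard_normal(n_out)
        x = rng.standard_normal((8, n_in))
        W = np.zeros((n_in, n_out))
        for k, (i, j) in enumerate(mask.edges):
            W[i, j] = w[k]
        expected = np.maximum(x @ W + b, 0.0)
        got = masked_affine_forward(x, w, b, mask, "relu")
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_nan_input_rejected(self):
        mask = ConnectivityMask(["a"], ["o"], np.array([[0, 0]]))
        with pytest.raises(ValueError, match="NaN"):
            masked_affine_forward(np.array([[np.nan]]), np.ones(1), np.zeros(1), mask)

    def test_dimension_mismatch_reported(self):
        mask = ConnectivityMask(["a", "b"], ["o"], np.array([[0, 0], [1, 0]]))
        with pytest.raises(ValueError, match="columns"):
            masked_affine_forward(np.ones((2, 3)), np.ones(2), np.zeros(1), mask)


class TestArctanh:
    def test_odd_function_zero(self):
        assert arctanh_activation(np.array(0.0)) == 0.0

    def test_closed_form_value(self):
        # atanh(0.5) = 0.5*ln(3), frozen from the series expansion
        assert arctanh_activation(np.array(0.5)) == pytest.approx(
            0.5493061443340549, abs=1e-12
        )

    def test_out_of_domain_clipped_finite(self):
        v = arctanh_activation(np.array(1.7))
        assert np.isfinite(v)
        assert v == pytest.approx(np.arctanh(1 - 1e-5))

    def test_monotone(self):
        z = np.linspace(-2, 2, 101)
        assert (np.diff(arctanh_activation(z)) >= 0).all()


class TestBuilders:
    def test_ge_network_is_single_layer_lasso_like(self):
        spec = build_ge_network([f"G{i}" for i in range(10)], "classification")
        assert len(spec.layers) == 1
        assert spec.layers[0].mask.n_edges == 10
        assert spec.layers[0].activation == "sigmoid"
        assert build_ge_network(["G0"], "regression").layers[0].activation == "relu"

    def test_me_network_dims_and_activations(self):
        spec = build_me_network(_gene_mask_fixture(6, 3), "classification")
        assert [len(ly.mask.out_ids) for ly in spec.layers] == [3, 1]
        assert spec.layers[0].activation == "arctanh"
        assert sum(ly.mask.n_edges for ly in spec.layers) == 6 + 3

    def test_me_network_regression_uses_relu_throughout(self):
        spec = build_me_network(_gene_mask_fixture(), "regression")
        assert [ly.activation for ly in spec.layers] == ["relu", "relu"]

    def test_me_ge_combined_layer_two_tagged_edges_per_gene(self):
        gm = _gene_mask_fixture(7, 3)
        spec = build_me_ge_network(gm, ["G0", "G1", "G2"], "classification")
        gene = spec.layer("gene")
        assert (gene.mask.out_degree() == 2).all()
        tags = gene.mask.tags
        assert (tags == "me").sum() == 3 and (tags == "ge").sum() == 3
        # trainable weight count: cpgs + 2 per gene + gene->output
        assert sum(ly.mask.n_edges for ly in spec.layers) == 7 + 2 * 3 + 3

    def test_me_ge_requires_intersected_order(self):
        gm = _gene_mask_fixture(6, 3)
        with pytest.raises(ValueError, match="gene_order"):
            build_me_ge_network(gm, ["G0", "G1"], "classification")

    def test_pathway_network_shapes_and_output_indegree(self):
        genes = [f"G{i:03d}" for i in range(400)]
        edges = np.array([(i, i % 400) for i in range(800)])
        gm = ConnectivityMask([f"cg{i}" for i in range(800)], genes, edges)
        h = simulate_hierarchy(genes, n_local=321, n_mid=44, n_global=6,
                               annotated_fraction=0.6, seed=2)
        base = build_me_ge_network(gm, genes, "classification")
        spec = build_pathway_network(base, build_pathway_masks(h, genes))
        dims = {ly.name: len(ly.mask.out_ids) for ly in spec.layers}
        assert (dims["pw_local"], dims["pw_mid"], dims["pw_global"]) == (321, 44, 6)
        n_unannotated = sum(1 for g in genes if not h.membership.get(g))
        assert spec.layers[-1].mask.n_edges == 6 + n_unannotated

    def test_pathway_network_all_unannotated_degenerates_to_me_ge(self):
        genes = ["G0", "G1", "G2"]
        gm = _gene_mask_fixture(6, 3)
        h = simulate_hierarchy(genes, n_local=2, n_mid=1, n_global=1,
                               annotated_fraction=0.0, seed=0)
        base = build_me_ge_network(gm, genes, "classification")
        spec = build_pathway_network(base, build_pathway_masks(h, genes))
        assert [ly.name for ly in spec.layers] == ["me_gene", "gene", "output"]
        assert spec.layers[-1].mask.n_edges == 3

    def test_dense_equivalent_dims_and_param_count(self):
        gm = _gene_mask_fixture(6, 3)
        base = build_me_ge_network(gm, ["G0", "G1", "G2"], "classification")
        spec = build_dense_equivalent(base, dims=(321, 44, 6))
        dims = [len(ly.mask.out_ids) for ly in spec.layers[2:]]
        assert dims == [321, 44, 6, 1]
        dense_params = sum(ly.mask.n_edges for ly in spec.layers[2:])
        assert dense_params == 3 * 321 + 321 * 44 + 44 * 6 + 6

    def test_dense_equivalent_equals_pathway_with_complete_masks(self):
        genes = ["G0", "G1", "G2"]
        gm = _gene_mask_fixture(6, 3)
        base = build_me_ge_network(gm, genes, "classification")
        # complete-bipartite pathway masks == dense layers of the same widths
        g2l = ConnectivityMask.dense(genes, ["p0", "p1"])
        l2m = ConnectivityMask.dense(["p0", "p1"], ["m0", "m1"])
        m2g = ConnectivityMask.dense(["m0", "m1"], ["t0"])
        skip = ConnectivityMask(genes, ["output"], np.empty((0, 2), dtype=np.int64))
        pw = build_pathway_network(base, (g2l, l2m, m2g, skip))
        dn = build_dense_equivalent(base, dims=(2, 2, 1))
        rng = np.random.default_rng(4)
        st = init_state(pw, seed=1)
        inputs = {
            "methylation": rng.uniform(0, 1, (5, 6)),
            "expression": rng.standard_normal((5, 3)),
        }
        out_pw = NetworkEngine(pw).predict(st, inputs)
        # same parameter values drive the dense twin (identical edge ordering)
        out_dn = NetworkEngine(dn).predict(
            type(st)(weights=st.weights, biases=st.biases), inputs
        )
        np.testing.assert_allclose(out_pw, out_dn, atol=1e-12)

    def test_add_covariates_per_gene_and_last_layer(self):
        gm = _gene_mask_fixture(6, 3)
        base = build_me_ge_network(gm, ["G0", "G1", "G2"], "classification")
        per_gene = add_covariates(base, ["sex"], mode="per_gene")
        gene = per_gene.layer("gene")
        assert gene.mask.n_edges == base.layer("gene").mask.n_edges + 3
        assert (gene.mask.tags == "covariate").sum() == 3
        last = add_covariates(base, ["sex", "age"], mode="last_layer")
        assert last.layers[-1].mask.n_edges == 3 + 2

    def test_covariate_edge_count_scales_with_genes(self):
        gm = _gene_mask_fixture(8, 4)
        base = build_me_ge_network(gm, [f"G{j}" for j in range(4)], "regression")
        spec = add_covariates(base, ["c1", "c2", "c3"], mode="per_gene")
        extra = spec.layer("gene").mask.n_edges - base.layer("gene").mask.n_edges
        assert extra == 3 * 4

    def test_locally_connected_baseline(self):
        ids = [f"f{i}" for i in range(100)]
        spec = build_locally_connected_baseline(ids, 10, 10, (8, 4), "classification")
        local = spec.layers[0]
        assert len(local.mask.out_ids) == 10
        assert local.mask.n_edges == 10 * 10
        # limiting case: full-width window collapses to one unit
        spec1 = build_locally_connected_baseline(ids, 100, 100, (4, 2), "regression")
        assert len(spec1.layers[0].mask.out_ids) == 1


class TestState:
    def test_output_bias_is_training_mean(self):
        spec = build_ge_network(["G0", "G1"], "regression")
        st = init_output_bias(init_state(spec, 0), np.array([2.0, 4.0, 6.0]))
        assert st.biases[-1][0] == pytest.approx(4.0)
        st = init_output_bias(st, np.full(17, 3.25))
        assert st.biases[-1][0] == pytest.approx(3.25)

    def test_output_bias_random_mean(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(101)
        spec = build_ge_network(["G0"], "regression")
        st = init_output_bias(init_state(spec, 0), y)
        assert st.biases[-1][0] == pytest.approx(float(np.sum(y) / len(y)), abs=1e-12)

    def test_same_seed_same_weights(self):
        spec = build_me_network(_gene_mask_fixture(), "classification")
        a, b = init_state(spec, 42), init_state(spec, 42)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


class TestNetworkProperties:
    def test_output_ranges_by_task(self):
        rng = np.random.default_rng(0)
        gm = _gene_mask_fixture(6, 3)
        inputs = {
            "methylation": rng.uniform(0, 1, (20, 6)),
            "expression": rng.standard_normal((20, 3)),
        }
        for task, lo, hi in (("classification", 0.0, 1.0), ("regression", 0.0, np.inf)):
            spec = build_me_ge_network(gm, ["G0", "G1", "G2"], task)
            st = init_state(spec, 3, gain=1.0)
            st.weights = [w * 3 for w in st.weights]  # push into extreme ranges
            out = NetworkEngine(spec).predict(st, inputs)
            assert (out >= lo).all()
            if np.isfinite(hi):
                assert (out < hi).all()

    def test_gradient_locality_masked_edges_only(self, make_random_network):
        # perturbing a weight on an edge that cannot reach the output never
        # changes the prediction
        spec, state = make_random_network(11)
        eng = NetworkEngine(spec)
        rng = np.random.default_rng(1)
        X = {"x": rng.standard_normal((6, 6))}
        base = eng.predict(state, X)
        # cut every outgoing path of hidden unit h0:0 downstream, then vary its
        # incoming weights: predictions must not move
        h0 = "h0:0"
        for li, ly in enumerate(spec.layers):
            for k, (i, j) in enumerate(ly.mask.edges):
                if ly.mask.in_ids[i] == h0:
                    state.weights[li][k] = 0.0
        cut = eng.predict(state, X)
        for li, ly in enumerate(spec.layers):
            for k, (i, j) in enumerate(ly.mask.edges):
                if ly.mask.out_ids[j] == h0:
                    state.weights[li][k] += 13.7
        np.testing.assert_allclose(eng.predict(state, X), cut, atol=1e-9)
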
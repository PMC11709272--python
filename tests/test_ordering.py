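import math

import numpy as np
import pandas as pd
import pytest

from dagsem import (
    LayerAssignment,
    NodeOrdering,
    OrderingSpec,
    adaptive_eta,
    bottomup_order,
    bottomup_order_from_covariance,
    correlation_matrix,
    default_glasso_lambda,
    glasso_precision,
    knowledge_order,
    layer_decomposition,
    population_covariance,
    random_dag,
    simulate_sem,
    topological_sort,
)

from conftest import random_sem


class TestCorrelationMatrix:
    def test_perfectly_correlated_columns(self):
        x = np.linspace(-1, 1, 50)
        S = correlation_matrix(pd.DataFrame({"a": x, "b": 3 * x + 2}), scale=True)
        assert S.loc["a", "b"] == pytest.approx(1.0)

    def test_unit_diagonal_when_scaled(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        S = correlation_matrix(data, scale=True)
        assert np.allclose(np.diag(S), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        data = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        S = correlation_matrix(data, scale=True)
        off = S.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 5 / math.sqrt(n)

    def test_zero_variance_column_named(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(data, scale=True)

    def test_unscaled_is_moment_covariance(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        S = correlation_matrix(data, scale=False)
        X = data.to_numpy() - data.to_numpy().mean(0)
        assert np.allclose(S, X.T @ X / 30)


class TestGlassoPrecision:
    def test_identity_input(self):
        S = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        prec = glasso_precision(S, 0.001)
        assert np.abs(prec.matrix.to_numpy() - np.eye(4)).max() < 1e-3

    def test_tiny_lambda_matches_inverse(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(60, 5))
        S = pd.DataFrame(A.T @ A / 60 + 0.5 * np.eye(5))
        prec = glasso_precision(S, 1e-6)
        assert np.abs(prec.matrix.to_numpy() - np.linalg.inv(S)).max() < 1e-4

    def test_huge_lambda_decouples(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(80, 4))
        S = pd.DataFrame(A.T @ A / 80 + np.eye(4))
        prec = glasso_precision(S, 100.0)
        off = prec.matrix.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 1e-8
        assert np.allclose(prec.diagonal, 1 / np.diag(S), atol=1e-6)

    def test_positive_definite_output(self, chain3):
        prec = glasso_precision(population_covariance(chain3), 0.01)
        assert np.linalg.eigvalsh(prec.matrix.to_numpy()).min() > 0


class TestDefaultGlassoLambda:
    def test_low_dimensional_constant(self):
        assert default_glasso_lambda(200, 100) == 0.001

    def test_high_dimensional_sqrt_rate(self):
        assert default_glasso_lambda(50, 100) == pytest.approx(
            math.sqrt(math.log(100) / 50), abs=1e-12
        )
        assert default_glasso_lambda(50, 100) == pytest.approx(0.3035, abs=5e-4)

    def test_boundary_takes_high_dimensional_branch(self):
        assert default_glasso_lambda(64, 64) == pytest.approx(math.sqrt(math.log(64) / 64))

    def test_flat_rule_option(self):
        assert default_glasso_lambda(50, 100, hd_rule="flat") == pytest.approx(
            math.log(100) / 50
        )


class TestBottomUpOrdering:
    def test_two_node_population(self, chain2):
        # Sigma = [[1, .8], [.8, 1.64]]; precision diag (1.64, 1.0): Y2 terminal
        sigma = population_covariance(chain2)
        assert np.allclose(sigma, [[1, 0.8], [0.8, 1.64]])
        order = bottomup_order_from_covariance(
            sigma, OrderingSpec(granularity="vertex", glasso_lambda=1e-8)
        )
        assert order.sequence == ("Y1", "Y2")

    def test_three_node_chain_population(self, chain3):
        sigma = population_covariance(chain3)
        prec_diag = np.diag(np.linalg.inv(sigma))
        assert np.allclose(prec_diag, [1.64, 1.64, 1.0])
        order = bottomup_order_from_covariance(
            sigma, OrderingSpec(granularity="vertex", glasso_lambda=1e-8)
        )
        assert order.sequence == ("Y1", "Y2", "Y3")

    def test_iid_columns_layer_mode_single_layer(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        layers = bottomup_order(
            data, OrderingSpec(granularity="layer", eta=100.0)
        )
        assert isinstance(layers, LayerAssignment)
        assert layers.layers == (("a", "b", "c", "d"),)

    def test_vertex_ordering_covers_all_columns(self):
        for seed in range(10):
            params = random_sem(6, 0.4, seed)
            data = simulate_sem(params, 200, seed)
            order = bottomup_order(data, OrderingSpec(granularity="vertex"))
            assert sorted(order.sequence) == sorted(data.columns)

    def test_layer_partition_covers_all_columns(self):
        for seed in range(10):
            params = random_sem(6, 0.4, seed)
            data = simulate_sem(params, 200, seed)
            layers = bottomup_order(data, OrderingSpec(granularity="layer", eta=0.05))
            flat = [v for layer in layers for v in layer]
            assert sorted(flat) == sorted(data.columns)

    def test_layer_eta_zero_reduces_to_vertex_on_exact_input(self, chain3):
        sigma = population_covariance(chain3)
        vertex = bottomup_order_from_covariance(
            sigma, OrderingSpec(granularity="vertex", glasso_lambda=1e-8)
        )
        layers = bottomup_order_from_covariance(
            sigma, OrderingSpec(granularity="layer", glasso_lambda=1e-8), eta=0.0
        )
        assert tuple((v,) for v in vertex.sequence) == layers.layers

    def test_population_orderings_respect_true_edges(self):
        hits = 0
        for seed in range(30):
            params = random_sem(seed % 8 + 3, 0.3, seed)
            sigma = population_covariance(params)
            order = bottomup_order_from_covariance(
                sigma, OrderingSpec(granularity="vertex", glasso_lambda=1e-8)
            )
            hits += all(order.precedes(k, j) for k, j in params.dag.edges)
        assert hits == 30

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bottomup_order(pd.DataFrame({"a": [1.0, 2.0]}), OrderingSpec())


class TestAdaptiveEta:
    def test_duplicated_halves_give_zero(self):
        rng = np.random.default_rng(6)
        half = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        data = pd.concat([half, half], ignore_index=True)
        assert adaptive_eta(data, 0.01, shuffle=False) == pytest.approx(0.0, abs=1e-10)

    def test_positive_on_noisy_data_and_shrinks_with_n(self):
        vals = {}
        for n in (200, 2000):
            etas = []
            for seed in range(10):
                rng = np.random.default_rng(1000 * n + seed)
                data = pd.DataFrame(rng.normal(size=(n, 6)))
                data.columns = [f"v{i}" for i in range(6)]
                etas.append(adaptive_eta(data, 0.01, seed=seed))
            vals[n] = np.mean(etas)
        assert vals[200] > 0 and vals[2000] > 0
        assert vals[2000] < vals[200]

    def test_small_sample_rejected(self):
        data = pd.DataFrame(np.random.default_rng(7).normal(size=(100, 3)))
        data.columns = list("abc")
        with pytest.raises(ValueError, match="n > 100"):
            adaptive_eta(data, 0.01)


class TestKnowledgeOrder:
    def test_diamond_layers(self, diamond):
        layers = knowledge_order(diamond, "layer")
        assert layers.layers == (("a",), ("b", "c"), ("d",))

    def test_chain_vertices(self, chain_graph):
        assert knowledge_order(chain_graph, "vertex").sequence == ("a", "b", "c")

    @pytest.mark.parametrize("seed", range(20))
    def test_flattened_layers_are_a_valid_vertex_order(self, seed):
        g = random_dag(9, 0.3, seed)
        flat = knowledge_order(g, "layer").flatten()
        assert all(flat.precedes(k, j) for k, j in g.edges)

    def test_matches_graph_core(self, diamond):
        assert knowledge_order(diamond, "vertex") == topological_sort(diamond)
        assert knowledge_order(diamond, "layer") == layer_decomposition(diamond)
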
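import json

import numpy as np
import pandas as pd
import pytest

from cypscreen import (
    ExpressionMatrix,
    TraitTable,
    ValidationError,
    build_network,
    heatmap_export,
    tendency_test,
)
from cypscreen.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def module_panel():
    config = SimulationConfig(
        seed=17, n_transcripts=120, n_genes=120, n_background_variants=0,
        generate_sequences=False, planted_module=list(range(3)),
        module_loading=0.95,
    )
    return simulate_dataset(config)


def test_planted_module_forms_complete_subgraph(module_panel):
    net = build_network(
        module_panel.expression, module_panel.traits,
        module_panel.ledger["planted_module"], alpha=0.05,
    )
    mod = module_panel.ledger["planted_module"]
    for i, a in enumerate(mod):
        for b in mod[i + 1:]:
            assert net.graph.has_edge(a, b)


def test_total_trait_connects_to_its_summands(module_panel):
    net = build_network(module_panel.expression, module_panel.traits, [], alpha=0.05)
    assert net.transcript_nodes == []
    ts_neighbors = set(net.graph.neighbors("TS"))
    assert ts_neighbors & set(module_panel.traits.mono_traits)


def test_edge_set_shrinks_as_alpha_tightens(module_panel):
    ids = module_panel.expression.transcript_ids[:30]
    nets = {
        a: build_network(module_panel.expression, module_panel.traits, ids, a)
        for a in (0.05, 0.01, 0.001)
    }
    edges = {a: set(map(frozenset, nets[a].graph.edges)) for a in nets}
    assert edges[0.001] <= edges[0.01] <= edges[0.05]


def test_independent_noise_rarely_connects_at_tiny_alpha(module_panel):
    ids = module_panel.expression.transcript_ids[10:40]
    net = build_network(module_panel.expression, module_panel.traits, ids, alpha=1e-6)
    gene_edges = net.edge_class_counts()["gene_gene"]
    assert gene_edges == 0


def test_clusters_partition_connected_nodes(module_panel):
    ids = module_panel.expression.transcript_ids[:20]
    net = build_network(module_panel.expression, module_panel.traits, ids, 0.05)
    clusters = net.clusters
    union = set().union(*clusters) if clusters else set()
    assert union == set(net.connected_nodes)
    assert sum(len(c) for c in clusters) == len(union)  # disjoint


def test_zero_variance_node_kept_without_edges(module_panel, caplog):
    expr = module_panel.expression
    data = expr.data.copy()
    data.loc["FLAT"] = 7.0
    em = ExpressionMatrix(data)
    with caplog.at_level("WARNING"):
        net = build_network(em, module_panel.traits, ["FLAT"], 0.05)
    assert "FLAT" in net.nodes
    assert net.graph.degree("FLAT") == 0


def test_every_edge_satisfies_threshold(module_panel):
    ids = module_panel.expression.transcript_ids[:25]
    net = build_network(module_panel.expression, module_panel.traits, ids, 0.05)
    el = net.edge_list()
    assert (el["p"] <= 0.05).all()
    assert (el["node_a"] != el["node_b"]).all()


class TestTendency:
    def test_planted_module_is_significant(self, module_panel):
        mod = module_panel.ledger["planted_module"]
        pool = [t for t in module_panel.expression.transcript_ids if t not in mod]
        res = tendency_test(module_panel.expression, module_panel.traits,
                            mod, pool, R=20, seed=3)
        assert res.observed_edges > res.control_edge_mean
        assert res.p_edges <= 0.01

    def test_reproducible_under_fixed_seed(self, module_panel):
        mod = module_panel.ledger["planted_module"]
        pool = [t for t in module_panel.expression.transcript_ids if t not in mod]
        a = tendency_test(module_panel.expression, module_panel.traits,
                          mod, pool, R=5, seed=9)
        b = tendency_test(module_panel.expression, module_panel.traits,
                          mod, pool, R=5, seed=9)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_minimal_replication_boundary(self, module_panel):
        mod = module_panel.ledger["planted_module"]
        pool = [t for t in module_panel.expression.transcript_ids if t not in mod]
        res = tendency_test(module_panel.expression, module_panel.traits,
                            mod, pool, R=2, seed=1)
        assert res.R == 2
        assert np.isfinite(res.control_edge_sd)
        assert 0 < res.p_edges <= 1

    def test_precondition_errors(self, module_panel):
        ids = module_panel.expression.transcript_ids
        with pytest.raises(ValidationError, match="disjoint"):
            tendency_test(module_panel.expression, module_panel.traits,
                          ids[:5], ids[:10], seed=0)
        with pytest.raises(ValidationError, match="pool"):
            tendency_test(module_panel.expression, module_panel.traits,
                          ids[:10], ids[10:15], seed=0)
        with pytest.raises(ValidationError, match="R = 2"):
            tendency_test(module_panel.expression, module_panel.traits,
                          ids[:5], ids[5:20], R=1, seed=0)


class TestHeatmapExport:
    def test_identical_rows_end_up_adjacent(self, module_panel):
        expr = module_panel.expression
        data = expr.data.iloc[:6].copy()
        data.loc["DUP"] = data.iloc[0].to_numpy()
        em = ExpressionMatrix(data)
        genes = list(data.index)
        _, order = heatmap_export(em, genes)
        a, b = order.index(genes[0]), order.index("DUP")
        assert abs(a - b) == 1

    def test_single_gene_identity_order(self, module_panel):
        expr = module_panel.expression
        tid = expr.transcript_ids[0]
        zdf, order = heatmap_export(expr, [tid])
        assert order == [tid]
        assert zdf.shape == (1, len(expr.samples))

    def test_correlated_pair_merges_before_anticorrelated(self):
        samples = [f"s{i}" for i in range(10)]
        base = np.sin(np.arange(10.0))
        df = pd.DataFrame(
            {
                "up1": 5 + base,
                "up2": 5 + base + 0.01 * np.arange(10),
                "down": 5 - base,
            },
            index=samples,
        ).T
        em = ExpressionMatrix(df)
        _, order = heatmap_export(em, ["up1", "down", "up2"])
        assert abs(order.index("up1") - order.index("up2")) == 1

    def test_constant_row_emits_zeros_with_warning(self, caplog):
        df = pd.DataFrame(
            [[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]],
            index=["flat", "var"], columns=["a", "b", "c"],
        )
        with caplog.at_level("WARNING"):
            zdf, _ = heatmap_export(ExpressionMatrix(df), ["flat", "var"])
        assert (zdf.loc["flat"] == 0).all()

    def test_rows_are_z_scored(self, module_panel):
        expr = module_panel.expression
        zdf, _ = heatmap_export(expr, expr.transcript_ids[:5])
        np.testing.assert_allclose(zdf.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(zdf.std(axis=1, ddof=1), 1.0, rtol=1e-9)
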
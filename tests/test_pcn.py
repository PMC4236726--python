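"""Pathway aggregation and permutation significance."""

import numpy as np
import pytest

from pcnet.containers import PathwayAnnotation, edge_key
from pcnet.pcn import (
    NullEnsemble,
    PipelineParams,
    aggregate_pathway_edges,
    edge_significance,
    empirical_p,
    feature_significance,
    load_null,
    permutation_null,
    save_null,
)
from pcnet.synthetic import SyntheticConfig, generate_dataset
from conftest import gene_network, oracle_aggregate, pathway_network


def annotation(**pathway_genes):
    return PathwayAnnotation({k: set(v) for k, v in pathway_genes.items()})


class TestAggregate:
    def test_single_edge_single_pair(self):
        net = gene_network([("g1", "g2", 0.6)])
        pn = aggregate_pathway_edges(net, annotation(P=["g1"], Q=["g2"]))
        assert pn.weight("P", "Q") == pytest.approx(0.6)
        assert pn.graph.edges["P", "Q"]["n_gene_edges"] == 1

    def test_mean_of_two_contributions(self):
        net = gene_network([("g1", "g2", 0.6), ("g3", "g4", 0.8)])
        pn = aggregate_pathway_edges(net, annotation(P=["g1", "g3"], Q=["g2", "g4"]))
        assert pn.weight("P", "Q") == pytest.approx(0.7)
        assert pn.graph.edges["P", "Q"]["n_gene_edges"] == 2

    def test_cross_membership_excludes_self_pair(self):
        net = gene_network([("g1", "g2", 0.5)])
        pn = aggregate_pathway_edges(
            net, annotation(A=["g1", "g2"], B=["g1"], C=["g2"])
        )
        assert set(pn.graph.edges) == {("A", "C"), ("A", "B"), ("B", "C")}
        for e in pn.graph.edges:
            assert pn.graph.edges[e]["weight"] == pytest.approx(0.5)
            assert pn.graph.edges[e]["n_gene_edges"] == 1

    def test_unannotated_gene_contributes_nothing(self):
        net = gene_network([("g1", "gx", 0.9), ("g1", "g2", 0.4)])
        pn = aggregate_pathway_edges(net, annotation(P=["g1"], Q=["g2"]))
        assert pn.weight("P", "Q") == pytest.approx(0.4)

    def test_no_annotated_gene_is_error(self):
        net = gene_network([("gx", "gy", 0.9)])
        with pytest.raises(ValueError):
            aggregate_pathway_edges(net, annotation(P=["other"]))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            genes = [f"g{i}" for i in range(int(rng.integers(4, 15)))]
            pathways = {
                f"P{k}": set(rng.choice(genes, size=int(rng.integers(1, 5)), replace=False))
                for k in range(int(rng.integers(2, 6)))
            }
            edges = [
                (genes[i], genes[j], float(rng.uniform(-1, 1)))
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
                if rng.random() < 0.3
            ]
            if not edges:
                continue
            net = gene_network(edges)
            ann = PathwayAnnotation(pathways)
            try:
                pn = aggregate_pathway_edges(net, ann)
            except ValueError:
                continue  # no annotated gene drawn
            weights, counts = oracle_aggregate(net, ann)
            got = pn.edge_weights()
            assert set(got) == set(weights)
            for pair in weights:
                assert got[pair] == pytest.approx(weights[pair])
                assert pn.graph.edges[pair]["n_gene_edges"] == counts[pair]


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SyntheticConfig(
        n_pathways=4,
        genes_per_pathway=5,
        n_samples_focal=12,
        n_samples_background=12,
        rho_within=0.6,
        seed=7,
    )
    return generate_dataset(cfg)


class TestPermutationNull:
    def test_deterministic_label_assignments(self, small_dataset):
        matrix, grouping, ann, _ = small_dataset
        kwargs = dict(m=12, annotation=ann, R=2, seed=5, record_features=False)
        a = permutation_null(matrix, grouping, **kwargs)
        b = permutation_null(matrix, grouping, **kwargs)
        assert a.label_assignments == b.label_assignments
        assert all(len(labels) == 12 for labels in a.label_assignments)
        assert a.null_weights == b.null_weights

    def test_m_larger_than_pool_rejected(self, small_dataset):
        matrix, grouping, ann, _ = small_dataset
        with pytest.raises(ValueError):
            permutation_null(matrix, grouping, m=matrix.n_samples + 1, annotation=ann, R=1)

    def test_absent_pair_scored_as_zero(self):
        null = NullEnsemble(
            R=2,
            m=3,
            seed=0,
            label_assignments=[["a", "b", "c"], ["a", "b", "d"]],
            null_weights=[{("P", "Q"): 0.4}, {}],
        )
        np.testing.assert_array_equal(null.weights_for(("P", "Q")), [0.4, 0.0])

    def test_roundtrip_through_disk(self, small_dataset, tmp_path):
        matrix, grouping, ann, _ = small_dataset
        null = permutation_null(matrix, grouping, m=12, annotation=ann, R=3, seed=9)
        save_null(null, tmp_path / "w.tsv", tmp_path / "m.json")
        back = load_null(tmp_path / "w.tsv", tmp_path / "m.json")
        assert back.R == null.R and back.m == null.m and back.seed == null.seed
        assert back.label_assignments == null.label_assignments
        for w_new, w_old in zip(back.null_weights, null.null_weights):
            assert set(w_new) == {k for k, v in w_old.items() if round(v, 6) != 0}
            for k in w_new:
                assert w_new[k] == pytest.approx(w_old[k], abs=1e-6)


def ensemble_with(weights, **kwargs):
    defaults = dict(R=len(weights), m=3, seed=0, label_assignments=[[]] * len(weights))
    defaults.update(kwargs)
    return NullEnsemble(null_weights=weights, **defaults)


class TestEdgeSignificance:
    def test_observed_above_all_nulls(self):
        null = ensemble_with([{("P", "Q"): 0.1}] * 150)
        obs = pathway_network([("P", "Q", 0.9)])
        out = edge_significance(obs, null, alpha_pcn=0.05)
        assert out.graph.edges["P", "Q"]["p_perm"] == pytest.approx(1 / 151)

    def test_zero_weight_dropped(self):
        null = ensemble_with([{("P", "Q"): w} for w in (-0.5, 0.5, -0.1, 0.1)])
        obs = pathway_network([("P", "Q", 0.0)])
        out = edge_significance(obs, null, alpha_pcn=0.05)
        assert out.n_edges == 0 and set(out.graph.nodes) == {"P", "Q"}

    def test_boundary_p_is_dropped(self):
        # all 19 nulls below the observed weight → p = 1/20 = 0.05 exactly
        null = ensemble_with([{("P", "Q"): 0.01}] * 19)
        obs = pathway_network([("P", "Q", 0.05)])
        out = edge_significance(obs, null, alpha_pcn=0.05)
        assert out.n_edges == 0

    def test_p_never_below_add_one_floor(self, small_dataset):
        matrix, grouping, ann, _ = small_dataset
        null = permutation_null(
            matrix, grouping, m=12, annotation=ann, R=10, seed=3, record_features=False
        )
        from pcnet.gcn import gcn_from_expression

        net = gcn_from_expression(matrix, grouping.samples("tumor"), alpha=0.5, r_threshold=None)
        agg = aggregate_pathway_edges(net, ann)
        out = edge_significance(agg, null, alpha_pcn=1.1)
        for _, _, d in out.graph.edges(data=True):
            assert d["p_perm"] >= 1 / 11


class TestFeatureSignificance:
    def test_observed_above_all(self):
        p_up, p_lo, p_two = feature_significance(np.zeros(150), 1.0)
        assert p_up == pytest.approx(1 / 151)
        assert p_two == pytest.approx(2 / 151)

    def test_all_equal(self):
        p_up, p_lo, p_two = feature_significance(np.ones(10), 1.0)
        assert p_up == p_lo == 1.0 and p_two == 1.0

    def test_median_observation_not_significant(self, rng):
        nulls = rng.normal(size=151)
        p_up, p_lo, p_two = feature_significance(nulls, float(np.median(nulls)))
        assert p_two > 0.9

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            feature_significance([], 0.0)


class TestEmpiricalP:
    def test_add_one_formula(self):
        assert empirical_p(np.array([0.1, 0.2, 0.9]), 0.5) == pytest.approx(2 / 4)

    def test_two_sided_uses_magnitude(self):
        assert empirical_p(np.array([-0.9, 0.1]), 0.5) == pytest.approx(2 / 3)
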
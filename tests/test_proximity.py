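import itertools
import math

import networkx as nx
import numpy as np
import pytest

from reposcreen.errors import (
    InvalidParameterError,
    NullDistributionError,
    ScoringError,
)
from reposcreen.proximity import (
    DrugTargetMap,
    NetworkProximity,
    closest_weighted_distance,
    distance_density_summary,
    proximity_z,
    read_drug_targets,
    sample_null,
    screen_by_distance,
    target_weight,
    write_drug_targets,
)

from conftest import build_network
from oracles import brute_force_weighted_distance


class TestTargetWeight:
    def test_non_member_weight_zero(self, path5):
        assert target_weight("b", {"a"}, path5) == 0.0

    def test_member_degree_zero(self):
        net = build_network([("a", "b")], nodes=["x"])
        assert target_weight("x", {"x"}, net) == 0.0  # -ln(0+1)

    def test_member_degree_one(self, path5):
        assert target_weight("a", {"a"}, path5) == pytest.approx(-math.log(2))

    def test_weight_never_positive(self, path5):
        for node in path5.nodes:
            assert target_weight(node, path5.nodes, path5) <= 0.0


class TestClosestWeightedDistance:
    def test_all_targets_in_disease_set_degree_one(self):
        net = build_network([("a", "b")])
        d, n_mapped, n_dropped = closest_weighted_distance({"a", "b"}, {"a"}, net)
        assert d == pytest.approx(-math.log(2))
        assert (n_mapped, n_dropped) == (1, 0)

    def test_path_distance_four(self, path5):
        d, _, _ = closest_weighted_distance({"a"}, {"e"}, path5)
        assert d == pytest.approx(4.0)

    def test_hand_evaluated_mixed_case(self):
        # path a-b-c, G={a,c}, T={b,c}: t=b -> min(1,1)+0 = 1;
        # t=c -> 0 - ln(deg(c)+1) = -ln 2; average = (1 - ln 2)/2
        net = build_network([("a", "b"), ("b", "c")])
        d, _, _ = closest_weighted_distance({"a", "c"}, {"b", "c"}, net)
        assert d == pytest.approx((1 - math.log(2)) / 2)

    def test_unmapped_targets_are_dropped(self, path5):
        d, n_mapped, n_dropped = closest_weighted_distance(
            {"a"}, {"b", "zzz"}, path5
        )
        assert d == pytest.approx(1.0)
        assert (n_mapped, n_dropped) == (1, 1)

    def test_all_targets_unmapped_is_scoring_error(self, path5):
        with pytest.raises(ScoringError):
            closest_weighted_distance({"a"}, {"zzz"}, path5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            nodes = sorted(g.nodes)
            G = set(rng.choice(nodes, size=int(rng.integers(1, 4)), replace=False))
            T = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
            net = build_network(list(g.edges), nodes=nodes)
            try:
                expected = brute_force_weighted_distance(g, G, T)
            except ValueError:
                with pytest.raises(ScoringError):
                    closest_weighted_distance(G, T, net)
                continue
            got = closest_weighted_distance(G, T, net)
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1:] == expected[1:]

    def test_adding_shortcut_edge_never_increases_distance(self):
        g = nx.path_graph(8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = build_network(list(g.edges))
        G, T = {"n0"}, {"n5", "n7"}
        before, _, _ = closest_weighted_distance(G, T, net)
        g.add_edge("n0", "n5")
        after, _, _ = closest_weighted_distance(G, T, build_network(list(g.edges)))
        assert after <= before


class TestSampleNull:
    def test_degenerate_complete_graph_errors(self):
        net = build_network(
            [(a, b) for a, b in itertools.combinations("abcde", 2)]
        )
        with pytest.raises(NullDistributionError):
            sample_null(net.nodes, net, k=2, n_iter=100, seed=0)

    def test_exact_enumeration_oracle_12_nodes(self):
        g = nx.random_regular_graph(3, 12, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = build_network(list(g.edges))
        G = {"n0", "n1", "n2"}
        exact = [
            brute_force_weighted_distance(g, G, set(pair))[0]
            for pair in itertools.combinations(sorted(net.nodes), 2)
        ]
        mu_exact = float(np.mean(exact))
        null = sample_null(G, net, k=2, n_iter=10_000, seed=3)
        se = np.std(exact, ddof=1) / math.sqrt(null.n_iter)
        assert abs(null.mu - mu_exact) < 3 * se

    def test_same_seed_reproduces_samples(self, default_study):
        net = default_study.network
        G = default_study.disease.genes
        a = sample_null(G, net, k=3, n_iter=200, seed=9)
        b = sample_null(G, net, k=3, n_iter=200, seed=9)
        np.testing.assert_array_equal(a.sample_distances, b.sample_distances)

    def test_invalid_parameters(self, path5):
        with pytest.raises(InvalidParameterError):
            sample_null({"a"}, path5, k=0, n_iter=100, seed=0)
        with pytest.raises(InvalidParameterError):
            sample_null({"a"}, path5, k=1, n_iter=10, seed=0)
        with pytest.raises(InvalidParameterError):
            sample_null({"a"}, path5, k=5, n_iter=100, seed=0)

    def test_degree_binned_mode_runs(self, default_study):
        net = default_study.network
        G = default_study.disease.genes
        nodes = sorted(net.nodes)[:3]
        null = sample_null(
            G, net, k=3, n_iter=100, seed=1, mode="degree_binned",
            _match_nodes=nodes,
        )
        assert null.sigma > 0


class TestProximityZ:
    @pytest.mark.parametrize("offset, expected", [(0.0, 0.0), (1.0, 1.0), (-2.5, -2.5)])
    def test_analytic_values(self, offset, expected, default_study):
        null = sample_null(
            default_study.disease.genes, default_study.network,
            k=2, n_iter=100, seed=0,
        )
        z = proximity_z(null.mu + offset * null.sigma, null)
        assert z == pytest.approx(expected)


class TestScreen:
    def test_strict_threshold(self):
        distances = {"d1": 0.5, "d2": 1.0, "d3": 1.5}
        assert screen_by_distance(distances, 1.0) == ["d1"]

    def test_infinite_threshold_keeps_all_sorted(self):
        distances = {"d1": 0.5, "d2": 1.0, "d3": 0.1}
        assert screen_by_distance(distances, math.inf) == ["d3", "d1", "d2"]

    def test_empty_input(self):
        assert screen_by_distance({}, 1.0) == []


class TestDensitySummary:
    def test_identical_inputs_identical_densities(self):
        x = list(np.random.default_rng(0).normal(size=100))
        table = distance_density_summary(x, x)
        np.testing.assert_allclose(
            table["drug_density"], table["reference_density"]
        )

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(1)
        table = distance_density_summary(
            rng.normal(size=200), rng.normal(2, 1, size=200), n_grid=512
        )
        for col in ("drug_density", "reference_density"):
            area = np.trapezoid(table[col], table["grid"])
            assert area == pytest.approx(1.0, abs=0.01)

    def test_shifted_samples_have_shifted_modes(self):
        rng = np.random.default_rng(2)
        table = distance_density_summary(
            rng.normal(0, 1, size=2000), rng.normal(3, 1, size=2000)
        )
        mode_drug = table["grid"][table["drug_density"].idxmax()]
        mode_ref = table["grid"][table["reference_density"].idxmax()]
        assert mode_ref - mode_drug == pytest.approx(3.0, abs=0.5)


class TestModel:
    def test_fit_is_order_independent_per_drug(self, default_study):
        dtm_fwd = default_study.drug_targets
        dtm_rev = DrugTargetMap()
        for entry in reversed(list(dtm_fwd)):
            dtm_rev.add(entry.drug_id, entry.drug_name, entry.targets)
        net, G = default_study.network, default_study.disease.genes
        a = NetworkProximity(net, G, dtm_fwd).fit(n_iter=200, seed=4).frame
        b = NetworkProximity(net, G, dtm_rev).fit(n_iter=200, seed=4).frame
        assert a.equals(b)

    def test_unmappable_drug_is_excluded_with_record(self, path5):
        dtm = DrugTargetMap()
        dtm.add("d1", "ok", ["e"])
        dtm.add("d2", "ghost", ["zzz"])
        res = NetworkProximity(path5, {"a"}, dtm).fit(n_iter=100, seed=0)
        assert [r.drug_id for r in res.results] == ["d1"]
        assert res.skipped_drugs == ["d2"]

    def test_summary_mentions_screen_counts(self, default_study):
        model = NetworkProximity(
            default_study.network,
            default_study.disease.genes,
            default_study.drug_targets,
        )
        text = model.fit(n_iter=100, seed=0).summary()
        assert "Drugs scored" in text and "threshold" in text.lower()


class TestDrugTargetIO:
    def test_round_trip(self, tmp_path):
        dtm = DrugTargetMap()
        dtm.add("D1", "drug one", ["A", "B"])
        dtm.add("D2", "drug two", ["C"])
        path = tmp_path / "dt.tsv"
        write_drug_targets(dtm, path)
        back = read_drug_targets(path)
        assert back["D1"].targets == {"A", "B"}
        assert back["D2"].drug_name == "drug two"
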
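"""Persistence, season association, co-occurrence networks, phylum groups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverbiome import (
    CooccurrenceNetwork,
    OtuTable,
    classify_persistence,
    cooccurrence_network,
    network_density,
    phylum_season_groups,
    season_association,
)
import networkx as nx


def table_with_meta(counts, seasons, taxonomy=None):
    counts = np.asarray(counts)
    ids = [f"s{j}" for j in range(counts.shape[1])]
    table = OtuTable([f"o{i}" for i in range(counts.shape[0])], ids, counts, taxonomy)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "station_id": [f"st{j}" for j in range(len(ids))],
            "habitat": "water",
            "season": seasons,
            "landform": "plain",
            "river_position_km": np.arange(len(ids), dtype=float),
        }
    )
    return table, meta


class TestPersistence:
    def test_strict_threshold_boundary(self):
        n = 100
        counts = np.zeros((2, n), dtype=int)
        counts[0, :30] = 1  # occupancy exactly 0.30 -> transient
        counts[1, :31] = 1  # 0.31 -> persistent
        t = OtuTable(["at", "above"], [f"s{j}" for j in range(n)], counts)
        labels = classify_persistence(t, threshold=0.30)
        assert labels["at"] == "transient"
        assert labels["above"] == "persistent"

    def test_ubiquitous_otu_is_persistent(self, tiny_table):
        labels = classify_persistence(tiny_table)
        assert labels["OTU3"] == "persistent"

    def test_zero_threshold_counts_any_occurrence(self, tiny_table):
        labels = classify_persistence(tiny_table, threshold=0.0)
        assert (labels == "persistent").all()


class TestSeasonAssociation:
    def test_perfect_separation_is_detected(self):
        """Completely separated seasons: closed-form exact rank-test oracle.

        With every autumn abundance above every spring abundance and no
        ties, the two-sided exact Mann-Whitney p is 2 / C(20, 10).
        """
        n = 10
        target = np.concatenate([np.arange(1, n + 1), np.arange(50, 50 + n)])
        counts = np.vstack([target, 1000 - target])  # constant depth 1000
        seasons = ["spring"] * n + ["autumn"] * n
        table, meta = table_with_meta(counts, seasons)
        labels = season_association(table, meta).set_index("otu_id")
        row = labels.loc["o0"]
        assert row["association"] == "autumn"
        assert row["p_value_adjusted"] < 0.05
        from math import comb

        assert row["p_value"] == pytest.approx(2 / comb(2 * n, n))
        assert labels.loc["o1", "association"] == "spring"

    def test_identical_seasons_are_unassociated(self):
        counts = np.tile(np.array([[30], [50]]), (1, 12))
        seasons = ["spring"] * 6 + ["autumn"] * 6
        table, meta = table_with_meta(counts, seasons)
        labels = season_association(table, meta).set_index("otu_id")
        assert (labels["association"] == "none").all()

    def test_transient_otus_are_not_tested(self, rng):
        counts = rng.integers(20, 60, (3, 12))
        counts[0] = 0
        counts[0, 0] = 5  # occupancy 1/12 -> transient
        seasons = ["spring"] * 6 + ["autumn"] * 6
        table, meta = table_with_meta(counts, seasons)
        labels = season_association(table, meta).set_index("otu_id")
        assert labels.loc["o0", "persistence"] == "transient"
        assert np.isnan(labels.loc["o0", "p_value"])

    def test_one_season_missing_errors(self, rng):
        counts = rng.integers(1, 9, (2, 6))
        table, meta = table_with_meta(counts, ["spring"] * 6)
        with pytest.raises(ValueError, match="season"):
            season_association(table, meta)

    def test_invariant_to_sample_order_and_depth(self, rng):
        counts = rng.integers(0, 80, (8, 16))
        counts[0, 8:] *= 5
        seasons = ["spring"] * 8 + ["autumn"] * 8
        table, meta = table_with_meta(counts, seasons)
        base = season_association(table, meta)
        order = rng.permutation(16)
        shuffled = table.select_samples([table.sample_ids[j] for j in order])
        scaled = OtuTable(
            shuffled.otu_ids,
            shuffled.sample_ids,
            shuffled.counts * rng.integers(1, 7, 16)[None, :],
        )
        again = season_association(scaled, meta)
        pd.testing.assert_frame_equal(base, again)


class TestCooccurrence:
    def test_identical_profiles_link_positively(self, rng):
        base = rng.integers(1, 50, 8)
        counts = np.vstack([base, base, rng.permutation(base)])
        t = OtuTable(["a", "b", "c"], [f"s{j}" for j in range(8)], counts)
        net = cooccurrence_network(t, adjust=False, p_threshold=0.05)
        assert net.graph.has_edge("a", "b")
        assert net.graph.edges["a", "b"]["rho"] == pytest.approx(1.0)
        assert net.graph.edges["a", "b"]["sign"] == "positive"

    def test_reversed_ranks_link_negatively(self):
        up = np.arange(1, 9)
        counts = np.vstack([up, up[::-1], np.full(8, 5)])
        t = OtuTable(["up", "down", "flat"], [f"s{j}" for j in range(8)], counts)
        net = cooccurrence_network(t, adjust=False, p_threshold=0.05)
        assert net.graph.edges["up", "down"]["sign"] == "negative"
        assert net.graph.edges["up", "down"]["rho"] == pytest.approx(-1.0)

    def test_constant_otu_excluded_not_fatal(self, rng):
        counts = rng.integers(1, 50, (3, 10))
        counts[2] = 7  # constant counts but relative abundance still varies
        counts = np.vstack([counts, np.zeros(10, dtype=int)])  # truly constant rel
        t = OtuTable(["a", "b", "c", "zero"], [f"s{j}" for j in range(10)], counts)
        net = cooccurrence_network(t)
        assert "zero" not in net.graph

    def test_independent_otus_rarely_linked(self, rng):
        """Null co-occurrence: ~<=1% of independent pairs pass both thresholds."""
        n_otus, n_samples = 15, 30  # 105 pairs
        counts = rng.integers(1, 200, (n_otus, n_samples))
        t = OtuTable([f"o{i}" for i in range(n_otus)], [f"s{j}" for j in range(n_samples)], counts)
        net = cooccurrence_network(t)
        assert net.n_edges <= 2

    def test_too_few_samples_rejected(self, rng):
        t = OtuTable(["a", "b"], [f"s{j}" for j in range(4)], rng.integers(1, 9, (2, 4)))
        with pytest.raises(ValueError, match="5 samples"):
            cooccurrence_network(t)


class TestNetworkDensity:
    def make_net(self, n_nodes, edges):
        g = nx.Graph()
        g.add_nodes_from((f"o{i}", {"phylum": "P"}) for i in range(n_nodes))
        for a, b in edges:
            g.add_edge(f"o{a}", f"o{b}", rho=0.9, p_adjusted=0.001, sign="positive")
        return CooccurrenceNetwork(g)

    def test_edges_over_nodes(self):
        net = self.make_net(12, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        assert network_density(net) == pytest.approx(5 / 12)

    def test_no_edges_gives_zero(self):
        assert network_density(self.make_net(4, [])) == 0.0

    def test_complete_graph_exceeds_one(self):
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        assert network_density(self.make_net(4, edges)) == pytest.approx(1.5)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="no nodes"):
            network_density(self.make_net(0, []))

    def test_phylum_subnetwork_restriction(self):
        g = nx.Graph()
        g.add_nodes_from([("a", {"phylum": "X"}), ("b", {"phylum": "X"}), ("c", {"phylum": "Y"})])
        g.add_edge("a", "b", rho=0.9, p_adjusted=0.001, sign="positive")
        g.add_edge("a", "c", rho=0.9, p_adjusted=0.001, sign="positive")
        net = CooccurrenceNetwork(g)
        assert network_density(net, phylum="X") == pytest.approx(0.5)
        assert network_density(net, phylum="Y") == pytest.approx(0.0)


class TestPhylumGroups:
    def labels_from(self, assoc):
        return pd.DataFrame(
            {"otu_id": [f"o{i}" for i in range(len(assoc))], "association": assoc}
        )

    def test_pure_autumn_phylum(self):
        labels = self.labels_from(["autumn"] * 10)
        phy = {f"o{i}": "Chloroflexi" for i in range(10)}
        out = phylum_season_groups(labels, phy).set_index("phylum")
        assert out.loc["Chloroflexi", "group"] == "autumn-dominated"

    def test_even_split_is_mixed(self):
        labels = self.labels_from(["autumn"] * 5 + ["spring"] * 5)
        phy = {f"o{i}": "Proteobacteria" for i in range(10)}
        out = phylum_season_groups(labels, phy).set_index("phylum")
        assert out.loc["Proteobacteria", "group"] == "mixed"

    def test_dominance_boundary_is_inclusive(self):
        labels = self.labels_from(["autumn"] * 3 + ["spring"])
        phy = {f"o{i}": "Bacteroidetes" for i in range(4)}
        out = phylum_season_groups(labels, phy, dominance=0.75).set_index("phylum")
        assert out.loc["Bacteroidetes", "group"] == "autumn-dominated"

    def test_no_associated_otus_is_unclassified(self):
        labels = self.labels_from(["none", "none"])
        phy = {"o0": "Spirochaetes", "o1": "Spirochaetes"}
        out = phylum_season_groups(labels, phy).set_index("phylum")
        assert out.loc["Spirochaetes", "group"] == "unclassified"
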
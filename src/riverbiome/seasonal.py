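"""Season-associated taxa, co-occurrence networks, and phylum seasonality.

Persistent OTUs (occupancy strictly above 30% of samples) are tested for
a spring-vs-autumn abundance shift with a two-sample rank test
(Mann-Whitney U by default) on per-sample relative abundances,
Benjamini-Hochberg adjusted across the tested OTUs; a significant OTU
is labelled with the season of greater median abundance. Co-occurrence
networks connect OTU pairs whose Spearman correlation passes both a
significance and an effect-size threshold; the network density
statistic d = edges / nodes (which may exceed 1) quantifies how
uniformly a phylum's OTUs covary. Phyla are then grouped as
autumn-dominated, spring-dominated or mixed by the share of their
season-associated OTUs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable, occupancy, relative_abundance

__all__ = [
    "classify_persistence",
    "season_association",
    "CooccurrenceNetwork",
    "cooccurrence_network",
    "network_density",
    "phylum_season_groups",
]


def classify_persistence(table: OtuTable, threshold: float = 0.30) -> pd.Series:
    """Label each OTU persistent (occupancy strictly > threshold) or transient."""
    occ = occupancy(table)
    labels = np.where(occ > threshold, "persistent", "transient")
    return pd.Series(labels, index=table.otu_ids, name="persistence")


def season_association(
    table: OtuTable,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "mannwhitney",
    correction: bool = True,
    persistence_threshold: float = 0.30,
) -> pd.DataFrame:
    """Detect season-associated OTUs among the persistent fraction.

    For every persistent OTU, the per-sample relative abundances of the
    two seasons are compared with a two-sided Mann-Whitney U test (or
    Welch's t on log10-transformed abundances with a 1e-6 pseudocount,
    ``test="welch_log"``); p-values are BH-adjusted across the tested
    OTUs when `correction` is set. An OTU is autumn- (spring-)
    associated if the adjusted p is below `alpha` and its median
    relative abundance is greater in autumn (spring); equal medians
    leave it unassociated.

    Returns one row per OTU (transient OTUs included with NaN p-values)
    with columns otu_id, persistence, association, p_value,
    p_value_adjusted, median_spring, median_autumn.
    """
    meta = metadata.set_index("sample_id").loc[table.sample_ids]
    seasons = meta["season"].to_numpy()
    spring_cols = np.flatnonzero(seasons == "spring")
    autumn_cols = np.flatnonzero(seasons == "autumn")
    if len(spring_cols) < 3 or len(autumn_cols) < 3:
        raise ValueError(
            f"need >=3 samples per season, got spring={len(spring_cols)}, "
            f"autumn={len(autumn_cols)}"
        )
    persistence = classify_persistence(table, persistence_threshold)
    rel = relative_abundance(table, per="sample")

    tested_idx = [i for i, o in enumerate(table.otu_ids) if persistence.iloc[i] == "persistent"]
    pvals = np.full(table.n_otus, np.nan)
    for i in tested_idx:
        x, y = rel[i, spring_cols], rel[i, autumn_cols]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            pvals[i] = 1.0
        elif test == "mannwhitney":
            both = np.concatenate([x, y])
            tie_free = np.unique(both).size == both.size
            method = "exact" if tie_free and max(x.size, y.size) <= 25 else "asymptotic"
            pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        elif test == "welch_log":
            pvals[i] = stats.ttest_ind(
                np.log10(x + 1e-6), np.log10(y + 1e-6), equal_var=False
            ).pvalue
        else:
            raise ValueError(f"test must be 'mannwhitney' or 'welch_log', got {test!r}")

    adj = np.full(table.n_otus, np.nan)
    if tested_idx:
        raw = pvals[tested_idx]
        adj[tested_idx] = (
            stats.false_discovery_control(raw, method="bh") if correction else raw
        )

    med_spring = np.median(rel[:, spring_cols], axis=1)
    med_autumn = np.median(rel[:, autumn_cols], axis=1)
    association = []
    for i in range(table.n_otus):
        if not np.isnan(adj[i]) and adj[i] < alpha and med_autumn[i] != med_spring[i]:
            association.append("autumn" if med_autumn[i] > med_spring[i] else "spring")
        else:
            association.append("none")
    return pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "persistence": persistence.to_numpy(),
            "association": association,
            "p_value": pvals,
            "p_value_adjusted": adj,
            "median_spring": med_spring,
            "median_autumn": med_autumn,
        }
    )


@dataclasses.dataclass
class CooccurrenceNetwork:
    """Undirected graph of significant OTU-OTU Spearman correlations.

    Nodes carry a ``phylum`` attribute; edges carry ``rho``,
    ``p_adjusted`` and ``sign`` ("positive"/"negative").
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subnetwork(self, phylum: str) -> "CooccurrenceNetwork":
        nodes = [v for v, d in self.graph.nodes(data=True) if d.get("phylum") == phylum]
        return CooccurrenceNetwork(self.graph.subgraph(nodes).copy())

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "otu_a": a,
                "otu_b": b,
                "rho": d["rho"],
                "p_adjusted": d["p_adjusted"],
                "sign": d["sign"],
                "phylum_a": self.graph.nodes[a].get("phylum", "unassigned"),
                "phylum_b": self.graph.nodes[b].get("phylum", "unassigned"),
            }
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows,
            columns=["otu_a", "otu_b", "rho", "p_adjusted", "sign", "phylum_a", "phylum_b"],
        )


def cooccurrence_network(
    table: OtuTable,
    p_threshold: float = 0.01,
    rho_threshold: float = 0.5,
    adjust: bool = True,
) -> CooccurrenceNetwork:
    """Build the OTU co-occurrence network from pairwise Spearman correlations.

    Correlations are computed on per-sample relative abundances across
    all samples. An edge is kept when the (BH-adjusted, unless `adjust`
    is off) p-value is below `p_threshold` **and** |rho| exceeds
    `rho_threshold`. OTUs constant across samples carry no rank
    information and are excluded from the correlation (they remain
    absent from the network); this is by construction, not an error.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for co-occurrence analysis")
    rel = relative_abundance(table, per="sample")
    variable = rel.std(axis=1) > 0
    idx = np.flatnonzero(variable)
    phyla = table.phyla
    g = nx.Graph()
    for i in idx:
        g.add_node(table.otu_ids[i], phylum=phyla[i])
    if len(idx) >= 2:
        sub = rel[idx]
        rho, pval = stats.spearmanr(sub.T)
        if len(idx) == 2:  # spearmanr returns scalars for two variables
            rho = np.array([[1.0, rho], [rho, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
        iu, ju = np.triu_indices(len(idx), k=1)
        ps = pval[iu, ju]
        p_adj = stats.false_discovery_control(ps, method="bh") if adjust else ps
        keep = (p_adj < p_threshold) & (np.abs(rho[iu, ju]) > rho_threshold)
        for k in np.flatnonzero(keep):
            a, b = table.otu_ids[idx[iu[k]]], table.otu_ids[idx[ju[k]]]
            r = float(rho[iu[k], ju[k]])
            g.add_edge(
                a,
                b,
                rho=r,
                p_adjusted=float(p_adj[k]),
                sign="positive" if r > 0 else "negative",
            )
    return CooccurrenceNetwork(g)


def network_density(net: CooccurrenceNetwork, phylum: str | None = None) -> float:
    """Network density d = edges / nodes (restricted to one phylum if given).

    Under this definition d can exceed 1 (a complete graph on k nodes
    has d = (k-1)/2).
    """
    sub = net if phylum is None else net.subnetwork(phylum)
    if sub.n_nodes == 0:
        raise ValueError(
            "network has no nodes" + (f" for phylum {phylum!r}" if phylum else "")
        )
    return sub.n_edges / sub.n_nodes


def phylum_season_groups(
    labels: pd.DataFrame,
    phylum_of: Mapping[str, str] | Sequence[str],
    dominance: float = 0.75,
) -> pd.DataFrame:
    """Classify each phylum's seasonal preference from its associated OTUs.

    A phylum is autumn-dominated when autumn-associated OTUs make up at
    least `dominance` of its season-associated OTUs (inclusive, so 3/4
    at the default 0.75 qualifies); spring-dominated symmetrically;
    otherwise mixed. Phyla without any season-associated OTU are
    reported as "unclassified".
    """
    if not isinstance(phylum_of, Mapping):
        phylum_of = dict(zip(labels["otu_id"], phylum_of))
    counts: dict[str, list[int]] = {}
    for _, row in labels.iterrows():
        ph = phylum_of.get(row["otu_id"], "unassigned")
        counts.setdefault(ph, [0, 0])
        if row["association"] == "autumn":
            counts[ph][0] += 1
        elif row["association"] == "spring":
            counts[ph][1] += 1
    rows = []
    for ph in sorted(counts):
        n_aut, n_spr = counts[ph]
        total = n_aut + n_spr
        if total == 0:
            group = "unclassified"
        elif n_aut / total >= dominance:
            group = "autumn-dominated"
        elif n_spr / total >= dominance:
            group = "spring-dominated"
        else:
            group = "mixed"
        rows.append((ph, n_aut, n_spr, group))
    return pd.DataFrame(rows, columns=["phylum", "n_autumn", "n_spring", "group"])
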
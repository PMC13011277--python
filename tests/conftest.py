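import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from optisyn.network import CoPrescriptionTable, DockingTable, HeteroNetwork

logging.getLogger("optisyn").setLevel(logging.ERROR)


@pytest.fixture
def tiny_network():
    """2 herbs, 3 compounds, 4 targets, a path PPI, 2 disease genes."""
    return HeteroNetwork(
        herbs=frozenset({"h1", "h2"}),
        compounds=frozenset({"c1", "c2", "c3"}),
        targets=frozenset({"t1", "t2", "t3", "t4"}),
        disease_genes=frozenset({"t1", "t2"}),
        herb_compound_edges=frozenset({("h1", "c1"), ("h1", "c2"), ("h2", "c3")}),
        compound_target_edges=frozenset(
            {("c1", "t1"), ("c1", "t3"), ("c2", "t2"), ("c3", "t4")}),
        ppi_edges=frozenset({frozenset({"t1", "t2"}), frozenset({"t2", "t3"}),
                             frozenset({"t3", "t4"})}),
    )


@pytest.fixture
def path_graph():
    g = nx.path_graph(4)
    return nx.relabel_nodes(g, {i: f"t{i + 1}" for i in g.nodes()})


@pytest.fixture
def coprescription():
    rows = pd.DataFrame({
        "herb_a": ["A", "A", "B", "C"],
        "herb_b": ["B", "C", "C", "D"],
        "frequency": [20.0, 10.0, 4.0, 8.0],
    })
    return CoPrescriptionTable(rows=rows, source="fixture")


@pytest.fixture
def docking_table():
    rows = pd.DataFrame({
        "compound_id": ["quercetin"] * 3 + ["rare"] * 2,
        "target_id": ["t1", "t2", "t3", "t1", "t2"],
        "affinity_kcal_mol": [-7.2, -6.1, -4.9, -4.0, 0.0],
    })
    return DockingTable(rows=rows, frequencies={"quercetin": 12, "rare": 2})


# Published ranking-table rows (eight-herb prescription): Z, dab, overlap
# rate, Hscore, Mscore, Ec, mean silhouette, GCN degree, average association.
TABLE4 = pd.DataFrame(
    [
        ("Epimedii Folium", -40.702, 1.863, 0.005, 0.019, 18.123, 0.016, 0.450, 13, 0.526),
        ("Achyranthis Bidentatae Radix", -83.249, 1.798, 0.005, 0.001, 19.997, 0.021, 0.620, 12, 0.545),
        ("Myrrha", -69.121, 1.822, 0.005, 0.003, 19.096, 0.009, 0.530, 15, 0.536),
        ("Forsythiae Fructus", -43.717, 1.841, 0.005, 0.006, 27.199, 0.023, 0.510, 11, 0.535),
        ("Astragali Radix", -77.270, 1.828, 0.005, 0.003, 27.520, 0.021, 0.470, 11, 0.529),
        ("Drynariae Rhizoma", -44.353, 1.850, 0.006, 0.005, 11.734, 0.033, 0.550, 15, 0.533),
        ("Lycii Fructus", -56.767, 1.832, 0.005, 0.002, 26.304, 0.006, 0.710, 13, 0.531),
        ("Alpiniae Officinarum Rhizoma", -104.606, 1.814, 0.005, 0.003, 5.856, 0.026, 0.640, 12, 0.514),
    ],
    columns=["herb", "z", "d_ab", "overlap_rate", "hscore", "mscore", "ec",
             "avg_silhouette", "gcn_degree", "avg_drug_association"],
)


@pytest.fixture
def table4():
    return TABLE4.copy()


# -- independent oracles used by several test modules --------------------------


def bfs_distances(graph, source):
    """Plain BFS hop counts, independent of the package's distance code."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_closest(graph, A, B, penalty):
    total, n = 0.0, 0
    for a in A:
        d = bfs_distances(graph, a)
        best = min((d[b] for b in B if b in d), default=None)
        total += penalty if best is None else best
        n += 1
    for b in B:
        d = bfs_distances(graph, b)
        best = min((d[a] for a in A if a in d), default=None)
        total += penalty if best is None else best
        n += 1
    return total / n


def brute_within(graph, A, penalty):
    total = 0.0
    for a in A:
        d = bfs_distances(graph, a)
        best = min((d[x] for x in A if x != a and x in d), default=None)
        total += penalty if best is None else best
    return total / len(A)


def brute_dunn(labels, dist):
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    inter = np.inf
    intra = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i == j:
                continue
            if labels[i] == labels[j]:
                intra = max(intra, dist[i, j])
            else:
                inter = min(inter, dist[i, j])
    return np.inf if intra == 0 else inter / intra


def brute_silhouette(labels, dist):
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([dist[i, j] for j in same])
        b = min(np.mean([dist[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels.tolist()) if c != labels[i])
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out
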
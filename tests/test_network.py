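"""Cluster networks, prevalence arithmetic and per-class totals."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bgclust import (
    build_network,
    class_totals,
    cluster_distance,
    label_known_clusters,
    percent,
    prevalence_table,
)
from bgclust.catalog_io import KnownLabel
from bgclust.cluster import NOISE, ClusterAssignment
from bgclust.hgt import HGTAnnotation
from bgclust.network import carrier_genomes, export_graphml, export_sif
from bgclust.records import GenomeMeta

from ._utils import make_bgc, random_distance_matrix


def _dist_df(values, ids):
    return pd.DataFrame(values, index=ids, columns=ids)


def test_cluster_distance_hand_case():
    ids = ["x1", "x2", "y1"]
    d = _dist_df([[0, 0.1, 0.4], [0.1, 0, 0.6], [0.4, 0.6, 0]], ids)
    assert cluster_distance(d, ["x1", "x2"], ["y1"]) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="non-empty"):
        cluster_distance(d, [], ["y1"])
    with pytest.raises(ValueError, match="disjoint"):
        cluster_distance(d, ["x1"], ["x1", "y1"])


def test_cluster_distance_matches_bruteforce():
    rng = np.random.default_rng(0)
    ids = [f"p{i}" for i in range(8)]
    d = _dist_df(random_distance_matrix(rng, 8), ids)
    for size_i in (1, 2, 3):
        members_i = ids[:size_i]
        members_j = ids[size_i : size_i + 3]
        expected = np.mean(
            [d.loc[a, b] for a, b in itertools.product(members_i, members_j)]
        )
        assert cluster_distance(d, members_i, members_j) == pytest.approx(expected)


def _two_cluster_setup(mean_distance):
    ids = ["a1", "a2", "b1", "b2"]
    v = np.full((4, 4), mean_distance)
    v[:2, :2] = 0.0
    v[2:, 2:] = 0.0
    np.fill_diagonal(v, 0.0)
    asg = ClusterAssignment(ids, [0, 0, 1, 1], eps=0.1, min_pts=2, class_label="NRPS")
    return [asg], _dist_df(v, ids)


def test_network_edges_respect_threshold():
    assignments, dist = _two_cluster_setup(0.2)
    g = build_network(assignments, dist, edge_threshold=0.5)
    assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
    assert g.edges[("NRPS:0", "NRPS:1")]["distance"] == pytest.approx(0.2)
    g2 = build_network(assignments, dist, edge_threshold=0.1)
    assert g2.number_of_nodes() == 2 and g2.number_of_edges() == 0


def test_network_nodes_carry_known_status():
    assignments, dist = _two_cluster_setup(0.2)
    known = {("NRPS", 0): KnownLabel(True, ("surfactin",))}
    g = build_network(assignments, dist, known, edge_threshold=0.5)
    assert g.nodes["NRPS:0"]["known"] and g.nodes["NRPS:0"]["compounds"] == "surfactin"
    assert not g.nodes["NRPS:1"]["known"]


def test_network_on_benchmark(benchmark_library, benchmark_distance, benchmark_assignments):
    known = label_known_clusters(benchmark_assignments, benchmark_library)
    g = build_network(benchmark_assignments, benchmark_distance, known)
    n_clusters = sum(a.n_clusters for a in benchmark_assignments)
    assert g.number_of_nodes() == n_clusters
    # node sizes sum to library size minus noise points
    n_noise = sum(a.n_noise for a in benchmark_assignments)
    assert sum(d["size"] for _, d in g.nodes(data=True)) == len(benchmark_library) - n_noise
    # edges only ever join same-class nodes
    for u, v in g.edges:
        assert g.nodes[u]["bgc_class"] == g.nodes[v]["bgc_class"]
    assert any(d["known"] for _, d in g.nodes(data=True))


def test_exports_are_readable(tmp_path, benchmark_library, benchmark_distance, benchmark_assignments):
    g = build_network(benchmark_assignments, benchmark_distance)
    gml = export_graphml(g, tmp_path / "net.graphml")
    back = nx.read_graphml(gml)
    assert set(back.nodes) == set(g.nodes) and back.number_of_edges() == g.number_of_edges()
    sif, attrs = export_sif(g, tmp_path / "net.sif", tmp_path / "nodes.tsv")
    attr_df = pd.read_csv(attrs, sep="\t")
    assert len(attr_df) == g.number_of_nodes()
    assert sif.read_text().count("\n") >= g.number_of_edges()


def test_percent_rounds_half_up():
    assert percent(18, 221) == 8.1
    assert percent(1, 8, 1) == 12.5
    assert percent(1, 800, 1) == 0.1  # 0.125 rounds half-up at one decimal
    assert percent(0, 221) == 0.0
    assert percent(1140, 5081, 0) == 22
    with pytest.raises(ValueError, match="denominator"):
        percent(1, 0)


def _stub_population(n_total, n_with, key="clusterX", group="other"):
    metadata = [GenomeMeta(f"g{i}", "Bacillus sp.", group, "proprietary") for i in range(n_total)]
    library = [
        make_bgc(f"b{i}", ["MKLVATNQRS"], genome_id=f"g{i}") for i in range(n_with)
    ]
    membership = {b.bgc_id: key for b in library}
    return library, metadata, membership


def test_prevalence_counts_strains_once():
    library, metadata, membership = _stub_population(10, 4)
    # second BGC on an already-carrying strain must not inflate the count
    extra = make_bgc("extra", ["MKLVATNQRS"], genome_id="g0")
    library.append(extra)
    membership["extra"] = "clusterX"
    table = prevalence_table(library, metadata, membership)
    row = table.iloc[0]
    assert row["n_strains_with"] == 4 and row["percent"] == 40.0
    assert row["n_bgcs"] == 5


def test_prevalence_includes_hgt_percentage():
    library, metadata, membership = _stub_population(10, 4)
    annotations = [
        HGTAnnotation(b.bgc_id, 1.0 if i < 3 else 0.0, i < 3) for i, b in enumerate(library)
    ]
    table = prevalence_table(library, metadata, membership, annotations)
    assert table.iloc[0]["percent_hgt"] == 75.0


def test_prevalence_requires_metadata():
    library, metadata, membership = _stub_population(4, 4)
    with pytest.raises(ValueError, match="no metadata"):
        prevalence_table(library, metadata[:-1], membership)


def test_carrier_genomes_set():
    library, _, membership = _stub_population(6, 3)
    assert carrier_genomes(library, membership, "clusterX") == {"g0", "g1", "g2"}
    assert carrier_genomes(library, membership, "absent") == set()


def test_class_totals_bookkeeping():
    lib = [
        make_bgc("n1", ["MKLVATNQRS"], "NRPS"),
        make_bgc("n2", ["MKLVATNQRS"], "NRPS"),
        make_bgc("n3", ["MKLVATNQRS"], "NRPS"),
        make_bgc("t1", ["MKLVATNQRS"], "terpene"),
        make_bgc("REF_r", ["MKLVATNQRS"], "NRPS", source="reference", compound="c"),
    ]
    asg_n = ClusterAssignment(["n1", "n2", "REF_r", "n3"], [0, 0, 0, NOISE], 0.1, 2, "NRPS")
    asg_t = ClusterAssignment(["t1"], [NOISE], 0.1, 2, "terpene")
    known = label_known_clusters([asg_n, asg_t], lib)
    totals = class_totals(lib, [asg_n, asg_t], known).set_index("class")
    assert totals.loc["NRPS", "n_bgcs"] == 3  # reference records not counted
    assert totals.loc["NRPS", "n_singletons"] == 1
    assert totals.loc["NRPS", "n_unknown"] == 1  # only the noise point
    assert totals.loc["NRPS", "percent_unknown"] == 33
    assert totals.loc["terpene", "percent_unknown"] == 100
    assert totals["n_bgcs"].sum() == 4


def test_class_totals_match_truth(benchmark_collection, benchmark_library, benchmark_assignments):
    known = label_known_clusters(benchmark_assignments, benchmark_library)
    totals = class_totals(benchmark_library, benchmark_assignments, known).set_index("class")
    truth_counts = benchmark_collection.truth["class_label"].value_counts()
    assert totals["n_bgcs"].to_dict() == truth_counts.to_dict()
    assert totals["n_bgcs"].sum() == len(benchmark_collection.records)
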
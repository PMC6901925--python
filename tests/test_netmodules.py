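import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hypergeom_enumeration
from xkmir.netmodules import (AnnotationTable, Cluster, ClusterOneParams,
                              EnrichmentRecord, cluster_modularity, cluster_one,
                              enrich, hypergeom_right_tail, retain_terms,
                              shared_processes)


def _clique(tag, size):
    g = nx.complete_graph(size)
    return nx.relabel_nodes(g, {i: f"{tag}{i:02d}" for i in g.nodes})


# --- modularity clustering -------------------------------------------------


def test_two_cliques_one_bridge():
    g = nx.union_all([_clique("a", 6), _clique("b", 6)])
    g.add_edge("a00", "b00")
    clusters = cluster_modularity(g)
    assert len(clusters) == 2
    members = sorted(sorted(c.gene_ids) for c in clusters)
    assert members[0] == sorted(f"a{i:02d}" for i in range(6))
    assert members[1] == sorted(f"b{i:02d}" for i in range(6))


def test_complete_graph_single_cluster():
    clusters = cluster_modularity(_clique("a", 8))
    assert len(clusters) == 1
    assert len(clusters[0].gene_ids) == 8


def test_empty_edges_singletons():
    g = nx.empty_graph(5)
    clusters = cluster_modularity(g)
    assert len(clusters) == 5
    assert all(len(c.gene_ids) == 1 for c in clusters)


def test_modularity_clusters_partition_nodes():
    g = nx.union_all([_clique("a", 5), _clique("b", 4)])
    g.add_edge("a00", "b00")
    clusters = cluster_modularity(g)
    seen = [n for c in clusters for n in c.gene_ids]
    assert sorted(seen) == sorted(g.nodes)


# --- cohesiveness clustering -----------------------------------------------

SMALL = ClusterOneParams(min_size=4, min_density=0.25, node_penalty=2)


def test_two_cliques_sharing_a_node():
    a = _clique("a", 8)
    b = _clique("b", 8)
    g = nx.union_all([a, b])
    shared = "s00"
    for n in list(a.nodes):
        g.add_edge(shared, n)
    for n in list(b.nodes):
        g.add_edge(shared, n)
    clusters = cluster_one(g, SMALL)
    assert len(clusters) == 2
    assert all(shared in c.gene_ids for c in clusters)


def test_graph_below_min_size_empty():
    clusters = cluster_one(_clique("a", 3), ClusterOneParams(min_size=10))
    assert clusters == []


def test_overlap_one_never_merges():
    g = nx.union_all([_clique("a", 6), _clique("b", 6)])
    g.add_edge("a00", "b00")
    params = ClusterOneParams(min_size=4, overlap_jaccard=1.0)
    clusters = cluster_one(g, params)
    assert len(clusters) == 2


def test_cluster_one_outputs_satisfy_filters(rng):
    g = nx.gnp_random_graph(40, 0.2, seed=5)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    params = ClusterOneParams(min_size=5, min_density=0.3)
    for c in cluster_one(g, params):
        assert len(c.gene_ids) >= 5
        sub = g.subgraph(c.gene_ids)
        k = len(c.gene_ids)
        assert 2 * sub.number_of_edges() / (k * (k - 1)) >= 0.3


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ClusterOneParams(min_density=1.5)


# --- enrichment ------------------------------------------------------------


def _annot(terms, universe):
    return AnnotationTable(
        {tid: (f"name {tid}", frozenset(genes)) for tid, genes in terms.items()},
        frozenset(universe),
    )


def test_exact_hypergeometric_example():
    # N=20, K=5, n=5, k=4 -> (C(5,4)*C(15,1) + C(5,5)) / C(20,5) = 76/15504
    assert hypergeom_right_tail(4, 5, 5, 20) == pytest.approx(76 / 15504)


def test_right_tail_at_zero_is_one():
    assert hypergeom_right_tail(0, 5, 5, 20) == 1.0


@settings(max_examples=40, deadline=None)
@given(st.integers(1, 12), st.data())
def test_hypergeom_matches_enumeration(N, data):
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(0, min(K, n)))
    assert hypergeom_right_tail(k, K, n, N) == pytest.approx(
        hypergeom_enumeration(k, K, n, N)
    )


def test_enrich_records_and_bh():
    universe = [f"g{i}" for i in range(20)]
    annot = _annot(
        {"T1": universe[:5], "T2": universe[5:15], "T3": universe[15:]}, universe
    )
    cluster = Cluster("c1", tuple(universe[:5]), "modularity")
    records = enrich(cluster, annot)
    by_term = {r.term_id: r for r in records}
    assert by_term["T1"].k == 5
    assert by_term["T1"].p_value == pytest.approx(1 / 15504)
    # BH step-up: q monotone in p-rank and >= p
    ordered = sorted(records, key=lambda r: r.p_value)
    qs = [r.q_value for r in ordered]
    assert qs == sorted(qs)
    assert all(r.q_value >= r.p_value - 1e-12 for r in records)
    # manual step-up comparison
    m = len(ordered)
    manual = [min(1.0, min(ordered[j].p_value * m / (j + 1) for j in range(i, m)))
              for i in range(m)]
    assert qs == pytest.approx(manual)


def test_enrich_drops_outside_genes():
    universe = [f"g{i}" for i in range(10)]
    annot = _annot({"T1": universe[:5]}, universe)
    cluster = Cluster("c1", ("g0", "g1", "alien"), "modularity")
    records = enrich(cluster, annot)
    assert records[0].n == 2


def test_enrich_empty_universe_rejected():
    with pytest.raises(ValueError):
        enrich(Cluster("c", ("g0",), "modularity"), _annot({}, []))


def _rec(term, p, genes, cluster="c1"):
    return EnrichmentRecord(cluster_id=cluster, term_id=term, term_name=term,
                            k=len(genes), K=5, n=5, N=20, p_value=p, q_value=p,
                            genes=tuple(genes))


def test_retain_requires_target_gene():
    recs = [_rec("T1", 0.01, ["i1", "i2"])]  # interactors only
    assert retain_terms(recs, {"t1"}) == []


def test_retain_requires_p_threshold():
    recs = [_rec("T1", 0.2, ["t1"])]
    assert retain_terms(recs, {"t1"}) == []


def test_retain_keeps_qualifying():
    recs = [_rec("T1", 0.01, ["t1", "i1"])]
    out = retain_terms(recs, {"t1"})
    assert len(out) == 1 and out[0].has_original_target


def test_retained_subset_of_input():
    recs = [_rec("T1", 0.01, ["t1"]), _rec("T2", 0.04, ["i1"]), _rec("T3", 0.9, ["t1"])]
    out = retain_terms(recs, {"t1"})
    assert {r.term_id for r in out} <= {r.term_id for r in recs}


# --- shared processes ------------------------------------------------------


def test_shared_intersection():
    a = [_rec("GO:1", 0.01, ["pa"]), _rec("GO:2", 0.01, ["pb"])]
    b = [_rec("GO:2", 0.01, ["hb"]), _rec("GO:3", 0.01, ["hc"])]
    shared = shared_processes(a, b)
    assert [s.term_id for s in shared] == ["GO:2"]
    assert shared[0].genes_a == ("pb",) and shared[0].genes_b == ("hb",)


def test_shared_disjoint_empty():
    assert shared_processes([_rec("GO:1", 0.01, ["x"])],
                            [_rec("GO:2", 0.01, ["y"])]) == []


def test_shared_symmetric():
    a = [_rec("GO:1", 0.01, ["pa"])]
    b = [_rec("GO:1", 0.01, ["hb"])]
    ab = shared_processes(a, b)
    ba = shared_processes(b, a)
    assert [s.term_id for s in ab] == [s.term_id for s in ba]


def test_shared_carries_mirnas():
    from types import SimpleNamespace

    a = [_rec("GO:1", 0.01, ["pa"])]
    b = [_rec("GO:1", 0.01, ["hb"])]
    hits_a = [SimpleNamespace(gene_id="pa", mirna_id="miR-1")]
    hits_b = [SimpleNamespace(gene_id="hb", mirna_id="miR-1")]
    shared = shared_processes(a, b, hits_a, hits_b)
    assert shared[0].mirnas_a == ("miR-1",)
    assert shared[0].mirnas_b == ("miR-1",)
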
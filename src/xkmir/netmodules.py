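"""Network decomposition and functional comparison.

Two clusterers: a parameter-free greedy modularity partitioner and a
cohesiveness-based overlapping clusterer (seed growth from unused nodes,
grow/shrink to a local optimum of W_in / (W_in + W_bound + penalty*|V|),
haircut, multi-pass Jaccard merging, size/density filters). Per-cluster GO
enrichment uses the exact right-tail hypergeometric test with
Benjamini-Hochberg correction inside each cluster's test family, followed
by the retention rule (p below threshold AND at least one gene from the
original target list) and the cross-species term intersection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import community
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    gene_ids: tuple[str, ...]
    method: str  # "modularity" | "cluster_one"
    quality: float = 0.0  # cohesiveness or modularity contribution

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("empty cluster")


@dataclass(frozen=True)
class ClusterOneParams:
    min_size: int = 50
    min_density: float = 0.25
    node_penalty: float = 2.0
    haircut: float = 0.0
    overlap_jaccard: float = 0.15
    max_merge_passes: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.min_density <= 1) or not (0 <= self.overlap_jaccard <= 1):
            raise ValueError("densities and overlap thresholds must lie in [0, 1]")


@dataclass
class AnnotationTable:
    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationTable":
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        seen: set[str] = set()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                tid, name, genes = parts[0], parts[1], frozenset(parts[2:])
                terms[tid] = (name, genes)
                seen |= genes
        return cls(terms, frozenset(universe) if universe is not None else frozenset(seen))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.terms):
                name, genes = self.terms[tid]
                fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    cluster_id: str
    term_id: str
    term_name: str
    k: int  # overlap
    K: int  # term size
    n: int  # cluster size (within universe)
    N: int  # universe size
    p_value: float
    q_value: float
    genes: tuple[str, ...]
    has_original_target: bool = False


@dataclass(frozen=True)
class SharedProcess:
    term_id: str
    term_name: str
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    mirnas_a: tuple[str, ...]
    mirnas_b: tuple[str, ...]


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------


def cluster_modularity(net: nx.Graph) -> list[Cluster]:
    """Greedy modularity partition of the (unweighted, undirected) graph.

    Singleton handling mirrors the degenerate cases: an empty edge set
    yields one cluster per node.
    """
    if net.number_of_nodes() == 0:
        return []
    unweighted = nx.Graph()
    unweighted.add_nodes_from(sorted(net.nodes))
    unweighted.add_edges_from(net.edges)
    if unweighted.number_of_edges() == 0:
        parts = [{n} for n in sorted(unweighted.nodes)]
    else:
        parts = community.greedy_modularity_communities(unweighted)
    clusters = []
    for members in sorted((sorted(p) for p in parts), key=lambda m: (-len(m), m[0])):
        sub = unweighted.subgraph(members)
        clusters.append(
            Cluster(
                cluster_id=f"M{len(clusters) + 1}",
                gene_ids=tuple(members),
                method="modularity",
                quality=float(sub.number_of_edges()),
            )
        )
    return clusters


def _cohesiveness(net: nx.Graph, nodes: set[str], penalty: float) -> float:
    w_in = 0
    w_bound = 0
    for u in nodes:
        for v in net.neighbors(u):
            if v in nodes:
                w_in += 1
            else:
                w_bound += 1
    w_in //= 2
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def _density(net: nx.Graph, nodes: tuple[str, ...]) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    e = net.subgraph(nodes).number_of_edges()
    return 2 * e / (k * (k - 1))


def cluster_one(net: nx.Graph, params: ClusterOneParams | None = None) -> list[Cluster]:
    """Cohesiveness-based overlapping clustering (unweighted edges).

    Seeds are taken from nodes not yet in any cluster, highest degree first
    (ties by node id). Each seed grows/shrinks greedily by the single move
    that most improves cohesiveness; after the haircut step, cluster pairs
    with Jaccard overlap >= the threshold are merged in multiple passes
    until a fixpoint; finally size and density filters apply.
    """
    params = params or ClusterOneParams()
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)

    covered: set[str] = set()
    raw: list[set[str]] = []
    order = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    for seed in order:
        if seed in covered or g.degree(seed) == 0:
            continue
        members = {seed}
        score = _cohesiveness(g, members, params.node_penalty)
        while True:
            best_move: tuple[float, str, str] | None = None
            boundary = {v for u in members for v in g.neighbors(u)} - members
            # ties broken by node id via the sorted scan and strict ">"
            for v in sorted(boundary):
                s = _cohesiveness(g, members | {v}, params.node_penalty)
                if s > score and (best_move is None or s > best_move[0]):
                    best_move = (s, "add", v)
            if len(members) > 1:
                for v in sorted(members):
                    s = _cohesiveness(g, members - {v}, params.node_penalty)
                    if s > score and (best_move is None or s > best_move[0]):
                        best_move = (s, "remove", v)
            if best_move is None:
                break
            score = best_move[0]
            if best_move[1] == "add":
                members.add(best_move[2])
            else:
                members.remove(best_move[2])
        # haircut: drop nodes whose in-cluster degree is below
        # haircut * average in-cluster degree (threshold 0 keeps everything)
        if params.haircut > 0 and len(members) > 1:
            sub = g.subgraph(members)
            avg = 2 * sub.number_of_edges() / len(members)
            members = {v for v in members if sub.degree(v) >= params.haircut * avg}
        if members:
            raw.append(set(members))
            covered |= members

    # multi-pass merging of overlapping clusters
    for _ in range(params.max_merge_passes):
        merged = False
        raw.sort(key=lambda s: sorted(s))
        for i, j in itertools.combinations(range(len(raw)), 2):
            a, b = raw[i], raw[j]
            if not a or not b:
                continue
            jac = len(a & b) / len(a | b)
            if jac >= params.overlap_jaccard and params.overlap_jaccard < 1.0:
                raw[i] = a | b
                raw[j] = set()
                merged = True
        raw = [s for s in raw if s]
        if not merged:
            break

    clusters = []
    for members in sorted((tuple(sorted(s)) for s in raw), key=lambda m: (-len(m), m)):
        if len(members) < params.min_size:
            continue
        if _density(g, members) < params.min_density:
            continue
        clusters.append(
            Cluster(
                cluster_id=f"C{len(clusters) + 1}",
                gene_ids=members,
                method="cluster_one",
                quality=_cohesiveness(g, set(members), params.node_penalty),
            )
        )
    return clusters


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(cluster: Cluster, annot: AnnotationTable) -> list[EnrichmentRecord]:
    """Right-tail hypergeometric enrichment of every annotation term in one
    cluster, BH-corrected across the terms tested for this cluster."""
    if not annot.universe:
        raise ValueError("empty annotation universe")
    genes = set(cluster.gene_ids) & annot.universe
    dropped = len(cluster.gene_ids) - len(genes)
    if dropped:
        logger.info("cluster %s: %d genes outside the universe dropped",
                    cluster.cluster_id, dropped)
    N, n = len(annot.universe), len(genes)
    rows = []
    for tid in sorted(annot.terms):
        name, tgenes = annot.terms[tid]
        overlap = tuple(sorted(genes & tgenes))
        p = hypergeom_right_tail(len(overlap), len(tgenes), n, N)
        rows.append((tid, name, overlap, len(tgenes), p))
    if not rows:
        return []
    _, q_values, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    return [
        EnrichmentRecord(
            cluster_id=cluster.cluster_id,
            term_id=tid,
            term_name=name,
            k=len(overlap),
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
            genes=overlap,
        )
        for (tid, name, overlap, K, p), q in zip(rows, q_values)
    ]


def retain_terms(
    records: list[EnrichmentRecord],
    original_target_genes,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Keep records with p < alpha that overlap the original target list in
    at least one gene (interactor-only terms are discarded)."""
    targets = set(original_target_genes)
    out = []
    for rec in records:
        has_target = bool(targets & set(rec.genes))
        if rec.p_value < alpha and has_target:
            out.append(
                EnrichmentRecord(**{**rec.__dict__, "has_original_target": has_target})
            )
    return out


def shared_processes(
    species_a_records: list[EnrichmentRecord],
    species_b_records: list[EnrichmentRecord],
    hits_a=None,
    hits_b=None,
) -> list[SharedProcess]:
    """Intersect post-retention term sets of two species; each shared term
    carries the per-species enriched genes and, via the miRNA->gene hit
    tables, the miRNAs targeting those genes."""

    def gene_to_mirnas(hits):
        m: dict[str, set[str]] = {}
        for h in hits or []:
            m.setdefault(h.gene_id, set()).add(h.mirna_id)
        return m

    map_a, map_b = gene_to_mirnas(hits_a), gene_to_mirnas(hits_b)

    def collect(records, term_id):
        genes: set[str] = set()
        name = ""
        for r in records:
            if r.term_id == term_id:
                genes |= set(r.genes)
                name = r.term_name
        return name, tuple(sorted(genes))

    terms_a = {r.term_id for r in species_a_records}
    terms_b = {r.term_id for r in species_b_records}
    shared = []
    for tid in sorted(terms_a & terms_b):
        name_a, genes_a = collect(species_a_records, tid)
        name_b, genes_b = collect(species_b_records, tid)
        mirnas_a = tuple(sorted({m for g in genes_a for m in map_a.get(g, ())}))
        mirnas_b = tuple(sorted({m for g in genes_b for m in map_b.get(g, ())}))
        shared.append(
            SharedProcess(tid, name_a or name_b, genes_a, genes_b, mirnas_a, mirnas_b)
        )
    return shared
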
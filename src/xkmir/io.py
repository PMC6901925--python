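"""Tabular readers/writers for pipeline artifacts (TSV, edge list, GraphML)."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .align import CrossKingdomPair
from .netmodules import Cluster, EnrichmentRecord, SharedProcess
from .targets import DuplexTargetHit, PlantTargetHit

HIT_COLUMNS = ["mirna_id", "transcript_id", "gene_id", "start", "end",
               "score", "score_type", "alignment"]


def write_hits(hits, path) -> None:
    """Unified hit table for both scanners (1-based closed coordinates)."""
    rows = []
    for h in hits:
        if isinstance(h, PlantTargetHit):
            score, stype = h.expectation, "expectation"
        elif isinstance(h, DuplexTargetHit):
            score, stype = h.mfe, "mfe"
        else:
            raise TypeError(f"unexpected hit type {type(h).__name__}")
        aln = (h.alignment if isinstance(h, PlantTargetHit) else h.duplex_structure)
        rows.append(
            [h.mirna_id, h.transcript_id, h.gene_id, h.site_start + 1, h.site_end,
             round(score, 4), stype, aln.replace("\n", ";")]
        )
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits(path):
    """Read a hit table back into lightweight hit objects."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        common = dict(
            mirna_id=row.mirna_id, transcript_id=row.transcript_id,
            gene_id=row.gene_id, site_start=int(row.start) - 1, site_end=int(row.end),
        )
        if row.score_type == "expectation":
            out.append(PlantTargetHit(expectation=float(row.score), seed_violations=0,
                                      alignment=str(row.alignment).replace(";", "\n"),
                                      **common))
        else:
            out.append(DuplexTargetHit(mfe=float(row.score),
                                       duplex_structure=str(row.alignment).replace(";", "\n"),
                                       **common))
    return out


PAIR_COLUMNS = ["mirna_id", "plant_gene", "human_gene",
                "nt_score", "nt_identity", "nt_p",
                "prot_score", "prot_identity", "prot_p"]


def write_pairs(pairs: list[CrossKingdomPair], path) -> None:
    rows = [
        [p.mirna_id, p.plant_gene, p.human_gene,
         p.nt_result.score, round(p.nt_result.identity_pct, 2), p.nt_result.p_value,
         p.protein_result.score, round(p.protein_result.identity_pct, 2),
         p.protein_result.p_value]
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_clusters(clusters: list[Cluster], path) -> None:
    rows = [[c.cluster_id, c.method, len(c.gene_ids), round(c.quality, 4),
             ",".join(c.gene_ids)] for c in clusters]
    pd.DataFrame(rows, columns=["cluster_id", "method", "size", "quality", "genes"]
                 ).to_csv(path, sep="\t", index=False)


def write_enrichment(records: list[EnrichmentRecord], path) -> None:
    rows = [[r.cluster_id, r.term_id, r.term_name, r.k, r.K, r.n, r.N,
             r.p_value, r.q_value, ",".join(r.genes)] for r in records]
    pd.DataFrame(rows, columns=["cluster", "term_id", "term_name", "k", "K", "n",
                                "N", "p", "q", "genes"]
                 ).to_csv(path, sep="\t", index=False)


def write_shared(shared: list[SharedProcess], path) -> None:
    rows = [[s.term_id, s.term_name,
             ",".join(s.genes_a), ",".join(s.mirnas_a),
             ",".join(s.genes_b), ",".join(s.mirnas_b)] for s in shared]
    pd.DataFrame(rows, columns=["term_id", "term_name", "genes_a", "mirnas_a",
                                "genes_b", "mirnas_b"]
                 ).to_csv(path, sep="\t", index=False)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [[u, v, round(d.get("weight", 1.0), 6)]
            for u, v, d in sorted(net.edges(data=True))]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"]).to_csv(path, sep="\t",
                                                                 index=False)


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(str(row[0]), str(row[1]), weight=float(row[2]) if len(row) > 2 else 1.0)
    return g


def read_network(path) -> nx.Graph:
    path = Path(path)
    if path.suffix in (".graphml", ".xml"):
        return nx.read_graphml(path)
    return read_edge_list(path)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
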
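"""Co-expression network reconstruction.

Mutual information is estimated from the Spearman rank correlation as
``mi = -0.5 * ln(1 - rho^2)`` (the Gaussian-copula estimator), the MI matrix
is pruned with the data-processing-inequality rule (every fully connected
gene triplet loses its weakest edge), the miRNA-target sub-network is the
induced graph on targets plus their first neighbors, and small components
are dropped before taking the giant component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: |rho| at which MI is capped to keep perfectly correlated pairs finite
RHO_CAP = 0.999999


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        # duplicate gene rows are median-collapsed on ingest
        if df.index.duplicated().any():
            df = df.groupby(level=0, sort=False).median()
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene_id", float_format="%.6g"
        )


@dataclass
class MIMatrix:
    gene_ids: list[str]
    mi: np.ndarray
    cap_value: float

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.mi.shape != (n, n):
            raise ValueError("MI matrix shape mismatch")


def mi_from_rho(rho: np.ndarray | float) -> np.ndarray | float:
    rho = np.clip(rho, -RHO_CAP, RHO_CAP)
    return -0.5 * np.log(1.0 - np.square(rho))


def spearman_mi(expr: ExpressionMatrix) -> MIMatrix:
    """Spearman-correlation mutual-information matrix.

    Ranks use average tie handling; constant gene rows have undefined
    correlation and get MI 0 with a warning.
    """
    n_genes, n_samples = expr.values.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    constant = np.array([np.ptp(row) == 0 for row in expr.values])
    if constant.any():
        logger.warning("%d constant gene rows; their MI is set to 0", constant.sum())
    if n_genes < 2:
        rho = np.ones((n_genes, n_genes))
    else:
        # rank-transform per gene (average ties), then Pearson of the ranks;
        # this stays well-defined row-wise even when some rows are constant
        ranks = np.apply_along_axis(stats.rankdata, 1, expr.values)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks)
    rho = np.nan_to_num(rho, nan=0.0)
    mi = np.asarray(mi_from_rho(rho))
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    np.fill_diagonal(mi, 0.0)
    return MIMatrix(expr.gene_ids, mi, cap_value=float(mi_from_rho(1.0)))


def permutation_mi_threshold(
    expr: ExpressionMatrix, *, n_perm: int = 10, quantile: float = 0.999, seed: int = 0
) -> float:
    """Data-driven MI cutoff: the given quantile of MI values obtained after
    independently shuffling each gene's samples (destroying co-expression)."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        shuffled = np.array([rng.permutation(row) for row in expr.values])
        null = spearman_mi(ExpressionMatrix(expr.gene_ids, expr.sample_ids, shuffled))
        iu = np.triu_indices(len(expr.gene_ids), k=1)
        vals.append(null.mi[iu])
    return float(np.quantile(np.concatenate(vals), quantile))


def dpi_prune(mim: MIMatrix, eps: float = 0.0, mi_threshold: float = 0.0) -> nx.Graph:
    """ARACNE-style network: threshold, then apply the data processing
    inequality to every fully connected triplet.

    Edge (i, j) is removed when some third gene k closes a triangle (all
    three edges above threshold) with ``mi(i,j) <= min(mi(i,k), mi(j,k)) -
    eps``; all decisions are evaluated against the original matrix, so the
    result does not depend on edge order. When a triangle's edges are all
    equal (eps = 0) the rule removes every edge of that triangle.
    """
    mi = mim.mi
    if not np.allclose(mi, mi.T):
        raise ValueError("MI matrix must be symmetric")
    n = len(mim.gene_ids)
    adj = mi > mi_threshold
    np.fill_diagonal(adj, False)
    removed = np.zeros_like(adj)
    for k in range(n):
        ik = adj[:, k]
        if not ik.any():
            continue
        # triangle (i, j, k): both i-k and j-k present
        cap = np.minimum.outer(mi[:, k], mi[:, k])
        tri = np.logical_and.outer(ik, ik)
        removed |= adj & tri & (mi <= cap - eps)
    keep = adj & ~removed
    g = nx.Graph()
    g.add_nodes_from(mim.gene_ids)
    ii, jj = np.nonzero(np.triu(keep, k=1))
    g.add_weighted_edges_from(
        (mim.gene_ids[i], mim.gene_ids[j], float(mi[i, j])) for i, j in zip(ii, jj)
    )
    return g


def extract_target_subnetwork(net: nx.Graph, target_genes) -> nx.Graph:
    """Induced subgraph on the targets plus their first neighbors; nodes are
    flagged with role ``target`` or ``interactor``."""
    targets = [t for t in target_genes if t in net]
    if not list(target_genes):
        raise ValueError("empty target gene list")
    missing = len(list(target_genes)) - len(targets)
    if missing:
        logger.info("%d target genes not present in the network", missing)
    keep = set(targets)
    for t in targets:
        keep.update(net.neighbors(t))
    sub = net.subgraph(keep).copy()
    tset = set(targets)
    for node in sub.nodes:
        sub.nodes[node]["role"] = "target" if node in tset else "interactor"
    return sub


def filter_components(net: nx.Graph, min_size: int = 10) -> tuple[nx.Graph, dict]:
    """Drop components with fewer than ``min_size`` nodes and return the
    giant component (ties broken by smallest node id) plus a report."""
    comps = [sorted(c) for c in nx.connected_components(net)]
    survivors = [c for c in comps if len(c) >= min_size]
    removed_sizes = sorted((len(c) for c in comps if len(c) < min_size), reverse=True)
    report = {
        "n_components": len(comps),
        "removed_component_sizes": removed_sizes,
        "surviving_component_sizes": sorted((len(c) for c in survivors), reverse=True),
    }
    if not survivors:
        logger.warning("no component of size >= %d; returning empty network", min_size)
        return nx.Graph(), report
    # tie rule: among equally large components the one whose smallest node id
    # sorts first wins
    biggest = max(len(c) for c in survivors)
    tied = [c for c in survivors if len(c) == biggest]
    giant_nodes = min(tied, key=lambda c: c[0])
    giant = net.subgraph(giant_nodes).copy()
    report["giant_component"] = {"n_nodes": giant.number_of_nodes(),
                                 "n_edges": giant.number_of_edges()}
    return giant, report
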
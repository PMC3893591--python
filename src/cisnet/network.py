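"""Gene-network statistics for CIS genes.

The co-expression network (e.g. an ARACNE edge list) is consumed as an
undirected simple graph on gene symbols.  The central question is whether
the CIS genes sit closer together in that graph than chance expects: the
statistic is the mean, over CIS genes, of the unweighted shortest-path
distance to the nearest *other* CIS gene, compared against gene sets drawn
uniformly from the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_network_edges",
    "write_network_edges",
    "mean_shortest_path_to_nearest_cis",
    "permutation_cluster_test",
    "cis_neighbourhood",
    "biallelic_enrichment",
    "term_enrichment",
    "ClusterTestResult",
    "EnrichmentResult",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterTestResult:
    """Outcome of the network-clustering permutation test."""

    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    genes_used: list[str] = field(default_factory=list)
    genes_missing: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    term: str
    hits_in_query: int
    query_size: int
    hits_in_background: int
    background_size: int
    raw_p: float
    adjusted_p: float = np.nan


def load_network_edges(path) -> nx.Graph:
    """Read a 2- or 3-column TSV edge list into an undirected simple graph.

    Duplicate edges collapse keeping the maximum weight; self-loop rows are
    dropped with a warning.
    """
    graph = nx.Graph()
    n_self = 0
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return graph
    if frame.empty:
        return graph
    for row in frame.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        weight = float(row[2]) if len(row) > 2 and pd.notna(row[2]) else 1.0
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], weight)
        else:
            graph.add_edge(a, b, weight=weight)
    if n_self:
        logger.warning("%s: dropped %d self-loop rows", path, n_self)
    return graph


def write_network_edges(graph: nx.Graph, path) -> None:
    with open(path, "w") as handle:
        for a, b, data in graph.edges(data=True):
            handle.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")


def _distance_matrix(graph: nx.Graph) -> tuple[list, dict, np.ndarray]:
    """All-pairs unweighted shortest-path matrix with unreachable pairs set
    to network diameter + 1 (the isolation penalty).  Memory is O(V^2)."""
    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    dist = np.full((len(nodes), len(nodes)), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        i = index[src]
        for tgt, d in lengths.items():
            dist[i, index[tgt]] = d
    finite = dist[np.isfinite(dist)]
    diameter = int(finite.max()) if finite.size else 0
    dist[np.isinf(dist)] = diameter + 1
    return nodes, index, dist


def _mean_nearest_from_matrix(dist: np.ndarray, member_idx: np.ndarray) -> float:
    sub = dist[np.ix_(member_idx, member_idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    # a fully isolated member has only diameter+1 entries, already the penalty
    return float(nearest.mean())


def _cluster_test_from_matrix(dist: np.ndarray, member_idx: np.ndarray,
                              n_perm: int, rng: np.random.Generator
                              ) -> tuple[float, np.ndarray, float]:
    """Permutation core shared by the public test and the calibration suite."""
    observed = _mean_nearest_from_matrix(dist, member_idx)
    n_nodes = dist.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        draw = rng.choice(n_nodes, size=len(member_idx), replace=False)
        null[b] = _mean_nearest_from_matrix(dist, draw)
    p = (np.count_nonzero(null <= observed) + 1) / (n_perm + 1)
    return observed, null, float(p)


def mean_shortest_path_to_nearest_cis(graph: nx.Graph, cis_genes) -> float:
    """Mean over CIS genes of the distance to the closest other CIS gene.

    CIS genes absent from the network are excluded (logged); a CIS gene
    disconnected from every other contributes network diameter + 1 so that
    isolation penalises rather than favours clustering.
    """
    present = [g for g in cis_genes if g in graph]
    missing = sorted(set(cis_genes) - set(present))
    if missing:
        logger.info("CIS genes absent from network, excluded: %s", ", ".join(missing))
    if len(present) < 2:
        raise ValueError("need at least 2 CIS genes present in the network")
    _, index, dist = _distance_matrix(graph)
    return _mean_nearest_from_matrix(dist, np.array([index[g] for g in present]))


def permutation_cluster_test(graph: nx.Graph, cis_genes, n_perm: int = 10_000,
                             seed: int = 0) -> ClusterTestResult:
    """Test whether the CIS genes cluster in the network.

    Null sets of the same size are drawn uniformly from all network nodes;
    p = (count of null means <= observed + 1) / (n_perm + 1), ties counting
    against the observed set.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    present = [g for g in cis_genes if g in graph]
    missing = sorted(set(cis_genes) - set(present))
    if len(present) < 2:
        raise ValueError("need at least 2 CIS genes present in the network")
    nodes = list(graph.nodes)
    if len(present) > len(nodes):
        raise ValueError("CIS set larger than the network")
    _, index, dist = _distance_matrix(graph)
    rng = np.random.default_rng(seed)
    observed, null, p = _cluster_test_from_matrix(
        dist, np.array([index[g] for g in present]), n_perm, rng)
    return ClusterTestResult(observed=observed, null=null, p_value=float(p),
                             n_perm=n_perm, seed=seed, genes_used=present,
                             genes_missing=missing)


def cis_neighbourhood(graph: nx.Graph, cis_genes) -> nx.Graph:
    """Induced subgraph on the CIS genes plus their first neighbours."""
    present = [g for g in cis_genes if g in graph]
    if not present:
        raise ValueError("no CIS genes present in the network")
    keep = set(present)
    for gene in present:
        keep.update(graph.adj[gene])
        if graph.degree[gene] == 0:
            logger.info("CIS gene %s is isolated in the network", gene)
    return graph.subgraph(keep).copy()


def biallelic_enrichment(hits_in: int, total_in: int, hits_out: int,
                         total_out: int) -> tuple[float, int, float]:
    """Two-sided Fisher exact test for hit enrichment inside the network.

    Returns ``(p, pct_in, pct_out)`` with the percentages formatted the way
    count tables are customarily reported: inside rounded to an integer
    percent, outside to two decimals.
    """
    if total_in <= 0 or total_out <= 0:
        raise ValueError("totals must be positive")
    if hits_in > total_in or hits_out > total_out:
        raise ValueError("hits cannot exceed totals")
    table = [[hits_in, total_in - hits_in], [hits_out, total_out - hits_out]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    pct_in = round(100.0 * hits_in / total_in)
    pct_out = round(100.0 * hits_out / total_out, 2)
    return float(p), int(pct_in), float(pct_out)


def term_enrichment(query, background, annotation: dict) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Upper-tail hypergeometric p per term against the full background, then
    Benjamini-Hochberg step-up across all tested terms; sorted by adjusted p.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    results: list[EnrichmentResult] = []
    for term, genes in annotation.items():
        term_bg = set(genes) & background
        if not term_bg:
            logger.warning("term %s has no genes in the background; skipped", term)
            continue
        k = len(term_bg & query)
        p = stats.hypergeom.sf(k - 1, len(background), len(term_bg), len(query))
        results.append(EnrichmentResult(
            term=term, hits_in_query=k, query_size=len(query),
            hits_in_background=len(term_bg), background_size=len(background),
            raw_p=float(p)))
    if results:
        adjusted = multipletests([r.raw_p for r in results], method="fdr_bh")[1]
        for res, adj in zip(results, adjusted):
            res.adjusted_p = float(adj)
    results.sort(key=lambda r: (r.adjusted_p, r.raw_p, r.term))
    return results
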
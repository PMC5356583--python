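"""Network topology analytics: degrees, overlaps, key drivers, mediators.

A *key regulator* is a gene whose count of directed descendants within a
hop limit is extreme (above mean + k·sd over all genes). *Distinct key
drivers* prune key regulators that are directly regulated by a
higher-degree key regulator, leaving independent entry points into the
regulated program. The *common downstream genes* of a driver set are the
genes in the top decile of smallest mean directed shortest-path distance
from the drivers — candidate signal integrators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .bayesnet import ConsensusNetwork

__all__ = [
    "KeyRegulatorCall",
    "MediatorRanking",
    "SubnetworkResult",
    "node_degree",
    "degree_correlation",
    "neighborhood_overlap_test",
    "call_key_regulators",
    "distinct_key_drivers",
    "project_seed_subnetwork",
    "mean_distance_to_drivers",
    "common_downstream_genes",
]


@dataclass
class KeyRegulatorCall:
    gene: str
    downstream_count: int
    threshold: float
    is_key: bool
    degree: int


@dataclass
class MediatorRanking:
    gene: str
    mean_distance: float
    reachable_from: int
    is_common_downstream: bool = False


@dataclass
class SubnetworkResult:
    members: set[str]
    components: list[set[str]]
    seeds_in_network: set[str]


def _graph_of(network) -> nx.DiGraph:
    if isinstance(network, ConsensusNetwork):
        return network.graph
    return network


def _undirected_neighborhood(g: nx.Graph, gene: str, hops: int) -> set[str]:
    und = g.to_undirected(as_view=False) if g.is_directed() else g
    dist = nx.single_source_shortest_path_length(und, gene, cutoff=hops)
    return {n for n, d in dist.items() if d > 0}


def node_degree(network, gene: str, hops: int = 1) -> int:
    """Number of distinct genes within ``hops`` undirected steps."""
    g = _graph_of(network)
    if gene not in g:
        raise KeyError(gene)
    return len(_undirected_neighborhood(g, gene, hops))


def degree_correlation(network1, network2, hops: int = 1) -> tuple[float, float]:
    """Spearman correlation of degree vectors over the common genes."""
    g1, g2 = _graph_of(network1), _graph_of(network2)
    common = sorted(set(g1.nodes) & set(g2.nodes))
    if len(common) < 10:
        raise ValueError("need at least 10 common genes")
    d1 = [node_degree(g1, g, hops) for g in common]
    d2 = [node_degree(g2, g, hops) for g in common]
    res = stats.spearmanr(d1, d2)
    return float(res.statistic), float(res.pvalue)


def neighborhood_overlap_test(
    network1,
    network2,
    gene: str,
    hops: int = 1,
    universe: set[str] | None = None,
) -> tuple[int, float]:
    """One-sided hypergeometric test for neighbor-set overlap.

    With universe size M and neighborhoods of sizes K and n overlapping in
    k genes, returns (k, P(X >= k)) for X ~ Hypergeom(M, K, n).
    """
    g1, g2 = _graph_of(network1), _graph_of(network2)
    if gene not in g1 or gene not in g2:
        raise KeyError(gene)
    n1 = _undirected_neighborhood(g1, gene, hops)
    n2 = _undirected_neighborhood(g2, gene, hops)
    if universe is None:
        universe = (set(g1.nodes) | set(g2.nodes)) - {gene}
    if not universe:
        raise ValueError("empty universe")
    if not (n1 <= universe and n2 <= universe):
        raise ValueError("universe must contain both neighborhoods")
    overlap = len(n1 & n2)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(n1), len(n2)))
    return overlap, min(p, 1.0)


def _descendants_within(g: nx.DiGraph, gene: str, hops: int) -> set[str]:
    dist = nx.single_source_shortest_path_length(g, gene, cutoff=hops)
    return {n for n, d in dist.items() if d > 0}


def call_key_regulators(
    network, hops: int = 3, sd_mult: float = 2.0, degree_hops: int = 1
) -> list[KeyRegulatorCall]:
    """Flag genes whose directed downstream reach is extreme.

    ``downstream_count`` counts distinct descendants within ``hops``
    directed steps; a gene is key when its count exceeds
    mean + sd_mult * sd over all genes. When the counts have zero spread
    nothing is called key.
    """
    g = _graph_of(network)
    genes = list(g.nodes)
    counts = {gene: len(_descendants_within(g, gene, hops)) for gene in genes}
    arr = np.array(list(counts.values()), dtype=float)
    sd = arr.std(ddof=0) if len(arr) else 0.0
    threshold = float(arr.mean() + sd_mult * sd) if len(arr) else 0.0
    calls = []
    for gene in genes:
        is_key = sd > 0 and counts[gene] > threshold
        calls.append(
            KeyRegulatorCall(
                gene=gene,
                downstream_count=counts[gene],
                threshold=threshold,
                is_key=is_key,
                degree=node_degree(g, gene, degree_hops),
            )
        )
    return calls


def distinct_key_drivers(
    network, key_regulators: list[KeyRegulatorCall]
) -> list[str]:
    """Drop key regulators directly regulated by a higher-degree key
    regulator; mutual equal-degree edges drop the lexicographically later
    gene. Result ordered by descending degree (ties: gene name)."""
    g = _graph_of(network)
    keys = {c.gene: c for c in key_regulators if c.is_key}
    survivors = set(keys)
    for kname, call in keys.items():
        for other, ocall in keys.items():
            if other == kname:
                continue
            if g.has_edge(other, kname) and ocall.degree > call.degree:
                survivors.discard(kname)
    # mutual edges among equal-degree survivors: keep the earlier name
    for kname in sorted(survivors):
        for other in sorted(survivors):
            if other <= kname:
                continue
            if (
                keys[kname].degree == keys[other].degree
                and g.has_edge(kname, other)
                and g.has_edge(other, kname)
            ):
                survivors.discard(other)
    return sorted(survivors, key=lambda k: (-keys[k].degree, k))


def project_seed_subnetwork(
    network, seeds: set[str], min_component_seeds: int = 3
) -> SubnetworkResult:
    """Induced subgraph on seeds plus their first undirected neighbors,
    keeping connected components that contain enough seeds."""
    g = _graph_of(network)
    seeds_in = set(seeds) & set(g.nodes)
    if not seeds_in:
        raise ValueError("no seed gene is present in the network")
    expanded = set(seeds_in)
    for s in seeds_in:
        expanded |= _undirected_neighborhood(g, s, 1)
    sub = g.subgraph(expanded).to_undirected(as_view=False)
    kept: list[set[str]] = []
    for comp in nx.connected_components(sub):
        if len(comp & seeds_in) >= min_component_seeds:
            kept.append(set(comp))
    if not kept:
        warnings.warn("no connected component carries enough seeds")
    members = set().union(*kept) if kept else set()
    return SubnetworkResult(members=members, components=kept, seeds_in_network=seeds_in)


def mean_distance_to_drivers(network, drivers: set[str]) -> list[MediatorRanking]:
    """Mean directed shortest-path distance from each driver to each gene.

    Genes unreachable from one or more drivers get infinite mean distance;
    a driver is at distance 0 from itself.
    """
    g = _graph_of(network)
    drivers = set(drivers)
    if not drivers:
        raise ValueError("driver set must be non-empty")
    missing = drivers - set(g.nodes)
    if missing:
        raise ValueError(f"drivers not in network: {sorted(missing)}")
    dist_maps = {d: nx.single_source_shortest_path_length(g, d) for d in drivers}
    out = []
    for gene in g.nodes:
        dists = [dist_maps[d].get(gene, math.inf) for d in drivers]
        reachable = sum(1 for x in dists if math.isfinite(x))
        mean = sum(dists) / len(dists) if reachable == len(dists) else math.inf
        out.append(
            MediatorRanking(gene=gene, mean_distance=mean, reachable_from=reachable)
        )
    return out


def common_downstream_genes(
    ranking: list[MediatorRanking], frac: float = 0.1
) -> list[str]:
    """Top ``frac`` of fully reachable genes by smallest mean distance,
    inclusive of ties at the cutoff. Marks ``is_common_downstream``."""
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    reachable = [r for r in ranking if math.isfinite(r.mean_distance)]
    if not reachable:
        warnings.warn("no gene is reachable from all drivers")
        return []
    reachable.sort(key=lambda r: (r.mean_distance, r.gene))
    k = math.ceil(frac * len(reachable))
    cutoff = reachable[k - 1].mean_distance
    chosen = [r for r in reachable if r.mean_distance <= cutoff]
    chosen_names = {r.gene for r in chosen}
    for r in ranking:
        r.is_common_downstream = r.gene in chosen_names
    return [r.gene for r in chosen]
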
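"""Network accuracy against reference collections and signature ROC curves.

Two complementary checks of a learned network:

* **edge accuracy** — the fraction of inferred regulations supported by a
  reference interaction database (edge sets) or falling within one
  annotated pathway (gene sets), with significance from a node-label
  permutation null;
* **signature ROC** — grow nested subnetworks around a seed gene by
  undirected graph distance and trace how well they capture an external
  gene signature. One minus specificity is the subnetwork's share of the
  network's genes, "sensitivity" is the share of subnetwork genes in the
  signature, and accuracy is the partial area under that curve at
  specificity above a floor (default 90%).

Also provides edge-recovery metrics (precision/recall/AUPRC against a
known ground-truth network) for simulation benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score

from .bayesnet import ConsensusNetwork

__all__ = [
    "ReferenceCollection",
    "RocCurve",
    "edge_accuracy",
    "permutation_null",
    "signature_roc",
    "partial_auc",
    "signature_roc_permutation_p",
    "skeleton_precision_recall",
    "edge_recovery_auprc",
]


@dataclass
class ReferenceCollection:
    """A reference standard: unordered interaction pairs or named gene sets."""

    name: str
    kind: str  # "edge_set" | "gene_set"
    pairs: set[frozenset[str]] = field(default_factory=set)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("edge_set", "gene_set"):
            raise ValueError("kind must be 'edge_set' or 'gene_set'")
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError("reference pairs must join two distinct genes")
        for name, members in self.gene_sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "ReferenceCollection":
        return cls(name=name, kind="edge_set", pairs={frozenset(p) for p in pairs})

    @classmethod
    def from_gene_sets(
        cls, name: str, gene_sets: Mapping[str, Iterable[str]]
    ) -> "ReferenceCollection":
        return cls(
            name=name,
            kind="gene_set",
            gene_sets={k: set(v) for k, v in gene_sets.items()},
        )

    @property
    def universe(self) -> set[str]:
        if self.kind == "edge_set":
            return {g for p in self.pairs for g in p}
        return {g for members in self.gene_sets.values() for g in members}


@dataclass
class RocCurve:
    """Nested-subnetwork ROC: (1-specificity, sensitivity) points + pAUC."""

    points: list[tuple[float, float]]
    pauc: float
    permutation_p: float | None = None


def _graph_of(network) -> nx.DiGraph:
    if isinstance(network, ConsensusNetwork):
        return network.graph
    return network


def _edge_pairs(network) -> list[tuple[str, str]]:
    return list(_graph_of(network).edges())


def edge_accuracy(network, reference: ReferenceCollection) -> float:
    """Fraction of network edges supported by the reference.

    Edge-set references: the unordered pair is in the reference. Gene-set
    references: both endpoints are co-members of at least one set. Edges
    with an endpoint outside the reference universe are excluded from the
    denominator; if no edge remains the accuracy is undefined (raises).
    """
    edges = _edge_pairs(network)
    if not edges:
        raise ValueError("network has no edges; accuracy undefined")
    universe = reference.universe
    scored = [(u, v) for u, v in edges if u in universe and v in universe]
    if not scored:
        raise ValueError("no network edge lies within the reference universe")
    if reference.kind == "edge_set":
        hits = sum(1 for u, v in scored if frozenset((u, v)) in reference.pairs)
    else:
        hits = sum(
            1
            for u, v in scored
            if any(u in s and v in s for s in reference.gene_sets.values())
        )
    return hits / len(scored)


def permutation_null(
    network,
    reference: ReferenceCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Node-label permutation null for :func:`edge_accuracy`.

    Returns (null mean, null sd, empirical p) with the +1-smoothed
    empirical p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    g = _graph_of(network)
    observed = edge_accuracy(network, reference)
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        permuted = nx.relabel_nodes(g, mapping, copy=True)
        null[b] = edge_accuracy(permuted, reference)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return float(null.mean()), float(null.std(ddof=1)), float(p)


def _nested_subnetworks(
    g: nx.Graph, seed_gene: str, max_radius: int
) -> list[set[str]]:
    """Gene sets within 1..max_radius undirected steps of the seed (seed
    excluded), cumulative."""
    und = g.to_undirected(as_view=False) if g.is_directed() else g
    dist = nx.single_source_shortest_path_length(und, seed_gene, cutoff=max_radius)
    out = []
    for h in range(1, max_radius + 1):
        out.append({n for n, d in dist.items() if 0 < d <= h})
    return out


def signature_roc(
    network,
    seed_gene: str,
    signature: Iterable[str],
    max_radius: int = 10,
) -> RocCurve:
    """ROC of nested seed subnetworks against an external gene signature.

    For radius h, with subnetwork S_h (genes within h undirected steps of
    the seed, seed excluded) and N network genes, the curve point is
    ``(|S_h| / N, |S_h ∩ signature| / |S_h|)``, anchored at (0, 0).
    """
    g = _graph_of(network)
    if seed_gene not in g:
        raise KeyError(seed_gene)
    sig = set(signature)
    if not sig:
        raise ValueError("signature must be non-empty")
    n_total = g.number_of_nodes()
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for s_h in _nested_subnetworks(g, seed_gene, max_radius):
        if not s_h:
            continue
        points.append((len(s_h) / n_total, len(s_h & sig) / len(s_h)))
    curve = RocCurve(points=points, pauc=0.0)
    curve.pauc = partial_auc(curve)
    return curve


def partial_auc(curve: RocCurve, spec_floor: float = 0.9) -> float:
    """Trapezoidal area over 1-specificity in [0, 1 - spec_floor], normalized.

    Linearly interpolates between curve points, truncates at the window's
    right edge, and divides by the window width so a curve with sensitivity
    1 throughout scores 1.
    """
    width = 1.0 - spec_floor
    if width <= 0:
        raise ValueError("spec_floor must be < 1")
    pts = sorted(set(curve.points))
    if not pts:
        return 0.0
    if pts[0][0] > 0:
        pts.insert(0, (0.0, 0.0))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if xs[-1] < width:
        # extend flat to the window edge at the last attained sensitivity
        xs = np.append(xs, width)
        ys = np.append(ys, ys[-1])
    grid = np.clip(xs, 0, width)
    area = float(np.trapezoid(np.interp(grid, xs, ys), grid))
    return area / width


def signature_roc_permutation_p(
    network,
    seed_gene: str,
    signature: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    max_radius: int = 10,
) -> float:
    """Empirical p for the signature pAUC under node-label permutation."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    g = _graph_of(network)
    observed = signature_roc(network, seed_gene, signature, max_radius=max_radius).pauc
    nodes = list(g.nodes)
    sig = set(signature)
    rng = np.random.default_rng(seed)
    # permuting node labels and keeping the signature fixed is equivalent to
    # permuting which nodes carry signature membership; relabel the graph.
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        permuted = nx.relabel_nodes(g, mapping, copy=True)
        new_seed = mapping[seed_gene]
        pauc = signature_roc(permuted, new_seed, sig, max_radius=max_radius).pauc
        if pauc >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def skeleton_precision_recall(
    learned_edges: Iterable[tuple[str, str]],
    true_edges: Iterable[tuple[str, str]],
) -> tuple[float, float]:
    """Undirected precision/recall of a learned edge set vs ground truth."""
    learned = {frozenset(e) for e in learned_edges}
    truth = {frozenset(e) for e in true_edges}
    if not learned:
        return 0.0, 0.0
    tp = len(learned & truth)
    return tp / len(learned), tp / len(truth) if truth else 0.0


def edge_recovery_auprc(
    network: ConsensusNetwork,
    true_edges: Iterable[tuple[str, str]],
    nodes: Sequence[str],
) -> float:
    """Area under precision-recall for ranking undirected gene pairs by
    consensus support (max of the two directed frequencies; 0 if absent)."""
    truth = {frozenset(e) for e in true_edges}
    freq: dict[frozenset[str], float] = {}
    for (u, v), f in network.edges.items():
        key = frozenset((u, v))
        freq[key] = max(freq.get(key, 0.0), f)
    labels, scores = [], []
    nodes = list(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = frozenset((nodes[i], nodes[j]))
            labels.append(1 if pair in truth else 0)
            scores.append(freq.get(pair, 0.0))
    return float(average_precision_score(labels, scores))
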
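"""Bayesian-network structure learning with copy-number priors.

The learner is score-based: each gene's discretized expression (3 states)
is scored against candidate parent sets with the BDeu marginal likelihood,
a structure prior nudges edge direction using cis-CNA flags (copy number is
causally upstream of expression, so a cis gene makes a credible regulator
and a poor target of purely transcriptional regulation), and simulated
annealing over single-edge moves explores the DAG space. A consensus
network keeps the edges that recur across independent restarts and then
removes any residual directed cycles, weakest edge first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "StructureSample",
    "ConsensusNetwork",
    "local_score",
    "edge_prior",
    "search_structure",
    "build_consensus",
    "resolve_cycles",
    "learn_consensus",
]

N_STATES = 3


@dataclass(frozen=True)
class StructureSample:
    """One learned structure: the best DAG visited by one annealing run."""

    edges: frozenset[tuple[str, str]]
    seed: int
    score: float
    #: best-so-far total score after each accepted improvement
    trace: tuple[float, ...] = ()


@dataclass
class ConsensusNetwork:
    """Consensus over structure samples: edges above a support threshold.

    ``graph`` is a directed graph whose edges carry a ``frequency``
    attribute (fraction of restarts containing the edge); guaranteed
    acyclic after :func:`resolve_cycles`.
    """

    graph: nx.DiGraph
    cis_genes: frozenset[str] = frozenset()
    removed_edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return {
            (u, v): d.get("frequency", 1.0) for u, v, d in self.graph.edges(data=True)
        }


def _encode(data: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    mat = data.to_numpy(dtype=np.int64)
    if mat.min() < 0 or mat.max() >= N_STATES:
        raise ValueError("discrete data must take values in {0,1,2}")
    return mat, {g: i for i, g in enumerate(data.index)}


def _bdeu(mat: np.ndarray, t: int, parents: tuple[int, ...], ess: float) -> float:
    q = N_STATES ** len(parents)
    a_j = ess / q
    a_jk = ess / (q * N_STATES)
    if parents:
        cfg = np.zeros(mat.shape[1], dtype=np.int64)
        for k, p in enumerate(parents):
            cfg += mat[p] * (N_STATES**k)
        counts = np.bincount(cfg * N_STATES + mat[t], minlength=q * N_STATES)
    else:
        counts = np.bincount(mat[t], minlength=N_STATES)
    counts = counts.reshape(q, N_STATES)
    n_j = counts.sum(axis=1)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )
    return score


def local_score(
    target: str,
    parents: Iterable[str],
    data: pd.DataFrame,
    ess: float = 1.0,
) -> float:
    """BDeu local marginal log-likelihood of ``target`` given ``parents``.

    With q parent configurations and r = 3 states the Dirichlet
    hyperparameters are alpha_jk = ess / (q r); the score is
    ``sum_j [ lgamma(a_j) - lgamma(a_j + N_j) ] +
    sum_jk [ lgamma(a_jk + N_jk) - lgamma(a_jk) ]``.
    """
    mat, idx = _encode(data)
    if target not in idx:
        raise KeyError(target)
    ptup = tuple(sorted(idx[p] for p in parents))
    for p in parents:
        if p not in idx:
            raise KeyError(p)
        if p == target:
            raise ValueError("target cannot be its own parent")
    return _bdeu(mat, idx[target], ptup, ess)


def edge_prior(
    regulator: str,
    target: str,
    cis_flags: Iterable[str],
    k_bonus: float = 10.0,
    k_penalty: float = 0.1,
) -> float:
    """Log structure-prior increment for a directed edge.

    A cis-flagged regulator earns ``log(k_bonus)`` (genetics points
    downstream); a cis-flagged target with a non-cis regulator pays
    ``log(k_penalty)`` (expression should not explain a genetics-anchored
    node). All other edges are prior-neutral.
    """
    cis = set(cis_flags)
    if regulator in cis:
        return math.log(k_bonus)
    if target in cis:
        return math.log(k_penalty)
    return 0.0


class _SearchState:
    """Mutable DAG + incremental scoring for the annealing loop."""

    def __init__(self, mat: np.ndarray, ess: float, prior: np.ndarray):
        self.mat = mat
        self.n = mat.shape[0]
        self.ess = ess
        self.prior = prior  # (n, n) log-prior increments, prior[u, v] for u->v
        self.parents: list[set[int]] = [set() for _ in range(self.n)]
        self.children: list[set[int]] = [set() for _ in range(self.n)]
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self.node_score = np.array(
            [self._score(t, ()) for t in range(self.n)], dtype=float
        )
        self.prior_total = 0.0

    def _score(self, t: int, parents: tuple[int, ...]) -> float:
        key = (t, parents)
        val = self.cache.get(key)
        if val is None:
            val = _bdeu(self.mat, t, parents, self.ess)
            self.cache[key] = val
        return val

    def total(self) -> float:
        return float(self.node_score.sum()) + self.prior_total

    def path_exists(self, src: int, dst: int, skip: tuple[int, int] | None = None) -> bool:
        """DFS for a directed path src ~> dst, optionally ignoring one edge."""
        if src == dst:
            return True
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for w in self.children[u]:
                if skip is not None and (u, w) == skip:
                    continue
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def delta_add(self, u: int, v: int) -> float:
        new = self._score(v, tuple(sorted(self.parents[v] | {u})))
        return new - self.node_score[v] + self.prior[u, v]

    def apply_add(self, u: int, v: int) -> None:
        self.parents[v].add(u)
        self.children[u].add(v)
        self.node_score[v] = self._score(v, tuple(sorted(self.parents[v])))
        self.prior_total += self.prior[u, v]

    def delta_delete(self, u: int, v: int) -> float:
        new = self._score(v, tuple(sorted(self.parents[v] - {u})))
        return new - self.node_score[v] - self.prior[u, v]

    def apply_delete(self, u: int, v: int) -> None:
        self.parents[v].discard(u)
        self.children[u].discard(v)
        self.node_score[v] = self._score(v, tuple(sorted(self.parents[v])))
        self.prior_total -= self.prior[u, v]

    def edge_list(self) -> list[tuple[int, int]]:
        return [(u, v) for v in range(self.n) for u in self.parents[v]]


def search_structure(
    data: pd.DataFrame,
    cis_flags: Iterable[str] = (),
    max_parents: int = 3,
    n_steps: int = 30000,
    t_initial: float = 2.0,
    t_final: float = 0.05,
    seed: int = 0,
    ess: float = 1.0,
    use_priors: bool = True,
    k_bonus: float = 10.0,
    k_penalty: float = 0.1,
) -> StructureSample:
    """Simulated-annealing search for a high-scoring DAG.

    Moves are single-edge add/delete/reverse; proposals creating a cycle or
    exceeding ``max_parents`` are rejected outright, others are accepted by
    the Metropolis rule on the total (BDeu + log-prior) score under a
    geometric temperature schedule. The best-scoring structure visited is
    returned. Deterministic given the seed.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    mat, idx = _encode(data)
    genes = list(data.index)
    n = len(genes)

    prior = np.zeros((n, n))
    if use_priors:
        cis = {g for g in cis_flags if g in idx}
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                prior[u, v] = edge_prior(
                    genes[u], genes[v], cis, k_bonus=k_bonus, k_penalty=k_penalty
                )

    rng = np.random.default_rng(seed)
    state = _SearchState(mat, ess, prior)
    temps = t_initial * (t_final / t_initial) ** (np.arange(n_steps) / max(n_steps - 1, 1))
    move_draw = rng.random(n_steps)
    pair_draw = rng.integers(0, n, size=(n_steps, 2))
    accept_draw = rng.random(n_steps)

    best_edges = frozenset()
    best_score = state.total()
    trace = [best_score]

    for step in range(n_steps):
        t_now = temps[step]
        mtype = move_draw[step]
        if mtype < 0.5:  # add
            u, v = int(pair_draw[step, 0]), int(pair_draw[step, 1])
            if u == v or u in state.parents[v]:
                continue
            if len(state.parents[v]) >= max_parents:
                continue
            if state.path_exists(v, u):
                continue
            delta = state.delta_add(u, v)
            if delta >= 0 or accept_draw[step] < math.exp(delta / t_now):
                state.apply_add(u, v)
        else:
            edges = state.edge_list()
            if not edges:
                continue
            u, v = edges[int(pair_draw[step, 0]) % len(edges)]
            if mtype < 0.75:  # delete
                delta = state.delta_delete(u, v)
                if delta >= 0 or accept_draw[step] < math.exp(delta / t_now):
                    state.apply_delete(u, v)
            else:  # reverse
                if len(state.parents[u]) >= max_parents:
                    continue
                if state.path_exists(u, v, skip=(u, v)):
                    continue
                delta = state.delta_delete(u, v) + (
                    state._score(u, tuple(sorted(state.parents[u] | {v})))
                    - state.node_score[u]
                    + state.prior[v, u]
                )
                if delta >= 0 or accept_draw[step] < math.exp(delta / t_now):
                    state.apply_delete(u, v)
                    state.apply_add(v, u)
        current = state.total()
        if current > best_score:
            best_score = current
            best_edges = frozenset(
                (genes[u], genes[v]) for u, v in state.edge_list()
            )
            trace.append(best_score)

    return StructureSample(
        edges=best_edges, seed=seed, score=float(best_score), trace=tuple(trace)
    )


def build_consensus(
    samples: Sequence[StructureSample],
    consensus_threshold: float = 0.3,
    nodes: Sequence[str] | None = None,
    cis_flags: Iterable[str] = (),
) -> ConsensusNetwork:
    """Keep edges present in at least ``consensus_threshold`` of samples,
    then resolve any directed cycles (weakest edge first)."""
    if not samples:
        raise ValueError("need at least one structure sample")
    if not 0 < consensus_threshold <= 1:
        raise ValueError("consensus_threshold must lie in (0, 1]")
    counts: dict[tuple[str, str], int] = {}
    for s in samples:
        for e in s.edges:
            counts[e] = counts.get(e, 0) + 1
    graph = nx.DiGraph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for (u, v), c in counts.items():
        freq = c / len(samples)
        if freq >= consensus_threshold:
            graph.add_edge(u, v, frequency=freq)
    net = resolve_cycles(graph)
    net.cis_genes = frozenset(cis_flags)
    for g in net.graph.nodes:
        net.graph.nodes[g]["cis"] = g in net.cis_genes
    return net


def resolve_cycles(graph: nx.DiGraph) -> ConsensusNetwork:
    """Delete the minimum-frequency edge on some directed cycle until acyclic.

    Ties break on the lexicographically smallest (regulator, target) pair.
    Deleted edges are recorded on the returned network.
    """
    g = graph.copy()
    removed: list[tuple[str, str, float]] = []
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        victim = min(
            ((u, v) for u, v, _ in cycle),
            key=lambda e: (g.edges[e].get("frequency", 1.0), e),
        )
        removed.append((victim[0], victim[1], g.edges[victim].get("frequency", 1.0)))
        g.remove_edge(*victim)
    return ConsensusNetwork(graph=g, removed_edges=removed)


def learn_consensus(
    data: pd.DataFrame,
    cis_flags: Iterable[str] = (),
    n_restarts: int = 20,
    consensus_threshold: float = 0.3,
    seed: int = 0,
    **search_kwargs,
) -> ConsensusNetwork:
    """Run ``n_restarts`` independent annealing searches and take consensus.

    Restart seeds are ``seed + k`` for k in 0..n_restarts-1.
    """
    cis = list(cis_flags)
    samples = [
        search_structure(data, cis_flags=cis, seed=seed + k, **search_kwargs)
        for k in range(n_restarts)
    ]
    return build_consensus(
        samples,
        consensus_threshold=consensus_threshold,
        nodes=list(data.index),
        cis_flags=[g for g in cis if g in set(data.index)],
    )
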
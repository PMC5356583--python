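"""Synthetic ground truth and coupled omics data.

Everything downstream of this module (discretization, structure search,
driver calling, survival screens) is exercised against data produced here,
so each generator is a pure function of its arguments including the seed.

The generative model is deliberately simple and fully known:

* a sparse causal DAG with a few hub regulators,
* per-sample copy-number log-ratios that are constant within contiguous
  genomic blocks (the co-localization confound that motivates using
  copy number as a causal anchor),
* linear-Gaussian structural equations for expression, with cis genes
  additionally driven by their own copy number,
* exponential proportional-hazards recurrence times coupled to a set of
  driver genes, with independent exponential censoring,
* a tissue atlas with planted tissue-specific genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CausalNetwork",
    "TissueMatrix",
    "generate_ground_truth_dag",
    "simulate_cna",
    "simulate_expression",
    "simulate_bcr",
    "make_tissue_fixture",
]


@dataclass
class CausalNetwork:
    """Ground-truth directed acyclic regulatory network.

    Parameters
    ----------
    genes
        Gene identifiers; list order doubles as genomic order for
        copy-number block simulation.
    edges
        Mapping ``(regulator, target) -> signed effect size``.
    cis_effects
        Mapping ``gene -> cis effect size`` for the subset of genes whose
        expression is driven by their own copy number.
    seed
        Seed the network was generated with (provenance only).
    """

    genes: list[str]
    edges: dict[tuple[str, str], float]
    cis_effects: dict[str, float]
    seed: int
    #: designated hub regulators (source-side, high fan-out)
    hubs: list[str] = field(default_factory=list)

    @property
    def cis_genes(self) -> list[str]:
        return [g for g in self.genes if g in self.cis_effects]

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.to_digraph()))

    def validate(self) -> None:
        gene_set = set(self.genes)
        for u, v in self.edges:
            if u not in gene_set or v not in gene_set:
                raise ValueError(f"edge endpoint not in gene list: {(u, v)}")
        if not set(self.cis_effects) <= gene_set:
            raise ValueError("cis genes must be a subset of genes")
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise ValueError("edge set contains a directed cycle")


@dataclass
class TissueMatrix:
    """Gene-by-tissue expression atlas with known planted specificity."""

    expression: pd.DataFrame
    #: planted truth: gene -> tissue it is specific to
    specific: dict[str, str] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return list(self.expression.columns)


def _check_finite_scalar(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def generate_ground_truth_dag(
    n_genes: int,
    n_hubs: int,
    mean_out_degree: float,
    frac_cis: float,
    seed: int,
    hub_boost: float = 10.0,
) -> CausalNetwork:
    """Sample a random DAG with hub-biased connectivity and cis flags.

    A random permutation of the genes fixes a topological order; each
    ordered pair (earlier regulator, later target) receives an edge with
    probability proportional to a per-regulator attachment weight
    (``hub_boost`` for hubs, 1 otherwise), scaled so the expected edge
    count is ``mean_out_degree * n_genes``. Hub genes are drawn from the
    source-side third of the causal order so that they act as master
    regulators with a substantial downstream cascade rather than terminal
    nodes. Edge effect sizes are signed with magnitude uniform on
    [0.5, 1.5] *per standard deviation of the regulator*: the stored weight
    is the drawn magnitude divided by the regulator's analytic marginal SD
    (computed in topological order for unit-variance noise and copy-number
    input). This keeps per-gene marginal variance bounded along regulatory
    cascades, as in real log-expression data, instead of letting variance
    accumulate without limit. ``round(frac_cis * n_genes)`` genes get a
    positive cis effect uniform on [0.5, 1.5].
    """
    if not isinstance(n_genes, (int, np.integer)) or n_genes < 5:
        raise ValueError("n_genes must be an integer >= 5")
    if not 0 <= n_hubs < n_genes:
        raise ValueError("n_hubs must satisfy 0 <= n_hubs < n_genes")
    _check_finite_scalar("mean_out_degree", mean_out_degree)
    if mean_out_degree < 0:
        raise ValueError("mean_out_degree must be >= 0")
    _check_finite_scalar("frac_cis", frac_cis)
    if not 0.0 < frac_cis < 1.0:
        raise ValueError("frac_cis must lie in (0, 1)")
    if hub_boost < 1:
        raise ValueError("hub_boost must be >= 1")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    order = list(rng.permutation(n_genes))
    # hubs sit in the source-side third of the causal order
    n_top = max(n_hubs, math.ceil(n_genes / 3))
    hub_positions = rng.choice(n_top, size=n_hubs, replace=False)
    hubs = {order[i] for i in hub_positions}

    n_cis = int(round(frac_cis * n_genes))
    cis_idx = rng.choice(n_genes, size=n_cis, replace=False)
    cis_effects = {
        genes[i]: float(rng.uniform(0.5, 1.5)) for i in sorted(cis_idx.tolist())
    }

    edges: dict[tuple[str, str], float] = {}
    target_edges = mean_out_degree * n_genes
    if target_edges > 0:
        # attachment weight per ordered pair, regulator earlier in order
        pairs = [
            (i, j) for i in range(n_genes) for j in range(i + 1, n_genes)
        ]
        pair_w = np.array(
            [hub_boost if order[i] in hubs else 1.0 for i, _ in pairs]
        )
        probs = np.minimum(target_edges * pair_w / pair_w.sum(), 1.0)
        draws = rng.random(len(probs)) < probs
        signs = rng.choice([-1.0, 1.0], size=len(probs))
        mags = rng.uniform(0.5, 1.5, size=len(probs))
        raw = {
            pairs[k]: float(signs[k] * mags[k])
            for k in range(len(pairs))
            if draws[k]
        }
        # analytic marginal variance per gene (unit-variance noise and CNA
        # input); weights are scaled to effects per SD of the regulator
        var = np.ones(n_genes)
        for j in range(n_genes):
            gene_j = genes[order[j]]
            v_j = 1.0 + cis_effects.get(gene_j, 0.0) ** 2
            for i in range(j):
                s = raw.get((i, j))
                if s is not None:
                    w = s / math.sqrt(var[i])
                    edges[(genes[order[i]], gene_j)] = w
                    v_j += w * w * var[i]
            var[j] = v_j

    net = CausalNetwork(
        genes=genes,
        edges=edges,
        cis_effects=cis_effects,
        seed=seed,
        hubs=sorted(genes[i] for i in hubs),
    )
    net.validate()
    return net


def cna_block_partition(
    genes: Sequence[str], mean_block_len: float, seed: int
) -> list[list[str]]:
    """Partition genes (in list order = genomic order) into contiguous blocks.

    Block lengths are drawn iid from 1 + Poisson(mean_block_len - 1), so the
    partition is deterministic given the seed and independent of the number
    of samples simulated on top of it.
    """
    if mean_block_len < 1:
        raise ValueError("mean_block_len must be >= 1")
    rng = np.random.default_rng(seed)
    blocks: list[list[str]] = []
    i = 0
    while i < len(genes):
        length = 1 + int(rng.poisson(mean_block_len - 1))
        blocks.append(list(genes[i : i + length]))
        i += length
    return blocks


def simulate_cna(
    truth: CausalNetwork,
    n_samples: int,
    segment_sd: float,
    seed: int,
    mean_block_len: float = 5.0,
    return_blocks: bool = False,
):
    """Per-sample segmental copy-number log-ratios.

    Genes are partitioned into contiguous blocks (in ``truth.genes`` order);
    within one sample every gene in a block shares a single
    Normal(0, segment_sd) draw, emulating co-localized gains/losses.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    _check_finite_scalar("segment_sd", segment_sd)
    if segment_sd <= 0:
        raise ValueError("segment_sd must be > 0")

    blocks = cna_block_partition(truth.genes, mean_block_len, seed)
    rng = np.random.default_rng(seed + 1)
    samples = [f"S{j:04d}" for j in range(n_samples)]
    values = np.empty((len(truth.genes), n_samples))
    row = 0
    for block in blocks:
        block_vals = rng.normal(0.0, segment_sd, size=n_samples)
        values[row : row + len(block), :] = block_vals
        row += len(block)
    cna = pd.DataFrame(values, index=list(truth.genes), columns=samples)
    if return_blocks:
        return cna, blocks
    return cna


def simulate_expression(
    truth: CausalNetwork,
    cna: pd.DataFrame,
    noise_sd: float | Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Linear-Gaussian structural equations evaluated in topological order.

    ``expr(g) = sum_parents w * expr(parent) + cis_effect(g) * cna(g)
    + Normal(0, noise_sd)``; the cis term applies only to cis-flagged genes.
    ``noise_sd`` may be a scalar (shared by all genes) or a per-gene mapping.
    """
    if isinstance(noise_sd, Mapping) or isinstance(noise_sd, pd.Series):
        sd_of = {g: float(noise_sd[g]) for g in truth.genes}
    else:
        _check_finite_scalar("noise_sd", noise_sd)
        sd_of = {g: float(noise_sd) for g in truth.genes}
    if any(not math.isfinite(s) or s <= 0 for s in sd_of.values()):
        raise ValueError("noise_sd must be > 0 for every gene")
    missing = set(truth.genes) - set(cna.index)
    if missing:
        raise ValueError(f"cna matrix missing genes: {sorted(missing)[:5]} ...")

    rng = np.random.default_rng(seed)
    samples = list(cna.columns)
    n = len(samples)
    expr: dict[str, np.ndarray] = {}
    parents_of: dict[str, list[tuple[str, float]]] = {g: [] for g in truth.genes}
    for (u, v), w in truth.edges.items():
        parents_of[v].append((u, w))

    for g in truth.topological_order():
        vals = rng.normal(0.0, sd_of[g], size=n)
        for parent, w in parents_of[g]:
            if parent not in expr:  # must be impossible under a valid DAG
                raise RuntimeError(f"parent {parent} evaluated after child {g}")
            vals = vals + w * expr[parent]
        if g in truth.cis_effects:
            vals = vals + truth.cis_effects[g] * cna.loc[g].to_numpy()
        expr[g] = vals

    mat = pd.DataFrame(
        np.vstack([expr[g] for g in truth.genes]),
        index=list(truth.genes),
        columns=samples,
    )
    return mat


def simulate_bcr(
    expression: pd.DataFrame,
    driver_genes: Sequence[str],
    log_hr: float | Sequence[float],
    baseline_rate: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential proportional-hazards recurrence with exponential censoring.

    The linear predictor is ``sum_i log_hr_i * z(expression of driver_i)``;
    failure times are Exponential(baseline_rate * exp(lp)), censoring times
    Exponential(censor_rate) (no censoring when ``censor_rate == 0``).

    Returns a data frame indexed by sample with columns ``time`` (months)
    and ``event`` (1 = recurrence observed).
    """
    drivers = list(driver_genes)
    missing = set(drivers) - set(expression.index)
    if missing:
        raise ValueError(f"driver genes absent from expression: {sorted(missing)}")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    if np.isscalar(log_hr):
        log_hrs = [float(log_hr)] * len(drivers)
    else:
        log_hrs = [float(b) for b in log_hr]
        if len(log_hrs) != len(drivers):
            raise ValueError("log_hr length must match driver_genes")

    rng = np.random.default_rng(seed)
    n = expression.shape[1]
    lp = np.zeros(n)
    for g, b in zip(drivers, log_hrs):
        x = expression.loc[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"driver {g} has zero expression variance")
        lp += b * (x - x.mean()) / sd

    rates = baseline_rate * np.exp(lp)
    fail = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        cens = np.full(n, np.inf)
    time = np.minimum(fail, cens)
    event = (fail <= cens).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event}, index=list(expression.columns)
    ).rename_axis("sample")


def make_tissue_fixture(
    n_genes: int,
    tissues: Sequence[str],
    n_specific_per_tissue: int,
    fold: float,
    seed: int,
) -> TissueMatrix:
    """Flat atlas (baseline 1.0) with planted tissue-specific genes at `fold`.

    The first ``n_specific_per_tissue * len(tissues)`` genes are assigned
    round-robin to tissues after a seeded shuffle of the gene order, so the
    planted truth is deterministic and non-overlapping by construction.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    if n_specific_per_tissue * len(tissues) > n_genes:
        raise ValueError("more planted specific genes than genes")
    if fold <= 1:
        raise ValueError("fold must be > 1")

    rng = np.random.default_rng(seed)
    genes = [f"T{i:04d}" for i in range(n_genes)]
    shuffled = list(rng.permutation(genes))
    expr = pd.DataFrame(1.0, index=genes, columns=tissues)
    specific: dict[str, str] = {}
    k = 0
    for tissue in tissues:
        for _ in range(n_specific_per_tissue):
            g = shuffled[k]
            expr.loc[g, tissue] = fold
            specific[g] = tissue
            k += 1
    return TissueMatrix(expression=expr, specific=specific)
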
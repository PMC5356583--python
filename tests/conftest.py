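import numpy as np
import pandas as pd
import pytest

from imbnet import preprocess, synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A 50-gene ground-truth network at the benchmark scale."""
    return synthetic.generate_ground_truth_dag(
        n_genes=50, n_hubs=3, mean_out_degree=1.5, frac_cis=0.2, seed=11
    )


@pytest.fixture(scope="session")
def small_omics(small_truth):
    """Coupled CNA + expression matrices for the 50-gene truth (n=200)."""
    cna = synthetic.simulate_cna(small_truth, n_samples=200, segment_sd=1.0, seed=11)
    expr = synthetic.simulate_expression(small_truth, cna, noise_sd=1.0, seed=12)
    return expr, cna


@pytest.fixture(scope="session")
def small_discrete(small_omics):
    expr, _ = small_omics
    return preprocess.discretize_expression(expr)


def random_dag(n, p, seed):
    """Independent-edge random DAG over a fixed topological order."""
    rng = np.random.default_rng(seed)
    genes = [f"N{i}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(genes[i], genes[j])] = 1.0
    return genes, edges
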
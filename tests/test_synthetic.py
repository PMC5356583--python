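"""Generators: determinism, graph sanity, and closed-form recoveries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imbnet import synthetic
from imbnet.synthetic import (
    CausalNetwork,
    generate_ground_truth_dag,
    make_tissue_fixture,
    simulate_bcr,
    simulate_cna,
    simulate_expression,
)


def has_cycle_dfs(genes, edges):
    """Independent cycle detector (iterative DFS, three-color)."""
    children = {g: [] for g in genes}
    for u, v in edges:
        children[u].append(v)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {g: WHITE for g in genes}
    for start in genes:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(children[start]))]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    return True
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(children[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return False


class TestGroundTruthDag:
    def test_zero_density_gives_no_edges_and_one_cis(self):
        net = generate_ground_truth_dag(5, 1, 0.0, 0.2, seed=1)
        assert len(net.edges) == 0
        assert len(net.cis_genes) == 1

    def test_edge_count_near_expectation_and_acyclic(self):
        net = generate_ground_truth_dag(50, 3, 1.5, 0.3, seed=7)
        # expected 75 edges; allow ~4 binomial SDs
        assert 40 <= len(net.edges) <= 110
        assert len(net.cis_genes) == 15
        assert not has_cycle_dfs(net.genes, net.edges)

    def test_determinism(self):
        a = generate_ground_truth_dag(50, 3, 1.5, 0.3, seed=7)
        b = generate_ground_truth_dag(50, 3, 1.5, 0.3, seed=7)
        assert a.edges == b.edges
        assert a.cis_effects == b.cis_effects
        c = generate_ground_truth_dag(50, 3, 1.5, 0.3, seed=8)
        assert c.edges != a.edges

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 4},
            {"n_hubs": 50},
            {"mean_out_degree": -1.0},
            {"mean_out_degree": float("nan")},
            {"frac_cis": 0.0},
            {"frac_cis": 1.0},
            {"frac_cis": float("inf")},
        ],
    )
    def test_parameter_validation(self, kwargs):
        base = dict(n_genes=50, n_hubs=3, mean_out_degree=1.0, frac_cis=0.2, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_ground_truth_dag(**base)

    def test_acyclic_over_many_seeds(self):
        for seed in range(30):
            net = generate_ground_truth_dag(30, 2, 2.0, 0.2, seed=seed)
            assert not has_cycle_dfs(net.genes, net.edges)

    def test_hubs_recorded_and_high_fanout(self):
        net = generate_ground_truth_dag(50, 3, 1.5, 0.2, seed=3)
        assert len(net.hubs) == 3
        outdeg = {}
        for u, _ in net.edges:
            outdeg[u] = outdeg.get(u, 0) + 1
        hub_deg = np.mean([outdeg.get(h, 0) for h in net.hubs])
        other = [outdeg.get(g, 0) for g in net.genes if g not in net.hubs]
        assert hub_deg > np.mean(other)


class TestSimulateCna:
    def test_same_block_equal_and_cross_block_uncorrelated(self, small_truth):
        cna, blocks = simulate_cna(
            small_truth, n_samples=200, segment_sd=1.0, seed=5, return_blocks=True
        )
        multi = [b for b in blocks if len(b) >= 2]
        assert multi, "partition should contain multi-gene blocks"
        g1, g2 = multi[0][0], multi[0][1]
        assert np.array_equal(cna.loc[g1].values, cna.loc[g2].values)
        # across blocks: near-zero correlation
        a, b = blocks[0][0], blocks[1][0]
        r = np.corrcoef(cna.loc[a], cna.loc[b])[0, 1]
        assert abs(r) < 0.2

    def test_vanishing_variance_limit(self, small_truth):
        cna = simulate_cna(small_truth, n_samples=10, segment_sd=1e-12, seed=0)
        assert np.allclose(cna.values, 0.0, atol=1e-9)

    def test_invalid_segment_sd_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate_cna(small_truth, n_samples=10, segment_sd=-1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_cna(small_truth, n_samples=10, segment_sd=0.0, seed=0)

    def test_determinism(self, small_truth):
        a = simulate_cna(small_truth, 20, 1.0, seed=9)
        b = simulate_cna(small_truth, 20, 1.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


def _manual_net(edges, cis=None, genes=None):
    gene_set = sorted({g for e in edges for g in e} | set(genes or []) | set(cis or {}))
    return CausalNetwork(
        genes=gene_set, edges=dict(edges), cis_effects=dict(cis or {}), seed=0
    )


class TestSimulateExpression:
    def test_orphan_gene_marginal_sd(self):
        net = _manual_net({}, genes=[f"G{i}" for i in range(5)])
        cna = pd.DataFrame(0.0, index=net.genes, columns=[f"S{i}" for i in range(500)])
        expr = simulate_expression(net, cna, noise_sd=1.0, seed=2)
        sd = expr.loc["G0"].std()
        assert 0.8 < sd < 1.2

    def test_chain_correlation_matches_closed_form(self):
        # R^2 = w^2 var(A) / (w^2 var(A) + sigma^2) -> corr > 0.95
        net = _manual_net({("A", "B"): 1.0})
        cna = pd.DataFrame(0.0, index=net.genes, columns=[f"S{i}" for i in range(500)])
        expr = simulate_expression(net, cna, noise_sd={"A": 1.0, "B": 0.1}, seed=3)
        r = np.corrcoef(expr.loc["A"], expr.loc["B"])[0, 1]
        assert r > 0.95

    def test_cis_gene_tracks_copy_number(self):
        net = _manual_net({}, cis={"A": 1.0}, genes=["A", "B"])
        rng = np.random.default_rng(0)
        cna = pd.DataFrame(
            rng.normal(0, 1.0, size=(2, 500)),
            index=["A", "B"],
            columns=[f"S{i}" for i in range(500)],
        )
        expr = simulate_expression(net, cna, noise_sd=1.0, seed=4)
        r = np.corrcoef(cna.loc["A"], expr.loc["A"])[0, 1]
        assert r > 0.5

    def test_rejects_bad_noise_and_missing_genes(self, small_truth):
        cna = simulate_cna(small_truth, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_expression(small_truth, cna, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_expression(small_truth, cna.iloc[:10], noise_sd=1.0, seed=0)


class TestSimulateBcr:
    def test_null_pvalues_uniform(self):
        """With no coupled driver, per-gene Cox p-values are uniform."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(size=(200, 300)),
            index=[f"G{i}" for i in range(200)],
            columns=[f"S{i}" for i in range(300)],
        )
        surv = simulate_bcr(expr, [], 0.0, baseline_rate=0.02, censor_rate=0.01, seed=1)
        pvals = []
        base = surv[["time", "event"]]
        for g in expr.index:
            df = base.copy()
            df["x"] = expr.loc[g].values
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            pvals.append(float(cph.summary.loc["x", "p"]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_driver_coefficient_recovery(self):
        """Planted log-HR 1 on one driver is recovered by a Cox fit
        (median over 5 seeds within [0.7, 1.3])."""
        from lifelines import CoxPHFitter

        coefs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            expr = pd.DataFrame(
                rng.normal(size=(5, 400)),
                index=[f"G{i}" for i in range(5)],
                columns=[f"S{i}" for i in range(400)],
            )
            surv = simulate_bcr(
                expr, ["G0"], 1.0, baseline_rate=0.02, censor_rate=0.005, seed=seed
            )
            df = surv[["time", "event"]].copy()
            df["x"] = expr.loc["G0"].values
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            coefs.append(float(cph.params_["x"]))
        assert 0.7 <= np.median(coefs) <= 1.3

    def test_heavy_censoring_limit(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(2, 50)),
            index=["A", "B"],
            columns=[f"S{i}" for i in range(50)],
        )
        surv = simulate_bcr(expr, [], 0.0, baseline_rate=0.01, censor_rate=1e6, seed=0)
        assert surv["event"].sum() == 0

    def test_event_rate_interior_and_validation(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(size=(2, 200)),
            index=["A", "B"],
            columns=[f"S{i}" for i in range(200)],
        )
        surv = simulate_bcr(expr, ["A"], 0.5, 0.02, 0.01, seed=2)
        assert 0 < surv["event"].mean() < 1
        assert (surv["time"] > 0).all()
        assert surv.index.is_unique
        with pytest.raises(ValueError):
            simulate_bcr(expr, ["A"], 0.5, -0.1, 0.01, seed=2)
        with pytest.raises(ValueError):
            simulate_bcr(expr, ["Z"], 0.5, 0.1, 0.01, seed=2)


class TestTissueFixture:
    def test_planted_gene_peaks_in_its_tissue(self):
        atlas = make_tissue_fixture(40, ["prostate", "liver", "brain"], 2, 10.0, seed=1)
        for gene, tis in atlas.specific.items():
            assert atlas.expression.loc[gene].idxmax() == tis

    def test_nonspecific_gene_is_flat(self):
        atlas = make_tissue_fixture(40, ["prostate", "liver", "brain"], 2, 10.0, seed=1)
        flat = [g for g in atlas.expression.index if g not in atlas.specific]
        assert flat
        row = atlas.expression.loc[flat[0]]
        assert row.nunique() == 1

    def test_capacity_and_fold_validation(self):
        with pytest.raises(ValueError):
            make_tissue_fixture(5, ["a", "b", "c"], 2, 10.0, seed=0)
        with pytest.raises(ValueError):
            make_tissue_fixture(40, ["a", "b"], 2, 1.0, seed=0)
        with pytest.raises(ValueError):
            make_tissue_fixture(40, ["a"], 2, 5.0, seed=0)
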